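"""Synthetic tumor/normal cohort generator with full truth labels.

The generator emulates the statistical structure of annotated tumor-only and
tumor/paired-normal variant callsets over an exome and coding-territory gene
panels:

* an exon-like exome territory (log-normal exon lengths, median 150 bp) of a
  configurable total coding size, with panels drawn as subsets of exome exons;
* somatic variants placed uniformly at a configurable rate (v/mb of coding
  space) with allelic fractions from a single-clone diploid model,
  Beta-distributed around purity/2;
* germline variants genotyped under Hardy-Weinberg from a shared population
  pool (database-known, high population MAF) plus per-sample private variants
  (absent from the germline resource) that tumor-only filtering cannot remove;
* FFPE-like artifacts: C:G>T:A, low VAF, strand-skewed, tumor-only;
* negative-binomial per-block coverage, independently re-drawn per assay;
* a panel of normals genotyped from the same population pool.

Every emitted call maps to exactly one truth entry (somatic / germline /
artifact), so every pipeline stage can be validated by truth accounting.
All randomness flows from per-(seed, sample, purpose) streams, so cohorts are
extensible without perturbing existing samples.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    CoverageProfile,
    PanelOfNormals,
    SampleCallset,
    Territory,
    ValidationError,
    VariantCall,
)

DEFAULT_PANEL_SPECS = (
    ("panel_A", 1.2),
    ("panel_B", 1.24),
    ("panel_C", 1.2),
    ("panel_D", 1.1),
    ("panel_E", 1.3),
)

#: pyrimidine-collapsed somatic SNV spectrum (C>T-rich, as in most tumors)
SOMATIC_SPECTRUM = {
    "C>A": 0.15, "C>G": 0.08, "C>T": 0.35, "T>A": 0.09, "T>C": 0.22, "T>G": 0.11,
}

_SBS_ALLELES = {
    "C>A": (("C", "A"), ("G", "T")),
    "C>G": (("C", "G"), ("G", "C")),
    "C>T": (("C", "T"), ("G", "A")),
    "T>A": (("T", "A"), ("A", "T")),
    "T>C": (("T", "C"), ("A", "G")),
    "T>G": (("T", "G"), ("A", "C")),
}

_INDEL_ALLELES = (("A", "AT"), ("C", "CAG"), ("TA", "T"), ("GAC", "G"))

#: class mix of non-synonymous coding variants (renormalized to 1-syn_fraction)
_NONSYN_CLASS_WEIGHTS = {
    "snv": 0.62,
    "indel": 0.12,
    "frameshift": 0.10,
    "splice": 0.10,
    "start_stop": 0.06,
}

_N_CHROMS = 8


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters of a synthetic cohort.

    ``tmb_true`` is the somatic mutation rate per coding megabase (all coding
    classes, synonymous included); ``purity`` the tumor-cell fraction, so
    clonal heterozygous somatic VAF centers on purity/2. Coverage is
    negative-binomial per ``coverage_block_bp`` block with the given mean and
    dispersion (NB size parameter). Germline heterozygous load and the
    private (database-absent) fraction control the tumor-only germline
    overhead; artifacts are C:G>T:A with VAF ~ U(0.01, 0.06) and the stated
    strand skew.
    """

    seed: int = 0
    exome_mb: float = 35.9
    panel_specs: tuple[tuple[str, float], ...] = DEFAULT_PANEL_SPECS
    tmb_true: float = 10.0
    purity: float = 0.8
    germline_het_per_exome: int = 5000
    germline_private_fraction: float = 0.03
    artifact_rate_per_mb: float = 1.0
    artifact_strand_skew: float = 0.95
    coverage_mean: float = 200.0
    coverage_dispersion: float = 10.0
    syn_fraction: float = 0.25
    n_normals_pon: int = 21
    vaf_concentration: float = 20.0
    coverage_block_bp: int = 500

    def __post_init__(self) -> None:
        if self.exome_mb <= 0:
            raise ValidationError("exome_mb must be positive")
        for name, mb in self.panel_specs:
            if mb > self.exome_mb:
                raise ValidationError(
                    f"panel {name!r} ({mb} MB) larger than exome ({self.exome_mb} MB)"
                )
        for f in (
            "tmb_true",
            "germline_het_per_exome",
            "artifact_rate_per_mb",
            "germline_private_fraction",
        ):
            if getattr(self, f) < 0:
                raise ValidationError(f"{f} must be >= 0")
        for f in (
            "purity",
            "artifact_strand_skew",
            "syn_fraction",
            "germline_private_fraction",
        ):
            if not (0.0 <= getattr(self, f) <= 1.0):
                raise ValidationError(f"{f} must be in [0,1]")
        if self.purity == 0:
            raise ValidationError("purity must be in (0,1]")


def _rng(seed: int, *key: object) -> np.random.Generator:
    entropy = [int(seed)] + [zlib.crc32(str(k).encode()) for k in key]
    return np.random.default_rng(np.random.SeedSequence(entropy))


class _TerritoryIndex:
    """Maps global base offsets in [0, total_bases) to (chrom, pos0)."""

    def __init__(self, territory: Territory):
        chroms, starts, lengths = [], [], []
        for chrom, s, e in territory.intervals:
            chroms.append(chrom)
            starts.append(s)
            lengths.append(e - s)
        self.chroms = np.array(chroms)
        self.starts = np.array(starts, dtype=np.int64)
        self.cum = np.cumsum(np.array(lengths, dtype=np.int64))
        self.total = int(self.cum[-1]) if len(self.cum) else 0

    def locate(self, offsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        i = np.searchsorted(self.cum, offsets, side="right")
        prev = np.where(i > 0, self.cum[i - 1], 0)
        return self.chroms[i], self.starts[i] + (offsets - prev)


def simulate_territories(
    cfg: SimulationConfig,
) -> tuple[Territory, list[Territory]]:
    """Exome territory plus panels as exon subsets of the stated coding sizes
    (within 1%); deterministic given the config seed."""
    rng = _rng(cfg.seed, "territories")
    target = int(cfg.exome_mb * 1e6)
    chunks, tot = [], 0
    while tot < target:
        c = np.maximum(
            30, rng.lognormal(np.log(150.0), 0.6, size=65536).astype(np.int64)
        )
        chunks.append(c)
        tot += int(c.sum())
    lengths = np.concatenate(chunks)
    n = int(np.searchsorted(np.cumsum(lengths), target)) + 1
    lengths = lengths[:n]
    gaps = rng.integers(200, 5001, size=n)
    per_chrom = int(np.ceil(n / _N_CHROMS))
    intervals = []
    for c in range(_N_CHROMS):
        lo, hi = c * per_chrom, min(n, (c + 1) * per_chrom)
        if lo >= hi:
            break
        pos = np.cumsum(gaps[lo:hi]) + np.concatenate(
            ([0], np.cumsum(lengths[lo:hi])[:-1])
        )
        chrom = f"chr{c + 1}"
        intervals.extend(
            (chrom, int(s), int(s + l)) for s, l in zip(pos, lengths[lo:hi])
        )
    exome = Territory.from_intervals("exome", intervals)

    panels = []
    n_iv = len(intervals)
    iv_len = np.array([e - s for _, s, e in intervals], dtype=np.int64)
    for name, mb in cfg.panel_specs:
        ptarget = int(mb * 1e6)
        order = rng.permutation(n_iv)
        cum = np.cumsum(iv_len[order])
        k = int(np.searchsorted(cum, ptarget)) + 1
        chosen = [intervals[j] for j in order[:k]]
        overshoot = int(cum[k - 1]) - ptarget
        if overshoot > 0:  # trim the last exon so the size is exact
            chrom, s, e = chosen[-1]
            chosen[-1] = (chrom, s, e - overshoot)
        panels.append(Territory.from_intervals(name, chosen))
    return exome, panels


# ---------------------------------------------------------------------------
# population germline pool

@dataclass
class PopulationPool:
    """Shared catalog of database-known germline sites with population MAFs."""

    chrom: np.ndarray
    pos0: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    maf: np.ndarray
    vclass: np.ndarray

    def __len__(self) -> int:
        return len(self.pos0)


def _draw_sbs_alleles(
    rng: np.random.Generator, n: int, spectrum: dict[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    classes = list(spectrum)
    probs = np.array([spectrum[c] for c in classes])
    probs = probs / probs.sum()
    idx = rng.choice(len(classes), size=n, p=probs)
    strand = rng.integers(0, 2, size=n)
    refs = np.empty(n, dtype=object)
    alts = np.empty(n, dtype=object)
    for i, (ci, si) in enumerate(zip(idx, strand)):
        refs[i], alts[i] = _SBS_ALLELES[classes[ci]][si]
    return refs, alts


def build_population_pool(
    cfg: SimulationConfig, exome: Territory
) -> PopulationPool:
    """Catalog sized so the expected per-sample heterozygous count under
    Hardy-Weinberg matches ``germline_het_per_exome``."""
    rng = _rng(cfg.seed, "population_pool")
    idx = _TerritoryIndex(exome)
    m0 = max(1000, int(cfg.germline_het_per_exome * 12))
    maf = np.exp(rng.uniform(np.log(1e-3), np.log(0.5), size=m0))
    het_p = 2 * maf * (1 - maf)
    m = int(np.searchsorted(np.cumsum(het_p), cfg.germline_het_per_exome)) + 1
    m = min(m, m0)
    maf = maf[:m]
    offsets = np.unique(rng.integers(0, idx.total, size=m))
    m = len(offsets)
    maf = maf[:m]
    chrom, pos0 = idx.locate(offsets)
    ref, alt = _draw_sbs_alleles(rng, m, {k: 1 / 6 for k in SOMATIC_SPECTRUM})
    vclass = np.where(
        rng.random(m) < cfg.syn_fraction, "synonymous", "snv"
    ).astype(object)
    return PopulationPool(
        chrom=chrom, pos0=pos0, ref=ref, alt=alt, maf=maf, vclass=vclass
    )


def _genotype_pool(
    pool: PopulationPool, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Hardy-Weinberg genotype draw: returns (het indices, hom indices)."""
    u = rng.random(len(pool))
    het = u < 2 * pool.maf * (1 - pool.maf)
    hom = u > 1 - pool.maf**2
    return np.nonzero(het)[0], np.nonzero(hom)[0]


def _germline_vafs(
    rng: np.random.Generator, n_het: int, n_hom: int
) -> np.ndarray:
    het = np.clip(rng.normal(0.5, 0.03, size=n_het), 0.35, 0.65)
    hom = np.clip(rng.normal(0.985, 0.01, size=n_hom), 0.90, 1.0)
    return np.concatenate([het, hom])


# ---------------------------------------------------------------------------
# per-sample truth generation

_TRUTH_COLUMNS = [
    "chrom", "pos0", "ref", "alt", "label", "true_vaf", "vclass",
    "splice_offset", "maf", "in_dbsnp", "skew_fwd",
]


def _somatic_truth(
    cfg: SimulationConfig,
    idx: _TerritoryIndex,
    rng: np.random.Generator,
    tmb_true: float,
) -> pd.DataFrame:
    n = rng.poisson(tmb_true * idx.total / 1e6)
    if n == 0:
        return pd.DataFrame(columns=_TRUTH_COLUMNS)
    chrom, pos0 = idx.locate(rng.integers(0, idx.total, size=n))
    mean = cfg.purity / 2
    a = cfg.vaf_concentration * mean
    b = cfg.vaf_concentration * (1 - mean)
    vaf = np.clip(rng.beta(a, b, size=n), 1e-3, 1.0)
    classes = ["synonymous"] + list(_NONSYN_CLASS_WEIGHTS)
    w = np.array(
        [cfg.syn_fraction]
        + [
            v * (1 - cfg.syn_fraction) / sum(_NONSYN_CLASS_WEIGHTS.values())
            for v in _NONSYN_CLASS_WEIGHTS.values()
        ]
    )
    vclass = np.array(classes, dtype=object)[rng.choice(len(classes), size=n, p=w)]
    ref = np.empty(n, dtype=object)
    alt = np.empty(n, dtype=object)
    snv_like = ~np.isin(vclass, ("indel", "frameshift"))
    r, a_ = _draw_sbs_alleles(rng, int(snv_like.sum()), SOMATIC_SPECTRUM)
    ref[snv_like], alt[snv_like] = r, a_
    n_indel = int((~snv_like).sum())
    pick = rng.integers(0, len(_INDEL_ALLELES), size=n_indel)
    ref[~snv_like] = [_INDEL_ALLELES[i][0] for i in pick]
    alt[~snv_like] = [_INDEL_ALLELES[i][1] for i in pick]
    splice_offset = np.full(n, np.nan)
    is_splice = vclass == "splice"
    splice_offset[is_splice] = rng.choice(
        [-2, -1, 1, 2], size=int(is_splice.sum())
    )
    return pd.DataFrame(
        {
            "chrom": chrom, "pos0": pos0, "ref": ref, "alt": alt,
            "label": "somatic", "true_vaf": vaf, "vclass": vclass,
            "splice_offset": splice_offset, "maf": np.nan,
            "in_dbsnp": False, "skew_fwd": np.nan,
        }
    )


def _germline_truth(
    cfg: SimulationConfig,
    idx: _TerritoryIndex,
    pool: PopulationPool,
    rng: np.random.Generator,
) -> pd.DataFrame:
    het_i, hom_i = _genotype_pool(pool, rng)
    sel = np.concatenate([het_i, hom_i])
    vaf = _germline_vafs(rng, len(het_i), len(hom_i))
    known = pd.DataFrame(
        {
            "chrom": pool.chrom[sel], "pos0": pool.pos0[sel],
            "ref": pool.ref[sel], "alt": pool.alt[sel],
            "label": "germline", "true_vaf": vaf, "vclass": pool.vclass[sel],
            "splice_offset": np.nan, "maf": pool.maf[sel],
            "in_dbsnp": True, "skew_fwd": np.nan,
        }
    )
    n_priv = rng.poisson(cfg.germline_private_fraction * cfg.germline_het_per_exome)
    chrom, pos0 = idx.locate(rng.integers(0, idx.total, size=n_priv))
    ref, alt = _draw_sbs_alleles(rng, n_priv, {k: 1 / 6 for k in SOMATIC_SPECTRUM})
    private = pd.DataFrame(
        {
            "chrom": chrom, "pos0": pos0, "ref": ref, "alt": alt,
            "label": "germline",
            "true_vaf": np.clip(rng.normal(0.5, 0.03, size=n_priv), 0.35, 0.65),
            "vclass": np.where(
                rng.random(n_priv) < cfg.syn_fraction, "synonymous", "snv"
            ).astype(object),
            "splice_offset": np.nan, "maf": np.nan,
            "in_dbsnp": False, "skew_fwd": np.nan,
        }
    )
    return pd.concat([known, private], ignore_index=True)


def _artifact_truth(
    cfg: SimulationConfig, idx: _TerritoryIndex, rng: np.random.Generator
) -> pd.DataFrame:
    n = rng.poisson(cfg.artifact_rate_per_mb * idx.total / 1e6)
    chrom, pos0 = idx.locate(rng.integers(0, idx.total, size=n))
    strand = rng.integers(0, 2, size=n)
    ref = np.where(strand == 0, "C", "G").astype(object)
    alt = np.where(strand == 0, "T", "A").astype(object)
    return pd.DataFrame(
        {
            "chrom": chrom, "pos0": pos0, "ref": ref, "alt": alt,
            "label": "artifact",
            "true_vaf": rng.uniform(0.01, 0.06, size=n),
            "vclass": "snv", "splice_offset": np.nan, "maf": np.nan,
            "in_dbsnp": False,
            "skew_fwd": np.where(
                rng.integers(0, 2, size=n) == 0,
                cfg.artifact_strand_skew,
                1 - cfg.artifact_strand_skew,
            ),
        }
    )


# ---------------------------------------------------------------------------
# coverage and call realization

def simulate_coverage(
    cfg: SimulationConfig,
    territory: Territory,
    rng: np.random.Generator,
    sample_id: str,
) -> CoverageProfile:
    """Negative-binomial depth per coverage block over the territory."""
    p_nb = cfg.coverage_dispersion / (cfg.coverage_dispersion + cfg.coverage_mean)
    by_chrom = {}
    block = cfg.coverage_block_bp
    for chrom in territory.chroms:
        starts, ends = territory.arrays(chrom)
        nb = np.maximum(1, np.ceil((ends - starts) / block)).astype(np.int64)
        total = int(nb.sum())
        rep_start = np.repeat(starts, nb)
        rep_end = np.repeat(ends, nb)
        j = np.arange(total) - np.repeat(np.cumsum(nb) - nb, nb)
        bs = rep_start + j * block
        be = np.minimum(bs + block, rep_end)
        depths = rng.negative_binomial(cfg.coverage_dispersion, p_nb, size=total)
        by_chrom[chrom] = (bs, be, depths.astype(np.int64))
    return CoverageProfile.from_arrays(sample_id, territory, by_chrom)


def realize_calls(
    truth: pd.DataFrame,
    cov: CoverageProfile,
    rng: np.random.Generator,
    *,
    sample_id: str,
    assay_id: str,
) -> SampleCallset:
    """Draw read support for each truth variant from the coverage profile.

    Variants with zero alt reads (or zero depth) in this assay are not
    called. VAF is the realized alt/total ratio; strand split is binomial at
    0.5 except for artifacts, which use their stored skew.
    """
    calls: list[VariantCall] = []
    if len(truth):
        for chrom, grp in truth.groupby("chrom", sort=True):
            pos0 = grp["pos0"].to_numpy(dtype=np.int64)
            depth = cov.depths_at(chrom, pos0)
            alt_n = rng.binomial(depth, grp["true_vaf"].to_numpy())
            p_fwd = np.where(
                np.isnan(grp["skew_fwd"].to_numpy()),
                0.5,
                np.nan_to_num(grp["skew_fwd"].to_numpy(), nan=0.5),
            )
            fwd = rng.binomial(alt_n, p_fwd)
            mq = rng.uniform(0.92, 1.0, size=len(grp))
            splice = grp["splice_offset"].to_numpy()
            mafs = grp["maf"].to_numpy()
            refs = grp["ref"].to_numpy()
            alts = grp["alt"].to_numpy()
            vclasses = grp["vclass"].to_numpy()
            in_db = grp["in_dbsnp"].to_numpy()
            labels = grp["label"].to_numpy()
            for k in range(len(grp)):
                if alt_n[k] == 0:
                    continue
                calls.append(
                    VariantCall(
                        chrom=chrom,
                        pos=int(pos0[k]) + 1,
                        ref=refs[k],
                        alt=alts[k],
                        total_depth=int(depth[k]),
                        alt_depth=int(alt_n[k]),
                        vaf=float(alt_n[k] / depth[k]),
                        alt_fwd=int(fwd[k]),
                        alt_rev=int(alt_n[k] - fwd[k]),
                        mq_pass_fraction=float(mq[k]),
                        variant_class=vclasses[k],
                        splice_offset=(
                            None if np.isnan(splice[k]) else int(splice[k])
                        ),
                        population_maf=(None if np.isnan(mafs[k]) else float(mafs[k])),
                        in_dbsnp=bool(in_db[k]),
                        in_cosmic=False,
                        truth_label=labels[k],
                    )
                )
    return SampleCallset(
        sample_id=sample_id, assay_id=assay_id, mode="tumor_only", calls=calls
    )


# ---------------------------------------------------------------------------
# sample / cohort assembly

@dataclass
class AssayData:
    callset: SampleCallset
    coverage: CoverageProfile


@dataclass
class SimulatedSample:
    sample_id: str
    tmb_true: float
    truth: pd.DataFrame
    assays: dict[str, AssayData] = field(default_factory=dict)
    normal: Optional[AssayData] = None

    @property
    def has_normal(self) -> bool:
        return self.normal is not None

    def truth_tmb(self, exome_mb: float) -> float:
        """Realized somatic density: placed somatic variants per coding MB."""
        return float((self.truth["label"] == "somatic").sum()) / exome_mb


def simulate_sample(
    cfg: SimulationConfig,
    exome: Territory,
    pool: PopulationPool,
    sample_id: str,
    tmb_true: Optional[float] = None,
    with_normal: bool = True,
) -> SimulatedSample:
    """Generate one sample's truth set and its exome tumor (and optionally
    normal) callsets and coverage profiles. Deterministic given (seed,
    sample_id)."""
    tmb = cfg.tmb_true if tmb_true is None else tmb_true
    idx = _TerritoryIndex(exome)
    rng = _rng(cfg.seed, "sample", sample_id)
    truth = pd.concat(
        [
            _somatic_truth(cfg, idx, rng, tmb),
            _germline_truth(cfg, idx, pool, rng),
            _artifact_truth(cfg, idx, rng),
        ],
        ignore_index=True,
    )
    truth = truth.drop_duplicates(subset=["chrom", "pos0", "ref", "alt"])
    truth = truth.sort_values(["chrom", "pos0", "ref", "alt"], ignore_index=True)

    cov = simulate_coverage(cfg, exome, _rng(cfg.seed, "cov", sample_id, "exome"), sample_id)
    tumor = realize_calls(
        truth, cov, _rng(cfg.seed, "calls", sample_id, "exome"),
        sample_id=sample_id, assay_id="exome",
    )
    sample = SimulatedSample(
        sample_id=sample_id,
        tmb_true=tmb,
        truth=truth,
        assays={"exome": AssayData(callset=tumor, coverage=cov)},
    )
    if with_normal:
        germ = truth[truth["label"] == "germline"].copy()
        # the normal's own allelic fractions are re-jittered independently
        nrng = _rng(cfg.seed, "normal", sample_id)
        n_het = int((germ["true_vaf"] < 0.8).sum())
        n_hom = len(germ) - n_het
        vafs = np.empty(len(germ))
        het_mask = (germ["true_vaf"] < 0.8).to_numpy()
        vafs[het_mask] = np.clip(nrng.normal(0.5, 0.03, size=n_het), 0.35, 0.65)
        vafs[~het_mask] = np.clip(nrng.normal(0.985, 0.01, size=n_hom), 0.90, 1.0)
        germ["true_vaf"] = vafs
        ncov = simulate_coverage(
            cfg, exome, _rng(cfg.seed, "cov", sample_id, "normal"), sample_id + "_N"
        )
        ncalls = realize_calls(
            germ, ncov, _rng(cfg.seed, "calls", sample_id, "normal"),
            sample_id=sample_id + "_N", assay_id="exome",
        )
        sample.normal = AssayData(callset=ncalls, coverage=ncov)
    return sample


def project_to_panel(
    cfg: SimulationConfig,
    sample: SimulatedSample,
    panel: Territory,
) -> AssayData:
    """Re-sequence the sample on a panel: retain truth variants inside the
    panel territory and re-draw coverage and read support independently."""
    truth = sample.truth
    keep = np.zeros(len(truth), dtype=bool)
    for chrom, grp in truth.groupby("chrom"):
        keep[grp.index] = panel.contains_many(
            chrom, grp["pos0"].to_numpy(dtype=np.int64)
        )
    sub = truth[keep]
    cov = simulate_coverage(
        cfg, panel, _rng(cfg.seed, "cov", sample.sample_id, panel.name),
        sample.sample_id,
    )
    calls = realize_calls(
        sub, cov, _rng(cfg.seed, "calls", sample.sample_id, panel.name),
        sample_id=sample.sample_id, assay_id=panel.name,
    )
    return AssayData(callset=calls, coverage=cov)


def simulate_pon(
    cfg: SimulationConfig,
    exome: Territory,
    pool: PopulationPool,
) -> PanelOfNormals:
    """Panel of normals genotyped from the population pool, with per-normal
    allelic-fraction jitter plus rare per-normal noise entries."""
    idx = _TerritoryIndex(exome)
    entries: dict[tuple[str, int, str, str], list[tuple[str, float]]] = {}
    for j in range(cfg.n_normals_pon):
        normal_id = f"pon_{j:02d}"
        rng = _rng(cfg.seed, "pon", j)
        het_i, hom_i = _genotype_pool(pool, rng)
        sel = np.concatenate([het_i, hom_i])
        vafs = _germline_vafs(rng, len(het_i), len(hom_i))
        for i, af in zip(sel, vafs):
            key = (
                str(pool.chrom[i]), int(pool.pos0[i]) + 1,
                str(pool.ref[i]), str(pool.alt[i]),
            )
            entries.setdefault(key, []).append((normal_id, float(af)))
        n_noise = rng.poisson(30)
        chrom, pos0 = idx.locate(rng.integers(0, idx.total, size=n_noise))
        ref, alt = _draw_sbs_alleles(
            rng, n_noise, {k: 1 / 6 for k in SOMATIC_SPECTRUM}
        )
        noise_af = rng.uniform(0.02, 0.15, size=n_noise)
        for c, p, r, a, af in zip(chrom, pos0, ref, alt, noise_af):
            entries.setdefault((str(c), int(p) + 1, str(r), str(a)), []).append(
                (normal_id, float(af))
            )
    return PanelOfNormals(entries=entries, n_normals=cfg.n_normals_pon)


@dataclass
class Cohort:
    cfg: SimulationConfig
    exome: Territory
    panels: list[Territory]
    pon: PanelOfNormals
    samples: list[SimulatedSample]


def simulate_cohort(
    cfg: SimulationConfig,
    n_samples: int,
    tmb_values: Optional[Sequence[float]] = None,
    n_paired: Optional[int] = None,
    with_panels: bool = True,
) -> Cohort:
    """Simulate a full cohort: territories, panel of normals, and per-sample
    exome (+ panel) callsets. ``tmb_values`` fixes each sample's somatic rate;
    by default rates are drawn log-uniformly in [1, 45] v/mb. The first
    ``n_paired`` samples (default: all) carry a matched normal."""
    exome, panels = simulate_territories(cfg)
    pool = build_population_pool(cfg, exome)
    pon = simulate_pon(cfg, exome, pool)
    if tmb_values is None:
        rng = _rng(cfg.seed, "cohort_tmb")
        tmb_values = np.exp(rng.uniform(np.log(1.0), np.log(45.0), size=n_samples))
    if len(tmb_values) != n_samples:
        raise ValidationError("tmb_values length must equal n_samples")
    if n_paired is None:
        n_paired = n_samples
    samples = []
    for i in range(n_samples):
        sid = f"S{i + 1:02d}"
        s = simulate_sample(
            cfg, exome, pool, sid,
            tmb_true=float(tmb_values[i]),
            with_normal=i < n_paired,
        )
        if with_panels:
            for panel in panels:
                s.assays[panel.name] = project_to_panel(cfg, s, panel)
        samples.append(s)
    return Cohort(cfg=cfg, exome=exome, panels=panels, pon=pon, samples=samples)


def as_paired(cs: SampleCallset, matched_normal_id: str) -> SampleCallset:
    """View a tumor callset under paired-calling provenance."""
    return replace(cs, mode="paired", matched_normal_id=matched_normal_id)


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = {}
    for f in fields(cfg):
        v = getattr(cfg, f.name)
        d[f.name] = [list(p) for p in v] if f.name == "panel_specs" else v
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "panel_specs" in d:
        d["panel_specs"] = tuple((str(n), float(m)) for n, m in d["panel_specs"])
    return SimulationConfig(**d)
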