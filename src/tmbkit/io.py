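"""Readers/writers for VCF 4.2, BED3, coverage TSV, panel-of-normals TSV and
configs, with a documented INFO-tag dialect.

Canonical tag dialect (single-sample, INFO-based; all per-allele tags are
Number=A so multi-allelic records split cleanly):

======== ======== =====================================================
tag      number   meaning
======== ======== =====================================================
DP       1        total read depth at the locus
AO       A        alt-supporting read count
SAF/SAR  A        alt reads on forward / reverse strand
MQPF     1        fraction of reads with mapping quality > 1
CLASS    A        variant effect class (snv, indel, frameshift,
                  start_stop, splice, synonymous, other)
SPLOFF   A        signed bp distance to the exon/intron boundary
MAF      A        population minor allele fraction (absent = unseen)
DB       0 flag   dbSNP membership
COSMIC   0 flag   COSMIC membership
TRUTH    A        simulator truth label (somatic/germline/artifact)
======== ======== =====================================================

Foreign VCFs are adapted by overriding tag names in :class:`TagDialect` —
e.g. ``alt_depth_tag="AD", alt_depth_kind="R"`` for AD-style (ref,alt...)
arrays — not by code changes. Multi-allelic records are split into one
:class:`~tmbkit.model.VariantCall` per alternate allele before any filtering.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import pysam
import yaml

from .filters import FilterConfig, FilterVerdict, RULE_CODES
from .model import (
    ContractError,
    CoverageProfile,
    PanelOfNormals,
    SampleCallset,
    Territory,
    ValidationError,
    VariantCall,
)

PathLike = Union[str, Path]


class DialectError(ValidationError):
    """A tag required by the dialect is missing from the VCF header."""


@dataclass(frozen=True)
class TagDialect:
    """Names of the INFO tags carrying each VariantCall field.

    ``alt_depth_kind`` is ``"A"`` when the alt-depth tag holds one value per
    alternate allele, or ``"R"`` when it holds (ref, alt1, alt2, ...) as with
    conventional AD arrays.
    """

    depth_tag: str = "DP"
    alt_depth_tag: str = "AO"
    alt_depth_kind: str = "A"
    strand_fwd_tag: str = "SAF"
    strand_rev_tag: str = "SAR"
    mq_tag: str = "MQPF"
    class_tag: str = "CLASS"
    splice_tag: str = "SPLOFF"
    maf_tag: str = "MAF"
    dbsnp_tag: str = "DB"
    cosmic_tag: str = "COSMIC"
    truth_tag: str = "TRUTH"

    def required_tags(self) -> tuple[str, ...]:
        return (
            self.depth_tag,
            self.alt_depth_tag,
            self.strand_fwd_tag,
            self.strand_rev_tag,
            self.mq_tag,
            self.class_tag,
        )


DEFAULT_DIALECT = TagDialect()


def _per_allele(value, alt_index: int, n_alts: int, kind: str = "A"):
    """Pull the value for one alt from a scalar or per-allele tuple."""
    if value is None:
        return None
    if isinstance(value, tuple):
        if kind == "R":
            return value[alt_index + 1]
        if len(value) == n_alts:
            return value[alt_index]
        if len(value) == 1:
            return value[0]
        raise ValidationError(
            f"per-allele tag has {len(value)} values for {n_alts} alts"
        )
    return value


def read_vcf(
    path: PathLike,
    dialect: TagDialect = DEFAULT_DIALECT,
    *,
    sample_id: Optional[str] = None,
    assay_id: str = "unknown",
    mode: str = "tumor_only",
    matched_normal_id: Optional[str] = None,
) -> SampleCallset:
    """Read a VCF into a callset, one VariantCall per (record, alt allele).

    Missing optional tags (MAF, SPLOFF, TRUTH, flags) yield absent fields;
    missing *required* tags in the header raise :class:`DialectError`.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise ValidationError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        header_info = set(vf.header.info.keys())
        for tag in dialect.required_tags():
            if tag not in header_info:
                raise DialectError(
                    f"required INFO tag {tag!r} missing from header of {path}"
                )
        sid = sample_id or (list(vf.header.samples)[0] if vf.header.samples else "sample")
        calls: list[VariantCall] = []
        for rec in vf:
            alts = rec.alts or ()
            n_alts = len(alts)
            info = rec.info
            for ai, alt in enumerate(alts):
                dp = info.get(dialect.depth_tag)
                ao = _per_allele(
                    info.get(dialect.alt_depth_tag), ai, n_alts,
                    dialect.alt_depth_kind,
                )
                saf = _per_allele(info.get(dialect.strand_fwd_tag), ai, n_alts)
                sar = _per_allele(info.get(dialect.strand_rev_tag), ai, n_alts)
                mq = info.get(dialect.mq_tag)
                if None in (dp, ao, saf, sar, mq):
                    raise ValidationError(
                        f"record {rec.chrom}:{rec.pos} missing a required tag"
                    )
                def opt(tag):
                    # pysam raises for tags absent from the header
                    return info.get(tag) if tag in header_info else None

                vclass = _per_allele(info.get(dialect.class_tag), ai, n_alts)
                sploff = _per_allele(opt(dialect.splice_tag), ai, n_alts)
                maf = _per_allele(opt(dialect.maf_tag), ai, n_alts)
                truth = _per_allele(opt(dialect.truth_tag), ai, n_alts)
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        total_depth=int(dp),
                        alt_depth=int(ao),
                        vaf=(int(ao) / int(dp)) if int(dp) else 0.0,
                        alt_fwd=int(saf),
                        alt_rev=int(sar),
                        mq_pass_fraction=float(mq),
                        variant_class=str(vclass),
                        splice_offset=None if sploff is None else int(sploff),
                        population_maf=None if maf is None else float(maf),
                        in_dbsnp=bool(
                            info.get(dialect.dbsnp_tag, False)
                            if dialect.dbsnp_tag in header_info
                            else False
                        ),
                        in_cosmic=bool(
                            info.get(dialect.cosmic_tag, False)
                            if dialect.cosmic_tag in header_info
                            else False
                        ),
                        truth_label=None if truth is None else str(truth),
                    )
                )
    return SampleCallset(
        sample_id=sid,
        assay_id=assay_id,
        mode=mode,
        calls=calls,
        matched_normal_id=matched_normal_id,
    )


def _build_header(
    callset: SampleCallset, dialect: TagDialect, contigs: dict[str, int]
) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for chrom, length in contigs.items():
        h.contigs.add(chrom, length=length)
    h.info.add(dialect.depth_tag, 1, "Integer", "Total read depth")
    h.info.add(dialect.alt_depth_tag, "A", "Integer", "Alt-supporting reads")
    h.info.add(dialect.strand_fwd_tag, "A", "Integer", "Alt reads, forward strand")
    h.info.add(dialect.strand_rev_tag, "A", "Integer", "Alt reads, reverse strand")
    h.info.add(dialect.mq_tag, 1, "Float", "Fraction of reads with MQ>1")
    h.info.add(dialect.class_tag, "A", "String", "Variant effect class")
    h.info.add(dialect.splice_tag, "A", "Integer", "Signed bp to exon/intron boundary")
    h.info.add(dialect.maf_tag, "A", "Float", "Population minor allele fraction")
    h.info.add(dialect.dbsnp_tag, 0, "Flag", "dbSNP membership")
    h.info.add(dialect.cosmic_tag, 0, "Flag", "COSMIC membership")
    h.info.add(dialect.truth_tag, "A", "String", "Simulator truth label")
    for code in RULE_CODES:
        h.filters.add(code, None, None, f"Failed the {code} rule")
    return h


def write_vcf(
    callset: SampleCallset,
    path: PathLike,
    verdicts: Optional[dict[tuple[str, int, str, str], FilterVerdict]] = None,
    dialect: TagDialect = DEFAULT_DIALECT,
    contigs: Optional[dict[str, int]] = None,
) -> None:
    """Write a callset as single-alt VCF records in the canonical dialect.

    With ``verdicts``, FILTER is PASS for survivors and the semicolon-joined
    failed rule codes otherwise; every call must then have a verdict.
    """
    if contigs is None:
        contigs = {}
        for c in callset:
            contigs[c.chrom] = max(contigs.get(c.chrom, 0), c.pos + len(c.ref) + 1000)
    header = _build_header(callset, dialect, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in callset:
            if verdicts is not None and v.key not in verdicts:
                raise ContractError(f"no filter verdict for call {v.key}")
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            rec.info[dialect.depth_tag] = v.total_depth
            rec.info[dialect.alt_depth_tag] = (v.alt_depth,)
            rec.info[dialect.strand_fwd_tag] = (v.alt_fwd,)
            rec.info[dialect.strand_rev_tag] = (v.alt_rev,)
            rec.info[dialect.mq_tag] = v.mq_pass_fraction
            rec.info[dialect.class_tag] = (v.variant_class,)
            if v.splice_offset is not None:
                rec.info[dialect.splice_tag] = (v.splice_offset,)
            if v.population_maf is not None:
                rec.info[dialect.maf_tag] = (v.population_maf,)
            if v.in_dbsnp:
                rec.info[dialect.dbsnp_tag] = True
            if v.in_cosmic:
                rec.info[dialect.cosmic_tag] = True
            if v.truth_label is not None:
                rec.info[dialect.truth_tag] = (v.truth_label,)
            if verdicts is not None:
                verdict = verdicts[v.key]
                if verdict.passed:
                    rec.filter.add("PASS")
                else:
                    for code in verdict.failed_rules:
                        rec.filter.add(code)
            out.write(rec)


def write_filtered_vcf(
    callset: SampleCallset,
    decisions: dict[tuple[str, int, str, str], FilterVerdict],
    path: PathLike,
    dialect: TagDialect = DEFAULT_DIALECT,
) -> None:
    """Audit VCF: FILTER=PASS for survivors, named rule codes otherwise."""
    write_vcf(callset, path, verdicts=decisions, dialect=dialect)


def read_filter_column(
    path: PathLike,
) -> dict[tuple[str, int, str, str], FilterVerdict]:
    """Recover per-call verdicts from the FILTER column of an audit VCF."""
    out: dict[tuple[str, int, str, str], FilterVerdict] = {}
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            codes = tuple(f for f in rec.filter.keys() if f != "PASS")
            for alt in rec.alts or ():
                out[(rec.chrom, rec.pos, rec.ref, alt)] = FilterVerdict(
                    passed=not codes, failed_rules=codes
                )
    return out


def read_bed(path: PathLike, name: Optional[str] = None) -> Territory:
    """Read a BED3+ file (0-based half-open) into a merged Territory."""
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected at least 3 BED columns"
                )
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            intervals.append((chrom, start, end))
    return Territory.from_intervals(name or path.stem, intervals)


def write_bed(territory: Territory, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in territory.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_coverage(
    path: PathLike, territory: Territory, sample_id: str = "sample"
) -> CoverageProfile:
    """Read a (chrom, start, end, depth) TSV (0-based half-open), restricted
    to the territory; intervals overlapping the territory edge are clipped."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "depth"],
        comment="#",
    )
    if (df["depth"] < 0).any():
        bad = df.index[df["depth"] < 0][0] + 1
        raise ValidationError(f"{path}:{bad}: negative depth")
    return CoverageProfile.from_intervals(
        sample_id,
        territory,
        df.itertuples(index=False, name=None),
    )


def write_coverage(cov: CoverageProfile, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, depth in cov.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\t{depth}\n")


def read_pon(path: PathLike) -> PanelOfNormals:
    """Read a panel-of-normals TSV (chrom, pos, ref, alt, normal_id, af)."""
    df = pd.read_csv(path, sep="\t")
    entries: dict[tuple[str, int, str, str], list[tuple[str, float]]] = {}
    for chrom, pos, ref, alt, nid, af in df[
        ["chrom", "pos", "ref", "alt", "normal_id", "af"]
    ].itertuples(index=False, name=None):
        entries.setdefault((str(chrom), int(pos), str(ref), str(alt)), []).append(
            (str(nid), float(af))
        )
    n_normals = df["normal_id"].nunique()
    return PanelOfNormals(entries=entries, n_normals=int(n_normals))


def write_pon(pon: PanelOfNormals, path: PathLike) -> None:
    rows = []
    for (chrom, pos, ref, alt), obs in sorted(pon.entries.items()):
        for nid, af in obs:
            rows.append((chrom, pos, ref, alt, nid, af))
    pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "normal_id", "af"]
    ).to_csv(path, sep="\t", index=False)


def load_filter_config(path: PathLike) -> FilterConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return FilterConfig(**data)


def dump_yaml(obj: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def verdicts_to_table(
    cs: SampleCallset,
    verdicts: dict[tuple[str, int, str, str], FilterVerdict],
) -> pd.DataFrame:
    """Audit table: one row per call, one boolean column per rule."""
    rows = []
    for v in cs:
        verdict = verdicts[v.key]
        row = {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "passed": verdict.passed,
        }
        for code in RULE_CODES:
            row[f"fail_{code}"] = code in verdict.failed_rules
        rows.append(row)
    return pd.DataFrame(rows)


def results_to_json(results: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    Path(path).write_text(Path(path).read_text() + "\n")


def filter_config_to_dict(cfg: FilterConfig) -> dict:
    return asdict(cfg)
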