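"""Somatic variant filter cascade for TMB estimation.

Seven independently evaluated rules, each named by a short code:

``class``    variant-effect class gate (non-synonymous coding classes, with an
             opt-in for coding synonymous variants)
``splice``   splice calls must sit within ±N bp of the exon/intron boundary
``maf``      germline-resource minor allele frequency must be below a cutoff
``dbsnp``    dbSNP-known variants are removed unless COSMIC-known
``support``  minimum alt-read count and allelic-fraction floor
``mq``       minimum fraction of reads with mapping quality > 1
``pon``      tumor/normal allelic-fraction ratio against a panel of normals

Defaults mirror routine tumor-only TMB filtering practice: ±2 bp splice
window, MAF < 0.01% (1e-4), ≥5 alt reads, VAF ≥ 5%, ≥90% of reads with MQ>1,
and Af_tumor/Af_normal strictly greater than 4 against every normal in which
the variant was detected. Support/MQ thresholds are inclusive; the MAF gate
and the PoN ratio are strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .model import (
    ContractError,
    PanelOfNormals,
    SampleCallset,
    ValidationError,
    VariantCall,
)

RULE_CODES = ("class", "splice", "maf", "dbsnp", "support", "mq", "pon")

#: classes that pass the class gate unconditionally
_ALWAYS_PASS_CLASSES = frozenset({"snv", "indel", "frameshift", "start_stop"})


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filter cascade. All thresholds strictly positive."""

    include_synonymous: bool = False
    splice_window_bp: int = 2
    maf_threshold: float = 1e-4
    min_alt_reads: int = 5
    min_vaf: float = 0.05
    min_mq_pass_fraction: float = 0.90
    pon_ratio: float = 4.0

    def __post_init__(self) -> None:
        for name in (
            "splice_window_bp",
            "maf_threshold",
            "min_alt_reads",
            "min_vaf",
            "min_mq_pass_fraction",
            "pon_ratio",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.min_vaf >= 1:
            raise ValidationError("min_vaf must be < 1")

    def with_vaf_cutoff(self, min_vaf: float) -> "FilterConfig":
        return replace(self, min_vaf=min_vaf)


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of the cascade for one call: pass/fail plus every failed rule."""

    passed: bool
    failed_rules: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_rules) == 0):
            raise ValidationError("passed must equal failed_rules being empty")


def splice_filter(v: VariantCall, cfg: FilterConfig) -> bool:
    """True iff a splice call lies within ±splice_window_bp of the boundary."""
    if v.variant_class != "splice":
        raise ContractError("splice_filter applies only to splice-class calls")
    if v.splice_offset is None:
        raise ValidationError(
            f"splice call without splice_offset at {v.chrom}:{v.pos}"
        )
    return abs(v.splice_offset) <= cfg.splice_window_bp


def class_filter(v: VariantCall, cfg: FilterConfig) -> bool:
    """Class gate: non-synonymous coding classes pass; synonymous only when
    ``include_synonymous``; splice calls pass iff within the splice window;
    anything else (deep intronic, UTR...) never passes."""
    c = v.variant_class
    if c in _ALWAYS_PASS_CLASSES:
        return True
    if c == "synonymous":
        return cfg.include_synonymous
    if c == "splice":
        return splice_filter(v, cfg)
    if c == "other":
        return False
    raise ValidationError(f"unknown variant class {c!r}")


def maf_filter(v: VariantCall, cfg: FilterConfig) -> bool:
    """True iff the variant is unseen in the germline resource or its MAF is
    strictly below the threshold."""
    if v.population_maf is None:
        return True
    if not (0.0 <= v.population_maf <= 1.0):
        raise ValidationError(f"population_maf {v.population_maf} outside [0,1]")
    return v.population_maf < cfg.maf_threshold


def dbsnp_cosmic_filter(v: VariantCall) -> bool:
    """Remove dbSNP-known variants unless they are also COSMIC-known."""
    return not (v.in_dbsnp and not v.in_cosmic)


def support_filter(v: VariantCall, cfg: FilterConfig) -> bool:
    """Alt-read count, VAF floor and MQ fraction, all inclusive thresholds."""
    return (
        v.alt_depth >= cfg.min_alt_reads
        and v.vaf >= cfg.min_vaf
        and v.mq_pass_fraction >= cfg.min_mq_pass_fraction
    )


def pon_filter(v: VariantCall, pon: PanelOfNormals, cfg: FilterConfig) -> bool:
    """True iff Af_tumor/Af_normal > pon_ratio against every normal in which
    the variant was detected (vacuously true if detected in none)."""
    for normal_id, af_normal in pon.afs_for(v.key):
        if af_normal <= 0:
            raise ValidationError(
                f"Af_normal {af_normal} in {normal_id} for {v.key}: "
                "detection implies Af_normal > 0"
            )
        if not v.vaf / af_normal > cfg.pon_ratio:
            return False
    return True


def evaluate_call(
    v: VariantCall, pon: PanelOfNormals, cfg: FilterConfig
) -> FilterVerdict:
    """Evaluate every rule independently and record all failures."""
    failed: list[str] = []
    c = v.variant_class
    if c in _ALWAYS_PASS_CLASSES:
        pass
    elif c == "synonymous":
        if not cfg.include_synonymous:
            failed.append("class")
    elif c == "splice":
        if not splice_filter(v, cfg):
            failed.append("splice")
    elif c == "other":
        failed.append("class")
    else:  # pragma: no cover - blocked by VariantCall validation
        raise ValidationError(f"unknown variant class {c!r}")
    if not maf_filter(v, cfg):
        failed.append("maf")
    if v.in_dbsnp and not v.in_cosmic:
        failed.append("dbsnp")
    if v.alt_depth < cfg.min_alt_reads or v.vaf < cfg.min_vaf:
        failed.append("support")
    if v.mq_pass_fraction < cfg.min_mq_pass_fraction:
        failed.append("mq")
    if not pon_filter(v, pon, cfg):
        failed.append("pon")
    return FilterVerdict(passed=not failed, failed_rules=tuple(failed))


def apply_cascade(
    cs: SampleCallset,
    pon: PanelOfNormals,
    cfg: FilterConfig,
    matched_normal: Optional[SampleCallset] = None,
) -> dict[tuple[str, int, str, str], FilterVerdict]:
    """Run the cascade over a callset; returns verdicts keyed by call key.

    In paired mode the matched normal's allelic fractions are merged into the
    panel of normals before the ratio rule, so the patient's own germline
    variants fail the ``pon`` rule (Af_tumor/Af_normal ≈ 1).
    """
    if cs.mode == "paired":
        if matched_normal is None:
            raise ContractError(
                "paired-mode cascade requires the matched normal callset "
                "(pass an empty callset if it carries no variants)"
            )
        pon = pon.with_matched_normal(matched_normal)
    elif matched_normal is not None and len(matched_normal) > 0:
        raise ContractError("matched normal supplied for a tumor_only callset")
    return {v.key: evaluate_call(v, pon, cfg) for v in cs}


def passing_calls(
    cs: SampleCallset,
    verdicts: dict[tuple[str, int, str, str], FilterVerdict],
) -> list[VariantCall]:
    """Calls whose verdict is a pass. Every call must have a verdict."""
    out = []
    for v in cs:
        try:
            verdict = verdicts[v.key]
        except KeyError:
            raise ContractError(f"no verdict for call {v.key}") from None
        if verdict.passed:
            out.append(v)
    return out
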