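"""Coverage-conditioned TMB calculation and tumor-only germline overhead.

TMB = (number of filter-passing variants at callable loci) / (megabases with
depth strictly greater than ``min_coverage``). The default threshold of 15
means a base needs depth ≥ 16 to enter the denominator, and a passing variant
is counted in the numerator only if its own locus is callable, keeping the
numerator and denominator in the same universe of bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .filters import FilterVerdict, passing_calls
from .model import (
    ContractError,
    CoverageProfile,
    SampleCallset,
    Territory,
    ValidationError,
)

DEFAULT_MIN_COVERAGE = 15


@dataclass(frozen=True)
class TMBResult:
    """Burden for one sample under one assay and synonymous mode.

    ``tmb`` is ``None`` (absent, never 0) when no base is callable.
    """

    sample_id: str
    assay_id: str
    mode: str
    include_synonymous: bool
    n_variants: int
    callable_mb: float
    tmb: Optional[float]
    min_coverage: int = DEFAULT_MIN_COVERAGE


@dataclass(frozen=True)
class OverheadResult:
    """Excess of tumor-only over paired filtering: residual germline burden."""

    sample_id: str
    delta_variants: int
    delta_tmb: Optional[float]
    include_synonymous: bool


def callable_megabases(
    cov: CoverageProfile,
    territory: Territory,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> float:
    """Megabases of territory with depth strictly greater than min_coverage."""
    return cov.callable_bases(min_coverage, territory) / 1e6


def compute_tmb(
    n_pass: int,
    callable_mb: float,
    *,
    sample_id: str,
    assay_id: str,
    mode: str,
    include_synonymous: bool,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> TMBResult:
    """Variants per megabase; absent (None) when the denominator is zero."""
    if n_pass < 0:
        raise ValidationError("n_pass must be >= 0")
    if callable_mb < 0:
        raise ValidationError("callable_mb must be >= 0")
    tmb = n_pass / callable_mb if callable_mb > 0 else None
    return TMBResult(
        sample_id=sample_id,
        assay_id=assay_id,
        mode=mode,
        include_synonymous=include_synonymous,
        n_variants=n_pass,
        callable_mb=callable_mb,
        tmb=tmb,
        min_coverage=min_coverage,
    )


def tmb_from_callset(
    cs: SampleCallset,
    verdicts: dict[tuple[str, int, str, str], FilterVerdict],
    cov: CoverageProfile,
    territory: Territory,
    *,
    include_synonymous: bool,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> TMBResult:
    """Count passing calls at callable loci and divide by callable megabases."""
    n_pass = 0
    for v in passing_calls(cs, verdicts):
        pos0 = v.pos - 1
        if territory.contains(v.chrom, pos0) and cov.depth_at(v.chrom, pos0) > min_coverage:
            n_pass += 1
    return compute_tmb(
        n_pass,
        callable_megabases(cov, territory, min_coverage),
        sample_id=cs.sample_id,
        assay_id=cs.assay_id,
        mode=cs.mode,
        include_synonymous=include_synonymous,
        min_coverage=min_coverage,
    )


def germline_overhead(tumor_only: TMBResult, paired: TMBResult) -> OverheadResult:
    """Tumor-only minus paired counts/TMB for one sample and assay: an
    estimate of residual germline variants surviving tumor-only filtering."""
    if tumor_only.sample_id != paired.sample_id:
        raise ContractError("overhead requires the same sample in both modes")
    if tumor_only.assay_id != paired.assay_id:
        raise ContractError("overhead requires the same assay in both modes")
    if tumor_only.include_synonymous != paired.include_synonymous:
        raise ContractError("overhead requires matching synonymous modes")
    if tumor_only.mode != "tumor_only" or paired.mode != "paired":
        raise ContractError("expected one tumor_only and one paired result")
    delta_tmb: Optional[float] = None
    if tumor_only.tmb is not None and paired.tmb is not None:
        delta_tmb = tumor_only.tmb - paired.tmb
    return OverheadResult(
        sample_id=tumor_only.sample_id,
        delta_variants=tumor_only.n_variants - paired.n_variants,
        delta_tmb=delta_tmb,
        include_synonymous=tumor_only.include_synonymous,
    )
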