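"""FFPE deamination artifact diagnostics.

Formalin fixation deaminates cytosine, producing spurious C:G>T:A calls that
are typically low-VAF and strand-imbalanced. Two diagnostics are provided:

* the fraction of passing variants that are C:G>T:A transitions (overall and
  per VAF bin), an established FFPE-artifact indicator;
* a per-variant strand-imbalance flag based on a two-sided exact binomial
  test of forward vs reverse alt reads against 0.5. The flag is a simplified,
  self-contained diagnostic (read-orientation models of caller pipelines are
  out of scope) and never enters the TMB filter cascade unless a caller
  explicitly wires it in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .filters import FilterConfig, FilterVerdict, apply_cascade, passing_calls
from .model import PanelOfNormals, SampleCallset, ValidationError, VariantCall

#: pyrimidine-collapsed single-base substitution classes
SBS_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COLLAPSE = {
    ("C", "A"): "C>A", ("G", "T"): "C>A",
    ("C", "G"): "C>G", ("G", "C"): "C>G",
    ("C", "T"): "C>T", ("G", "A"): "C>T",
    ("T", "A"): "T>A", ("A", "T"): "T>A",
    ("T", "C"): "T>C", ("A", "G"): "T>C",
    ("T", "G"): "T>G", ("A", "C"): "T>G",
}

DEFAULT_VAF_BINS = (0.0, 0.02, 0.05, 0.10, 1.0)


@dataclass(frozen=True)
class SpectrumSummary:
    """Substitution spectrum of the passing calls of one sample.

    ``transition_ratio`` is the fraction of C:G>T:A calls among *all* passing
    variants (indels included by default); absent when nothing passes.
    """

    n_passing: int
    n_snv: int
    counts: dict[str, int]
    transition_ratio: Optional[float]
    vaf_bin_edges: tuple[float, ...]
    vaf_bin_ratios: tuple[Optional[float], ...]


def is_cg_to_ta(v: VariantCall) -> bool:
    return v.is_snv and (v.ref, v.alt) in (("C", "T"), ("G", "A"))


def transition_ratio(
    cs: SampleCallset,
    verdicts: dict[tuple[str, int, str, str], FilterVerdict],
    vaf_bins: Optional[Sequence[float]] = None,
    snv_only: bool = False,
) -> SpectrumSummary:
    """C:G>T:A transition fraction of the passing calls, plus spectrum counts.

    With ``snv_only`` the denominator is restricted to SNVs instead of all
    passing variants.
    """
    edges = tuple(vaf_bins) if vaf_bins is not None else DEFAULT_VAF_BINS
    if len(edges) < 2 or any(a >= b for a, b in zip(edges, edges[1:])):
        raise ValidationError("vaf_bins must be strictly increasing edges")
    counts = {c: 0 for c in SBS_CLASSES}
    n_pass = 0
    n_snv = 0
    n_cg_ta = 0
    bin_total = [0] * (len(edges) - 1)
    bin_cg_ta = [0] * (len(edges) - 1)
    for v in passing_calls(cs, verdicts):
        if snv_only and not v.is_snv:
            continue
        n_pass += 1
        if v.is_snv:
            n_snv += 1
            counts[_COLLAPSE[(v.ref, v.alt)]] += 1
        hit = is_cg_to_ta(v)
        n_cg_ta += hit
        for b in range(len(edges) - 1):
            lo, hi = edges[b], edges[b + 1]
            if (lo <= v.vaf < hi) or (hi == edges[-1] and v.vaf == hi):
                bin_total[b] += 1
                bin_cg_ta[b] += hit
                break
    ratio = n_cg_ta / n_pass if n_pass else None
    bin_ratios = tuple(
        (c / t) if t else None for c, t in zip(bin_cg_ta, bin_total)
    )
    return SpectrumSummary(
        n_passing=n_pass,
        n_snv=n_snv,
        counts=counts,
        transition_ratio=ratio,
        vaf_bin_edges=edges,
        vaf_bin_ratios=bin_ratios,
    )


def strand_imbalance_flag(v: VariantCall, alpha: float = 0.01) -> bool:
    """True iff forward/reverse alt-read counts reject balance (binomial
    two-sided exact test against 0.5) at the given significance level."""
    if v.alt_depth == 0:
        raise ValidationError("strand test undefined for alt_depth 0")
    p = stats.binomtest(v.alt_fwd, v.alt_depth, 0.5).pvalue
    return p < alpha


def vaf_stratified_report(
    cs: SampleCallset,
    pon: PanelOfNormals,
    cfg: FilterConfig,
    cutoffs: Sequence[float] = (0.02, 0.05),
    matched_normal: Optional[SampleCallset] = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Re-run the cascade at each VAF cutoff and summarize artifact signals.

    One row per cutoff: passing count, C:G>T:A transition ratio and the
    fraction of passing calls carrying the strand-imbalance flag. Lowering
    the cutoff (e.g. 5% -> 2%) exposes the low-VAF stratum where FFPE
    artifacts concentrate.
    """
    rows = []
    for cutoff in cutoffs:
        v_cfg = cfg.with_vaf_cutoff(cutoff)
        verdicts = apply_cascade(cs, pon, v_cfg, matched_normal=matched_normal)
        summary = transition_ratio(cs, verdicts)
        flagged = sum(
            strand_imbalance_flag(v, alpha)
            for v in passing_calls(cs, verdicts)
            if v.alt_depth > 0
        )
        rows.append(
            {
                "sample_id": cs.sample_id,
                "assay_id": cs.assay_id,
                "vaf_cutoff": cutoff,
                "n_pass": summary.n_passing,
                "transition_ratio": summary.transition_ratio,
                "strand_flag_fraction": (
                    flagged / summary.n_passing if summary.n_passing else None
                ),
            }
        )
    return pd.DataFrame(rows)
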