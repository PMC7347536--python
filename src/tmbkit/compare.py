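"""Cross-assay harmonization statistics.

Pearson correlation with p-values obtained through the t-statistic
t = r * sqrt((n-2) / (1 - r^2)) on n-2 degrees of freedom, Bonferroni
correction, exome/panel conversion factors (ratio of cohort means), and
overall/positive/negative percent agreement (OPA/PPA/NPA) of the high-TMB
classification at a fixed variants-per-megabase cutoff (default > 10,
strict: exactly 10 v/mb is negative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .filters import FilterVerdict, passing_calls
from .model import SampleCallset, ValidationError


class DegenerateInputError(ValidationError):
    """Statistic undefined for this input (zero variance, zero mean...)."""


@dataclass(frozen=True)
class CorrelationResult:
    assay_pair: tuple[str, str]
    n: int
    r: float
    t: float
    p: float
    p_bonferroni: Optional[float] = None


@dataclass(frozen=True)
class AgreementStats:
    """Contingency of panel-vs-reference high-TMB classification.

    Percentages are absent (None) when their denominator is zero.
    """

    conversion_factor: float
    cutoff: float
    tp: int
    tn: int
    fp: int
    fn: int
    opa: Optional[float]
    ppa: Optional[float]
    npa: Optional[float]


def pearson_with_p(
    x: Sequence[float],
    y: Sequence[float],
    assay_pair: tuple[str, str] = ("panel", "reference"),
) -> CorrelationResult:
    """Pearson r with a two-sided p-value from the t-conversion."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance input")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        t = math.inf if r > 0 else -math.inf
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = 2 * float(stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(assay_pair=assay_pair, n=n, r=r, t=t, p=p)


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """min(1, m*p) for a family of m tests."""
    m = len(p_values)
    out = []
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"p-value {p} outside [0,1]")
        out.append(min(1.0, m * p))
    return out


def conversion_factor(
    reference_tmbs: Sequence[float], panel_tmbs: Sequence[float]
) -> float:
    """Mean reference (exome) TMB divided by mean panel TMB."""
    ref = np.asarray(reference_tmbs, dtype=float)
    pan = np.asarray(panel_tmbs, dtype=float)
    if ref.shape != pan.shape:
        raise ValidationError("vectors must have equal length")
    if pan.mean() <= 0:
        raise DegenerateInputError("panel mean TMB must be > 0")
    return float(ref.mean() / pan.mean())


def agreement(
    reference_tmbs: Sequence[float],
    panel_tmbs: Sequence[float],
    factor: float,
    cutoff: float = 10.0,
) -> AgreementStats:
    """OPA/PPA/NPA of factor-corrected panel TMB against the reference at a
    strict > cutoff classification; the reference defines truth."""
    ref = np.asarray(reference_tmbs, dtype=float)
    pan = np.asarray(panel_tmbs, dtype=float)
    if ref.shape != pan.shape:
        raise ValidationError("vectors must have equal length")
    ref_pos = ref > cutoff
    pan_pos = (factor * pan) > cutoff
    tp = int(np.sum(ref_pos & pan_pos))
    tn = int(np.sum(~ref_pos & ~pan_pos))
    fp = int(np.sum(~ref_pos & pan_pos))
    fn = int(np.sum(ref_pos & ~pan_pos))
    total = tp + tn + fp + fn
    opa = 100.0 * (tp + tn) / total if total else None
    ppa = 100.0 * tp / (tp + fn) if (tp + fn) else None
    npa = 100.0 * tn / (tn + fp) if (tn + fp) else None
    return AgreementStats(
        conversion_factor=factor,
        cutoff=cutoff,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        opa=opa,
        ppa=ppa,
        npa=npa,
    )


def syn_nonsyn_ratio(
    cs: SampleCallset,
    verdicts: dict[tuple[str, int, str, str], FilterVerdict],
) -> Optional[float]:
    """Ratio of passing synonymous to passing non-synonymous variants.

    Verdicts must come from a synonymous-inclusive cascade run; absent when
    no non-synonymous variant passes.
    """
    n_syn = 0
    n_nonsyn = 0
    for v in passing_calls(cs, verdicts):
        if v.variant_class == "synonymous":
            n_syn += 1
        else:
            n_nonsyn += 1
    if n_nonsyn == 0:
        return None
    return n_syn / n_nonsyn
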