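"""End-to-end orchestration: cascade -> TMB table -> harmonization report.

These functions tie the filter cascade, the coverage-conditioned TMB engine
and the comparison statistics together over a simulated (or loaded) cohort,
and are shared by the CLI, the analysis drivers and the acceptance script.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .compare import (
    agreement,
    bonferroni,
    conversion_factor,
    pearson_with_p,
    syn_nonsyn_ratio,
)
from .filters import FilterConfig, apply_cascade
from .model import (
    ContractError,
    CoverageProfile,
    PanelOfNormals,
    SampleCallset,
    Territory,
)
from .simulate import Cohort, SimulatedSample, as_paired
from .tmb import TMBResult, germline_overhead, tmb_from_callset


def call_assay(
    callset: SampleCallset,
    cov: CoverageProfile,
    territory: Territory,
    pon: PanelOfNormals,
    cfg: FilterConfig,
    *,
    mode: str = "tumor_only",
    matched_normal: Optional[SampleCallset] = None,
    min_coverage: int = 15,
) -> tuple[dict, TMBResult]:
    """Run the cascade in the requested mode and compute the burden."""
    if mode == "paired":
        if matched_normal is None:
            raise ContractError("paired mode requires a matched normal callset")
        cs = as_paired(callset, matched_normal.sample_id)
    else:
        cs = callset
        matched_normal = None
    verdicts = apply_cascade(cs, pon, cfg, matched_normal=matched_normal)
    result = tmb_from_callset(
        cs, verdicts, cov, territory,
        include_synonymous=cfg.include_synonymous,
        min_coverage=min_coverage,
    )
    return verdicts, result


def _territory_for(cohort: Cohort, assay_id: str) -> Territory:
    if assay_id == "exome":
        return cohort.exome
    for p in cohort.panels:
        if p.name == assay_id:
            return p
    raise ContractError(f"unknown assay {assay_id!r}")


def cohort_tmb_table(
    cohort: Cohort,
    base_cfg: FilterConfig = FilterConfig(),
    *,
    min_coverage: int = 15,
    paired_assays: Sequence[str] = ("exome",),
) -> pd.DataFrame:
    """TMB for every (sample, assay, mode, synonymous-mode) combination.

    Panels are analyzed tumor-only; assays listed in ``paired_assays`` are
    additionally analyzed in paired mode for samples with a matched normal.
    """
    rows = []
    for sample in cohort.samples:
        for assay_id, data in sample.assays.items():
            territory = _territory_for(cohort, assay_id)
            modes = ["tumor_only"]
            if sample.has_normal and assay_id in paired_assays:
                modes.append("paired")
            for mode in modes:
                for include_syn in (False, True):
                    cfg = FilterConfig(
                        include_synonymous=include_syn,
                        splice_window_bp=base_cfg.splice_window_bp,
                        maf_threshold=base_cfg.maf_threshold,
                        min_alt_reads=base_cfg.min_alt_reads,
                        min_vaf=base_cfg.min_vaf,
                        min_mq_pass_fraction=base_cfg.min_mq_pass_fraction,
                        pon_ratio=base_cfg.pon_ratio,
                    )
                    _, res = call_assay(
                        data.callset, data.coverage, territory, cohort.pon, cfg,
                        mode=mode,
                        matched_normal=(
                            sample.normal.callset if mode == "paired" else None
                        ),
                        min_coverage=min_coverage,
                    )
                    rows.append(
                        {
                            "sample_id": res.sample_id,
                            "assay_id": assay_id,
                            "mode": mode,
                            "include_synonymous": include_syn,
                            "n_variants": res.n_variants,
                            "callable_mb": res.callable_mb,
                            "tmb": res.tmb,
                            "tmb_true": sample.tmb_true,
                            "truth_tmb": sample.truth_tmb(cohort.exome.coding_mb),
                        }
                    )
    return pd.DataFrame(rows)


def cohort_overheads(table: pd.DataFrame, assay_id: str = "exome") -> pd.DataFrame:
    """Germline overhead (tumor-only minus paired) per sample and syn mode."""
    rows = []
    for (sid, syn), grp in table[table["assay_id"] == assay_id].groupby(
        ["sample_id", "include_synonymous"]
    ):
        modes = grp.set_index("mode")
        if not {"tumor_only", "paired"} <= set(modes.index):
            continue
        to = modes.loc["tumor_only"]
        pa = modes.loc["paired"]
        res = germline_overhead(
            TMBResult(sid, assay_id, "tumor_only", syn, int(to["n_variants"]),
                      float(to["callable_mb"]), to["tmb"]),
            TMBResult(sid, assay_id, "paired", syn, int(pa["n_variants"]),
                      float(pa["callable_mb"]), pa["tmb"]),
        )
        rows.append(
            {
                "sample_id": sid,
                "include_synonymous": syn,
                "delta_variants": res.delta_variants,
                "delta_tmb": res.delta_tmb,
            }
        )
    return pd.DataFrame(rows)


def harmonization_report(
    table: pd.DataFrame,
    *,
    reference_assay: str = "exome",
    reference_mode: str = "paired",
    cutoff: float = 10.0,
    min_shared: int = 3,
) -> pd.DataFrame:
    """Per-(assay, syn-mode) comparison to the reference: Pearson r with
    t-based p and Bonferroni correction over the family, conversion factor
    and OPA/PPA/NPA at the strict > cutoff classification. Rows are ordered
    by correlation, reference first."""
    ref = table[
        (table["assay_id"] == reference_assay) & (table["mode"] == reference_mode)
    ]
    if ref.empty:
        raise ContractError(
            f"reference {reference_assay}/{reference_mode} absent from table"
        )
    rows = []
    test_assays = table[
        (table["assay_id"] != reference_assay) | (table["mode"] != reference_mode)
    ]
    for (assay_id, mode, syn), grp in test_assays.groupby(
        ["assay_id", "mode", "include_synonymous"]
    ):
        ref_syn = ref[ref["include_synonymous"] == syn].set_index("sample_id")
        grp = grp.set_index("sample_id")
        shared = sorted(set(ref_syn.index) & set(grp.index))
        if len(shared) < min_shared:
            continue
        x = grp.loc[shared, "tmb"].to_numpy(dtype=float)
        y = ref_syn.loc[shared, "tmb"].to_numpy(dtype=float)
        corr = pearson_with_p(x, y, assay_pair=(assay_id, reference_assay))
        factor = conversion_factor(y, x)
        ag = agreement(y, x, factor, cutoff=cutoff)
        rows.append(
            {
                "assay_id": assay_id,
                "mode": mode,
                "include_synonymous": syn,
                "n": corr.n,
                "r": corr.r,
                "t": corr.t,
                "p": corr.p,
                "conversion_factor": factor,
                "opa": ag.opa,
                "ppa": ag.ppa,
                "npa": ag.npa,
                "tp": ag.tp, "tn": ag.tn, "fp": ag.fp, "fn": ag.fn,
            }
        )
    report = pd.DataFrame(rows)
    if not report.empty:
        report["p_bonferroni"] = bonferroni(report["p"].tolist())
        report = report.sort_values("r", ascending=False, ignore_index=True)
    return report


def cohort_syn_ratios(
    cohort: Cohort, base_cfg: FilterConfig = FilterConfig()
) -> pd.DataFrame:
    """Passing synonymous/non-synonymous ratio per sample and assay (cascade
    run synonymous-inclusive, tumor-only)."""
    cfg = FilterConfig(
        include_synonymous=True,
        splice_window_bp=base_cfg.splice_window_bp,
        maf_threshold=base_cfg.maf_threshold,
        min_alt_reads=base_cfg.min_alt_reads,
        min_vaf=base_cfg.min_vaf,
        min_mq_pass_fraction=base_cfg.min_mq_pass_fraction,
        pon_ratio=base_cfg.pon_ratio,
    )
    rows = []
    for sample in cohort.samples:
        for assay_id, data in sample.assays.items():
            verdicts = apply_cascade(data.callset, cohort.pon, cfg)
            rows.append(
                {
                    "sample_id": sample.sample_id,
                    "assay_id": assay_id,
                    "syn_nonsyn_ratio": syn_nonsyn_ratio(data.callset, verdicts),
                }
            )
    return pd.DataFrame(rows)


def recovery_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum recovery of the generating somatic rate from paired-mode,
    synonymous-inclusive exome TMB (the estimator that matches the truth
    definition: all somatic coding classes)."""
    est = table[
        (table["assay_id"] == "exome")
        & (table["mode"] == "paired")
        & (table["include_synonymous"])
    ]
    rows = []
    for tmb_true, grp in est.groupby("tmb_true"):
        mean_est = grp["tmb"].mean()
        mean_truth = grp["truth_tmb"].mean()
        rows.append(
            {
                "tmb_true": tmb_true,
                "n_samples": len(grp),
                "mean_estimated_tmb": mean_est,
                "mean_truth_tmb": mean_truth,
                "relative_bias": (mean_est - mean_truth) / mean_truth,
            }
        )
    return pd.DataFrame(rows)


def recovery_correlation(table: pd.DataFrame) -> float:
    """Pearson r between estimated and realized-truth TMB across samples."""
    est = table[
        (table["assay_id"] == "exome")
        & (table["mode"] == "paired")
        & (table["include_synonymous"])
    ]
    r = pearson_with_p(
        est["tmb"].to_numpy(dtype=float),
        est["truth_tmb"].to_numpy(dtype=float),
        assay_pair=("estimate", "truth"),
    )
    return r.r


def germline_accounting(
    sample: SimulatedSample,
    cohort: Cohort,
    cfg: FilterConfig,
    assay_id: str = "exome",
) -> tuple[int, int]:
    """Truth-label accounting of the germline overhead for one sample.

    Returns (tumor_only_pass - paired_pass, number of truth-labelled germline
    calls passing tumor-only but failing paired). The two are equal by
    construction: merging the matched normal can only remove calls, and it
    removes only the patient's germline.
    """
    data = sample.assays[assay_id]
    v_to = apply_cascade(data.callset, cohort.pon, cfg)
    paired_cs = as_paired(data.callset, sample.normal.callset.sample_id)
    v_pa = apply_cascade(
        paired_cs, cohort.pon, cfg, matched_normal=sample.normal.callset
    )
    n_to = sum(v.passed for v in v_to.values())
    n_pa = sum(v.passed for v in v_pa.values())
    germline_lost = sum(
        1
        for call in data.callset
        if call.truth_label == "germline"
        and v_to[call.key].passed
        and not v_pa[call.key].passed
    )
    return n_to - n_pa, germline_lost
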