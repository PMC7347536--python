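#!/usr/bin/env python
"""Filter the synthetic cohort and compute TMB in every analysis mode.

Re-simulates the study cohort deterministically (seed 7), runs the filter
cascade (class gate, ±2 bp splice window, MAF < 0.01%, dbSNP-unless-COSMIC,
≥5 alt reads / ≥5% VAF / ≥90% MQ>1, panel-of-normals Af ratio > 4) and the
coverage-conditioned TMB calculation (>15x denominator), for tumor-only and
paired modes and with/without synonymous variants. Writes the burden table
and the tumor-only germline overhead per paired sample.
"""

from pathlib import Path

from tmbkit.pipeline import cohort_overheads, cohort_tmb_table
from tmbkit.simulate import SimulationConfig, simulate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cohort = simulate_cohort(SimulationConfig(seed=SEED), n_samples=14, n_paired=7)
    table = cohort_tmb_table(cohort)
    table.to_csv(RESULTS / "tmb_table.tsv", sep="\t", index=False)
    print(f"{len(table)} TMB rows -> {RESULTS / 'tmb_table.tsv'}")

    exome_paired = table[(table["assay_id"] == "exome") & (table["mode"] == "paired")
                         & table["include_synonymous"]]
    print("paired exome TMB (syn-incl) vs truth:")
    print(exome_paired[["sample_id", "tmb", "truth_tmb"]]
          .round(2).to_string(index=False))

    over = cohort_overheads(table)
    over.to_csv(RESULTS / "germline_overhead.tsv", sep="\t", index=False)
    for syn, grp in over.groupby("include_synonymous"):
        label = "incl. synonymous" if syn else "excl. synonymous"
        print(
            f"tumor-only germline overhead ({label}): "
            f"{grp['delta_variants'].mean():.1f} ± {grp['delta_variants'].std():.1f} "
            f"variants = {grp['delta_tmb'].mean():.2f} ± {grp['delta_tmb'].std():.2f} v/mb "
            f"(n={len(grp)})"
        )


if __name__ == "__main__":
    main()
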