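# Methods

## Scope and data model

`tmbkit` starts from *called, annotated* variants: VCF records carrying read
depth, alt-supporting reads, strand split, a mapping-quality pass fraction, a
variant-effect class, a population minor allele frequency and dbSNP/COSMIC
membership flags. Read-level processing (alignment, UMI consensus, the
variant caller itself) is out of scope, as is annotation: class and MAF
arrive as tags. Multi-allelic records are split into one call per alternate
allele before any filtering; an indel's allelic fraction is alt/total depth
at its anchor position. VCF positions are 1-based; territories (BED) and
coverage intervals are 0-based half-open, converted only at I/O boundaries.

The canonical tag dialect (DP, AO, SAF/SAR, MQPF, CLASS, SPLOFF, MAF, DB,
COSMIC, TRUTH; all per-allele tags Number=A) is a package construction:
vendor pipelines disagree on which fields carry these quantities, so foreign
VCFs are adapted by overriding tag names in `TagDialect` (including AD-style
Number=R alt depths), never by code changes.

## Filter cascade

Seven rules, evaluated independently so a verdict can report *all* failure
reasons; the final pass set is identical to a sequential pipeline.
Directions and boundary semantics:

- class gate: {snv, indel, frameshift, start_stop} pass; `synonymous` passes
  only in the synonymous-inclusive mode; `other` never passes.
- splice window: |offset| ≤ 2 bp, symmetric at donor and acceptor sites;
  offsets are signed, compared by absolute value.
- population MAF: strict `< 1e-4` (0.01 %). A variant absent from the
  resource cannot fail a frequency gate.
- dbSNP-unless-COSMIC: membership flags only; no re-annotation.
- support: `alt_depth ≥ 5` **and** `vaf ≥ 0.05`, both inclusive. The
  read-count threshold is interpreted as alt-supporting reads: a *total*
  depth of 5 at a 5 % allelic fraction would imply 0.25 supporting reads,
  which is not a coherent calling threshold.
- mapping quality: fraction of all reads at the locus with MQ > 1 must be
  ≥ 0.90 (inclusive). The fraction is over all reads, not alt reads only.
- panel of normals: `Af_tumor / Af_normal > 4` (strict) must hold against
  every normal in which the variant was detected; normals without the
  variant satisfy the condition vacuously (the alternative reading — the
  ratio must hold in all 21 normals including non-detections — would make
  the rule unsatisfiable for variants absent from any normal). Detection
  implies Af_normal > 0; a stored zero is a data error. In paired mode the
  matched normal's allelic fractions are merged into the panel before this
  rule, which is what removes the patient's own germline (ratio ≈ 1).

Tightening any threshold can only shrink the pass set (property-tested), and
the paired-mode pass set is always a subset of the tumor-only pass set.

## TMB

`tmb = n_pass / callable_mb`. The denominator counts territory bases with
depth **strictly greater** than 15 — a base needs ≥ 16× — and the numerator
counts a passing variant only if its own locus is callable, keeping
numerator and denominator in one universe of bases (a variant observed at a
sub-threshold locus would otherwise be normalized by territory it does not
belong to). A sample with no callable base reports TMB as *absent*, never 0,
with a warning. For a panel the denominator territory is the panel's coding
territory; for the exome it is the exome annotation-overlap territory
(default 35.9 MB). Non-coding panel content never enters numerator or
denominator.

Germline overhead is the tumor-only minus paired difference in passing
counts (and in v/mb) for the same sample, assay and synonymous mode — an
estimate of residual germline contamination of tumor-only TMB. On simulated
data this difference equals, exactly, the number of truth-labelled germline
calls that pass tumor-only filtering but not paired filtering (the matched
normal can only remove calls, and it removes only germline).

## Harmonization statistics

Pearson r is converted to `t = r·√((n−2)/(1−r²))` and a two-sided p-value
from the t-distribution with n−2 df (sidedness is a package choice);
Bonferroni multiplies by the number of assay/mode/synonymous combinations
compared in one run. The conversion factor is the ratio of cohort means,
estimated and applied on the same cohort — deliberately reproducing the
circular calibration a harmonization study uses; multiplying the panel
values by it equalizes means exactly. Agreement classifies high-TMB at a
strict `> 10 v/mb` (exactly 10 is negative) after factor correction, with
the reference assay defining truth; OPA/PPA/NPA are absent, never 0 or
NaN, when their denominator is empty. The t-based p-value is checked
against a permutation oracle in aggregate: per dataset the permutation p is
discrete and conditional (at n = 5 there are only 120 permutations), so the
test compares mean analytic p to mean permutation p over hundreds of
Gaussian datasets, where the residual error is genuinely Monte-Carlo.

## Artifact diagnostics

The C:G>T:A transition fraction of passing calls is the FFPE deamination
indicator; (ref, alt) ∈ {(C,T), (G,A)} with pyrimidine-collapsed spectrum
counts, the denominator being all passing variants (indels included; an
SNV-only denominator is a switch). Default VAF bins are
[0, 0.02), [0.02, 0.05), [0.05, 0.10), [0.10, 1]. The strand-imbalance flag
is a two-sided exact binomial test of forward vs reverse alt reads against
0.5 at α = 0.01 — a deliberately simple, self-contained stand-in for
caller-level read-orientation models, diagnostic-only: it never enters the
TMB cascade unless a caller wires it in explicitly. Its false-positive rate
on balanced strands is bounded by α (the exact test is conservative); its
recall on simulated skew-0.95 artifacts is limited at low VAF, where few
alt reads carry little strand information.

## Synthetic cohort generator

The generator emulates the statistical structure of the inputs, not reads:

- **Territory.** Exon-like intervals with log-normal lengths (median 150 bp,
  σ = 0.6; a convenience — TMB arithmetic is length-model-independent) over
  8 chromosomes, totalling `exome_mb` (default 35.9). Panels are random exon
  subsets hitting their coding size exactly (last exon trimmed); defaults
  {1.2, 1.24, 1.2, 1.1, 1.3} MB.
- **Somatic variants.** Poisson at `tmb_true` per coding MB, uniform over
  the territory; VAF ~ Beta(mean = purity/2, concentration 20) — a
  single-clone diploid model, the minimal structure supporting the VAF-cutoff
  sensitivity analysis; default purity 0.8. Class mix: 25 % synonymous,
  remainder snv/indel/frameshift/splice/start_stop (62/12/10/10/6 %);
  splice offsets within ±2. SNV spectrum is C>T-rich (35 % C:G>T:A).
- **Germline.** A shared population catalog with log-uniform(1e-3, 0.5)
  MAFs, sized so the expected per-sample heterozygous count under
  Hardy-Weinberg genotyping is `germline_het_per_exome` (default 5000;
  homozygous sites follow from f²). All catalog sites are dbSNP-flagged with
  their MAF, so they fail the maf and dbsnp rules and are additionally
  caught by the panel of normals. Per-sample *private* germline variants
  (Poisson, mean = 3 % of the het load, i.e. ~150 per exome) carry no
  database annotation and survive tumor-only filtering — they are the
  germline overhead. Tumor and matched-normal allelic fractions are jittered
  independently around 0.5 (het) / 0.985 (hom).
- **Artifacts.** Tumor-only C:G>T:A calls at `artifact_rate_per_mb`
  (default 1.0), VAF ~ U(0.01, 0.06), strand skew 0.95 in a random
  direction. Under the 5 % VAF floor ~20 % of them still pass, so the
  estimator carries a contamination floor of ~0.2 artifacts per megabase —
  negligible against high burdens but a ~10 % relative overestimate at a
  true burden of 2 v/mb. This floor is real FFPE behavior, and is exactly
  why orientation-aware artifact filtering matters at low TMB.
- **Coverage.** Negative-binomial depth (mean 200, dispersion 10) per 500 bp
  block, drawn independently per assay; panel re-sequencing re-draws depth
  and read support from each variant's latent VAF, so panels show realistic
  assay noise and dropout (a variant with zero alt reads in an assay is not
  called there).
- **Panel of normals.** 21 normals genotyped from the same population
  catalog with per-normal Af jitter plus ~30 low-Af noise sites each.
- **Determinism.** Every quantity is drawn from a stream keyed by
  (seed, purpose, sample), so cohorts are byte-reproducible and extensible
  without perturbing existing samples.

What the generator does **not** emulate: trinucleotide context and
signature structure, subclonal architecture, copy number, sequence-context
coverage bias, caller-specific error modes, microsatellite instability.
Passing tests therefore demonstrate the correctness and internal
consistency of the filtering/denominator/harmonization machinery under a
realistic statistical structure — not performance on real FFPE data.

## Numerical and degenerate-input choices

Zero-variance correlation inputs, zero panel means and empty agreement
classes raise or return absent values rather than NaN. Territory merge is
an idempotent, order-independent sorted sweep; abutting intervals merge.
Coverage queries outside the owning territory are errors, while uncovered
bases inside it are explicit zeros. The VariantCall invariant
`vaf = alt/total` is enforced to 5e-3 to admit rounded inputs; VCF
round-trips preserve fractions to 1e-6. Analysis problem sizes (14-sample
harmonization cohort, 20-sample recovery cohort, 10-replicate panel-size
experiment) were chosen so each driver completes in seconds to a few
minutes on a single CPU while keeping Monte-Carlo error well inside the
effects examined.

## Known limitations

- The conversion factor is fit and applied on the same cohort (as in
  harmonization practice); a fit/apply split across cohorts is available in
  the library but not the default.
- The strand-imbalance flag is underpowered below ~10 alt reads; it is a
  diagnostic, not a filter.
- Panel correlations at n = 7 samples are themselves noisy; the simulator
  reproduces that honestly rather than smoothing it away.
- At very low true burden the artifact contamination floor dominates
  relative error (see above).
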