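# Methods

## Scope and data model

`refstab` treats an RT-qPCR experiment as a table of quantification
cycles Cq per (sample, gene, technical replicate), an array experiment as
a log2 expression matrix (probes × samples) with a many-to-one
probe→gene map, and clinical context as per-sample annotations: discrete
groups (stage, lymph-node status, recurrence), continuous covariates
(tumor volume in cm³; the DCE-MRI amplitude A_Brix, dimensionless, whose
low values mark hypoxic tumors), and competing-risk survival triples
(months, event ∈ {progression, competing_death, censored}). All I/O is
delimited UTF-8 text (CSV/TSV by extension); missing Cq tokens
`Undetermined`/`NA`/empty map to an undetermined value. Ids are
case-sensitive and whitespace-stripped; the decimal separator is `.`.

## Replicate QC and comparative ΔCq

Duplicate reactions are averaged per (sample, gene). A pair is excluded —
flagged, never errored — when mean Cq > 37 (detection limit), replicate
SD > 0.4 cycles (n−1 denominator; poor precision), or all replicates are
undetermined. Thresholds are strict inequalities, so boundary values
37.0 and 0.40 pass.

Normalized expression is the comparative-Cq quantity
ΔCq = Cq_gene − mean(Cq_refs); the package stores −ΔCq so that higher
values mean higher abundance. The method assumes amplification
efficiency 2 (one cycle per doubling); `cq_to_log_quantity` exposes the
general −Cq·log2(E) transform for E ∈ (1, 2]. Two identities follow
directly and are tested: the reference genes' ΔCq values sum to zero in
every sample, and any global per-sample shift (loading) cancels exactly.

Samples in which any *reference* gene failed QC cannot be normalized and
are dropped with a logged reason. For stability analysis, which needs a
complete matrix, QC-missing cells are resolved by complete-case deletion
of **samples** by default (preserving the candidate panel under
evaluation); deletion of genes is available as an option. Dropping genes
by default would let a single failed well eliminate a candidate from the
ranking, which is not how a panel evaluation should behave.

## geNorm

All computation is on the log2 scale, where expression ratios become
differences (this matches the definition of M as an SD of log ratios and
avoids overflow). Pairwise variation of two genes is the sample SD (n−1)
of their per-sample log2 difference; M is the mean pairwise variation
with all other candidates. Ranking proceeds by stepwise exclusion of the
highest-M gene, recomputing M each step, until two genes remain; those
two are reported tied (the measure cannot separate them) and ordered
alphabetically. Removal ties are broken by removing the alphabetically
last gene, for determinism. The trace records, per step, the remaining
set, the mean M over it (the quantity conventionally plotted), and the
removed gene's own M.

Normalization factors are per-sample arithmetic means of the selected
genes' log2 values (log of the geometric mean of relative quantities).
V_n/n+1 is the sample SD of NF_{n+1} − NF_n for n = 2…G−1 along the
ranking. `select_optimal_set` returns the smallest n with V_n/n+1 below
the 0.15 cutoff; if none falls below, all genes are returned with a
warning flag.

Pipeline-level panel selection passes `min_genes=3`: normalizing against
at least three reference genes is the established geNorm recommendation
for a final panel, and with a very stable pair V_2/3 is almost
automatically below any cutoff (for three equally stable independent
genes V_2/3 = σ/√6), so the bare "smallest n" rule would routinely stop
at two. The V criterion then decides only whether a fourth or fifth gene
is needed. The bare function keeps `min_genes=2` so the rule itself is
unchanged.

## NormFinder

The grouped model is y_igj = α_i + b_gj + d_ig + ε_igj with zero-sum
gene-by-group deviations d_ig and heteroscedastic noise. Estimation is
closed-form (no REML/ML iteration):

* residuals r_igj = y_igj − ȳ_ig· − ȳ_·gj + ȳ_··g within each group;
* σ̂²_ig = [G/(G−1)] · Σ_j r²_igj/(n_g−1), truncated at 0 (the factor
  undoes the variance absorbed by the per-sample means across G genes);
* d̂_ig = ȳ_ig· − ȳ_i·· − (ȳ_··g − ȳ_···), with sampling variance
  approximated by σ̂²_ig/n_g;
* empirical-Bayes shrinkage: prior variance
  γ̂² = max(0, var(d̂) − mean(σ̂²_ig/n_g)), and
  d̃_ig = d̂_ig · γ̂²/(γ̂² + σ̂²_ig/n_g) — so γ̂² = 0 collapses all
  deviations to zero and shrinkage always contracts.

The grouped stability value averages over groups
|d̃_ig| + √(s + γ̂²s/(γ̂² + s)) with s = σ̂²_ig/n_g; ungrouped it is the
residual SD. Ranking ascends, ties alphabetical. The exact estimator
constants follow this stated structure; what the package guarantees — and
what the tests assert — is parameter recovery: stability values that
rank genes by their true noise SD and penalize planted inter-group
shifts, with loading effects fully absorbed by b_gj. The zero-sum
constraint means a planted shift of one gene in one group is recovered
as (1 − 1/G) of its size, which the tests account for. Subgroup scans
run one grouped fit per clinical dichotomy; continuous covariates are
split at the cohort median with values equal to the median in the
below-or-equal group, mirroring the subgroup layout such analyses
report.

## Screening cascade

Gene-level decisions use the "at least one probe" rule throughout.
Thresholds: |log2 FC| > log2(1.5) under hypoxia in ≥1 cell line;
two-sided p < α = 0.05 for Spearman (A_Brix, tumor volume), Mann-Whitney
(dichotomies) and univariate Cox PH on progression (delegated to
lifelines; the contract is the exclusion decision, not the fitter);
mean log2 expression < 7. All strict. No multiple-testing correction by
default — a screen for *instability* should err toward exclusion — but
per-filter Benjamini-Hochberg is available. Constant probes and constant
covariates yield undefined correlations and never exclude (warned); the
outcome filter is skipped below 10 observed progressions. The filters
are mutually independent, so stage order (hypoxia → covariate → groups →
outcome → floor) affects only the bookkeeping counts, never the survivor
set — asserted by test. CV ranking uses SD/mean of the log2 values; note
this is not invariant to shifts of the log scale (tested explicitly),
which is why survivors are compared within expression-level tertile
bins.

## Validation

Spearman throughout (rank-based, hence invariant under strictly
monotone transforms — property-tested). The tertile split labels a
sample high when its value ≥ the 67th percentile (linear interpolation
between order statistics); an explicit cut can replace the percentile,
with the same ≥ boundary rule, so an all-equal input is entirely high.
Intra-tumor concordance asks, per tumor with ≥2 biopsies, whether all
biopsies fall on one side of the cut. Survival comparisons (cumulative
incidence under competing risks, Gray's test) are standard statistics
outside this package's contribution; `export_survival_table` emits the
grouped (sample, group, time, event) table they consume.

## Synthetic cohorts

The generator's defaults emulate the study design the package targets:
a 74-patient qPCR cohort (150 with A_Brix on 42 for array screening; 32
observed A_Brix in the validation-sized cohort), eight cell lines in
paired normoxic/hypoxic culture, duplicate reactions, and eight tumors
with 22 biopsies total. The default candidate panel plants CHCHD1,
SRSF9, TMBIM6 as stable (biological SD 0.15 log2), two candidates as
pure noise (SD 0.6), two tracking A_Brix (|slope| 0.45/SD plus residual
0.4 — total SD ≈ 0.6), two group-shifted (0.8 log2 in one clinical
group, residual 0.4), and three hypoxia-induced targets (A_Brix slope
−0.5, residual 0.5, cell-line fold changes 1.2–2 log2; STC2 also carries
a log-hazard coefficient 0.6). These magnitudes follow the panel design
being emulated: stable genes well under the M ≈ 0.5 practice threshold,
unstable ones clearly outside it.

Generative layers: log2 signal = base + covariate/group effects +
biological noise; array value = signal + N(0, 0.1) per probe;
Cq = 35 − signal + loading + N(0, 0.15) per replicate, with per-sample
loading N(0, 0.5) — the 35-cycle offset is arbitrary and cancels in
every contrast. A_Brix is lognormal(log 1.51, 0.4), matching the
reported cohort median and range; survival is exponential progression
(rate 0.0095/month ⇒ ≈43% progress by 60 months) against a competing
death rate 0.0012/month, administrative censoring at 60 months and 15%
uniform dropout from month 24. All randomness flows from one explicit
seed (independent streams per generator function); same seed ⇒
byte-identical output.

What the generator does *not* emulate: probe-level chemistry and
cross-hybridization, RNA-quality (RIN) degradation effects, plate/batch
layouts, inter-plate calibrators, and correlated co-regulation among
candidates beyond the planted effects. Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
structure, not robustness to those real-data artifacts.

## Problem sizes and numerical choices

Simulation-based tests use the emulated cohort sizes (n = 74 for
end-to-end recovery over 50 seeds; n = 200 for NormFinder recovery over
20 seeds; 200 genes for screening calibration pooled over 3 seeds;
n = 500 for loading-removal checks, where a single gene's chance
correlation with the loading vector has SD ≈ 1/√500, so the check uses
the mean absolute correlation across ~20 genes). Invariance assertions
use 1e−9 absolute tolerance; exact identities use 1e−12. Variance
truncations at zero are the only projections applied. Degenerate inputs
are contracts, not crashes: two-gene geNorm reports a tied pair, empty
reference lists and constant covariates raise, QC failures flag.

## Known limitations

* geNorm cannot separate the final two genes, and co-regulated
  candidates depress each other's M — the screening stage's pathway
  reasoning is out of scope (only CV/expression helpers support it).
* The NormFinder uncertainty term is one defensible choice among the
  closed-form variants; rankings, not absolute stability values, are
  the supported output.
* Efficiency-corrected (standard-curve) quantification and inter-plate
  calibration are not implemented; the comparative method assumes
  near-perfect efficiency, which should be verified upstream.
* The Cox filter uses lifelines' default Wald p-values, which are
  mildly conservative at moderate event counts.
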