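# Methods

## Scope and data model

The package analyses a two-group tumor cohort (group A = TNBC, group B =
non-TNBC throughout the defaults) measured on two platforms: aCGH probe
log2 ratios (test vs. reference DNA) for copy number, and NanoString-style
miRNA counts with housekeeping/positive/negative control probes for
expression. The two assays may cover different sample subsets; each stage
uses the samples available to it. All genomic coordinates are 1-based
inclusive internally; BED input is converted on read (start+1, stop) and
back on write. Chromosome labels normalize to `chrN`.

## Copy-number stage

**Segment calling.** The upstream vendor segmentation algorithm behind the
source data is proprietary; the caller here emits maximal runs of
consecutive same-sign probes and applies the two published filters: at
least `min_probes = 3` probes and `|mean log2| > abs_threshold = 0.25`.
A probe with log2 ratio exactly 0 breaks a run. Segment bounds are the
first/last probe positions of the run, so planted breakpoints are resolved
only to the probe grid. This caller is deliberately simple and is validated
by construction rather than against the proprietary algorithm.

**Burden summary.** Group means/SDs of per-case call counts use the
flagged-case denominator (cases with ≥ 1 call) — the convention under
which the published per-case averages (total/flagged, e.g. 292/16 = 18.25)
reconcile. Groups are compared by a Welch t-test on per-case counts; with
fewer than two flagged cases in a group the test is reported as undefined.

**Recurrent regions.** Per chromosome and direction, atomic intervals are
formed between the union of all segment breakpoints; each atom counts its
distinct supporting cases. Atoms with penetrance `n/denominator ≥
min_frequency` (default 0.25, inclusive — exact-25% regions appear in the
published tables, so the threshold is inclusive by default and exposed as
a flag) are retained, and contiguous retained atoms of one direction merge.
A merged region's `n_cases` is the minimum over its atoms, preserving the
invariant that every base of an emitted region is supported by at least
`n_cases` segments. The denominator defaults to the number of cases with
≥ 1 call. Gains and losses are scored independently, so one base can sit in
a gain region and a loss region supported by different cases.

## Expression stage

**Normalization** follows published nCounter guidance at the level the
source describes, as an explicit three-step scheme: (1) per-sample scaling
by (cohort geometric mean of per-sample positive-control geometric means) /
(sample positive-control geometric mean); (2) background subtraction of
mean(negative) + 2·SD(negative), floored at zero; (3) housekeeping content
scaling computed like step 1; then log2(x + 1). A sample whose
positive-control (or post-background housekeeping) geometric mean is zero
cannot be normalized and raises an error naming the sample. On a matrix
with flat controls and zero negatives the scheme is exactly idempotent.

**Differential expression** is a per-miRNA Welch (unequal-variance) t-test
on log2 values — the unequal-variance choice mirrors the clinical t-tests;
the pooled-variance alternative was not stated by the source and is not
offered. log2FC is mean(A) − mean(B), so up-regulation in TNBC is positive.
BH adjustment runs across all endogenous miRNAs; the significant set
requires both `p ≤ 0.05` and `q ≤ 0.25`. A zero-variance miRNA with equal
group means gets p = 1 (t = 0) by convention; with unequal means p = 0.

**Clustering** uses 1 − Pearson correlation distance with average linkage
(scipy's implementation; ties resolved by scipy's deterministic nearest-
pair scan, so repeated runs on identical input agree). Results are
invariant to global affine transforms of the profiles. Zero-variance
profiles make the correlation undefined and raise with the profile name.
Trees serialize to Newick with branch lengths from merge-height
differences.

## Integration stage

Mapping uses any-overlap (≥ 1 base) between a miRNA locus and a retained
region; when several regions overlap, the largest overlap wins (first in
genome order on ties). All bundled panel loci are strictly contained in
single regions, so the tie rule is exercised only by synthetic data. DE
miRNAs without a locus record are logged and stay in the DE denominator but
cannot map. Concordance keeps gain∧up and loss∧down entries, sorted by
chromosome and start.

Target voting retains a (miRNA, gene) pair present in ≥ `min_databases`
(default 2) prediction sets; gene symbols are uppercased and stripped, with
no alias resolution. The reduction statistic treats the voted-target union
across panel miRNAs as a flat set (per-miRNA multiplicity is not counted;
the source is ambiguous on this point and the flat-set reading is used).
Percentages report to one decimal place; zero denominators report as
not-applicable (None).

## Panel evaluation

AUC is the tie-aware Mann–Whitney probability (ties 0.5), computed from
midranks; its 95% CI uses the DeLong structural-component variance
(Var = var(V10)/m + var(V01)/n). Per-miRNA AUCs are reported oriented —
max(AUC, 1 − AUC) with a flag — because a panel contains both up- and
down-regulated members. Under perfect separation the DeLong variance is
zero and the interval collapses to the point.

The source does not state how its combined-panel AUC was obtained. The
implementation here standardizes each panel miRNA, fits an unpenalized
logistic combination (ridge-stabilized with a small fixed penalty under
perfect separation, flagged on the model), reports the apparent
(resubstitution) AUC of the linear predictor, and attaches a stratified
percentile-bootstrap 95% interval (class counts preserved; the interval is
widened if needed to contain the apparent AUC, which resubstitution bias
can push above the bootstrap percentiles). Published values from the
original cohort are therefore not reproduction targets — only the
machinery is, and it is validated by enumeration oracles and simulation.

"Altered expression" per case is not defined by the source; the rule here
flags a panel miRNA in a case when its z-score against the reference-group
mean/SD exceeds 1.96 in the direction of the miRNA's panel log2FC sign.
The threshold and reference group are arguments.

## Clinical association

Continuous covariates (age, tumor size) are log-transformed before a Welch
t-test; categorical covariates use a two-sided Fisher exact test on
collapsed 2×2 tables (grade I/II vs III; stage well/moderately vs poorly
differentiated; lymph node ±; histology ductal vs other). Missing values
are dropped pairwise, so each variable reports its own n; an empty margin
returns p = 1, flagged.

Per-miRNA models are OLS with log2 expression as outcome and subtype, age,
tumor size, lymph node, histology, and grade *or* stage (never both — they
overlap almost completely) as covariates. Rank-deficient designs raise an
error listing aliased covariates. Log base 2 is used for "log-transformed"
outcomes, consistent with the log2FC scale.

Multiple imputation is chained equations with type-1 predictive-mean
matching (k = 5 donors, 10 burn-in iterations per chain, one independent
chain per imputed dataset, all driven by one seeded generator). PMM draws
donors' observed values, so binary covariates stay binary. Per-imputation
OLS fits pool by Rubin's rules: `T = W + (1 + 1/m)·B`, with the
Barnard–Rubin-style df `(m−1)(1 + W/((1+1/m)B))²`; when B = 0 (no
missingness) the complete-data residual df is used, making pooled output
exactly equal to the complete-case fit. A purpose-built imputer is used
rather than an off-the-shelf one to guarantee bit-identical output under a
fixed seed and native handling of the binary-coded covariates.

## Enrichment

Over-representation is the hypergeometric upper tail P[X ≥ overlap] for
X ~ Hyp(universe, set size, query size), BH-adjusted across sets (one
shared BH implementation serves the whole package). The default universe is
the union of all set members; supplying an explicit universe changes the
test, and query genes outside it are dropped with a warning. The
miRNA × pathway matrix counts each miRNA's targets per set and can be fed
to the hierarchical clustering for panel subgrouping. Curated pathway
content is consumed as GMT input, never bundled; results depend on the
supplied collection and are not comparable across collections.

## Synthetic cohorts

The generator emulates the reference study's statistical structure, not its
raw data (which was never deposited):

- **Sizes.** Defaults: 25 group-A and 16 group-B cases (the aCGH arm);
  expression examples often use 19 + 24 (the expression arm).
- **Regions.** Each case carries each configured region independently with
  its group's penetrance (defaults: the published regions at their
  published frequencies, group-exclusive). Probes inside a carried region
  shift by ±0.58 log2 = log2(3/2), a single-copy gain/loss — the source
  states only the ±0.25 call threshold, so the true effect size is a
  design choice. Probe noise SD 0.2; probes every 1 Mb by default.
- **miRNAs.** log2 expression = baseline (default 8 ≈ 256 counts) +
  subtype log2FC (group A only; defaults: the published panel fold
  changes) + dosage coupling × (±1 per carried overlapping region; default
  0.58) + N(0, 0.5), plus a per-sample N(0, 0.3) log2 library shift,
  exponentiated and rounded. Counts are therefore log-normal-ish — the
  real platform's count distribution is unstated. Positive controls follow
  a fixed geometric ladder scaled by the library shift; negatives are
  Poisson(2); housekeeping sits at log2 = 10 with SD 0.05. 783 null
  miRNAs (total 800 endogenous, matching the assay's codeset size) live on
  a separate contig so they never overlap planted regions.
- **Clinical.** Age ~ N(56, 12) truncated at 16; tumor size lognormal with
  median 3 cm; categorical probabilities per group shaped like the
  published cohort (e.g. P(grade III) 0.48 vs 0.19). Missingness is MCAR
  per covariate (default rate 0.15).

What passing tests show: the machinery recovers planted penetrances, fold
changes and regression effects, controls type-I error, and satisfies the
exact combinatorial identities. What they do not show: robustness to FFPE
artifacts, probe GC bias, tumor purity, batch effects, non-MCAR
missingness, or any real count distribution — none of which the generator
models.

## Numerical choices and problem sizes

Determinism: every stochastic routine takes a seed and uses an isolated
`numpy` Generator; identical seeds give byte-identical outputs. Monte-Carlo
checks in the test suite use desk-scale sizes chosen so the whole suite
runs in well under a minute — e.g. 400 replicate cohorts for the
penetrance-recovery check, 200 simulations for effect-recovery and 300 for
type-I error — with acceptance bands of 3 standard errors computed at the
n actually used. Exhaustive oracles (AUC pair enumeration, Fisher table
enumeration, per-base region counting) run on small inputs where full
enumeration is feasible.

## Known limitations

- The segment caller is a stated-filter run caller, not a re-implementation
  of the vendor's algorithm; segment boundaries resolve to the probe grid.
- The combined-panel score and the per-case alteration rule are documented
  stand-ins for methods the source leaves unspecified; their outputs on the
  original cohort are not comparable quantities.
- Cytoband labels are pass-through strings; no karyotype lookup.
- No survival analysis, ordinal/interaction models, MNAR sensitivity,
  batch correction, or tumor-purity adjustment.
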