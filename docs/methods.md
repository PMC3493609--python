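# Methods

This note documents the statistical procedures, default parameters and
design choices behind `lipidcohort`, and what the synthetic-data tests do
and do not demonstrate about real cohorts.

## Data model and quality control

A cohort is a subjects × metabolites matrix of strictly positive
concentrations with explicit NaN missingness (never zeros — all downstream
statistics are log-scale), a two-level group factor, and clinical
covariates. Units are fixed per metabolite (µM for NEFA, nM for oxylipins
and endocannabinoids) and never converted implicitly; class sums refuse
mixed units.

Raw quantification records are corrected for surrogate losses by dividing
the raw concentration by the surrogate recovery fraction. The reporting
rule drops a record iff S/N < 2, concentration < lowest calibrant, or
recovery < 40%; all three comparisons are strict, so a record exactly at a
threshold is reported. This is a deliberate literal reading of the usual
phrasing of such criteria ("below 40%"); the filter partitions its input
and is idempotent. At the cohort level two application modes exist:
mask failing values per subject, or (default) exclude a metabolite
panel-wide when more than 50% of either group is unreportable — the
default mirrors all-or-nothing reporting tables in which a metabolite
either appears with full group summaries or not at all.

## Univariate statistics

Group location is summarized by the geometric mean GM = exp(mean(ln x)),
the natural summary for log-normal concentration data, and the group
effect by the percent change ΔGM = 100·(GM₁ − GM₀)/GM₀. Report tables
round GMs to 3 significant figures and ΔGM to the nearest integer percent.

Group differences are tested by the two-sided Mann–Whitney U test with
midranks for ties. Two modes: `exact` enumerates the full permutation null
of U over group labelings (valid under ties; limited to n₁+n₂ ≤ 20, with
the two-sided p defined as the tail probability of |U − n₁n₂/2|), and
`normal-approx` (default at the study's 12/43 sizes) uses the
tie-corrected normal approximation with continuity correction via SciPy.

Multiplicity is controlled by Benjamini–Hochberg step-up FDR at q = 0.1.
The FDR family is one `summarize_cohort` call — by default the whole
panel including computed class sums — rather than per report table; this
is the conservative and explicit choice since the family used originally
is not recoverable. Class Σ rows are computed per subject before any GM,
because the GM of sums is not the sum of GMs.

## Enzyme-activity indices

Plasma NEFA product:substrate ratios proxy desaturase/elongase
activities: SCD (16:1n7/16:0, 18:1n9/18:0), D6D (18:3n6/18:2n6,
20:3n3/20:4n6), ELOVL2 (22:4n6/20:4n6, 22:5n3/20:5n3) and the composite
ELOVL2/D6D/SPCS chain-shortening axis (22:5n6/22:4n6, 22:6n3/22:5n3).
Because GM is multiplicative, GM(product/substrate) = GM(product)/GM(substrate)
exactly on complete data, and ratio ΔGM is invariant to common unit
rescaling.

A composite index value for a subject is the **arithmetic mean** of that
subject's component ratios; subjects missing any component are excluded
(no imputation). The arithmetic-mean convention is adopted because it
reproduces the reported composite SCD and ELOVL2 geometric means from
their reported component GMs at printed precision; it does not reproduce
the reported non-diabetic ELOVL2/D6D/SPCS composite (6.71 vs 5.94 from
components), which was presumably computed per subject on unrounded data —
that row's absolute level is therefore not treated as a fixture, though
its ΔGM is self-consistent.

## Discriminant modeling

Features are natural-log transformed, mean-centered and scaled to unit
variance, with all parameters fitted on training rows only. The class
vector is coded {0,1} and centered; the classification threshold is the
midpoint of the class mean predictions.

**PLS-DA** uses NIPALS for a single response: wₐ ∝ Xₐ'y (normalized),
tₐ = Xₐwₐ, pₐ = Xₐ'tₐ/tₐ'tₐ, qₐ = y'tₐ/tₐ'tₐ, then deflation
Xₐ₊₁ = Xₐ − tₐpₐ'. The regression vector is B = W(P'W)⁻¹q. There is no
randomized initialization; successive score vectors are mutually
orthogonal by construction.

**OPLS-DA** fixes the predictive weight w ∝ X'y and iteratively removes
orthogonal components: p = X't/t't, w_o ∝ p − (w'p)w, t_o = Xw_o,
deflate by t_o p_o'. Since w_o ⊥ w and X'y ∝ w, orthogonal scores have
exactly zero sample correlation with the class vector. One predictive
latent variable is fitted on the filtered matrix; its fitted values
coincide with (k+1)-component PLS-DA to machine precision, which the test
suite verifies over random instances. New data are filtered with the
stored (w_o, p_o) pairs before prediction. The reporting model defaults
to one orthogonal component; predictive scores are oriented so the
disease group scores positive, making disease-elevated features load
positive.

**Q²** = 1 − PRESS/TSS accumulates squared held-out prediction errors
over stratified k-fold cross-validation (default 7 folds, the common
chemometrics convention), with log/center/scale preprocessing refitted in
each training fold and TSS taken about the training-fold mean. A
venetian-blind (every-kth-sample) fold scheme is available since the fold
scheme used by commercial chemometrics software is not documented.
**AUROC** is the Mann–Whitney concordance probability P(s₊>s₋) + ½P(tie)
computed from ranks.

**External validation** splits the cohort, stratified by class, into
three near-equal test blocks that partition it exactly (at 12+43 subjects
the test sets hold 18, 18 and 19); each block is predicted by a model
trained on the complement, and performance is reported per repeat and as
mean ± sd.

## Iterative variable selection

One IVS run, deterministic given its seed (NumPy PCG64):

1. fix a stratified fold assignment for the whole run, so greedy move
   comparisons are evaluated on a noise-free objective;
2. randomly partition the candidate set into ⌈p/20⌉ subsets (small enough
   for exhaustive single-move search);
3. within each subset, converge backward deletion (remove the variable
   whose removal most improves cross-validated Q², while any removal
   improves it by more than the tolerance, default 1e-4), then forward
   re-addition, cycling until 1-move optimality;
4. union the subset optima and repeat from (2) on the union until the
   outer objective gain falls below tolerance (cap: 10 outer iterations).

Accepted moves strictly improve the objective, so each run's trajectory
is non-decreasing. Ties on objective gain break to the lexicographically
first variable name, independent of the seed. The ensemble draws run
seeds from `SeedSequence(seed).generate_state(n_runs)`, giving the prefix
property (the first k runs are identical for any ensemble size), and
returns the max-Q² run, preferring smaller selections then lower run
index on exact ties.

Feature selection is deliberately *not* nested inside the final model's
cross-validation — matching the original small-cohort workflow — so the
reported Q² of an IVS-selected model is optimistic. `overfitting_estimate`
quantifies that optimism directly: for each of 7 stratified 2/3–1/3
splits, a full IVS ensemble runs on the training portion alone and the
winner's training Q² is compared with its held-out Q²; the mean ± sd
percent drop is reported (relative to training Q² when positive,
otherwise in absolute Q² points).

## Correlation networks

Per-group Spearman ρ and p matrices (midranks; t-approximation p-values,
appropriate at n = 12/43, with an exact permutation option for n ≤ 8)
cover metabolites plus clinical covariates; variables constant within a
group are masked. The heatmap export places the reference group strictly
above the diagonal and the disease group below.

Connectivity networks embed the distance d = 1 − |ρ| (masked entries → 1)
by MDS. The default is seeded SMACOF stress majorization initialized from
the classical (Torgerson) solution; classical MDS alone is the
deterministic fallback and reconstructs dims-realizable configurations
exactly. The embedding defaults to 2 dimensions (a 3-D option exists) and
is reported with Kruskal stress-1. A rigid alignment (translation +
rotation only, distances untouched) places the glucose node at the origin
and the SFA centroid in the lower-right quadrant for display consistency.
Edges are pairs significant in that group — defaults p < 0.05 (reference)
and p < 0.01 (disease), with no multiple-testing correction, as is
conventional for these displays — signed by ρ. Edge sets are nested
across thresholds by construction.

Metabolite classes with at least dims+2 embedded members receive
Hotelling T² ellipses: center = mean, shape = sample covariance, boundary
radius² = dims(k−1)/(k−dims)·F₁₋α(dims, k−dims), times (k+1)/k for the
default prediction (new observation) region; α = 0.05.

The pathway graph places annotated metabolites as nodes sized by |ΔGM|
and draws substrate→product edges widthed by |ΔP:S|, both colored
increased/decreased/not-significant from the FDR decisions; edges lacking
a ratio result are drawn gray with zero width and flagged.

## Synthetic cohort generator

The generator emulates the study design the chain assumes: two groups of
12 and 43 subjects; per-metabolite log-normal concentrations with the
group effect entering only as a location shift on the log scale (median =
group GM); pathway-coupled metabolites generated as substrate × log-normal
ratio so that product/substrate ratio GMs are controlled exactly; and
Gaussian clinical covariates optionally rank-coupled to a named variable
via a Gaussian copula (latent Pearson r = 2·sin(πρₛ/6) for a Spearman
target ρₛ, infeasible beyond |ρₛ| > 0.999). Everything is reproducible
bitwise from the seed.

`default_paper_spec` anchors ~40 panel variables at reported cohort
geometric means, with log-scale sds back-calculated from reported
[min, max] ranges under the assumption that an observed range at these
group sizes spans about ±2.5 log-sd. Specific choices:

- Class totals (Σ NEFA, Σ SFA, Σ MUFA, Σ PUFA, Σ NAE, Σ LAA) are
  generated as their own anchored variables rather than as sums of the
  generated species: only a subset of species is anchored and their
  inter-correlations are unknown, so a literal sum could not match the
  reported totals. Consequently generated totals are internally
  independent of their nominal components — acceptable for testing the
  statistics, not a claim about real covariance structure.
- Index metabolites without reported concentrations are back-derived for
  internal consistency with reported ratios (20:5n3 from 22:5n3 and the
  0.82/1.40 ratio; 20:4n6 from 22:4n6 and the 0.02/0.03 ratio) or
  generated by couplings at the reported ratio GMs (18:3n6, 20:3n3,
  22:5n6, 22:6n3), with ratio log-sd defaulting to 0.25 — tight enough
  that index direction is stable at n = 12/43, loose enough for realistic
  subject scatter.
- Clinical covariates use the reported mean ± sd per group; fasting
  glucose is coupled to total NEFA at Spearman ρ = 0.68 (the reported
  association) and HbA1c to the same axis at ρ = 0.5. A reported sd of
  ±0 (lactate) is replaced by 0.2 mmol/L to avoid a degenerate law.

What passing tests show — and what they do not: the generator produces
the marginal laws, effect sizes and a single planted covariate coupling;
it does not simulate the dense inter-metabolite correlation fabric,
batch/instrument effects, medication effects or non-log-normal tails of
real plasma panels. Tests on it validate the *statistical machinery*
(calibration, recovery, invariances), not biological conclusions.

## Numerical choices and problem sizes

- Positivity, two-level groups and annotation coverage are validated at
  table construction; zero-variance features fail preprocessing by name
  (detected at relative tolerance 1e-10).
- Exact Mann–Whitney enumeration is capped at n₁+n₂ = 20; Spearman exact
  permutation at n = 8.
- NIPALS stops with an error when a requested component exceeds the
  predictive rank (‖X'y‖ vanishing relative to ‖X‖).
- Test-suite simulation sizes are chosen to keep the default run at
  laptop scale: 50 seeded repetitions × 5-run ensembles for the
  planted-recovery benchmark, 200 replicates for null-calibration checks,
  n = 2000/group for generator-fidelity checks, n = 5000 for ellipse
  coverage. The pipeline default of 20 IVS runs (CLI `--runs` overrides,
  library default 100) keeps full bundles under a few seconds.

## Known limitations

- Composite-index aggregation beyond the arithmetic-mean convention
  (e.g. the original ELOVL2/D6D/SPCS composite level) is not recoverable
  from printed summaries.
- The Mann–Whitney normal approximation is used by default at n = 12/43;
  exact enumeration is impractical there, and p-values near the FDR
  boundary can differ slightly from an exact test's.
- SMACOF stress depends weakly on the seed; classical MDS is provided
  where strict determinism across library versions matters.
- The generator's independence between anchored totals and their species
  (above) means computed Σ rows ("Σ SFA (computed)") and anchored Σ
  variables differ by design.
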