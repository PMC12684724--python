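# Methods

`isocontext` analyzes stable-isotope labeling experiments from the
feature-table level up: it finds isotopologue ladders without a target
list, converts them into corrected mass isotopomer distributions
(MIDs), and places unknown metabolites next to annotated ones through
MID-similarity networks. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic benchmark
does and does not demonstrate.

## Isotopologue detection

A tracer such as U-13C-glucose shifts part of every downstream
metabolite's isotopologue envelope upward by multiples of the
13C-12C mass difference (1.0033548 Da; 15N 0.9970349, 2H 1.0062767).
Detection scans base features in descending mean unlabeled intensity
and, for each, assembles candidate members at

    m/z(n) ~ m/z(base) + n * delta / z,   n = 1..n_max

within a retention-time window. Two grouping details differ from the
naive "window around base + n*delta" formulation and exist because both
m/z values in the comparison are *measured*:

* **Pair tolerance.** `ppm_tol` is the per-feature mass accuracy. When
  two measured values are compared, their errors add, so the member
  window is `pair_tol_factor * ppm_tol` (default factor 2, the
  worst-case propagation of two ±`ppm_tol` errors). With independent
  2 ppm errors per feature, a raw 5 ppm pair window would lose ~8% of
  true members; the propagated window loses ~0.04%.
* **Ladder-chain targets.** Each n's target is extrapolated from the
  nearest already-matched member, not from the base, so one unlucky
  base-feature mass error cannot shift every target of the ladder at
  once. Per-link errors are then independent.

For each candidate group, member intensities are normalized within each
sample to relative intensities (vectors indexed by isotopologue index
n; an n with no feature contributes zero — a dropout gap must not shift
the distribution). This makes detection invariant to rescaling any
single sample. At every position n >= 1 a two-sided Welch t-test
compares labeled versus unlabeled relative intensities; a group is
retained when its smallest p-value reaches `alpha` and (by default) the
labeled mean exceeds the unlabeled mean at some position. Retained
groups consume their members, so no feature belongs to two groups and
the greedy scan is deterministic.

**Multiplicity.** A run tests many base x position hypotheses, so raw
per-test `alpha` would give a family-wise false-detection rate far
above `alpha`. Benjamini–Hochberg adjustment across all tests of the
run is therefore the default (`fdr=True`); under a complete null the
probability of any detected group is then bounded by `alpha`, which is
the property the null-simulation test checks. Strong real signals
(p ~ 1e-4 at 3+3 replicates and 5% CV) are unaffected.

Defaults: `ppm_tol` 5 ppm, `rt_window` 10 s, `n_max` 10, charge 1,
`alpha` 0.05, `min_replicates` 2, noise floor 0 (intensity units are
instrument-arbitrary, so no universal floor is meaningful).

## MID correction

Writing the unlabeled condition's measured MID as the kernel
`u = (u_0..u_{L-1})`, the measured labeled MID `m` is modeled as

    m = C(u) f,     C[i, j] = u[i-j]   (0 for i < j),

where `f` is the tracer-incorporation distribution. `C` is lower
triangular; truncated columns are **not** renormalized — mass the model
cannot place belongs in the reported residual, not hidden by rescaling.
Correction solves `min ||C f - m||_2, f >= 0` (non-negative least
squares) and renormalizes `f` to the simplex. Using the *measured*
unlabeled MID as kernel (rather than a theoretical pattern) means
instrument effects common to both tracer states cancel; it also means
no formula is required, which is what makes the step non-targeted.

Per-sample MIDs are normalized first and averaged afterwards, so each
replicate contributes equally regardless of its total intensity. The
per-element sd of the corrected MID comes from correcting each labeled
replicate separately — assumption-light but approximate (it folds the
kernel's sampling error into every replicate identically).
Unequal-length vectors are zero-padded everywhere; `correct_mid(u, u)`
returns e0 to machine precision for any valid kernel (self-correction
identity, tested over 1000 random kernels).

## Labeling filters

* `min_labeled_enrichment` (default 0.05): enrichment is 1 - M0 of the
  corrected MID, the fraction of molecules carrying any label.
* `max_unlabeled_labeling` (default 0.05): apparent labeling
  1 - M0 of the raw unlabeled MID. A compound with k tracer-element
  atoms shows 1 - (1-p)^k apparent labeling from natural abundance
  alone (~12% at k = 12 for 13C), so when an annotated formula is
  available the expected natural tail is added to the threshold
  (`natural_tail_allowance`, binomial expectation). Without a formula
  the raw threshold applies.
* `min_quantification`, `max_residual` (default 0.05),
  `min_replicate_fraction` (default 0.5): intensity floor,
  reconstruction-error ceiling, and minimum fraction of labeled
  replicates with usable data.

Rules are evaluated in that order and a rejection carries the first
failing rule's name. The kept set shrinks monotonically as any
threshold tightens.

## Contextualization

Nodes are metabolites (group IDs or user-supplied node IDs) with one
MID per (experiment, condition). Similarity between two nodes is
computed per shared scope and combined by mean (default) or min;
vectors of different lengths are zero-padded. Metrics: cosine
(default), or a Euclidean score 1 - ||a-b||/sqrt(2) normalized by the
simplex diameter so both live in [0, 1]. Edges at or above the
threshold (default 0.9) form an undirected network; isolated nodes are
kept. Network filtering drops edges below a similarity floor, then
nodes with out-of-range degree, in one deterministic pass without
cascade recomputation. Pathway overlay matches context nodes to
Cytoscape-JSON pathway nodes by exact identifier equality (node id,
display name, or a user-supplied identifier map; optional
case-folding); duplicate identifiers among pathway nodes are an error
rather than a silent choice. No graph layout is computed — exports are
plain Cytoscape JSON plus edge/match CSVs.

The defaults (cosine, mean, 0.9) are design choices, surfaced as flags:
no single similarity definition is canonical for MID comparison.

## Synthetic data: what it emulates and what it does not

The simulator is the package's test bed and defines its study
conditions. Per compound it draws one feature per isotopologue with
expected fraction above 1e-8, at the adduct m/z plus n * delta/z with
Gaussian per-feature ppm jitter (sd 2 ppm), shared retention time with
jitter (sd 1 s), and per-sample intensities `base_abundance * fraction *
lognormal(cv)` (unit-mean multiplicative noise, cv 5% — multiplicative
noise matches MS intensity behavior). The measured labeled MID is the
incorporation distribution convolved with the natural pattern,
truncated at the tracer-atom count and renormalized — algebraically
identical to `C(u) f` renormalized, so in the noise-free limit the
pipeline must recover every incorporation distribution to numerical
precision, and does (max-abs error ~1e-16).

The benchmark panel: 20 compounds (6-12 carbons) in 4 pathway groups
whose incorporation patterns are small multiplicative perturbations of
4 base patterns; within-group cosine >= 0.95 and cross-group < 0.8 are
asserted at generation time. 3+3 replicates, 50 decoy features drawn
uniformly over the observed m/z / retention-time ranges with no
isotopologue partners. The null configuration draws labeled samples
from the unlabeled model (incorporation = e0).

Deliberate simplifications: only the tracer element contributes natural
isotopes (no O/S fine structure — harmless for the pipeline round trip
because correction only ever sees the simulated unlabeled measurement,
but real 13C data has slightly heavier M+1/M+2 tails); no
chromatographic peak shapes; no adduct cross-talk; decoys carry no
correlation structure. Mass errors are drawn independently per feature,
which is *harsher* than real instruments (where errors correlate within
a run); the pair-tolerance and chain-matching design above exists to
survive exactly this. Passing the benchmark therefore demonstrates the
statistical and numerical machinery, not robustness to chromatographic
artifacts or adduct confusion.

## Numerical choices and degenerate inputs

* Welch test: zero variance in both groups returns p = 1 for equal
  means and the p -> 0 limit (infinite t) otherwise, so the noise-free
  configuration detects cleanly instead of dividing by zero.
* NNLS all-zero solutions (possible only for pathological kernels with
  u_0 = 0) raise a degenerate-solution error.
* MID CSV rows are renormalized when their sum is within 2% of 1
  (third-party exports are rounded) and rejected beyond that; sums
  within 1e-9 of 1 are left untouched for bit-stability.
* All numeric CSV output uses shortest round-trip `repr`; readers parse
  with correctly-rounded conversion, so write/read cycles are
  bit-exact (identifiers exact, numerics to the last ulp).
* Ties are broken deterministically everywhere (closest m/z then
  feature id; similarity then node id; combined normalized distance
  then compound name).

## Problem sizes used in the shipped checks

Self-correction: 1000 random kernels, lengths 2-12. Deconvolution
oracle: 200 random (f, u) pairs at L <= 4 against an exhaustive
simplex-direction grid (coarse 0.01 pass plus exhaustive 0.001
refinement box around the coarse optimum — exact for this convex
objective — with the ray scale solved in closed form); the solver's
objective must not exceed the grid's by more than 1e-6. Type-I: 200
null simulations of 5 compounds each. Benchmark: the 20-compound panel
above. These sizes give stable Monte-Carlo estimates (binomial SE
~1.5% at n = 200) while keeping the full suite in the low tens of
seconds.

## Known limitations

Single charge state per run, no per-feature charge inference; no
adduct grouping across features; no tracer-purity correction; no
theoretical natural-abundance correction without an unlabeled
measurement; no flux estimation; node identity across experiments is
by supplied node id only (no m/z-RT re-matching); the MS2 score is one
fixed metric (greedy sqrt-intensity cosine), not a library of metrics.
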