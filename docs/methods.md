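# Methods

This note documents the statistical models, the numerical choices, and the
design decisions behind `bprsnet`, in the order the pipeline runs them.

## Data model

The raw input is an n × p matrix of integer category scores in 1..K
(default: the 18 BPRS items on a 7-point scale), plus an item catalog
giving each item a code, a full name and a group label (the packaged BPRS
catalog carries the 8 DSM / 10 non-DSM split). Loading is strict by
default: any missing, non-integer or out-of-range cell aborts with the
offending row/column named (`reject-file`); a `drop-row` policy removes and
counts the affected rows instead. The strict default reflects how complete
scale forms are typically required at enrollment; how partially missing
forms should be treated is genuinely study-specific, so it is a switch, not
a guess.

Item summaries (per-category counts, percentages, means, SDs) use the n−1
SD denominator and half-up rounding to one decimal, the conventions of
printed clinical tables. Both denominators reproduce the packaged reference
table at one decimal, so the choice is conventional. One inconsistency in
that source table is worth knowing: the printed counts for the
disorientation item imply a mean of 1.35 (→ 1.3) while the printed mean is
1.4; the package reports what the counts imply.

The high-dose antipsychotic flag is a single rule: chlorpromazine
equivalent ≥ 1000 mg/day or prescribed/defined daily-dose ratio ≥ 1.5,
both bounds inclusive.

## Polychoric correlation

Two-step estimator. Step 1 sets per-item thresholds at Φ⁻¹ of the
cumulative category proportions; step 2 holds them fixed and maximizes each
pair's contingency log-likelihood Σ_ab n_ab log π_ab(ρ) over
ρ ∈ [−0.999, 0.999] (bounded Brent, xatol 1e−6). The two-step form is the
standard default of the psychometric tooling and decouples testing of the
two steps; full joint ML differs negligibly at these sample sizes.

Numerical choices:

* Rectangle probabilities come from a closed-form bivariate normal CDF
  built on Owen's T function (accurate to ~1e−14 against quadrature). A
  closed form is used deliberately: it is deterministic, which the
  reproducibility contract (byte-identical reruns) requires, and fast
  enough for the resampling loops.
* Cells with zero counts contribute nothing; occupied cells are clamped at
  1e−12 before the log so sparse 7×7 tables cannot produce −∞. No other
  continuity correction is applied.
* Empty categories are merged into their upper neighbor (merges logged), so
  thresholds stay strictly increasing. Constant items abort with the item
  named — no latent correlation is estimable from them.
* The assembled pairwise matrix, if indefinite, is projected to the nearest
  positive-definite correlation matrix by alternating projections
  (eigenvalue floor 1e−8, unit diagonal restored each sweep) and flagged
  `pd_adjusted`.

## Network estimation

Graphical lasso over a λ path of 100 log-spaced values from
λ_max = max off-diagonal |S| (empty graph) down to λ_max/100, EBIC with
γ = 0.5 selecting the model, ties broken toward the larger penalty. γ, path
length and floor are exposed as configuration; the defaults are the
de-facto standards of the ecosystem. The L1 fit itself delegates to
scikit-learn's `graphical_lasso` (identical objective, off-diagonal
penalty, diagonal unpenalized); the package's own EBIC and
partial-correlation conversion sit on top, and a brute-force
penalized-likelihood oracle in the test suite pins the solver to the stated
objective at tolerance 1e−4. The Gaussian constant is omitted from the
likelihood throughout; selection is invariant to it. Edges are counted at
|Θ_ij| > 1e−8, a float-noise guard only.

## Centrality

Strength sums absolute weights (the network can contain negative partial
correlations, and magnitude is the ecosystem convention). Closeness and
betweenness use the 1/|w| distance transform — the key non-printed
convention, stated here explicitly. Closeness is (p−1)/Σ distances within
the node's connected component (isolated nodes score 0); a harmonic variant
is available behind a flag since the reciprocal-total and harmonic forms
differ on disconnected graphs and published reports rarely say which was
used. Betweenness is the unnormalized Brandes pair count with fractional
tie-splitting; z-scores (n−1 SD) make the reported scales comparable.

## Community detection

The spin-glass objective is the configuration-null Potts Hamiltonian on
absolute weights,

    H(σ) = −Σ_{i<j} (a_ij − γ s_i s_j / 2m) δ(σ_i, σ_j),   a_ij = |w_ij|,

with γ = 0.5, up to 17 spins, start temperature 1, stop 0.01, cooling 0.99.
Optimization is single-node Metropolis annealing with p·spins proposals per
temperature, best-visited-state tracking and 10 restarts (both the
proposal schedule and best-state tracking are implementation choices made
for reliable minima on ~18-node graphs at negligible cost; on 6-node test
graphs the annealer provably reaches the exhaustive minimum). Runs are
deterministic given the seed. Negative edges enter through their absolute
values; the negative-weight extension of the spin-glass model is out of
scope.

## Resampling

* **Case-dropping bootstrap / CS.** Drop proportions 0.10–0.75 in steps of
  0.05, 100 subsamples per proportion by default (both configurable — the
  published method's convention balanced against desk-scale runtime); the
  full pipeline is re-fit per subsample and each centrality vector is
  correlated with the full-sample vector. CS(index) is the largest drop
  fraction whose correlations reach 0.7 in ≥ 95% of draws. The correlation
  is product-moment by default with a Spearman option: descriptions of the
  method speak of "ranking correlation" while the reference implementation
  defaults to product-moment, so both are offered and the default follows
  the implementation. Failed subsample fits (e.g. an item going constant)
  are skipped and counted.
* **Nonparametric bootstrap.** Case resampling with replacement, 1000 draws
  by default; 2.5%/97.5% empirical quantiles for every edge and centrality
  and for pairwise differences; a difference is "significant" when its
  interval excludes 0. For a truly absent edge the sparse estimator sits at
  exactly zero in most resamples, so interval coverage of 0 exceeds the
  nominal 95% — the tests assert the one-sided direction.
* **Permutation test.** Statistic: mean(group 1) − mean(group 2) (for fixed
  group sizes the sum-difference statistic is equivalent up to scaling, and
  p is invariant to common standardization of the centralities). The null
  reassigns the observed values to groups of the same sizes. Exhaustive
  enumeration is the default whenever C(p, n₁) ≤ R (for 18 items and the
  8/10 split, 43,758 < 100,000 random reassignments, so exact is also
  cheaper); Monte-Carlo mode uses the add-one estimator
  p = (1 + #{|null| ≥ |obs|})/(1 + R) to avoid p = 0.

## Synthetic cohorts

The generator is the exact model the polychoric step assumes: latent
multivariate normal, discretized per item through thresholds that match
target category probabilities. Defaults emulate the published cohort —
n = 1438, 18 items, marginals from the packaged frequency table (strong
floor effects: 36–80% of responses in category 1), and three planted
clusters of sizes 10/3/5 mirroring the reported positive/negative/general
symptom communities. Within-block pairs get a random spanning tree (so
planted communities are connected) plus random extras up to density 0.5,
weights uniform on [0.15, 0.45] — the magnitude range of the strongest
published edges; 4 cross-block bridges at 0.1 tie the graph together. The
target pattern becomes a unit-diagonal precision matrix, diagonally loaded
until the smallest eigenvalue reaches 0.05; loading (rather than weight
shrinking) is used so the *achieved* partial correlations — re-derived
after loading and stored on the spec — are exactly what recovery
experiments score against. All-positive within-block weights were chosen
over random signs: both were evaluated, signs reduce the needed loading but
worsen pattern specificity of the lasso, and published symptom clusters are
defined by positive within-cluster association.

What the generator does *not* emulate: rater effects, item-level
non-normal latent distributions, missing data, and any covariate
structure. Passing recovery tests therefore shows the chain of estimators
is faithful to its own model, not that real BPRS data satisfy that model.

## Calibration findings (computed by the tests and `scripts/acceptance.py`)

* Edge detection at the emulated cohort scale is sensitivity ≈ 0.95–1.0 but
  specificity ≈ 0.6–0.8: with a dense 10-node block, L1 compensation plus
  EBIC's small selected λ admit many tiny spurious edges even with the
  noiseless latent correlation as input. This is a documented property of
  EBIC-glasso on dense blocks (the same estimator reaches specificity
  ≈ 0.96 on a sparse chain truth at the same n) and is consistent with the
  very dense networks reported for real cohorts of this size.
* Those spurious cross-block edges occasionally make merging two planted
  blocks the *true* Hamiltonian optimum of the estimated network, so the
  planted partition is recovered exactly in only about half of replicates —
  the annealer itself is exact on small graphs.
* The permutation test's attainable size is quantized by the discrete null:
  at the scaled-down 8-node validation (C(8,3) = 56 assignments) the
  largest attainable level-0.05 size is 2/56 ≈ 0.036, and ties from
  isolated zero-strength nodes deflate it further (measured ≈ 0.02–0.055
  across base seeds); at the full 18-item split the size is ≈ 0.0499. The
  8-node group sizes use 3/5, the cohort's unequal 8/10 split scaled down,
  chosen from this discreteness analysis before running the experiment.
* Problem sizes in the test suite and the reproduction script (subsample
  counts, bootstrap draws, replicate counts) are desk-scale choices; each
  is a parameter, and the defaults on the library functions remain the
  full-scale conventions.

## Known limitations

* Polyserial/Pearson fallbacks, nonparanormal transforms, mixed graphical
  models, directed or temporal networks are out of scope (the data model is
  cross-sectional ordinal ratings).
* No expected-influence or bridge centrality; strength uses magnitudes, so
  strongly negative hubs are ranked as central.
* The spin-glass model here is the positive-weight variant; networks
  dominated by negative edges would need the signed extension.
* CS-coefficients are reported on the grid actually evaluated; a CS of 0
  means "no evaluated drop fraction qualified", not that stability is
  exactly zero.
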