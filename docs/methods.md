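# Methods

This note documents the statistical procedures implemented in `traitspace`,
the assumptions they make, and the design choices taken where the underlying
methods literature leaves the recipe open.

## Fuzzy-coded trait data

A trait table holds one row per taxon and one integer column per trait
state.  States belong to *trait groups* (e.g. the eight feeding-habit
states), and a taxon's scores within a group are interpreted jointly — a
score is an affinity relative to the other states of the same group, not an
independent measurement.  Groups with few states are coded 0–3, groups with
many states 0–5.  The bundled dictionary has 11 groups and 63 states
covering feeding habit, locomotion/substrate relation, food type,
respiration, maximal size, resistance form, dispersal, aquatic stage, life
cycle duration, voltinism, and reproduction.

Unknown cells are represented by an explicit mask, never by zero: a zero is
an observed statement of "no affinity", and conflating the two would pull
every incompletely known taxon toward the no-affinity corner of the space.

**Standardization.** Scores of each trait group are rescaled to [0, 1] by
dividing by the group's maximum *possible* code (3 or 5).  This removes the
unequal weight that the two coding ranges would otherwise carry into a
covariance-based ordination while preserving the within-group affinity
structure.  Dividing by the observed per-group maximum instead
(`standardization: observed_minmax`) is available as a sensitivity switch;
it gives identical results whenever some taxon attains the maximum code, as
is typical in expert-coded databases.  Per-trait standardization (z-scores
or per-row percent conversion) is deliberately not offered in the pipeline:
it would destroy the relatedness of states within a group.

**Merging tables.** Databases recorded against slightly different trait sets
are merged by mapping trait names (`name_map`) and zero-filling traits that
the addition's protocol did not record because the taxa cannot express them
(`zero_fill`).  Zero-filled cells are *observed* zeros (mask true).  The
merged table always carries the base table's trait set; duplicate taxon
identifiers are rejected rather than silently replaced.

## Centred PCA of incomplete data

Let x_ij be the standardized score of taxon i on trait j with observation
mask m_ij.  The method:

- available-case means: x̄_j = Σ_i m_ij x_ij / Σ_i m_ij;
- pairwise-deletion covariance: entry (j, k) sums
  (x_ij − x̄_j)(x_ik − x̄_k) over taxa with both traits observed, divided by
  n_jk − 1;
- eigendecomposition of that matrix; pairwise-deletion matrices need not be
  positive semi-definite, so eigenvalues below 10⁻¹² of the largest are
  clipped to zero and excluded from variance-proportion denominators;
- score of taxon i on axis a: Σ_j m_ij (x_ij − x̄_j) u_ja — missing terms
  contribute nothing.  An optional switch rescales each score by
  p / p_observed(i); it is off by default because it inflates the noise of
  poorly known taxa, and at ~1% missingness the difference is negligible.
- axis signs are fixed by making the largest-magnitude loading of each axis
  positive, so repeated runs and fixtures are reproducible.

On complete data this reduces exactly to classical centred PCA; the test
suite asserts equality against an independent implementation (eigenvalues to
1e-8, scores to 1e-6).  With ~1% of cells missing, the leading eigenvalue
moves by well under 5% (smoke-tested).  The limitation to keep in mind:
pairwise deletion is only unbiased when cells are missing at random, and
with heavy, structured missingness the covariance matrix can acquire large
negative eigenvalues — the clipped spectrum then overstates the variance
explained by the leading axes.

**Axis selection.** The broken-stick null expects the k-th largest piece of
a randomly broken unit stick of p pieces to be b_k = (1/p) Σ_{i=k}^{p} 1/i.
An axis is significant when its variance proportion exceeds b_k, and the
retained count is the leading run of significant axes (stop at the first
failure).  Sticks are computed over the positive-eigenvalue axes so observed
proportions and expectations sum to one over the same set.  A `rule="any"`
variant counts every significant axis; the first-failure rule is the default
because later exceedances in an already sub-broken-stick spectrum carry no
interpretable signal.

**Trait screening.** Pearson correlations between each trait (available
cases) and each axis's scores; traits with |r| > 0.5 (configurable) are
reported per axis.  Zero-variance traits get r = 0 with a warning flag, and
zero-eigenvalue axes are skipped as carrying no signal.

## Convex-hull occupancy and null models

The occupied functional trait space is the d-dimensional Lebesgue volume of
the convex hull of the taxa in the retained axes (qhull).  Degenerate clouds
— at most d points, or affinely dependent ones — have volume 0 and are
flagged, not raised.  To damp outlier influence, hulls may be computed on
the ⌊0.95·n⌋ taxa closest to the cloud centroid (per-axis mean), ties broken
by input order.

Group summaries report per-group hull volumes, volume per taxon
(100·V_g/n_g, the "standardized" space), and the even-split expectation
V_total / n_groups against which group volumes are compared.  Per-group
moments use the sample variance (n − 1); singleton groups report variance 0
with a flag.

**Null models.** Three nulls destroy inter-axis dependence while keeping
marginal structure: per-axis uniform over the observed range, per-axis
normal with the observed mean and standard deviation, and per-axis random
permutation of the observed scores (which preserves each marginal exactly).
Simulated clouds have the observed size n; trimming is applied identically
to the observed and every simulated cloud; occupancy is
100 · V_obs / mean(V_null) (median available via `null_center`), and the
one-sided p-value (1 + #{V_null ≤ V_obs}) / (n_reps + 1) is small when the
observed cloud is concentrated.  The default is 999 replicates, making the
smallest attainable p-value 0.001.

One numerical subtlety is handled explicitly: a cloud simulated inside the
observed per-axis bounds (or with the observed moments) almost never attains
those bounds itself, so its hull is stochastically smaller than the observed
one and the naive comparison is biased toward "occupancy above 100%".  Each
simulated cloud is therefore affinely aligned, axis by axis, onto the
observed range (uniform model) or observed mean and standard deviation
(normal model).  With this alignment the observed cloud is exchangeable with
the null draws whenever its axes truly are independent, and the test is
exactly calibrated — verified empirically in the suite: analyzing uniform
clouds with the uniform model rejects at 5% ± 3 points and centres occupancy
on 100%.

## PERMANOVA and PERMDISP

Both tests run on Euclidean distances between component-score rows, by
default the broken-stick-retained axes (capped at the first four, which is
where multi-trait structure typically lives; configurable).

**PERMANOVA** (one-way): SS_total = Σ_{i<j} d²_ij / n, SS_within =
Σ_groups Σ_{i<j∈g} d²_ij / n_g, pseudo-F =
(SS_between/(g−1)) / (SS_within/(n−g)), R² = SS_between/SS_total.  The
p-value comes from raw permutation of group labels,
(1 + #{F_perm ≥ F_obs}) / (n_perms + 1); it can never print as 0, and the
smallest attainable value is 1/(n_perms+1).  Raw-label permutation is exact
under exchangeability of taxa, which holds for a one-way layout.

**PERMDISP**: each taxon's distance to its group's *spatial median* (the
point minimizing summed Euclidean distances; Weiszfeld iteration with the
Vardi–Zhang step when an iterate lands on a data point, tolerance 1e-9),
then a one-way ANOVA F on these distances.  Group labels are permuted raw
and the medians and distances recomputed each time.  This differs from the
classical residual-permutation variant (as in vegan's betadisper): raw-label
permutation is simpler and exact under the global null that groups share one
distribution, but it conflates location and dispersion alternatives —
strongly separated group centroids will also reject.  The spatial median is
the default centre because it is robust to outlying taxa; a centroid variant
is available for cross-package comparison.  A singleton group has distance 0
by construction.

The relatedness suite repeats both tests three ways — rare groups pooled
into "Others", broken out into their real labels, and omitted — because
conclusions about taxonomic constraint can hinge on how rare higher taxa are
handled.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not any real
database's numbers.  Defaults: 596 taxa in 12 taxonomic groups (Coleoptera
and Trichoptera dominating, as in European macroinvertebrate databases, with
the "Others" pool split over 10 rare higher taxa in the full-resolution
label vector), the bundled 11-group/63-trait dictionary, and a 1.03%
missing-cell rate.

Each group receives an archetype profile over the 63 traits, a convex
mixture (1 − s)·shared + s·group-specific with s = `syndrome_strength`
(default 0.8); entries are Beta(0.4, 1.1) draws, pushing mass toward zero
because real fuzzy profiles are sparse.  Taxa are archetype + Gaussian noise
(sd 0.15 by default) clipped to [0, 1], scaled by the group's maximum code
and rounded half-away-from-zero (documented to avoid platform-dependent
banker's rounding).  Missingness is injected per cell, independently,
Bernoulli(rate).  Everything is fixed by a single seed.

What the generator does *not* emulate: realistic trait–trait correlation
matrices, expert coding idiosyncrasies, taxonomic autocorrelation finer than
the group level, or structured (non-random) missingness.  Passing tests on
synthetic tables therefore demonstrate that the machinery recovers planted
structure and is calibrated under its stated nulls — not that any particular
ecological conclusion holds for real assemblages.

## Problem sizes and numerical choices

Calibration checks in the suite use deliberately compact designs: type-I
calibration of the null-model test on 3-D uniform clouds of 60 points (200
outer × 99 inner replicates), PERMANOVA calibration on 30 taxa in 3 groups
(200 simulations × 99 permutations), and syndrome recovery on 8-group ×
12-taxa tables (50 replicates).  These sizes give binomial standard errors
comfortably inside the ±3-percentage-point acceptance bands while keeping
the default test run fast.  Production defaults are 999 replicates /
permutations throughout.

Other numerical conventions: eigenvalues below 10⁻¹² of the largest are
zero; hull computations reject non-finite coordinates; trimming keeps
⌊fraction·n⌋ points with stable tie-breaking; the pipeline derives
independent per-stage random substreams from the top-level seed, so adding a
stage never changes another stage's randomness.
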