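# Methods

This note records the models implemented, the defaults and why, the
numerical choices, what the synthetic data do and do not emulate, and the
known limitations.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Song variables and aggregation

A recording contributes note count `N`, duration `D` (s), and maximum,
minimum and peak frequency (Hz); pace `N/D` and bandwidth `MaxF − MinF`
are derived.  Records with nonpositive duration or inverted frequency
bounds are rejected with a reason; a peak frequency outside the
[min, max] band warns but does not reject (it is a measurement quirk, not
an impossibility of the other fields).

Species aggregation is **mean then log**: the arithmetic mean of each raw
variable per species, then the natural log of that mean.  The alternative
(log then mean) is a configuration away in principle but is not the
default because the composite quantities of interest (e.g. mean bandwidth)
live on the raw scale.  All logs in the package are natural; the base only
rescales composites and coefficients.

## Performance frontiers

*Binned maximum* (`UpperBoundRegression`): half-open pace bins
`[lo, lo+2)` Hz with the last bin closed, spanning 0–40 Hz and extending
upward when the data demand; within each nonempty bin the single song with
maximal bandwidth is selected (ties broken by smaller pace, then input
order, making the fit invariant to row shuffling); OLS is computed through
the **selected songs' actual pace values**, not bin midpoints (midpoints
are available as an option).  Diagnostics: R², the F statistic of the
slope with (1, n−2) df, and its p-value.

*Sliding percentile* (`SlidingPercentileBound`): windows of width 2 Hz
advancing by 1 Hz; within each window holding at least 32 songs, the 90th
percentile of bandwidth (linear interpolation); OLS of percentile on
window center.  The 32-song floor suppresses outlier-driven windows; width
and step are configuration because no single geometry is canonical — at
study scale (~1,800 songs over ~0–40 Hz) these defaults retain a few dozen
windows, which is the regime the method is meant for.  Small toy datasets
must lower `min_count` explicitly.

*Vocal deviation* is the signed orthogonal distance from the frontier in
raw units (pace O(10) Hz against bandwidth O(10³) Hz).  The mixed-unit
plane is deliberate: the frontier itself is defined in those units, and
the published deviation scores that this statistic follows are likewise
unstandardized.  Species-level vocal performance is the mean of per-song
deviations (not the deviation of the species means); the distinction
matters because deviation is nonlinear in (pace, bw) only through the
frontier fit, but the mean-of-songs version weights a species' sampled
repertoire directly.

## Trees and covariance structures

Trees are rooted, with nonnegative branch lengths on every non-root edge;
polytomies are accepted for covariance construction (bifurcation is only
asserted where an operation genuinely needs it).  Matrices are ordered
alphabetically by tip label and all joins are by label.

The Brownian covariance is `V[i,j] =` shared root-to-MRCA path length,
built from an incidence decomposition `V = A·diag(b)·Aᵀ` so that
branch-length transforms are single matrix products.  A root edge, when
present, counts as variance shared by every tip: trees parsed from plain
Newick normally have none (whole-tree matrices then match `ape::vcv`
exactly; see the R cross-check tests), while the stem edge retained when
pruning to a species subset keeps pruned-tree covariances exact marginals
of the full-tree covariance.

Transforms: λ multiplies off-diagonals (λ∈[0,1]); κ exponentiates each
branch length (κ∈[0,3], κ=0 giving unit branches); δ exponentiates each
entry of `V` element-wise (δ∈[0,3]); the single-optimum OU process uses
the ancestor-at-optimum covariance
`V[i,j] = e^{−α d_ij}(1 − e^{−2α t_ij})/(2α)` with `d` the patristic
distance and `t` the MRCA depth, which reduces continuously to Brownian
motion as α→0 and has a constant diagonal on ultrametric trees; its
stationary variance is absorbed into the residual σ².  α is bounded in
[10⁻⁸, 50/tree-height] (half-lives shorter than ~1% of the tree are not
distinguishable from a star).  All bounds are configurable.  Trees are
used with raw branch lengths — no rescaling to unit height is applied to
user trees before fitting, since every transform family except κ is
scale-equivariant in ways the profiled σ² absorbs.

Degenerate matrices (e.g. zero-length terminal branches duplicating a
tip's row) are handled by a documented ridge of `10⁻¹⁰·mean(diag)` added
only when the Cholesky factorization fails, and logged.

## Phylogenetic PCA

Revell-style: GLS ancestral mean, evolutionary covariance `R`,
eigen-decomposition; scores are centered traits projected on the
eigenvectors.  Default mode is **correlation** (traits standardized by
their evolutionary SDs) because the song variables mix log-Hz, log-s and
log-counts and because published loading tables of this kind have
magnitudes ≤ 1; covariance mode is available.  No λ estimation inside the
PPCA by default (plain Brownian `V`), matching the method's basic form; a
λ pre-transform is exposed.  Eigenvectors are sign-oriented so the
largest-|loading| variable loads positively — eigenvectors are sign-
ambiguous and reproducible output requires a convention.  Kaiser retention
(eigenvalue > 1) flags the components carried forward as responses.
Vocal deviation is never an input to the PPCA: it is computed from pace
and bandwidth, which are already in the table.  Song scores are computed
once from the consensus tree; recomputing per posterior tree is possible
by rerunning the PPCA per tree, but the default keeps responses fixed so
that across-tree variation reflects the model fits only.

## PGLS and model fitting

Everything is maximum likelihood (never REML) so AICc is comparable
across mean structures.  GLS quantities come from Cholesky whitening and
a pivoted QR — no explicit inverses; rank-deficient designs raise with
the offending columns named; an exact fit (σ̂²=0) is flagged degenerate
rather than silently producing an infinite likelihood surface.

Transform parameters are profiled: a 5-point grid scan (log-spaced for α)
brackets the optimum, then bounded scalar minimization to 10⁻⁶ on the
parameter; estimates within numerical reach of a bound are flagged
`boundary`.  The parameter count is `k = design columns + 1 (σ²) + 1` if a
transform is estimated — a fixed, documented convention.  Predictors are
not standardized before fitting, so coefficients stay on their log or
measurement scales.

Missing data: listwise deletion, with one shared complete-case set per
response across the whole candidate set (otherwise AICc values would be
computed on different data and would not be comparable); `n` is recorded
per fit.  Outlier removal is never automatic — exclusions are an explicit
config list of species ids.

## Candidate set and multimodel inference

15 mean structures — constant; {BodySize, BeakSize, BeakMoment};
{Habitat, EnvPC1}; all 6 morphology+habitat pairs; 3 morphology ×
categorical-Habitat interactions — crossed with 5 families: 75 fits per
response.  BeakMoment is the term pair (beak size, log beak length), the
approximation of the beak's moment of inertia (width × depth × length to
an unspecified power), and its interaction model expands into both
BeakSize×Habitat and BeakLength×Habitat product columns.  Interactions
with the continuous climate axis are rejected by construction: there is
no directional prediction for how particular climate-PC values modulate a
morphology effect, and the constraint also limits collinearity.

Weights are computed over the **full pooled candidate set** (structures ×
families in one AICc ranking); the evidence-ratio denominator is the
total weight of the constant models across the five families.  When that
denominator underflows, the ratio is reported with a `> 10⁶` sentinel
flag rather than a meaningless quotient.  Pruning follows the
uninformative-parameter rule: a model within 2 AICc of a higher-ranked
model whose parameter set is a strict subset of its own is removed (the
top model is never removable).  Averaging takes the smallest
weight-ordered prefix reaching 95% cumulative weight, renormalizes, and
zero-substitutes absent parameters — so an averaged coefficient shrinks
toward zero in proportion to the weight of models omitting it, including
the intercept's treatment symmetric with everything else.  Across a
posterior tree sample the entire fit–select–average cycle runs per tree
and per-tree averaged coefficients are combined by an unweighted mean;
transform estimates are averaged like coefficients and the family
reported is the modal top-model family.

## Synthetic data

The generator produces the study conditions end to end: a pure-birth tree
rescaled to unit height (276 species by default; the simulator's clock is
run past the n-th speciation by one exponential waiting time so no two
tips coincide); a pseudo posterior sample by multiplicative lognormal
branch jitter (topology fixed — cheaper than true posterior variation and
sufficient to exercise the averaging machinery); morphology composites as
correlated multivariate Brownian motion (beak–body r = 0.80, beak–length
r = 0.85, body–length r = 0.63); habitat by thresholding a latent
Brownian trait at prevalence quantiles (0.45/0.30/0.25
closed/semi-open/open) — a threshold model was chosen over a Markov
transition model because it gives direct control over the
habitat–climate correlation (Environment PC1 = standardized latent +
noise, r = 0.70); and songs in which log pace carries beak (−0.5) and
habitat (+0.2/+0.4) effects, log center frequency carries a negative
body-size effect (−0.35), residuals are Brownian on the tree, and
per-song bandwidth is uniform on (0, frontier(pace) × performance
factor], so no song exceeds the generative frontier
`bw = 5066.2 − 79.374·pace` at its realized pace.  Note counts are
back-solved from pace and duration so `N/D` is exact.  Recordings per
species are lognormal (mean 6.6, SD 5.4, floored at 1).

The pace dispersion (Brownian σ² = 0.8 on the unit tree, per-song jitter
0.15, species-mean pace capped at 45 Hz) was chosen so the per-recording
pace distribution occupies the full 0–40 Hz bin grid the binned-maximum
method assumes; with a narrow pace distribution the sparse high-pace bins
sit far below the frontier and bias the slope steep — a property of the
estimator worth knowing about in real data too.  The per-species
performance factor is uniform on (0.8, 1.0] minus 0.3 × centered beak
size (clipped to (0.05, 1]), embedding the beak-moment→performance effect
for recovery tests.

What the generator does **not** emulate: harmonic structure or amplitude
(no audio exists at all), measurement error in morphology, biogeographic
realism of the climate table (its variables are noisy linear functions of
one latent axis plus engineered near-duplicates for the redundancy
filter), topological uncertainty in the posterior sample, and any
correlation between sampling effort and traits.  Passing tests therefore
demonstrate that the statistical machinery recovers known structure under
the model's own assumptions — not that those assumptions hold in field
recordings.

## Pipeline and determinism

Responses analyzed: the Kaiser-retained song principal components, the
seven individual log song variables, and vocal deviation.  The run log
records every default actually used (bin width, window geometry, PPCA
mode, the k convention, weight pooling, species dropped at each stage).
All output is delimited text and JSON with fixed float formatting and no
timestamps, so identical config + seed reproduces byte-identical files.
All randomness flows from the single config seed through spawned
substreams.

Problem sizes in the shipped tests and the acceptance script (e.g. 40–120
species in pipeline tests, 20–50 replicates in recovery experiments, a
single 276-species bundle for study-scale quantities) are the package's
own choices balancing statistical resolution against a short default test
run.

## Known limitations

* Single-optimum OU only; no multi-optimum or branch-specific regimes.
* No measurement-error ("within-species variance") models in PGLS.
* The κ transform on a pruned tree operates on the merged branch lengths
  of the pruned topology, as any tree-based implementation must; κ is not
  marginal-consistent under pruning (unlike V itself).
* The evidence-ratio sentinel and the `boundary` flag are reported but no
  automatic refitting or bound-widening is attempted.
* The percentile-frontier window geometry behind any particular published
  df count is not inferable from the data; it is configuration, reported
  in the run log.
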