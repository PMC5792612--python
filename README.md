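# ovensong

Phylogenetic comparative analysis of bird song: does ecology shape acoustic
mating signals directly, through the sound-transmission properties of
habitats, or indirectly, because selection on body and beak size drags the
song along with it?  `ovensong` implements the full analytical pipeline for
asking that question across a species radiation — performance-frontier
statistics for the pace–bandwidth trade-off, phylogenetic PCA of song
variables, phylogenetic generalized least squares (PGLS) under five
covariance transformations, and AICc-based multimodel inference averaged
over a posterior sample of trees — together with a synthetic-data generator
that produces study-scale datasets with known ground truth for every stage.

It is written for comparative bioacousticians and evolutionary ecologists:
people with per-recording song measurements, per-species morphology and
habitat tables, and a time-calibrated phylogeny.

## The statistics at the core

**Performance frontier and vocal deviation.**  Songs trade off pace (notes
per second, `PACE = N/D`) against frequency bandwidth (`BW = MaxF − MinF`):
slow songs can be broad- or narrow-band, fast songs only narrow-band, so
the joint distribution is triangular.  Its upper edge is estimated two
ways: (i) binned-maximum regression — OLS through the widest-bandwidth song
in each 2-Hz pace bin — and (ii) a sliding-window 90th-percentile fit with
windows of fewer than 32 songs discarded.  Each song's *vocal deviation* is
its signed orthogonal distance below the frontier,

    d = (m·pace − bw + b) / √(m² + 1),

so larger deviation means lower vocal performance.

**Phylogenetic PCA.**  Species means are not independent; the PPCA
replaces the sample mean and covariance with their GLS analogues under the
Brownian-motion covariance `V` of the tree
(`a = (1ᵀV⁻¹1)⁻¹1ᵀV⁻¹X`, `R = (X−1a)ᵀV⁻¹(X−1a)/(n−1)`) and
eigen-decomposes `R` (or its correlation rescaling).  Components with
eigenvalue > 1 are retained (Kaiser criterion).

**PGLS with profiled covariance transforms.**  Each candidate model is a
GLS regression whose error covariance comes from the tree under one of
five families — Brownian motion, Pagel's λ (signal strength), κ
(speciational change), δ (time-dependent rates), or a single-optimum
Ornstein–Uhlenbeck process — with the transform parameter estimated by
profile maximum likelihood jointly with the coefficients.

**Multimodel inference.**  Fifteen mean structures (constant; body size,
beak size, or the two-term "beak moment" = beak size + log beak length;
categorical habitat or a climate PC1; all morphology + habitat pairs; and
morphology × categorical-habitat interactions) crossed with the five
covariance families give 75 fits per response, ranked jointly by AICc.
Akaike weights `w_i ∝ exp(−ΔAICc_i/2)` yield evidence ratios against the
constant models, nested models within 2 AICc of a simpler competitor are
pruned as uninformative, the 95% cumulative-weight set is model-averaged
with zero substitution for absent parameters, and the whole procedure can
be repeated across a posterior sample of trees and averaged.

## Worked example

```python
import numpy as np
import ovensong as ov

bundle = ov.make_bundle(ov.SimulationConfig(seed=42, n_species=120))
songs, _ = ov.derive_song_features(bundle.songs)
frontier = ov.upper_bound_regression(songs["pace_hz"], songs["bandwidth_hz"])
print(f"frontier: bw = {frontier.slope_:.2f} * pace + {frontier.intercept_:.1f}"
      f"  (R^2 = {frontier.r_squared_:.2f}, n = {frontier.n_points_} bins)")

table = ov.species_aggregate(songs).join(bundle.predictors)
table = table.join(ov.encode_habitat(table["habitat"]))
table["vocal_deviation"] = ov.species_vocal_performance(songs, frontier)

ppca = ov.phylogenetic_pca(
    table[[f"log_{v}" for v in ov.acoustics.SONG_VARIABLES]], bundle.tree)
print("PPCA eigenvalues:", np.round(ppca.eigenvalues_, 2),
      "-> retained", len(ppca.retained_))

fits = ov.fit_model_set("log_max_freq_hz", table, bundle.tree)
ranking = ov.rank_models(fits)
top = ranking.fits[0]
print(f"top model for log max frequency: {top.spec.label} [{top.spec.family}], "
      f"weight {ranking.weights[0]:.2f}")
weights = ov.all_parameter_weights(ranking.fits, ranking.weights)
print(f"Body Size total weight: {weights['Body Size']:.2f}")
idx = ov.cumulative_weight_set(ranking)
avg = ov.model_average([ranking.fits[i] for i in idx], ranking.weights[idx])
print(f"averaged Body Size coefficient: {avg.averaged_beta['Body Size']:.3f}")
```

prints

```
frontier: bw = -75.77 * pace + 4671.6  (R^2 = 0.98, n = 30 bins)
PPCA eigenvalues: [2.83 1.65 1.17 1.03 0.28 0.04 0.  ] -> retained 4
top model for log max frequency: BodySize [lambda], weight 0.40
Body Size total weight: 1.00
averaged Body Size coefficient: -0.279
```

The fitted frontier slope (−75.8) sits within 5% of the generative slope
(−79.374).  The song table compresses onto a few components (frequency,
length, pace axes).  For maximum frequency the body-size model wins under
the λ transform, the Body Size parameter carries the full Akaike weight,
and its averaged coefficient is negative — bigger birds sing lower — which
is exactly the effect the generator embedded.

The same pipeline runs from the shell: `ovensong simulate`, `ovensong
songstats`, `ovensong ppca`, `ovensong fit`, `ovensong average`, and
`ovensong run --config analysis.toml` for the whole report (deterministic:
identical config + seed gives byte-identical output files).

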