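"""Synthetic trees, predictors and song tables with known ground truth.

The generator emulates the statistical structure the comparative analysis
assumes, at the scale of the real study system (276 species, a mean of 6.6
recordings per species with SD 5.4):

* an ultrametric pure-birth tree rescaled to unit height, plus a pseudo
  posterior sample made by lognormal jitter of its branch lengths;
* morphology composites evolving as correlated multivariate Brownian
  motion (beak-body correlation targeted at 0.8, matching the collinearity
  reported for the real composites);
* habitat from thresholding a latent Brownian trait into three ordered
  categories, which gives the categories phylogenetic signal and direct
  control over their correlation with the continuous climate axis
  (Environment PC1 = standardized latent + Gaussian noise, targeted
  r = 0.7);
* songs whose species-mean log pace carries habitat and beak effects,
  whose species-mean log frequency carries a negative body-size effect,
  and whose per-song bandwidth is drawn uniformly below a triangular
  performance frontier ``bw <= intercept + slope * pace`` scaled by a
  per-species performance factor, so no song ever exceeds the generative
  frontier at its realized pace.

Every stochastic choice flows from the single seed in
:class:`SimulationConfig` through deterministic substreams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import random
from pathlib import Path

import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .phylo import Phylogeny, TreeSet

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SimulationConfig:
    """Generative parameters; defaults are the study-scale conditions."""

    seed: int
    n_species: int = 276
    songs_per_species_mean: float = 6.6
    songs_per_species_sd: float = 5.4
    n_posterior_trees: int = 100
    tree_jitter_sd: float = 0.1

    # performance frontier (bandwidth Hz as a function of pace Hz)
    frontier_slope: float = -79.374
    frontier_intercept: float = 5066.2

    # morphology: multivariate BM of (body_size, beak_size, log_beak_length)
    morphology_means: tuple[float, float, float] = (3.45, 2.21, 2.89)
    morphology_sds: tuple[float, float, float] = (0.50, 0.45, 0.50)
    beak_body_corr: float = 0.80
    beak_length_corr: float = 0.85     # beak_size ~ log_beak_length
    body_length_corr: float = 0.63

    # habitat threshold model and climate axis
    habitat_prevalence: tuple[float, float, float] = (0.45, 0.30, 0.25)
    habitat_env_corr: float = 0.70

    # song generative coefficients (log scale; predictors centered)
    pace_log_intercept: float = math.log(9.0)
    pace_beak_beta: float = -0.5
    pace_habitat_beta: tuple[float, float] = (0.20, 0.40)  # semi-open, open
    pace_sigma2: float = 0.8           # BM residual variance, unit-height tree
    pace_song_jitter_sd: float = 0.15  # within-species lognormal jitter
    pace_species_cap: float = 45.0     # ceiling on species-mean pace (Hz)

    freq_log_intercept: float = math.log(3200.0)
    freq_body_beta: float = -0.35
    freq_sigma2: float = 0.04
    freq_song_jitter_sd: float = 0.05

    duration_log_mean: float = 0.813   # lognormal ~ mean 2.5 s, sd 1.2 s
    duration_log_sd: float = 0.455

    # per-species performance factor (fraction of the frontier attainable)
    performance_base: tuple[float, float] = (0.80, 1.00)  # uniform range
    performance_beak_effect: float = 0.30  # subtracted per centered beak unit
    min_frequency_floor: float = 100.0

    def validate(self) -> None:
        for name in ("beak_body_corr", "beak_length_corr",
                     "body_length_corr", "habitat_env_corr"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name}={v} is not an attainable correlation")
        if abs(sum(self.habitat_prevalence) - 1.0) > 1e-9:
            raise ValueError("habitat prevalences must sum to 1")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")

    def substreams(self, n: int) -> list[np.random.Generator]:
        seqs = np.random.SeedSequence(self.seed).spawn(n)
        return [np.random.default_rng(s) for s in seqs]


@dataclasses.dataclass
class SyntheticBundle:
    """Everything one analysis run needs, plus the generative truth."""

    tree: Phylogeny
    tree_set: TreeSet
    predictors: pd.DataFrame
    songs: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.tree.write(out / "tree.nwk")
        self.tree_set.write(out / "posterior_trees.nwk")
        self.predictors.to_csv(out / "predictors.csv",
                               float_format="%.10g", lineterminator="\n")
        self.songs.to_csv(out / "songs.csv", index=False,
                          float_format="%.10g", lineterminator="\n")
        (out / "truth.json").write_text(
            json.dumps(self.truth, indent=2, sort_keys=True) + "\n")


def simulate_tree(n_tips: int, seed: int) -> Phylogeny:
    """Ultrametric pure-birth tree rescaled to unit height.

    Tips are labeled ``sp0001 ...`` in a canonical traversal order so the
    alphabetical matrix ordering is stable across runs.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips, rng=rng,
    )
    # the simulator stops at the n-th speciation, leaving the two newest
    # tips coincident; run the clock to the next (uncreated) event so every
    # terminal branch is positive and the tree stays ultrametric
    extra = rng.expovariate(float(n_tips))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree.seed_node.edge.length = None  # no stem below the root
    width = max(4, len(str(n_tips)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:0{width}d}"
    height = max(leaf.distance_from_root()
                 for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / height
    return Phylogeny(tree)


def perturb_trees(tree: Phylogeny, m: int, jitter_sd: float,
                  seed: int) -> TreeSet:
    """Pseudo posterior sample: multiplicative lognormal branch jitter.

    Topology is preserved; each branch length is multiplied by an
    independent lognormal factor with log-SD ``jitter_sd`` (median 1).
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = tree.to_newick()
    trees = []
    for _ in range(m):
        t = Phylogeny.from_newick(base)
        for edge in t._tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = float(
                    edge.length * math.exp(rng.normal(0.0, jitter_sd)))
        trees.append(t)
    return TreeSet(trees)


def _bm_draws(tree: Phylogeny, cov: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    """Multivariate BM tip values: rows species (alphabetical), cols traits."""
    Lv = np.linalg.cholesky(
        tree.covariance().matrix + 1e-12 * np.eye(tree.n_tips))
    Lc = np.linalg.cholesky(cov)
    Z = rng.standard_normal((tree.n_tips, cov.shape[0]))
    return Lv @ Z @ Lc.T


def simulate_predictors(tree: Phylogeny, config: SimulationConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Species predictor table: morphology composites, habitat, climate axis."""
    config.validate()
    s = np.asarray(config.morphology_sds)
    C = np.array([
        [1.0, config.beak_body_corr, config.body_length_corr],
        [config.beak_body_corr, 1.0, config.beak_length_corr],
        [config.body_length_corr, config.beak_length_corr, 1.0],
    ])
    if np.linalg.eigvalsh(C).min() <= 0:
        raise ValueError("morphology correlation targets are jointly "
                         "unattainable (matrix not positive definite)")
    cov = C * np.outer(s, s)
    morph = _bm_draws(tree, cov, rng)
    means = np.asarray(config.morphology_means)
    df = pd.DataFrame(
        morph + means, index=list(tree.tip_labels),
        columns=["body_size", "beak_size", "log_beak_length"],
    )
    df.index.name = "species"

    # habitat: latent BM trait cut at prevalence quantiles (threshold model)
    latent = _bm_draws(tree, np.array([[1.0]]), rng).ravel()
    z = (latent - latent.mean()) / latent.std()
    q_closed, q_semi, _ = config.habitat_prevalence
    cut1, cut2 = np.quantile(z, [q_closed, q_closed + q_semi])
    habitat = np.where(z <= cut1, "closed",
                       np.where(z <= cut2, "semi_open", "open"))
    df["habitat"] = habitat
    r = config.habitat_env_corr
    noise = rng.standard_normal(len(z))
    df["env_pc1"] = r * z + math.sqrt(1.0 - r * r) * noise
    return df


def simulate_climate(predictors: pd.DataFrame,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Bioclim-style table driven by the species' climate axis.

    Temperature variables track the axis on a Celsius-like scale and
    precipitation variables on a millimetre-like scale; a few variables are
    near-duplicates of the annual means (|r| > 0.9) so the redundancy
    filter has something to remove.  Elevation is carried but is not a PCA
    candidate.
    """
    env = predictors["env_pc1"].to_numpy()
    n = len(env)

    def track(scale: float, base: float, coupling: float,
              noise: float) -> np.ndarray:
        return base + scale * (coupling * env
                               + noise * rng.standard_normal(n))

    out = pd.DataFrame(index=predictors.index)
    out["bio1"] = track(5.0, 22.0, -1.0, 0.3)
    out["bio2"] = track(2.0, 11.0, 0.5, 0.9)
    out["bio3"] = track(6.0, 55.0, -0.6, 0.8)
    out["bio7"] = track(4.0, 18.0, 0.7, 0.8)
    # near-duplicates of bio1: should be dropped by the |r| < 0.9 filter
    out["bio10"] = out["bio1"] + rng.normal(0.0, 0.4, n)
    out["bio11"] = out["bio1"] - 6.0 + rng.normal(0.0, 0.4, n)
    out["bio4"] = track(15.0, 80.0, 0.6, 0.9)
    out["bio5"] = track(4.0, 28.0, -0.8, 0.75)
    out["bio6"] = track(5.0, 12.0, -0.8, 0.75)
    out["bio8"] = track(5.0, 23.0, -0.7, 0.9)
    out["bio9"] = track(5.0, 20.0, -0.7, 0.9)
    out["bio12"] = track(600.0, 1800.0, -1.0, 0.35)
    out["bio13"] = out["bio12"] / 6.0 + rng.normal(0.0, 25.0, n)
    out["bio14"] = track(30.0, 40.0, -0.6, 0.85)
    out["bio15"] = track(20.0, 60.0, 0.6, 0.85)
    out["bio16"] = out["bio12"] / 2.5 + rng.normal(0.0, 50.0, n)
    out["bio17"] = track(80.0, 150.0, -0.7, 0.8)
    out["bio18"] = track(150.0, 450.0, -0.6, 0.85)
    out["bio19"] = track(120.0, 350.0, -0.5, 0.9)
    out["elevation"] = track(800.0, 1200.0, 0.5, 1.0)
    return out


def _song_counts(n_species: int, config: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Recordings per species: lognormal matched to mean/sd, floored at 1."""
    m, s = config.songs_per_species_mean, config.songs_per_species_sd
    sigma2 = math.log(1.0 + (s / m) ** 2)
    mu = math.log(m) - 0.5 * sigma2
    draws = rng.lognormal(mu, math.sqrt(sigma2), n_species)
    return np.maximum(1, np.rint(draws)).astype(int)


def simulate_songs(predictors: pd.DataFrame, tree: Phylogeny,
                   config: SimulationConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Per-recording song table bounded by the generative frontier.

    Species-mean log pace = intercept + beak and habitat effects + BM
    residual; species-mean log center frequency = intercept + (negative)
    body-size effect + BM residual.  Per song: pace jitters around the
    species mean; duration is lognormal; the note count is back-solved from
    pace and duration (so pace = N/D exactly); bandwidth is uniform on
    (0, frontier(pace) * performance_factor]; min/max/peak frequencies are
    placed around the species center frequency.  A pace at which the
    frontier is nonpositive is redrawn (and counted).
    """
    config.validate()
    sp = list(predictors.index)
    n = len(sp)
    beak_c = predictors["beak_size"] - predictors["beak_size"].mean()
    body_c = predictors["body_size"] - predictors["body_size"].mean()
    hab = predictors["habitat"]
    hsemi, hopen = config.pace_habitat_beta

    resid_pace = _bm_draws(tree, np.array([[config.pace_sigma2]]), rng).ravel()
    resid_freq = _bm_draws(tree, np.array([[config.freq_sigma2]]), rng).ravel()
    order = pd.Index(tree.tip_labels)
    resid_pace = pd.Series(resid_pace, index=order).loc[sp].to_numpy()
    resid_freq = pd.Series(resid_freq, index=order).loc[sp].to_numpy()

    log_pace = (config.pace_log_intercept
                + config.pace_beak_beta * beak_c.to_numpy()
                + np.where(hab == "semi_open", hsemi, 0.0)
                + np.where(hab == "open", hopen, 0.0)
                + resid_pace)
    # the trade-off makes very fast species-mean paces infeasible; cap them
    log_pace = np.minimum(log_pace, math.log(config.pace_species_cap))
    log_freq = (config.freq_log_intercept
                + config.freq_body_beta * body_c.to_numpy()
                + resid_freq)
    lo, hi = config.performance_base
    perf = (rng.uniform(lo, hi, n)
            - config.performance_beak_effect * beak_c.to_numpy())
    perf = np.clip(perf, 0.05, 1.0)

    counts = _song_counts(n, config, rng)
    m_f, b_f = config.frontier_slope, config.frontier_intercept
    rows = []
    n_redrawn = 0
    for i, species in enumerate(sp):
        for _ in range(counts[i]):
            for attempt in range(100):
                pace = math.exp(log_pace[i]
                                + rng.normal(0.0, config.pace_song_jitter_sd))
                dur = float(rng.lognormal(config.duration_log_mean,
                                          config.duration_log_sd))
                n_notes = max(1, int(round(pace * dur)))
                pace_real = n_notes / dur
                cap = (b_f + m_f * pace_real) * perf[i]
                if cap > 0:
                    break
                n_redrawn += 1
            else:
                raise RuntimeError("frontier nonpositive at every drawn pace")
            bw = rng.uniform(0.0, cap)
            cf = math.exp(log_freq[i]
                          + rng.normal(0.0, config.freq_song_jitter_sd))
            min_f = max(cf - 0.5 * bw, config.min_frequency_floor)
            max_f = min_f + bw
            rows.append({
                "species": species, "n_notes": n_notes,
                "duration_s": dur, "max_freq_hz": max_f,
                "min_freq_hz": min_f,
                "peak_freq_hz": float(rng.uniform(min_f, max_f)),
            })
    if n_redrawn:
        logger.info("redrew %d songs whose pace put the frontier below zero",
                    n_redrawn)
    return pd.DataFrame(rows)


def make_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Simulate a full study: tree, posterior sample, predictors, songs."""
    config.validate()
    rng_pred, rng_song, rng_trees = config.substreams(3)
    tree = simulate_tree(config.n_species, config.seed)
    tree_set = perturb_trees(
        tree, config.n_posterior_trees, config.tree_jitter_sd,
        seed=int(rng_trees.integers(2 ** 31)),
    )
    predictors = simulate_predictors(tree, config, rng_pred)
    songs = simulate_songs(predictors, tree, config, rng_song)
    truth = {
        "seed": config.seed,
        "n_species": config.n_species,
        "frontier_slope": config.frontier_slope,
        "frontier_intercept": config.frontier_intercept,
        "pace_beak_beta": config.pace_beak_beta,
        "pace_habitat_beta": list(config.pace_habitat_beta),
        "freq_body_beta": config.freq_body_beta,
        "beak_body_corr": config.beak_body_corr,
        "habitat_env_corr": config.habitat_env_corr,
        "songs_per_species_mean": config.songs_per_species_mean,
        "habitat_prevalence": list(config.habitat_prevalence),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
    }
    return SyntheticBundle(tree=tree, tree_set=tree_set,
                           predictors=predictors, songs=songs, truth=truth)
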