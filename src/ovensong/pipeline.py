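"""End-to-end orchestration: ingest, frontiers, PPCA, models, reports.

``run_pipeline`` wires the stages together: read the tree(s) and tables,
derive and aggregate song features, fit both performance frontiers and
score vocal deviation, run the phylogenetic PCA of the log song variables,
assemble predictors, fit and rank the 75-model candidate set for every
response (the retained song principal components, the seven individual log
song traits, and vocal deviation), prune uninformative models, average the
95% cumulative-weight set, and — when a posterior tree sample is supplied —
repeat the averaging across trees.

All outputs are plain text (CSV + JSON) written with fixed float formatting
so a rerun with the same configuration is byte-identical; the run log
records every methodological default actually used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from pathlib import Path
import numpy as np
import pandas as pd

from . import acoustics, multimodel, predictors as pred
from .pgls import ALL_PARAMETERS
from .phylo import FAMILIES, Phylogeny, TreeSet
from .ppca import PhylogeneticPCA

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

#: the seven species-level log song traits analyzed individually
LOG_TRAITS = tuple(f"log_{v}" for v in acoustics.SONG_VARIABLES)


@dataclasses.dataclass
class AnalysisConfig:
    """File paths, method options and the seed for one pipeline run."""

    tree: str
    songs: str
    morphology: str | None = None
    habitat: str | None = None
    climate: str | None = None
    trees: str | None = None            # optional posterior sample
    predictors: str | None = None       # pre-built composite table

    outdir: str = "ovensong_out"
    seed: int = 0
    exclude: tuple[str, ...] = ()

    bin_width: float = 2.0
    percentile_window: float = 2.0
    percentile_step: float = 1.0
    percentile_q: float = 90.0
    percentile_min_count: int = 32
    ppca_mode: str = "correlation"
    families: tuple[str, ...] = FAMILIES
    cumulative_threshold: float = 0.95
    min_overlap: int = 10
    max_posterior_trees: int | None = None

    @classmethod
    def from_toml(cls, path: str | Path) -> "AnalysisConfig":
        raw = tomllib.loads(Path(path).read_text())
        flat: dict = {}
        for key, value in raw.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("exclude", "families"):
            if key in flat:
                flat[key] = tuple(flat[key])
        base = Path(path).parent
        for key in ("tree", "songs", "morphology", "habitat", "climate",
                    "trees", "predictors"):
            if flat.get(key):
                p = Path(flat[key])
                flat[key] = str(p if p.is_absolute() else base / p)
        return cls(**flat)

    def validate_paths(self) -> None:
        for key in ("tree", "songs", "morphology", "habitat", "climate",
                    "trees", "predictors"):
            value = getattr(self, key)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{key} file not found: {value}")


@dataclasses.dataclass
class ReportBundle:
    """All pipeline outputs plus the audit log."""

    ppca_table: pd.DataFrame
    ppca_scores: pd.DataFrame
    species_table: pd.DataFrame
    frontier: dict
    rankings: pd.DataFrame            # per-response competitive models
    parameter_weights: pd.DataFrame   # responses x parameters (MCC tree)
    averaged_beta: pd.DataFrame       # responses x parameters
    tree_averaged_beta: pd.DataFrame | None
    log: list[str]

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)

        def dump(df: pd.DataFrame, name: str, index: bool = True) -> None:
            df.to_csv(out / name, float_format=_FLOAT_FMT, index=index,
                      lineterminator="\n")

        dump(self.ppca_table, "song_ppca.csv")
        dump(self.ppca_scores, "song_ppca_scores.csv")
        dump(self.species_table, "species_table.csv")
        dump(self.rankings, "model_ranking.csv", index=False)
        dump(self.parameter_weights, "parameter_weights.csv")
        dump(self.averaged_beta, "averaged_coefficients.csv")
        if self.tree_averaged_beta is not None:
            dump(self.tree_averaged_beta, "tree_averaged_coefficients.csv")
        (out / "frontier.json").write_text(
            json.dumps(self.frontier, indent=2, sort_keys=True) + "\n")
        (out / "run_log.txt").write_text("\n".join(self.log) + "\n")


def _read_species_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValueError(f"{path} lacks a 'species' column")
    return df.set_index("species")


def _assemble_predictors(config: AnalysisConfig,
                         log: list[str]) -> pd.DataFrame:
    """Merge morphology composites, habitat dummies and the climate axis."""
    if config.predictors:
        table = _read_species_csv(config.predictors)
        if "habitat" in table.columns and "habitat_open" not in table.columns:
            table = table.join(pred.encode_habitat(table["habitat"]))
        log.append("predictors: read pre-built composite table")
    else:
        parts = []
        if config.morphology:
            parts.append(pred.morphology_composites(
                _read_species_csv(config.morphology)))
            log.append("predictors: morphology composites (natural log)")
        if config.habitat:
            hab = _read_species_csv(config.habitat)
            dummies = pred.encode_habitat(hab["habitat"])
            if "env_pc1" in hab.columns:
                dummies = dummies.join(hab["env_pc1"])
            parts.append(dummies)
        if not parts:
            raise ValueError("no predictor tables configured")
        table = parts[0].join(parts[1:], how="inner")
    if config.climate:
        climate = _read_species_csv(config.climate)
        retained = pred.climate_filter(climate)
        scores, model = pred.env_pca(climate, variables=retained)
        table = table.drop(columns=[c for c in ("env_pc1",)
                                    if c in table.columns])
        table = table.join(scores["PC1"].rename("env_pc1"), how="inner")
        log.append(
            "climate: retained "
            + ",".join(retained)
            + f"; PC1 explains {model.variance_fractions_[0]:.3f} of variance"
            + f"; Kaiser retains {len(model.retained_)} components"
            + " (PC2 computed, reported, not used as a predictor)"
        )
    return table


def run_pipeline(config: AnalysisConfig) -> ReportBundle:
    """Execute every stage; deterministic given the config."""
    config.validate_paths()
    log: list[str] = [
        f"seed: {config.seed}",
        f"frontier bins: width {config.bin_width} Hz, binned-max x = actual pace",
        f"percentile window: {config.percentile_window} Hz step "
        f"{config.percentile_step} Hz q={config.percentile_q} "
        f"min_count={config.percentile_min_count}",
        f"ppca mode: {config.ppca_mode}",
        "aggregation: mean of raw song variables then natural log",
        "vocal performance: species mean of per-song deviations",
        "parameter count k: design columns + sigma^2 + estimated transform",
        "weights: computed over the full candidate set "
        "(all mean structures x families)",
    ]
    tree = Phylogeny.read(config.tree)

    songs_raw = pd.read_csv(config.songs)
    songs, rejected = acoustics.derive_song_features(songs_raw)
    if len(rejected):
        log.append(f"rejected recordings: {len(rejected)} "
                   f"({rejected['reason'].value_counts().to_dict()})")
    species_songs = acoustics.species_aggregate(songs)

    bound = acoustics.upper_bound_regression(
        songs["pace_hz"], songs["bandwidth_hz"], bin_width=config.bin_width)
    pct = acoustics.percentile_bound(
        songs["pace_hz"], songs["bandwidth_hz"],
        window_width=config.percentile_window, step=config.percentile_step,
        q=config.percentile_q, min_count=config.percentile_min_count)
    frontier = {"binned_max": bound.summary(), "percentile": pct.summary()}
    vp = acoustics.species_vocal_performance(songs, bound)

    predictor_table = _assemble_predictors(config, log)

    merged = species_songs.join(vp, how="inner").join(
        predictor_table, how="inner")
    overlap = sorted(set(merged.index) & set(tree.tip_labels))
    dropped = sorted(set(merged.index) - set(overlap))
    if dropped:
        log.append(f"species without tree tips dropped: {dropped}")
    excluded = [s for s in config.exclude if s in overlap]
    if excluded:
        overlap = [s for s in overlap if s not in excluded]
        log.append(f"explicitly excluded species: {excluded}")
    if len(overlap) < config.min_overlap:
        raise ValueError(
            f"only {len(overlap)} species shared by all tables and the tree "
            f"(minimum {config.min_overlap}); intersection: {overlap}"
        )
    merged = merged.loc[overlap]
    analysis_tree = tree.subset(overlap)
    log.append(f"species analyzed: {len(overlap)}")

    ppca_model = PhylogeneticPCA(mode=config.ppca_mode).fit(
        merged[list(LOG_TRAITS)], analysis_tree)
    scores = ppca_model.scores_
    n_retained = len(ppca_model.retained_)
    log.append(
        "song ppca eigenvalues: "
        + " ".join(f"{v:.4f}" for v in ppca_model.eigenvalues_)
        + f"; Kaiser retains {n_retained}"
    )
    pc_names = []
    for j in range(n_retained):
        name = f"Song PC{j + 1}"
        merged[name] = scores.iloc[:, j]
        pc_names.append(name)

    responses = (pc_names + list(LOG_TRAITS) + ["vocal_deviation"])
    ranking_rows = []
    weight_rows = {}
    beta_rows = {}
    tree_beta_rows = {}
    tree_set = None
    if config.trees:
        tree_set = TreeSet.read(config.trees)
        if config.max_posterior_trees:
            tree_set = TreeSet(tree_set.trees[:config.max_posterior_trees])
        if not set(overlap) <= set(tree_set.tip_labels):
            raise ValueError("posterior trees lack species present in the data")
        if set(tree_set.tip_labels) != set(overlap):
            tree_set = TreeSet([t.subset(overlap) for t in tree_set])
        log.append(f"posterior sample: {len(tree_set)} trees")

    for response in responses:
        fits = multimodel.fit_model_set(
            response, merged, analysis_tree, families=config.families)
        ms = multimodel.rank_models(fits)
        retained_fits, prune_log = multimodel.prune_uninformative(ms)
        for line in prune_log:
            log.append(f"{response}: {line}")
        tab = ms.table()
        tab.insert(0, "response", response)
        keep = tab["delta_aicc"] <= 2.0
        informative = {id(f) for f in retained_fits}
        keep &= np.array([id(f) in informative for f in ms.fits])
        ranking_rows.append(tab[keep])
        weight_rows[response] = multimodel.all_parameter_weights(
            ms.fits, ms.weights)
        idx = multimodel.cumulative_weight_set(
            ms, threshold=config.cumulative_threshold)
        avg = multimodel.model_average([ms.fits[i] for i in idx],
                                       ms.weights[idx])
        beta_rows[response] = avg.averaged_beta
        if tree_set is not None:
            tavg = multimodel.average_across_trees(
                tree_set, response, merged, families=config.families,
                threshold=config.cumulative_threshold)
            tree_beta_rows[response] = tavg.averaged_beta

    bundle = ReportBundle(
        ppca_table=ppca_model.table(),
        ppca_scores=scores,
        species_table=merged,
        frontier=frontier,
        rankings=pd.concat(ranking_rows, ignore_index=True),
        parameter_weights=pd.DataFrame(weight_rows).T.reindex(
            columns=[p for p in ALL_PARAMETERS if p != "Intercept"]),
        averaged_beta=pd.DataFrame(beta_rows).T.reindex(
            columns=list(ALL_PARAMETERS)),
        tree_averaged_beta=(pd.DataFrame(tree_beta_rows).T.reindex(
            columns=list(ALL_PARAMETERS)) if tree_beta_rows else None),
        log=log,
    )
    bundle.write(config.outdir)
    return bundle
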