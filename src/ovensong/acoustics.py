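"""Song features, species aggregation, performance frontiers, vocal deviation.

Each recording contributes five measured variables — note count ``N``, song
duration ``D`` (s), maximum/minimum/peak frequency (Hz) — from which two are
derived: pace ``N/D`` (notes per second, Hz) and frequency bandwidth
``MaxF - MinF`` (Hz).  Pace and bandwidth trade off: fast songs cannot be
broad-band, producing a triangular joint distribution whose upper edge is a
performance frontier.  Two frontier estimators are provided:

:class:`UpperBoundRegression`
    the traditional binned-maximum method — bin pace into fixed-width bins,
    keep the single widest-bandwidth song per bin, and run OLS through those
    maxima;
:class:`SlidingPercentileBound`
    a sliding-window quantile method — the 90th percentile of bandwidth in
    overlapping pace windows, windows with fewer than ``min_count`` songs
    dropped, then OLS of percentile on window center.

Vocal deviation is the signed orthogonal distance of a song from the fitted
frontier in the raw (mixed-unit) pace-bandwidth plane: positive below the
line (low performance), negative above.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

#: raw per-recording columns expected on input tables
SONG_COLUMNS = ("species", "n_notes", "duration_s", "max_freq_hz",
                "min_freq_hz", "peak_freq_hz")

#: the seven per-species song variables carried through the analysis
SONG_VARIABLES = ("pace_hz", "bandwidth_hz", "max_freq_hz", "min_freq_hz",
                  "peak_freq_hz", "duration_s", "n_notes")


def derive_song_features(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate recordings and derive pace and bandwidth.

    Returns ``(clean, rejected)``: ``clean`` carries ``pace_hz`` and
    ``bandwidth_hz`` columns in addition to the raw ones; ``rejected``
    carries a ``reason`` column.  A peak frequency outside the
    [min, max] band is warned about but not rejected.
    """
    missing = [c for c in SONG_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"song table missing columns: {missing}")
    df = records.copy()
    reasons = pd.Series("", index=df.index, dtype=object)
    reasons[df["duration_s"] <= 0] = "nonpositive duration"
    bad_band = (df["max_freq_hz"] < df["min_freq_hz"]) & (reasons == "")
    reasons[bad_band] = "max frequency below min frequency"
    neg = (df["min_freq_hz"] < 0) & (reasons == "")
    reasons[neg] = "negative minimum frequency"
    nonpos_notes = (df["n_notes"] <= 0) & (reasons == "")
    reasons[nonpos_notes] = "nonpositive note count"

    rejected = df[reasons != ""].copy()
    rejected["reason"] = reasons[reasons != ""]
    clean = df[reasons == ""].copy()
    clean["pace_hz"] = clean["n_notes"] / clean["duration_s"]
    clean["bandwidth_hz"] = clean["max_freq_hz"] - clean["min_freq_hz"]

    odd_peak = (
        (clean["peak_freq_hz"] > clean["max_freq_hz"])
        | (clean["peak_freq_hz"] < clean["min_freq_hz"])
    )
    if odd_peak.any():
        warnings.warn(
            f"{int(odd_peak.sum())} recordings have peak frequency outside "
            "the [min, max] band", stacklevel=2,
        )
    if len(rejected):
        logger.info("rejected %d recordings: %s", len(rejected),
                    rejected["reason"].value_counts().to_dict())
    return clean, rejected


def species_aggregate(songs: pd.DataFrame) -> pd.DataFrame:
    """Per-species arithmetic means of the raw song variables, then ln.

    Aggregation order is mean-then-log: the mean of each raw variable is
    taken on its measurement scale and the natural log of that mean is
    stored as ``log_<variable>``.  Species whose mean is nonpositive for any
    logged variable are dropped with a warning (log undefined).
    """
    need = set(SONG_VARIABLES) | {"species"}
    missing = need - set(songs.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    table = songs.groupby("species", sort=True)[list(SONG_VARIABLES)].mean()
    table["n_recordings"] = songs.groupby("species", sort=True).size()
    bad = (table[list(SONG_VARIABLES)] <= 0).any(axis=1)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} species with nonpositive mean song "
            f"variables: {sorted(table.index[bad])}", stacklevel=2,
        )
        table = table[~bad]
    for v in SONG_VARIABLES:
        table[f"log_{v}"] = np.log(table[v])
    table.index.name = "species"
    return table


def _ols_line(x: np.ndarray, y: np.ndarray) -> dict:
    """Simple OLS with the diagnostics reported for frontier fits."""
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 points for a regression")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue ** 2)
    if n > 2:
        denom = max(1.0 - r2, 1e-300)
        f = r2 / denom * (n - 2)
        p = float(stats.f.sf(f, 1, n - 2))
    else:
        f, p = math.inf, float("nan")
    return {
        "slope": float(res.slope), "intercept": float(res.intercept),
        "r_squared": r2, "f_statistic": float(f),
        "df": (1, n - 2), "p_value": p, "n_points": n,
    }


def orthogonal_deviation(pace, bandwidth, slope: float, intercept: float):
    """Signed orthogonal distance from the line ``bw = slope*pace + intercept``.

    ``d = (m*pace - bw + b) / sqrt(m^2 + 1)``: zero on the line, positive
    below it (bandwidth short of the frontier, i.e. low performance),
    negative above.
    """
    pace = np.asarray(pace, dtype=float)
    bandwidth = np.asarray(bandwidth, dtype=float)
    return (slope * pace - bandwidth + intercept) / math.hypot(slope, 1.0)


class _BoundMixin:
    """Shared post-fit surface of the two frontier estimators."""

    def predict(self, pace):
        check_is_fitted(self, "slope_")
        return self.slope_ * np.asarray(pace, dtype=float) + self.intercept_

    def deviation(self, pace, bandwidth):
        """Signed orthogonal distance of songs from the fitted frontier."""
        check_is_fitted(self, "slope_")
        return orthogonal_deviation(pace, bandwidth, self.slope_, self.intercept_)

    def summary(self) -> dict:
        check_is_fitted(self, "slope_")
        return {
            "method": self.method,
            "slope": self.slope_, "intercept": self.intercept_,
            "r_squared": self.r_squared_, "f_statistic": self.f_statistic_,
            "df": list(self.df_), "p_value": self.p_value_,
            "n_points": self.n_points_,
        }

    def _store(self, d: dict) -> None:
        self.slope_ = d["slope"]
        self.intercept_ = d["intercept"]
        self.r_squared_ = d["r_squared"]
        self.f_statistic_ = d["f_statistic"]
        self.df_ = d["df"]
        self.p_value_ = d["p_value"]
        self.n_points_ = d["n_points"]


class UpperBoundRegression(_BoundMixin, BaseEstimator):
    """Binned-maximum upper-bound regression of bandwidth on pace.

    Pace is cut into half-open bins ``[lo, lo + bin_width)`` (the last bin
    closed) spanning ``[bin_start, max(bin_stop, ceil(max pace))]``; within
    each nonempty bin the song with maximal bandwidth is kept (ties broken
    by smaller pace, then input order) and an ordinary least-squares line is
    fitted through the selected songs.

    Parameters
    ----------
    bin_width : float
        Width of the pace bins in Hz (notes/s). Default 2.
    bin_start, bin_stop : float
        The default grid spans 0-40 Hz and extends past ``bin_stop``
        whenever the data demand it.
    x_values : {"actual", "midpoint"}
        Regress on the selected songs' actual pace values (default) or on
        bin midpoints.
    """

    method = "binned_max"

    def __init__(self, bin_width: float = 2.0, bin_start: float = 0.0,
                 bin_stop: float = 40.0, x_values: str = "actual"):
        self.bin_width = bin_width
        self.bin_start = bin_start
        self.bin_stop = bin_stop
        self.x_values = x_values

    def fit(self, pace, bandwidth):
        if self.x_values not in ("actual", "midpoint"):
            raise ValueError("x_values must be 'actual' or 'midpoint'")
        pace = np.asarray(pace, dtype=float).ravel()
        bw = np.asarray(bandwidth, dtype=float).ravel()
        if pace.shape != bw.shape:
            raise ValueError("pace and bandwidth lengths differ")
        w = float(self.bin_width)
        hi = max(float(self.bin_stop),
                 w * math.ceil(float(pace.max()) / w))
        edges = np.arange(self.bin_start, hi + 0.5 * w, w)
        # np.digitize with right-open bins; clamp the top edge into last bin
        idx = np.digitize(pace, edges[1:-1], right=False)
        idx[pace >= edges[-1]] = len(edges) - 2
        sel_pace, sel_bw = [], []
        order = np.arange(len(pace))
        for b in range(len(edges) - 1):
            mask = idx == b
            if not mask.any():
                continue
            # maximal bandwidth; ties -> smallest pace, then input order
            cand = np.lexsort((order[mask], pace[mask], -bw[mask]))[0]
            j = np.flatnonzero(mask)[cand]
            sel_bw.append(bw[j])
            if self.x_values == "actual":
                sel_pace.append(pace[j])
            else:
                sel_pace.append(0.5 * (edges[b] + edges[b + 1]))
        if len(sel_bw) < 2:
            raise ValueError("insufficient bins: need >= 2 nonempty pace bins")
        self.support_ = pd.DataFrame({"pace_hz": sel_pace, "bandwidth_hz": sel_bw})
        self._store(_ols_line(np.asarray(sel_pace), np.asarray(sel_bw)))
        return self


class SlidingPercentileBound(_BoundMixin, BaseEstimator):
    """Sliding-window bandwidth percentile regressed on window center.

    Windows of ``window_width`` Hz advance by ``step`` Hz from
    ``window_start``; within each window with at least ``min_count`` songs
    the ``q``-th percentile of bandwidth (linear interpolation) is computed,
    and OLS is fitted through (window center, percentile) pairs.  Windows
    with fewer than ``min_count`` songs are excluded to avoid outlier-driven
    estimates.
    """

    method = "percentile"

    def __init__(self, window_width: float = 2.0, step: float = 1.0,
                 q: float = 90.0, min_count: int = 32,
                 window_start: float = 0.0):
        self.window_width = window_width
        self.step = step
        self.q = q
        self.min_count = min_count
        self.window_start = window_start

    def fit(self, pace, bandwidth):
        pace = np.asarray(pace, dtype=float).ravel()
        bw = np.asarray(bandwidth, dtype=float).ravel()
        if pace.shape != bw.shape:
            raise ValueError("pace and bandwidth lengths differ")
        centers, pcts, counts = [], [], []
        lo = float(self.window_start)
        pmax = float(pace.max())
        n_dropped = 0
        while lo < pmax:
            hi = lo + self.window_width
            mask = (pace >= lo) & (pace < hi)
            k = int(mask.sum())
            if k >= self.min_count:
                centers.append(lo + 0.5 * self.window_width)
                pcts.append(float(np.percentile(bw[mask], self.q)))
                counts.append(k)
            elif k > 0:
                n_dropped += 1
            lo += self.step
        if len(centers) < 2:
            raise ValueError(
                "insufficient windows: fewer than 2 windows reached "
                f"min_count={self.min_count}"
            )
        if n_dropped:
            logger.info("dropped %d windows below min_count=%d",
                        n_dropped, self.min_count)
        self.support_ = pd.DataFrame(
            {"center_hz": centers, "percentile_hz": pcts, "n_songs": counts}
        )
        self._store(_ols_line(np.asarray(centers), np.asarray(pcts)))
        return self


# -- thin functional wrappers -------------------------------------------------

def upper_bound_regression(pace, bandwidth, **kwargs) -> UpperBoundRegression:
    """Fit the binned-maximum frontier; see :class:`UpperBoundRegression`."""
    return UpperBoundRegression(**kwargs).fit(pace, bandwidth)


def percentile_bound(pace, bandwidth, **kwargs) -> SlidingPercentileBound:
    """Fit the sliding-percentile frontier; see :class:`SlidingPercentileBound`."""
    return SlidingPercentileBound(**kwargs).fit(pace, bandwidth)


def vocal_deviation(pace, bandwidth, bound) -> np.ndarray:
    """Signed orthogonal distance from a fitted frontier.

    ``bound`` may be a fitted frontier estimator or a ``(slope, intercept)``
    pair.  Higher values mean lower vocal performance.
    """
    if isinstance(bound, tuple):
        slope, intercept = bound
        return orthogonal_deviation(pace, bandwidth, slope, intercept)
    return bound.deviation(pace, bandwidth)


def species_vocal_performance(songs: pd.DataFrame, bound) -> pd.Series:
    """Species-level vocal performance: mean of per-song deviations."""
    dev = vocal_deviation(songs["pace_hz"], songs["bandwidth_hz"], bound)
    out = pd.Series(dev, index=songs.index).groupby(songs["species"]).mean()
    out.name = "vocal_deviation"
    out.index.name = "species"
    return out.sort_index()
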