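"""Covariate-adjusted failure-probability curves from a random survival forest.

A forest of bootstrap survival trees (log-rank splits, Nelson-Aalen terminal
estimates — the engine is scikit-survival's RandomSurvivalForest) yields a
cumulative hazard H(t | x) per covariate profile; F(t | x) = 1 - exp(-H).
Treatment-group curves are adjusted by g-computation / partial dependence:
every cohort member's group covariate is set to each level in turn, keeping
their remaining covariates, and the individual cumulative probabilities are
averaged. Monthly time-specific event probabilities are the first
differences of the adjusted curve, lightly smoothed and rescaled so that
their running sum re-matches the cumulative curve at the horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sksurv.ensemble import RandomSurvivalForest
from sksurv.util import Surv

from .survival import _check_times_events


@dataclass
class HazardCurveSet:
    """Adjusted cumulative and monthly failure-probability curves per group."""

    time_grid: np.ndarray
    cumulative: dict[str, np.ndarray]
    monthly: dict[str, np.ndarray]
    group_covariate: str
    adjustment_covariates: list[str]
    smoothing_window: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.cumulative:
            for m, F, f in zip(self.time_grid, self.cumulative[g],
                               self.monthly[g]):
                rows.append((g, int(m), F, f))
        return pd.DataFrame(rows, columns=["group", "month", "cumulative",
                                           "monthly"])


class HazardCurveForest(BaseEstimator):
    """Random-survival-forest estimator of adjusted failure curves.

    Parameters
    ----------
    n_trees : int
        Bootstrap survival trees in the ensemble (1000 by default; each
        grown on a resample of the training cohort's size).
    mtry : int or None
        Covariates tried per split; ``None`` uses ceil(sqrt(#features))
        after one-hot encoding.
    min_terminal_events : int
        Minimum size of a terminal node, mapped onto the underlying
        tree-growing control (sample-count semantics).
    bootstrap : bool
        Disable to grow every tree on the full cohort (used by the
        degenerate-forest Nelson-Aalen oracle).

    ``fit(X, durations, events)`` accepts a DataFrame of categorical and/or
    numeric covariates; categoricals are one-hot encoded internally with
    the training levels remembered, so prediction rejects unseen levels.
    """

    def __init__(self, n_trees: int = 1000, mtry: int | None = None,
                 min_terminal_events: int = 15, bootstrap: bool = True,
                 random_state: int | None = None):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_terminal_events = min_terminal_events
        self.bootstrap = bootstrap
        self.random_state = random_state

    # -- encoding -----------------------------------------------------------

    def _encode(self, X: pd.DataFrame, fit: bool) -> np.ndarray:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
            X.columns = [f"x{i}" for i in X.columns]
        if fit:
            self.feature_names_ = [str(c) for c in X.columns]
            self.categories_ = {}
            for c in X.columns:
                if not pd.api.types.is_numeric_dtype(X[c]):
                    self.categories_[str(c)] = sorted(map(str, X[c].unique()))
        missing = [c for c in self.feature_names_ if c not in X.columns]
        if missing:
            raise ValueError(f"profile lacks model covariates: {missing}")
        cols = []
        names = []
        for c in self.feature_names_:
            if c in self.categories_:
                vals = X[c].astype(str)
                known = self.categories_[c]
                unseen = sorted(set(vals) - set(known))
                if unseen:
                    raise ValueError(
                        f"covariate {c!r} has unseen level(s) {unseen}; "
                        f"training levels were {known}")
                for lv in known[1:]:  # first level = reference
                    cols.append((vals == lv).to_numpy(dtype=float))
                    names.append(f"{c}={lv}")
            else:
                cols.append(X[c].to_numpy(dtype=float))
                names.append(c)
        if fit:
            self.encoded_names_ = names
        return np.column_stack(cols)

    # -- fitting ------------------------------------------------------------

    def fit(self, X, durations, events):
        t, e = _check_times_events(durations, events)
        if e.sum() == 0:
            raise ValueError("survival forest requires at least one event")
        Xe = self._encode(X, fit=True)
        keep = np.ptp(Xe, axis=0) > 0  # constant columns carry no split
        if not keep.any():
            keep[0] = True  # degenerate design: forest reduces to root nodes
        self.active_columns_ = keep
        mtry = self.mtry or math.ceil(math.sqrt(max(int(keep.sum()), 1)))
        self.forest_ = RandomSurvivalForest(
            n_estimators=self.n_trees,
            max_features=min(mtry, int(keep.sum())),
            min_samples_leaf=self.min_terminal_events,
            min_samples_split=max(2, 2 * self.min_terminal_events),
            bootstrap=self.bootstrap,
            n_jobs=1,
            random_state=self.random_state,
        )
        self.forest_.fit(Xe[:, keep], Surv.from_arrays(event=e, time=t))
        self.event_times_ = self.forest_.unique_times_
        return self

    # -- prediction ---------------------------------------------------------

    def predict_cumulative_hazard(self, X, time_grid) -> np.ndarray:
        """Ensemble-average H(t) per profile, step-interpolated on the grid."""
        Xe = self._encode(X, fit=False)[:, self.active_columns_]
        chf = self.forest_.predict_cumulative_hazard_function(
            Xe, return_array=True)
        grid = np.asarray(time_grid, dtype=float)
        idx = np.searchsorted(self.event_times_, grid, side="right") - 1
        H = np.concatenate([np.zeros((chf.shape[0], 1)), chf], axis=1)
        return H[:, idx + 1]

    def predict_cumulative(self, X, time_grid) -> np.ndarray:
        """F(t | x) = 1 - exp(-H(t | x)) per profile (rows) and grid month."""
        return 1.0 - np.exp(-self.predict_cumulative_hazard(X, time_grid))


def fit_rsf(X, durations, events, n_trees: int = 1000, mtry: int | None = None,
            min_terminal_events: int = 15, seed: int | None = None,
            bootstrap: bool = True) -> HazardCurveForest:
    return HazardCurveForest(
        n_trees=n_trees, mtry=mtry, min_terminal_events=min_terminal_events,
        bootstrap=bootstrap, random_state=seed,
    ).fit(X, durations, events)


def adjusted_group_curves(model: HazardCurveForest, cohort: pd.DataFrame,
                          group_covariate: str, time_grid,
                          smoothing_window: int = 3,
                          max_profiles: int | None = None,
                          random_state: int | None = None) -> HazardCurveSet:
    """G-computation group curves with monthly probabilities.

    For each level g of ``group_covariate``, the whole cohort (optionally a
    random subsample of ``max_profiles`` rows — a Monte-Carlo version of the
    same average) is given group level g while keeping every other
    covariate, and the individual F(t) predictions are averaged.
    """
    if group_covariate not in model.feature_names_:
        raise ValueError(f"{group_covariate!r} is not a model covariate")
    levels = model.categories_.get(group_covariate)
    if levels is None:
        levels = sorted(map(str, cohort[group_covariate].unique()))
    grid = np.asarray(time_grid, dtype=float)
    sub = cohort
    if max_profiles is not None and len(cohort) > max_profiles:
        rng = np.random.default_rng(random_state)
        sub = cohort.iloc[rng.choice(len(cohort), max_profiles, replace=False)]
    cumulative: dict[str, np.ndarray] = {}
    monthly: dict[str, np.ndarray] = {}
    for g in levels:
        forced = sub.copy()
        forced[group_covariate] = g
        F = model.predict_cumulative(forced, grid).mean(axis=0)
        cumulative[g] = F
        monthly[g] = monthly_probability(F, smoothing_window=smoothing_window)
    adj = [c for c in model.feature_names_ if c != group_covariate]
    return HazardCurveSet(time_grid=grid, cumulative=cumulative,
                          monthly=monthly, group_covariate=group_covariate,
                          adjustment_covariates=adj,
                          smoothing_window=smoothing_window)


def monthly_probability(F, smoothing_window: int = 3) -> np.ndarray:
    """Monthly event probabilities as the smoothed derivative of F.

    f(m) = F(m) - F(m-1) on the integer-month grid, then a centred moving
    average of ``smoothing_window`` months (edges truncated), negative
    values clipped, and a single rescaling so that the running sum matches
    F at the horizon. ``smoothing_window=1`` reproduces the raw first
    differences exactly.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 1 or F.size < 2:
        raise ValueError("F must be a 1-D curve with at least two points")
    if np.any(np.diff(F) < -1e-12):
        raise ValueError("F must be non-decreasing; project before deriving")
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd integer")
    f = np.diff(F, prepend=F[0])  # f[0] = 0: the grid starts at the origin
    if smoothing_window > 1:
        half = smoothing_window // 2
        kernel = np.ones(smoothing_window)
        num = np.convolve(f, kernel, mode="same")
        den = np.convolve(np.ones_like(f), kernel, mode="same")
        f = num / den
        f = np.clip(f, 0.0, None)
    total = F[-1] - F[0]
    s = f.sum()
    if s > 0:
        f = f * (total / s)
    return f
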