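"""Aggregated boosted trees (ABT) and per-predictor relative influence.

An ABT model bags B bootstrap replicates of a stagewise least-squares
gradient-boosted ensemble of depth-limited regression trees (shrinkage and
per-iteration row subsampling inside each replicate).  Relative influence of
a predictor is the squared-error reduction attributed to splits on that
predictor, summed over all trees and replicates and normalized to percent —
the standard variable-importance readout for boosted regression trees.
Categorical predictors (sampling site, habitat) enter via one-hot encoding;
their column influences are summed back to the original predictor before
normalization, so "sites" reports one number.

Defaults (25 replicates of 500 depth-3 trees, shrinkage 0.01, bag fraction
0.5) are conventional boosted-regression-tree settings for a few hundred
observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor


@dataclass(frozen=True)
class AbtParams:
    n_trees: int = 500
    max_depth: int = 3
    shrinkage: float = 0.01
    bag_fraction: float = 0.5
    n_replicates: int = 25

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.shrinkage <= 1:
            raise ValueError("shrinkage must lie in (0, 1]")
        if not 0 < self.bag_fraction <= 1:
            raise ValueError("bag_fraction must lie in (0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class AbtModel:
    replicates: list[GradientBoostingRegressor]
    feature_names: list[str]
    group_of: dict[str, str]  # encoded column -> original predictor
    params: AbtParams
    seed: int
    predictors: list[str] = field(default_factory=list)

    @property
    def fitted(self) -> bool:
        return bool(self.replicates)


def _encode(X: pd.DataFrame, categorical: list[str]) -> tuple[pd.DataFrame, dict[str, str]]:
    enc = pd.get_dummies(X, columns=categorical, prefix_sep="=")
    group_of: dict[str, str] = {}
    for col in enc.columns:
        origin = col.split("=", 1)[0] if "=" in col else col
        group_of[col] = origin if origin in X.columns else col
    return enc.astype(float), group_of


def fit_abt(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    params: AbtParams | None = None,
    seed: int = 0,
    categorical: list[str] | None = None,
) -> AbtModel:
    """Fit a bagged boosted-tree model; deterministic given ``seed``."""
    params = params or AbtParams()
    y = np.asarray(y, dtype=float)
    if X.isna().any().any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    if len(X) < 20:
        raise ValueError("need at least 20 observations")
    if np.ptp(y) == 0:
        raise ValueError("constant response: nothing to explain")
    if categorical is None:
        categorical = [c for c in X.columns if X[c].dtype == object or str(X[c].dtype) == "category"]
    for c in categorical:
        if X[c].nunique() < 2:
            warnings.warn(f"categorical predictor {c!r} has a single level", stacklevel=2)
    enc, group_of = _encode(X, categorical)
    rng = np.random.default_rng(seed)
    n = len(enc)
    reps: list[GradientBoostingRegressor] = []
    for _ in range(params.n_replicates):
        idx = rng.integers(0, n, size=n)  # bootstrap rows
        reg = GradientBoostingRegressor(
            loss="squared_error",
            n_estimators=params.n_trees,
            max_depth=params.max_depth,
            learning_rate=params.shrinkage,
            subsample=params.bag_fraction,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        reg.fit(enc.iloc[idx].to_numpy(), y[idx])
        reps.append(reg)
    return AbtModel(
        replicates=reps,
        feature_names=list(enc.columns),
        group_of=group_of,
        params=params,
        seed=seed,
        predictors=list(X.columns),
    )


def predict(model: AbtModel, X: pd.DataFrame, categorical: list[str] | None = None) -> np.ndarray:
    """Bagged prediction: mean over replicate ensembles."""
    if categorical is None:
        categorical = [c for c in X.columns if X[c].dtype == object or str(X[c].dtype) == "category"]
    enc, _ = _encode(X, categorical)
    enc = enc.reindex(columns=model.feature_names, fill_value=0.0)
    return np.mean([r.predict(enc.to_numpy()) for r in model.replicates], axis=0)


def raw_influence(model: AbtModel) -> dict[str, float]:
    """Unnormalized split-gain influence summed over trees and replicates."""
    if not model.fitted:
        raise ValueError("model is not fitted")
    totals = np.zeros(len(model.feature_names))
    for reg in model.replicates:
        for stage in reg.estimators_:
            tree = stage[0].tree_
            totals += tree.compute_feature_importances(normalize=False)
    grouped: dict[str, float] = {p: 0.0 for p in model.predictors}
    for col, val in zip(model.feature_names, totals):
        grouped[model.group_of[col]] = grouped.get(model.group_of[col], 0.0) + float(val)
    return grouped


def relative_influence(model: AbtModel) -> pd.Series:
    """Per-predictor influence in percent, descending; sums to 100."""
    raw = raw_influence(model)
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("no splits with positive gain: influence undefined")
    pct = pd.Series({k: 100.0 * v / total for k, v in raw.items()})
    return pct.sort_values(ascending=False)
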