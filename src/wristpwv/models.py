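"""Estimation models: multivariable baselines, a general boosted-tree
regressor, and the hierarchical classify-then-regress model with
overlapping zones.

The hierarchical model partitions the PWV range at a boundary ``tau``
(default 1600 cm/s) into low/high subdivisions.  A random-forest global
classifier routes each measurement to a subdivision; an XGBoost local
regressor trained on that subdivision's range *extended by half the
overlap width W on each side of the boundary* produces the estimate, so
measurements misclassified near the boundary still fall inside the range
their regressor has seen.  With tau = 1600 and W = 400 the low submodel
trains up to 1800 cm/s and the high submodel from 1400 cm/s.

Training utilities: 100 cm/s-bin oversampling to balance the PWV
distribution, participant-disjoint splits, leave-one-participant-out
validation for hyperparameter choice, and normalized feature importances.
Two hyperparameter profiles mirror the settings used for the male and
female cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from xgboost import XGBRegressor

__all__ = [
    "MultivariableModel",
    "HierarchicalModel",
    "MALE_PROFILE",
    "FEMALE_PROFILE",
    "fit_multivariable",
    "oversample_bins",
    "fit_general",
    "fit_hierarchical",
    "predict_hierarchical",
    "loo_validate",
    "feature_importance",
    "participant_split",
    "check_participant_disjoint",
]

# printed settings for the two cohorts: forest size/depth differ, the low
# submodel depth differs for the male profile
MALE_PROFILE = {
    "clf": {"n_estimators": 100, "max_depth": 20, "min_samples_split": 3, "min_samples_leaf": 1},
    "reg_low": {"n_estimators": 200, "colsample_bytree": 0.7, "gamma": 0.0, "max_depth": 5},
    "reg_high": {"n_estimators": 200, "colsample_bytree": 0.7, "gamma": 0.0, "max_depth": 3},
}
FEMALE_PROFILE = {
    "clf": {"n_estimators": 250, "max_depth": 9, "min_samples_split": 3, "min_samples_leaf": 1},
    "reg_low": {"n_estimators": 200, "colsample_bytree": 0.7, "gamma": 0.0, "max_depth": 3},
    "reg_high": {"n_estimators": 200, "colsample_bytree": 0.7, "gamma": 0.0, "max_depth": 3},
}
_DEFAULT_REG = {"n_estimators": 200, "colsample_bytree": 0.7, "gamma": 0.0, "max_depth": 3,
                "learning_rate": 0.1}


@dataclass
class MultivariableModel:
    """PWV = C1 * Age + C2 * X + C3 with X = SI/M^(1/3) or P2O/M."""

    C1: float
    C2: float
    C3: float
    variant: str  # "si" or "p2o"

    def predict(self, age: np.ndarray, x: np.ndarray) -> np.ndarray:
        return self.C1 * np.asarray(age, float) + self.C2 * np.asarray(x, float) + self.C3


def multivariable_predictor(features: pd.DataFrame, variant: str) -> np.ndarray:
    """The normalized second predictor for each variant."""
    m = features["cycle_len"].to_numpy(float)
    if variant == "si":
        return features["si"].to_numpy(float) / np.cbrt(m)
    if variant == "p2o":
        return features["p2o"].to_numpy(float) / m
    raise ValueError(f"unknown variant {variant!r}")


def fit_multivariable(features: pd.DataFrame, pwv: Sequence[float], variant: str = "si") -> MultivariableModel:
    """Ordinary least squares for the two-predictor linear model."""
    y = np.asarray(pwv, dtype=float)
    x2 = multivariable_predictor(features, variant)
    X = np.column_stack([features["age"].to_numpy(float), x2, np.ones(len(y))])
    if len(y) < 3:
        raise ValueError("need at least 3 measurements")
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design (a predictor is constant or collinear)")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return MultivariableModel(C1=float(coef[0]), C2=float(coef[1]), C3=float(coef[2]), variant=variant)


def oversample_bins(
    train: pd.DataFrame,
    pwv_col: str = "pwv",
    bin_width: float = 100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Balance the PWV distribution: every non-empty ``bin_width`` bin is
    topped up by duplicating its rows (with a fixed seed) to the largest
    bin count.  Originals are retained; duplicates carry
    ``_oversampled = True`` so validation folds can exclude them."""
    if train.empty:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    out = train.copy()
    if "_oversampled" not in out.columns:
        out["_oversampled"] = False
    bins = np.floor(out[pwv_col].to_numpy(float) / bin_width).astype(int)
    counts = pd.Series(bins).value_counts()
    target = int(counts.max())
    pieces = [out]
    for b, cnt in counts.items():
        deficit = target - int(cnt)
        if deficit <= 0:
            continue
        pool = out.index[bins == b]
        picked = rng.choice(pool, size=deficit, replace=True)
        dup = out.loc[picked].copy()
        dup["_oversampled"] = True
        pieces.append(dup)
    return pd.concat(pieces, ignore_index=True)


def _make_regressor(params: dict | None, seed: int) -> XGBRegressor:
    p = dict(_DEFAULT_REG)
    if params:
        p.update(params)
    return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0, **p)


def fit_general(
    X: pd.DataFrame, y: Sequence[float], params: dict | None = None, seed: int = 0
) -> XGBRegressor:
    """General XGBoost regression over the whole PWV range (the comparison
    baseline for the hierarchical model)."""
    if X.shape[1] == 0:
        raise ValueError("empty feature set")
    model = _make_regressor(params, seed)
    model.fit(X, np.asarray(y, dtype=float))
    return model


@dataclass
class HierarchicalModel:
    tau: float
    W: float
    classifier: RandomForestClassifier
    low_regressor: XGBRegressor
    high_regressor: XGBRegressor
    feature_names: list[str]
    seed: int
    train_participants: set = field(default_factory=set)

    @property
    def low_range_upper(self) -> float:
        return self.tau + self.W / 2.0

    @property
    def high_range_lower(self) -> float:
        return self.tau - self.W / 2.0


def fit_hierarchical(
    X: pd.DataFrame,
    y: Sequence[float],
    tau: float = 1600.0,
    W: float = 400.0,
    clf_params: dict | None = None,
    reg_params_low: dict | None = None,
    reg_params_high: dict | None = None,
    seed: int = 0,
    participants: Sequence[str] | None = None,
) -> HierarchicalModel:
    """Train the global classifier and the two overlap-zone regressors.

    The classifier learns the binary label ``pwv < tau``.  The low
    regressor trains on rows with ``pwv <= tau + W/2`` and the high one on
    ``pwv >= tau - W/2``; rows inside the overlapping zone appear in both.
    """
    if W < 0:
        raise ValueError("overlap width W must be >= 0")
    y = np.asarray(y, dtype=float)
    labels = (y < tau).astype(int)  # 1 = low subdivision

    cp = dict(MALE_PROFILE["clf"])
    if clf_params:
        cp.update(clf_params)
    clf = RandomForestClassifier(random_state=seed, n_jobs=1, **cp)
    clf.fit(X, labels)

    low_mask = y <= tau + W / 2.0
    high_mask = y >= tau - W / 2.0
    for name, mask in (("low", low_mask), ("high", high_mask)):
        if int(mask.sum()) < 5:
            raise ValueError(f"{name} submodel range contains fewer than 5 measurements")
    low = _make_regressor(reg_params_low, seed)
    low.fit(X[low_mask], y[low_mask])
    high = _make_regressor(reg_params_high, seed)
    high.fit(X[high_mask], y[high_mask])

    return HierarchicalModel(
        tau=tau, W=W, classifier=clf, low_regressor=low, high_regressor=high,
        feature_names=list(X.columns), seed=seed,
        train_participants=set(participants) if participants is not None else set(),
    )


def predict_hierarchical(
    model: HierarchicalModel, X: pd.DataFrame, blend: bool = False
) -> np.ndarray:
    """Route each row by the classifier's majority vote and return the
    routed submodel's prediction.  ``blend=True`` instead mixes the two
    submodels by the class probabilities (non-default)."""
    missing = [f for f in model.feature_names if f not in X.columns]
    if missing:
        raise ValueError(f"missing model features: {missing}")
    X = X[model.feature_names]
    pred_low = model.low_regressor.predict(X)
    pred_high = model.high_regressor.predict(X)
    if blend:
        p_low = model.classifier.predict_proba(X)[:, list(model.classifier.classes_).index(1)]
        return p_low * pred_low + (1.0 - p_low) * pred_high
    is_low = model.classifier.predict(X).astype(bool)
    return np.where(is_low, pred_low, pred_high)


def check_participant_disjoint(train_ids: Sequence[str], test_ids: Sequence[str]) -> None:
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise ValueError(f"participant-split violated; shared ids: {sorted(overlap)}")


def participant_split(
    participants: Sequence[str], test_frac: float = 0.3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Row masks (train, test) that are participant-disjoint."""
    participants = np.asarray(participants)
    uniq = np.unique(participants)
    rng = np.random.default_rng(seed)
    test_ids = set(rng.choice(uniq, size=max(1, int(round(test_frac * len(uniq)))), replace=False))
    test_mask = np.isin(participants, list(test_ids))
    check_participant_disjoint(participants[~test_mask], participants[test_mask])
    return ~test_mask, test_mask


def loo_validate(
    X: pd.DataFrame,
    y: Sequence[float],
    participants: Sequence[str],
    param_grid: list[dict],
    model: str = "hierarchical",
    tau: float = 1600.0,
    W: float = 400.0,
    oversample: bool = True,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Leave-one-participant-out hyperparameter selection.

    For each grid point and each participant, *all* of that participant's
    measurements are removed from fitting and then predicted; the grid
    point minimizing the pooled RMSE wins.  Ties prefer the smaller model
    (fewer estimators, then shallower trees).  Returns the chosen
    parameters and a per-(grid, participant) RMSE table.
    """
    if not param_grid:
        raise ValueError("empty parameter grid")
    y = np.asarray(y, dtype=float)
    participants = np.asarray(participants)
    uniq = np.unique(participants)
    if len(uniq) < 6:
        raise ValueError("need at least 6 participants for leave-one-out validation")

    rows = []
    pooled: list[tuple[int, float, dict]] = []
    for gi, params in enumerate(param_grid):
        sq_errors: list[np.ndarray] = []
        for pid in uniq:
            held = participants == pid
            Xtr, ytr = X[~held], y[~held]
            if oversample:
                df = Xtr.copy()
                df["pwv"] = ytr
                df = oversample_bins(df, seed=seed)
                ytr = df.pop("pwv").to_numpy()
                df = df.drop(columns=["_oversampled"])
                Xtr = df
            if model == "hierarchical":
                m = fit_hierarchical(
                    Xtr, ytr, tau=tau, W=W,
                    reg_params_low=params, reg_params_high=params, seed=seed,
                )
                pred = predict_hierarchical(m, X[held])
            else:
                m = fit_general(Xtr, ytr, params=params, seed=seed)
                pred = m.predict(X[held])
            err = y[held] - pred
            sq_errors.append(err**2)
            rows.append({"grid_index": gi, "participant": pid,
                         "rmse": float(np.sqrt(np.mean(err**2)))})
        rmse = float(np.sqrt(np.mean(np.concatenate(sq_errors))))
        pooled.append((gi, rmse, params))

    def tie_key(item: tuple[int, float, dict]) -> tuple:
        _, rmse, p = item
        return (round(rmse, 9), p.get("n_estimators", np.inf), p.get("max_depth", np.inf))

    best = min(pooled, key=tie_key)
    return best[2], pd.DataFrame(rows)


def feature_importance(model) -> dict[str, pd.Series]:
    """Normalized importance rankings (scores sum to 1 per component)."""

    def norm(names: Sequence[str], scores: np.ndarray) -> pd.Series:
        s = np.asarray(scores, dtype=float)
        total = s.sum()
        if total <= 0:
            s = np.ones_like(s)
            total = s.sum()
        return pd.Series(s / total, index=list(names)).sort_values(ascending=False)

    if isinstance(model, HierarchicalModel):
        return {
            "classifier": norm(model.feature_names, model.classifier.feature_importances_),
            "low": norm(model.feature_names, model.low_regressor.feature_importances_),
            "high": norm(model.feature_names, model.high_regressor.feature_importances_),
        }
    if hasattr(model, "feature_importances_"):
        try:
            names = model.feature_names_in_
        except AttributeError:
            names = [f"f{i}" for i in range(len(model.feature_importances_))]
        return {"model": norm(names, model.feature_importances_)}
    raise ValueError("model is not fitted or does not expose importances")
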