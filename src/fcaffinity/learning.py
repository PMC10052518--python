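"""Regression of log10 KD on interface features.

Four estimator families are supported, with fixed default
hyperparameters chosen for this problem size: support vector
regression (RBF kernel, C = 1, epsilon = 0.1), ordinary least squares
(MLR), a small multi-layer perceptron (two hidden layers of 20 and 2
tanh units, L-BFGS, strong L2 penalty alpha = 20), and a random forest
(10 trees, depth 10).

Feature selection runs in two stages, mirroring common practice for
low-dimensional tabular structure data: iterative elimination of the
least-important feature (accepted while the 10-fold CV R² does not
degrade beyond a tolerance) followed by correlation pruning of
near-duplicate features.  Importances are impurity-based for the
forest, absolute standardized coefficients for MLR, and seeded
permutation importance for SVR/MLP.

All evaluation is 10-fold cross-validation with per-fold
standardization, so the held-out fold never leaks into the scaler.
A shuffled-label control is provided: with responses permuted, the
mean CV R² should drop to about zero or below for every algorithm.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .interface_features import FeatureCatalog, extract_features
from .mutator import VariantSpec, apply_mutations
from .structure_io import ComplexModel

logger = logging.getLogger(__name__)

ALGORITHMS = ("SVR", "MLR", "MLP", "RFR")


class LearningError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class RegressorConfig:
    """Algorithm choice plus the fixed default hyperparameters."""

    algorithm: str
    random_state: int = 10

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise LearningError(f"unknown algorithm {self.algorithm!r}")

    def make_estimator(self, seed: int | None = None):
        rs = self.random_state if seed is None else seed
        if self.algorithm == "SVR":
            return SVR(kernel="rbf", gamma="auto", C=1.0, epsilon=0.1, tol=1e-3)
        if self.algorithm == "MLR":
            return LinearRegression(fit_intercept=True)
        if self.algorithm == "MLP":
            return MLPRegressor(
                solver="lbfgs", alpha=20, hidden_layer_sizes=(20, 2),
                activation="tanh", max_iter=4000, tol=1e-5,
                early_stopping=True, random_state=rs,
            )
        return RandomForestRegressor(
            n_estimators=10, criterion="squared_error", max_depth=10,
            random_state=rs,
        )


@dataclasses.dataclass
class CVReport:
    """Per-fold and mean metrics of a 10-fold cross-validation run."""

    algorithm: str
    r2: list[float]
    mae: list[float]
    mse: list[float]
    seed: int
    feature_ids: list[str]
    importances: dict[str, float] | None = None

    def __post_init__(self):
        if any(v < 0 for v in self.mae) or any(v < 0 for v in self.mse):
            raise LearningError("MAE/MSE must be non-negative")

    @property
    def n_folds(self) -> int:
        return len(self.r2)

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2))

    @property
    def mean_mae(self) -> float:
        return float(np.mean(self.mae))

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.mse))

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm, "seed": self.seed,
            "folds": self.n_folds,
            "r2": self.r2, "mae": self.mae, "mse": self.mse,
            "mean_r2": self.mean_r2, "mean_mae": self.mean_mae,
            "mean_mse": self.mean_mse,
            "feature_ids": self.feature_ids,
            "importances": self.importances,
        }


def variant_feature_table(reference: ComplexModel, catalog: FeatureCatalog,
                          specs: Sequence[VariantSpec]) -> pd.DataFrame:
    """Model each variant on the reference and extract the catalog
    features; one row per variant, indexed by mutation string."""
    rows = []
    for spec in specs:
        model = apply_mutations(reference, spec)
        vec = extract_features(model, catalog, provenance=str(spec))
        rows.append(vec.as_dict())
    return pd.DataFrame(rows, index=[str(s) for s in specs])


# --- standardization --------------------------------------------------

def standardize(train: pd.DataFrame,
                apply_to: pd.DataFrame | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame | None, StandardScaler, list[str]]:
    """Zero-mean/unit-variance scaling fitted on ``train`` only.

    Constant training columns carry no information and would divide by
    zero; they are dropped from both frames with a warning.  Returns
    (scaled train, scaled apply_to, fitted scaler, kept column names).
    """
    variances = train.var(axis=0, ddof=0)
    kept = [c for c in train.columns if variances[c] > 1e-12]
    dropped = [c for c in train.columns if c not in kept]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant feature(s): "
                      f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}")
    scaler = StandardScaler().fit(train[kept])
    out_train = pd.DataFrame(scaler.transform(train[kept]),
                             columns=kept, index=train.index)
    out_apply = None
    if apply_to is not None:
        out_apply = pd.DataFrame(scaler.transform(apply_to[kept]),
                                 columns=kept, index=apply_to.index)
    return out_train, out_apply, scaler, kept


# --- importances ------------------------------------------------------

def importance_rank(X: pd.DataFrame, y: np.ndarray,
                    config: RegressorConfig, seed: int = 0) -> pd.Series:
    """Per-feature importance, normalized to sum 1.

    The frame is standardized internally.  Forest: impurity importance;
    MLR: absolute standardized coefficient; SVR/MLP: permutation
    importance (mean R² drop over 10 seeded permutations, clipped at 0).
    """
    Xs, _, _, kept = standardize(X)
    est = config.make_estimator(seed)
    est.fit(Xs.values, y)
    if config.algorithm == "RFR":
        raw = est.feature_importances_
    elif config.algorithm == "MLR":
        raw = np.abs(est.coef_)
    else:
        perm = permutation_importance(
            est, Xs.values, y, n_repeats=10, random_state=seed, scoring="r2")
        raw = np.clip(perm.importances_mean, 0.0, None)
    total = raw.sum()
    norm = raw / total if total > 0 else np.full(len(raw), 1.0 / len(raw))
    out = pd.Series(0.0, index=X.columns)
    out[kept] = norm
    return out


# --- cross-validation -------------------------------------------------

def cross_validate(X: pd.DataFrame, y: np.ndarray,
                   config: RegressorConfig, k: int = 10,
                   seed: int = 0) -> CVReport:
    """Shuffled k-fold CV with the scaler refitted inside each fold."""
    y = np.asarray(y, float)
    if len(X) != len(y):
        raise LearningError("X and y length mismatch")
    if len(X) < k:
        raise LearningError(f"{len(X)} samples cannot fill {k} folds")
    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    r2s, maes, mses = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-column warnings per fold
        for train_idx, test_idx in folds.split(X):
            Xtr, Xte, _, _ = standardize(X.iloc[train_idx], X.iloc[test_idx])
            est = config.make_estimator(seed)
            est.fit(Xtr.values, y[train_idx])
            pred = est.predict(Xte.values)
            r2s.append(float(r2_score(y[test_idx], pred)))
            maes.append(float(mean_absolute_error(y[test_idx], pred)))
            mses.append(float(mean_squared_error(y[test_idx], pred)))
    return CVReport(config.algorithm, r2s, maes, mses, seed,
                    list(X.columns))


def shuffled_control(X: pd.DataFrame, y: np.ndarray,
                     config: RegressorConfig, k: int = 10,
                     seed: int = 0,
                     permutation: np.ndarray | None = None) -> CVReport:
    """Cross-validation with permuted responses.  A model that has
    learned real structure should collapse to R² ≈ 0 or below here."""
    y = np.asarray(y, float)
    if permutation is None:
        permutation = np.random.default_rng(seed).permutation(len(y))
    return cross_validate(X, y[permutation], config, k=k, seed=seed)


# --- feature selection ------------------------------------------------

def eliminate_features(X: pd.DataFrame, y: np.ndarray,
                       config: RegressorConfig, k: int = 10,
                       seed: int = 0, tolerance: float = 0.01) -> list[str]:
    """Iteratively drop the least-important feature while the mean
    k-fold CV R² stays within ``tolerance`` of the initial model's.
    Stops at the first rejected removal.  Deterministic given the seed.
    """
    if X.shape[1] < 1:
        raise LearningError("need at least one feature")
    current = list(X.columns)
    if len(current) == 1:
        return current
    baseline = cross_validate(X, y, config, k=k, seed=seed).mean_r2
    while len(current) > 1:
        imps = importance_rank(X[current], y, config, seed=seed)
        weakest = imps.idxmin()  # ties resolve to the first column
        candidate = [c for c in current if c != weakest]
        score = cross_validate(X[candidate], y, config, k=k, seed=seed).mean_r2
        if baseline - score < tolerance:
            current = candidate
            logger.info("dropped %s (CV R² %.4f)", weakest, score)
        else:
            break
    return current


def correlation_prune(X: pd.DataFrame, threshold: float = 0.9,
                      importances: pd.Series | None = None) -> list[str]:
    """Greedily break up highly correlated feature pairs.

    Pairs with |Pearson r| ≥ ``threshold`` are visited in order of
    descending |r| (ties by feature id); from each pair still intact the
    member with lower importance is dropped (ties drop the second id).
    Constant columns correlate with nothing and are kept.
    """
    cols = list(X.columns)
    if importances is None:
        importances = pd.Series(1.0, index=cols)
    corr = X.corr().abs()
    pairs = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and r >= threshold:
                pairs.append((r, a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    dropped: set[str] = set()
    for _, a, b in pairs:
        if a in dropped or b in dropped:
            continue
        if importances.get(a, 0.0) < importances.get(b, 0.0):
            dropped.add(a)
        else:
            dropped.add(b)
    return [c for c in cols if c not in dropped]


# --- end-to-end model -------------------------------------------------

@dataclasses.dataclass
class AffinityModel:
    """A trained prediction path: reference structure + catalog +
    scaler + fitted regressor over the selected features."""

    config: RegressorConfig
    catalog: FeatureCatalog
    reference: ComplexModel
    feature_ids: list[str]
    scaler: StandardScaler
    estimator: object
    seed: int = 0

    @classmethod
    def train(cls, reference: ComplexModel, catalog: FeatureCatalog,
              X: pd.DataFrame, y: np.ndarray, config: RegressorConfig,
              feature_ids: Sequence[str] | None = None,
              seed: int = 0) -> "AffinityModel":
        ids = list(feature_ids) if feature_ids is not None else list(X.columns)
        Xs, _, scaler, kept = standardize(X[ids])
        est = config.make_estimator(seed)
        est.fit(Xs.values, np.asarray(y, float))
        return cls(config, catalog, reference, kept, scaler, est, seed)

    def features_of(self, spec: VariantSpec) -> pd.DataFrame:
        """Model the variant on the reference structure and evaluate the
        catalog.  Off-catalog mutations do not enter the features and
        are dropped first, so two variants with equal effective
        signatures get identical features."""
        fc_positions = self.catalog.fc_positions()
        reduced = VariantSpec(frozenset(
            m for m in spec.mutations if m.eu_position in fc_positions))
        model = apply_mutations(self.reference, reduced)
        vec = extract_features(model, self.catalog, provenance=str(spec))
        return pd.DataFrame([vec.as_dict()])[self.feature_ids]

    def predict(self, spec: VariantSpec) -> float:
        """Predicted log10 KD at pH 7.0 for one variant."""
        feats = self.features_of(spec)
        return float(self.estimator.predict(self.scaler.transform(feats))[0])

    def predict_many(self, specs: Sequence[VariantSpec]) -> np.ndarray:
        frames = [self.features_of(s) for s in specs]
        feats = pd.concat(frames, ignore_index=True)
        return self.estimator.predict(self.scaler.transform(feats))

    def save(self, path: str) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str) -> "AffinityModel":
        return joblib.load(path)


def predict(model: AffinityModel, spec: VariantSpec) -> float:
    return model.predict(spec)
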