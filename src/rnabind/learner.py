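"""Gradient tree boosting with undersampling for imbalanced residue data.

Labels follow the ±1 convention with logistic loss
L(y, Θ) = log(1 + exp(−2yΘ)).  Training is the classic stagewise descent:
Θ₀ is the half log-odds of the positive rate; each stage fits a depth-limited
regression tree to the negative gradients r_i = 2y_i / (1 + exp(2y_iΘ(χ_i)))
and replaces each leaf value by the one-step Newton minimiser of the leaf's
loss, applied with shrinkage ν.  Scores are σ(2Θ) ∈ (0, 1).

Class imbalance is handled by 1:1 random undersampling of the majority
class, applied strictly inside each training fold during cross-validation so
test folds keep their natural imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.tree import DecisionTreeRegressor

from .evaluation import EvalReport, metrics_from_scores, summarize_folds

MODEL_SCHEMA_VERSION = 1


def undersample(X, y, seed: int) -> np.ndarray:
    """Indices of a 1:1 balanced subset: all minority-class samples plus a
    uniform without-replacement sample of the majority class."""
    y = np.asarray(y)
    classes, counts = np.unique(y), None
    if len(classes) < 2:
        raise ValueError("undersampling needs both classes present")
    counts = {c: int(np.sum(y == c)) for c in classes}
    if counts[classes[0]] == counts[classes[1]]:
        return np.arange(len(y))
    minority, majority = sorted(classes, key=lambda c: counts[c])
    rng = np.random.default_rng(seed)
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y == majority)
    keep_maj = rng.choice(maj_idx, size=len(min_idx), replace=False)
    idx = np.concatenate([min_idx, keep_maj])
    return np.sort(idx)


@dataclass
class GTBConfig:
    n_stages: int = 500       # M
    learning_rate: float = 0.1  # ν
    max_depth: int = 3
    subsample: float = 1.0
    seed: int = 0


@dataclass
class GTBModel:
    """Additive ensemble Θ_M(χ) = Θ₀ + ν Σ_m h_m(χ) with per-leaf Newton
    values (the stage weights β_m are absorbed into the leaves)."""

    theta0: float
    trees: list = field(default_factory=list)
    config: GTBConfig = field(default_factory=GTBConfig)
    n_features: int = 0
    feature_mask: np.ndarray | None = None  # columns used at fit time
    train_deviance: list[float] = field(default_factory=list)
    schema_version: int = MODEL_SCHEMA_VERSION

    def decision_function(self, X) -> np.ndarray:
        X = self._check(X)
        theta = np.full(X.shape[0], self.theta0)
        for tree in self.trees:
            theta += self.config.learning_rate * tree.predict(X)
        return theta

    def _check(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature width {X.shape[1] if X.ndim == 2 else '?'} does not "
                f"match model width {self.n_features}")
        if self.feature_mask is not None:
            X = X[:, self.feature_mask]
        return X

    def save(self, path) -> None:
        joblib.dump({"schema_version": self.schema_version, "model": self}, path)

    @classmethod
    def load(cls, path) -> "GTBModel":
        payload = joblib.load(path)
        if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(
                f"model schema version {payload.get('schema_version')} is not "
                f"supported (expected {MODEL_SCHEMA_VERSION})")
        return payload["model"]


def _deviance(y: np.ndarray, theta: np.ndarray) -> float:
    return float(np.mean(np.logaddexp(0.0, -2.0 * y * theta)))


def train_gtb(X, y, config: GTBConfig | None = None,
              feature_mask: np.ndarray | None = None) -> GTBModel:
    """Fit the boosting ensemble on ±1 labels.

    ``feature_mask`` restricts training (and later prediction) to a column
    subset while the model keeps the full input width, so a selected-feature
    model still consumes full 189-wide matrices.
    """
    config = config or GTBConfig()
    X_full = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X_full.ndim != 2 or X_full.shape[0] != len(y):
        raise ValueError("X must be 2D with one row per label")
    if X_full.shape[0] < 2 or len(np.unique(y)) < 2:
        raise ValueError("training needs ≥2 samples and both classes")
    Xm = X_full[:, feature_mask] if feature_mask is not None else X_full

    pos = float(np.mean(y == 1))
    theta0 = 0.5 * np.log(pos / (1.0 - pos))
    theta = np.full(len(y), theta0)
    rng = np.random.default_rng(config.seed)
    model = GTBModel(theta0=theta0, config=config,
                     n_features=X_full.shape[1], feature_mask=feature_mask)
    model.train_deviance.append(_deviance(y, theta))

    n = len(y)
    for _ in range(config.n_stages):
        # negative gradient of the logistic loss
        resid = 2.0 * y / (1.0 + np.exp(2.0 * y * theta))
        rows = (rng.choice(n, size=max(1, int(round(config.subsample * n))),
                           replace=False)
                if config.subsample < 1.0 else np.arange(n))
        tree = DecisionTreeRegressor(
            max_depth=config.max_depth,
            random_state=int(rng.integers(0, 2**31 - 1)))
        tree.fit(Xm[rows], resid[rows])
        # one-step Newton leaf values: γ = Σr / Σ|r|(2−|r|)
        leaves = tree.apply(Xm[rows])
        values = tree.tree_.value
        for leaf in np.unique(leaves):
            r_leaf = resid[rows][leaves == leaf]
            denom = np.sum(np.abs(r_leaf) * (2.0 - np.abs(r_leaf)))
            gamma = 0.0 if denom <= 0 else float(np.sum(r_leaf) / denom)
            values[leaf, 0, 0] = gamma
        theta += config.learning_rate * tree.predict(Xm)
        model.trees.append(tree)
        model.train_deviance.append(_deviance(y, theta))
    return model


def predict_scores(model: GTBModel, X) -> np.ndarray:
    """Per-row binding score σ(2Θ_M(χ)) ∈ (0, 1)."""
    theta = model.decision_function(X)
    return 1.0 / (1.0 + np.exp(-2.0 * theta))


def predict_labels(model: GTBModel, X, threshold: float = 0.5) -> np.ndarray:
    return np.where(predict_scores(model, X) > threshold, 1, -1)


@dataclass
class CVProtocol:
    n_folds: int = 10
    seed: int = 0
    stratified: bool = True
    groups: np.ndarray | None = None  # e.g. protein ids for grouped folds


@dataclass
class CVResult:
    fold_reports: list[EvalReport]
    summary: dict[str, tuple[float, float]]  # metric → (mean, sample sd)

    def metrics_tsv(self) -> str:
        keys = ["SN", "SP", "Precision", "ACC", "F", "MCC", "AUC"]
        lines = ["fold\t" + "\t".join(keys)]
        for i, rep in enumerate(self.fold_reports):
            d = rep.as_dict()
            lines.append(str(i) + "\t" +
                         "\t".join(f"{d.get(k, float('nan')):.4f}" for k in keys))
        mean = "mean\t" + "\t".join(f"{self.summary[k][0]:.4f}" for k in keys)
        sd = "sd\t" + "\t".join(f"{self.summary[k][1]:.4f}" for k in keys)
        return "\n".join(lines + [mean, sd]) + "\n"


def cross_validate(X, y, protocol: CVProtocol | None = None,
                   config: GTBConfig | None = None,
                   feature_mask: np.ndarray | None = None,
                   threshold: float = 0.5) -> CVResult:
    """K-fold cross-validation with in-fold 1:1 undersampling.

    Each fold's training portion is undersampled to class balance before
    fitting; the untouched test portion keeps its natural imbalance.
    """
    protocol = protocol or CVProtocol()
    config = config or GTBConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if protocol.groups is not None:
        splitter = GroupKFold(n_splits=protocol.n_folds)
        splits = splitter.split(X, y, groups=protocol.groups)
    elif protocol.stratified:
        splitter = StratifiedKFold(n_splits=protocol.n_folds, shuffle=True,
                                   random_state=protocol.seed)
        splits = splitter.split(X, y)
    else:
        from sklearn.model_selection import KFold
        splitter = KFold(n_splits=protocol.n_folds, shuffle=True,
                         random_state=protocol.seed)
        splits = splitter.split(X, y)

    reports: list[EvalReport] = []
    for k, (train_idx, test_idx) in enumerate(splits):
        y_tr = y[train_idx]
        if len(np.unique(y[test_idx])) < 2 or len(np.unique(y_tr)) < 2:
            raise ValueError(
                f"fold {k} lacks a class; consider residue-level stratified "
                f"folds (disable grouped mode)")
        bal = undersample(X[train_idx], y_tr, seed=protocol.seed + k)
        fold_config = GTBConfig(**{**config.__dict__,
                                   "seed": config.seed + k})
        model = train_gtb(X[train_idx][bal], y_tr[bal], fold_config,
                          feature_mask=feature_mask)
        scores = predict_scores(model, X[test_idx])
        reports.append(metrics_from_scores(scores, y[test_idx],
                                           threshold=threshold))
    return CVResult(fold_reports=reports, summary=summarize_folds(reports))
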