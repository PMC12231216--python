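"""Ensemble presence/background modelling core.

Five weighted classifiers — GLM (logistic regression with linear and
quadratic terms), GAM (logistic additive model on per-layer spline
bases), GBM (stochastic gradient-boosted trees), RF (random forest) and a
Maxent-style model (L1-penalized weighted logistic regression on linear,
quadratic, product and hinge features; the standard maxent-penalized-
logistic equivalence) — are fit on a weighted training table, evaluated
by repeated stratified 70/30 split-sampling (20 repetitions) with
weighted AUC and TSS, combined by a (weighted) mean into an ensemble
suitability surface, and binarized at the threshold maximizing
sensitivity + specificity.

All row weights from the training table are honored by every member:
presences carry weight 1 and pseudo-absences n_presence/n_absence, so the
weighted prevalence the models see is 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import SplineTransformer

from .geodata import EnvStack, Raster
from .occurrences import TrainingTable

ALGORITHM_NAMES = ("glm", "gam", "gbm", "rf", "maxent")


@dataclass
class AlgorithmSpec:
    """Name + hyperparameters of one ensemble member."""

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ALGORITHM_NAMES:
            raise ValueError(f"unknown algorithm {self.name!r}; choose from {ALGORITHM_NAMES}")


def default_algorithm_specs() -> list[AlgorithmSpec]:
    return [AlgorithmSpec(name) for name in ALGORITHM_NAMES]


# ---------------------------------------------------------------------------
# feature construction helpers


class _Standardizer:
    """Column-wise (x - mean)/sd with degenerate-column protection."""

    def fit(self, X: np.ndarray) -> "_Standardizer":
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.sd_


def _poly_features(Z: np.ndarray) -> np.ndarray:
    return np.hstack([Z, Z**2])


def _maxent_features(Z: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Linear + quadratic + pairwise-product + two-sided hinge expansion.

    ``knots`` has shape (n_layers, n_knots) in standardized units.
    """
    n, p = Z.shape
    blocks = [Z, Z**2]
    prods = [Z[:, [i]] * Z[:, [j]] for i in range(p) for j in range(i + 1, p)]
    if prods:
        blocks.append(np.hstack(prods))
    hinges = []
    for j in range(p):
        k = knots[j][None, :]
        zj = Z[:, [j]]
        hinges.append(np.maximum(0.0, zj - k))  # forward hinge
        hinges.append(np.maximum(0.0, k - zj))  # reverse hinge
    blocks.append(np.hstack(hinges))
    return np.hstack(blocks)


# ---------------------------------------------------------------------------
# fitted model


@dataclass
class FittedModel:
    spec: AlgorithmSpec
    layer_names: list[str]
    scaler: _Standardizer
    estimator: object
    feature_kind: str  # "poly" | "raw" | "spline" | "maxent"
    knots: np.ndarray | None = None
    training_summary: dict = field(default_factory=dict)

    def _features(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler.transform(np.asarray(X, dtype=float))
        if self.feature_kind == "poly":
            return _poly_features(Z)
        if self.feature_kind == "spline":
            return self.spline_.transform(Z)
        if self.feature_kind == "maxent":
            return self.maxent_scaler_.transform(_maxent_features(Z, self.knots))
        return Z

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Suitability scores in [0, 1] for predictor rows ordered as
        ``layer_names``."""
        F = self._features(X)
        p = self.estimator.predict_proba(F)[:, 1]
        return np.clip(p, 0.0, 1.0)


def _check_table(table: TrainingTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    y = table.df["response"].to_numpy(dtype=int)
    w = table.df["weight"].to_numpy(dtype=float)
    X = table.predictors()
    if len(np.unique(y)) < 2:
        raise ValueError("training table contains a single response class")
    if (w <= 0).any():
        raise ValueError("row weights must be positive")
    return X, y, w


def fit_algorithm(spec: AlgorithmSpec, table: TrainingTable, seed: int = 0) -> FittedModel:
    """Fit one weighted ensemble member; deterministic given the seed."""
    X, y, w = _check_table(table)
    hp = dict(spec.hyperparameters)
    scaler = _Standardizer().fit(X)
    Z = scaler.transform(X)
    model = FittedModel(spec, list(table.layer_names), scaler, None, "raw")

    if spec.name == "glm":
        est = LogisticRegression(
            C=hp.get("C", 1e4), solver="lbfgs", max_iter=hp.get("max_iter", 2000)
        )
        F = _poly_features(Z)
        est.fit(F, y, sample_weight=w)
        model.feature_kind = "poly"

    elif spec.name == "gam":
        spline = SplineTransformer(
            n_knots=hp.get("n_knots", 6), degree=hp.get("degree", 3), include_bias=False
        )
        F = spline.fit_transform(Z)
        est = LogisticRegression(
            C=hp.get("C", 100.0), solver="lbfgs", max_iter=hp.get("max_iter", 2000)
        )
        est.fit(F, y, sample_weight=w)
        model.feature_kind = "spline"
        model.spline_ = spline

    elif spec.name == "gbm":
        est = GradientBoostingClassifier(
            n_estimators=hp.get("n_estimators", 150),
            learning_rate=hp.get("learning_rate", 0.1),
            max_depth=hp.get("max_depth", 3),
            subsample=hp.get("subsample", 0.8),
            random_state=seed,
        )
        est.fit(Z, y, sample_weight=w)

    elif spec.name == "rf":
        est = RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 250),
            min_samples_leaf=hp.get("min_samples_leaf", 2),
            random_state=seed,
            n_jobs=1,
        )
        est.fit(Z, y, sample_weight=w)

    elif spec.name == "maxent":
        n_knots = hp.get("n_hinge_knots", 10)
        qs = np.linspace(0.05, 0.95, n_knots)
        knots = np.quantile(Z, qs, axis=0).T  # (n_layers, n_knots)
        F_raw = _maxent_features(Z, knots)
        fscaler = _Standardizer().fit(F_raw)
        F = fscaler.transform(F_raw)
        C_path = hp.get("C_path", (0.05, 0.2, 1.0, 5.0))
        C_best = _maxent_select_C(F, y, w, C_path, seed)
        est = LogisticRegression(
            l1_ratio=1, C=C_best, solver="liblinear", max_iter=hp.get("max_iter", 500),
            random_state=seed,
        )
        est.fit(F, y, sample_weight=w)
        model.feature_kind = "maxent"
        model.knots = knots
        model.maxent_scaler_ = fscaler
        model.training_summary["C_selected"] = C_best

    model.estimator = est
    return model


def _maxent_select_C(F, y, w, C_path, seed) -> float:
    """Pick the L1 penalty by weighted log-loss on a stratified 20% holdout."""
    if len(C_path) == 1:
        return float(C_path[0])
    rng = np.random.default_rng(seed)
    hold = np.zeros(len(y), dtype=bool)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        k = max(1, int(round(0.2 * idx.size)))
        hold[rng.choice(idx, size=k, replace=False)] = True
    if hold.all() or (~hold).all() or len(np.unique(y[~hold])) < 2:
        return float(C_path[-1])
    best_C, best_loss = None, np.inf
    for C in C_path:
        est = LogisticRegression(
            l1_ratio=1, C=C, solver="liblinear", max_iter=500, random_state=seed
        )
        est.fit(F[~hold], y[~hold], sample_weight=w[~hold])
        p = np.clip(est.predict_proba(F[hold])[:, 1], 1e-9, 1 - 1e-9)
        loss = -np.average(
            y[hold] * np.log(p) + (1 - y[hold]) * np.log(1 - p), weights=w[hold]
        )
        if loss < best_loss:
            best_C, best_loss = float(C), loss
    return best_C


# ---------------------------------------------------------------------------
# evaluation metrics (weighted, presence/background)


def _check_scores(scores, labels, weights):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    w = np.ones_like(s) if weights is None else np.asarray(weights, dtype=float)
    if s.shape != y.shape or s.shape != w.shape:
        raise ValueError("scores, labels and weights must have the same length")
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("both classes must be present")
    return s, y, w


def auc(scores, labels, weights=None) -> float:
    """Weighted Mann-Whitney AUC: probability that a random presence
    outscores a random absence; ties count 1/2; the (i, j) pair carries
    weight w_i * w_j."""
    s, y, w = _check_scores(scores, labels, weights)
    order = np.argsort(s, kind="mergesort")
    s, y, w = s[order], y[order], w[order]
    wp = np.where(y == 1, w, 0.0)
    wa = np.where(y == 0, w, 0.0)
    wp_tot = wp.sum()
    # for each distinct score: absence weight there pairs concordantly with
    # presence weight strictly above, and half-counts ties at the same score
    uniq, start = np.unique(s, return_index=True)
    end = np.append(start[1:], len(s))
    cum_wp_below = 0.0
    num = 0.0
    for a, b in zip(start, end):
        wp_here = wp[a:b].sum()
        wa_here = wa[a:b].sum()
        num += wa_here * (wp_tot - cum_wp_below - wp_here) + 0.5 * wa_here * wp_here
        cum_wp_below += wp_here
    denom = wp_tot * wa.sum()
    return float(num / denom)


def confusion_at(scores, labels, weights=None, threshold: float = 0.5):
    """Weighted (sensitivity, specificity) at ``score >= threshold``."""
    s, y, w = _check_scores(scores, labels, weights)
    pres, absn = y == 1, y == 0
    sens = w[pres & (s >= threshold)].sum() / w[pres].sum()
    spec = w[absn & (s < threshold)].sum() / w[absn].sum()
    return float(sens), float(spec)


def tss(sensitivity: float, specificity: float) -> float:
    """True Skill Statistic = sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


def max_ss_threshold(scores, labels, weights=None):
    """Threshold maximizing sensitivity + specificity.

    Candidates are the observed unique scores plus a -inf sentinel
    (classify-everything-presence); ties resolve to the smallest
    threshold. Returns (threshold, sensitivity, specificity).
    """
    s, y, w = _check_scores(scores, labels, weights)
    order = np.argsort(s, kind="mergesort")
    s, y, w = s[order], y[order], w[order]
    wp_tot = w[y == 1].sum()
    wa_tot = w[y == 0].sum()
    uniq, start = np.unique(s, return_index=True)
    end = np.append(start[1:], len(s))
    wp_at = np.array([np.sum(w[a:b][y[a:b] == 1]) for a, b in zip(start, end)])
    wa_at = np.array([np.sum(w[a:b][y[a:b] == 0]) for a, b in zip(start, end)])
    # sens at threshold u_i: presence weight with score >= u_i
    sens = (wp_tot - np.concatenate([[0.0], np.cumsum(wp_at)[:-1]])) / wp_tot
    spec = np.concatenate([[0.0], np.cumsum(wa_at)[:-1]]) / wa_tot
    cand = np.concatenate([[-np.inf], uniq])
    sens = np.concatenate([[1.0], sens])
    spec = np.concatenate([[0.0], spec])
    total = sens + spec
    best = int(np.argmax(total))  # argmax returns the first (smallest) maximizer
    return float(cand[best]), float(sens[best]), float(spec[best])


# ---------------------------------------------------------------------------
# repeated split-sample evaluation


@dataclass
class EvalResult:
    records: pd.DataFrame  # repetition, auc, tss, threshold, sensitivity, specificity
    n_repetitions: int
    train_fraction: float
    seed: int
    algorithms: list[str]

    @property
    def mean_auc(self) -> float:
        return float(self.records["auc"].mean())

    @property
    def mean_tss(self) -> float:
        return float(self.records["tss"].mean())

    @property
    def sd_auc(self) -> float:
        return float(self.records["auc"].std(ddof=1))

    @property
    def sd_tss(self) -> float:
        return float(self.records["tss"].std(ddof=1))

    def to_dict(self) -> dict:
        return {
            "algorithms": self.algorithms,
            "n_repetitions": self.n_repetitions,
            "train_fraction": self.train_fraction,
            "seed": self.seed,
            "records": self.records.to_dict(orient="records"),
            "aggregates": {
                "mean_auc": self.mean_auc,
                "sd_auc": self.sd_auc,
                "mean_tss": self.mean_tss,
                "sd_tss": self.sd_tss,
            },
        }


def _stratified_split(y: np.ndarray, train_frac: float, rng: np.random.Generator):
    """Per-class shuffle; floor(train_frac * n_class) rows to train."""
    train = np.zeros(len(y), dtype=bool)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 rows; cannot split")
        idx = rng.permutation(idx)
        n_train = int(np.floor(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)  # both sides non-empty
        train[idx[:n_train]] = True
    return train


def _subtable(table: TrainingTable, keep: np.ndarray) -> TrainingTable:
    return TrainingTable(
        table.df.loc[keep].reset_index(drop=True), table.species, table.layer_names
    )


def repeated_split_evaluate(
    specs: AlgorithmSpec | Sequence[AlgorithmSpec],
    table: TrainingTable,
    n_reps: int = 20,
    train_frac: float = 0.7,
    seed: int = 0,
    ensemble_weights: Sequence[float] | None = None,
) -> EvalResult:
    """Repeated stratified split-sample evaluation (default 70/30 x 20).

    Each repetition refits every member on the training split, scores the
    held-out split with the (weighted-mean) ensemble, and records the
    held-out weighted AUC and the TSS at that repetition's
    max-sensitivity+specificity threshold. Fully deterministic given
    ``seed``.
    """
    if isinstance(specs, AlgorithmSpec):
        specs = [specs]
    specs = list(specs)
    if not specs:
        raise ValueError("at least one algorithm spec required")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    y = table.df["response"].to_numpy(dtype=int)
    w = table.df["weight"].to_numpy(dtype=float)
    wts = None if ensemble_weights is None else np.asarray(ensemble_weights, dtype=float)
    rows = []
    for rep in range(n_reps):
        ss = np.random.SeedSequence([seed, rep])
        rng = np.random.default_rng(ss)
        fit_seed = int(ss.generate_state(1)[0] % 2**31)
        train = _stratified_split(y, train_frac, rng)
        sub = _subtable(table, train)
        X_test = table.predictors()[~train]
        member_scores = np.column_stack(
            [fit_algorithm(sp, sub, seed=fit_seed).predict(X_test) for sp in specs]
        )
        scores = np.average(member_scores, axis=1, weights=wts)
        a = auc(scores, y[~train], w[~train])
        thr, sens, spc = max_ss_threshold(scores, y[~train], w[~train])
        rows.append(
            {
                "repetition": rep, "auc": a, "tss": tss(sens, spc),
                "threshold": thr, "sensitivity": sens, "specificity": spc,
            }
        )
    return EvalResult(
        records=pd.DataFrame(rows),
        n_repetitions=n_reps,
        train_fraction=train_frac,
        seed=seed,
        algorithms=[sp.name for sp in specs],
    )


# ---------------------------------------------------------------------------
# ensemble prediction and binarization


@dataclass
class SuitabilityMap:
    raster: Raster
    species: str
    models: list[FittedModel]
    model_weights: np.ndarray
    weighting: str = "uniform"


@dataclass
class BinaryMap:
    raster: Raster
    threshold: float
    species: str
    rule: str = "max_sens_spec"


def ensemble_predict(
    models: Sequence[FittedModel],
    env: EnvStack,
    weights: Sequence[float] | None = None,
    species: str = "",
    weighting: str = "uniform",
) -> SuitabilityMap:
    """Cell-wise weighted mean of member suitability scores.

    ``weights=None`` gives the unweighted mean; pass per-member mean AUCs
    (renormalized internally) for AUC-weighted aggregation.
    """
    models = list(models)
    if not models:
        raise ValueError("empty model list")
    names = models[0].layer_names
    for m in models:
        if m.layer_names != names:
            raise ValueError("all ensemble members must share the same predictor layers")
    stack = env.subset(names)
    X, idx = stack.to_matrix()
    wts = np.ones(len(models)) if weights is None else np.asarray(weights, dtype=float)
    if wts.shape != (len(models),) or (wts < 0).any() or wts.sum() == 0:
        raise ValueError("invalid ensemble weights")
    wts = wts / wts.sum()
    scores = np.zeros(X.shape[0])
    for m, wt in zip(models, wts):
        scores += wt * m.predict(X)
    vals = np.full(env.grid.shape, np.nan).ravel()
    vals[idx] = scores
    vals = vals.reshape(env.grid.shape)
    mask = stack.combined_mask
    return SuitabilityMap(Raster(env.grid, vals, mask), species, models, wts, weighting)


def binarize(suit: SuitabilityMap, table: TrainingTable) -> BinaryMap:
    """Threshold the ensemble surface at the max sensitivity+specificity
    point of the ensemble scores recomputed at the training rows."""
    X = table.df[suit.models[0].layer_names].to_numpy()
    scores = np.zeros(X.shape[0])
    for m, wt in zip(suit.models, suit.model_weights):
        scores += wt * m.predict(X)
    y = table.df["response"].to_numpy(dtype=int)
    w = table.df["weight"].to_numpy(dtype=float)
    thr, _, _ = max_ss_threshold(scores, y, w)
    if not np.isfinite(thr):  # -inf sentinel: everything classified suitable
        thr = float(np.min(scores))
    return BinaryMap(suit.raster.threshold(thr), float(thr), suit.species)
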