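"""Ten presence/absence learners behind one fit/predict-probability contract.

The algorithm set mirrors the classic ensemble-SDM platform roster:

========  ==============================================================
ANN       single-hidden-layer perceptron (8 units), logistic output
CTA       classification tree, cost-complexity pruned
FDA       flexible discriminant analysis: LDA on a MARS hinge basis
GAM       penalized cubic-spline additive logistic model
GBM       gradient-boosted trees (500 trees, depth 3)
GLM       logistic regression with linear + quadratic terms per covariate
MARS      multivariate adaptive regression splines, logistic link
RF        random forest (500 trees)
SRE       surface range envelope: per-covariate quantile box, binary
XGBOOST   histogram-based extreme gradient boosting
========  ==============================================================

All learners consume an occurrence table (label column in {0,1} plus
covariate columns) and emit probabilities in [0,1]; the SRE emits {0,1}.
Rows with missing covariate values predict NaN. Stochastic learners are
deterministic under a fixed seed.

The SRE and MARS/FDA basis machinery are implemented here from scratch;
everything else stands on scikit-learn estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer, SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

ALGORITHM_IDS = ("ANN", "CTA", "FDA", "GAM", "GBM", "GLM", "MARS", "RF", "SRE", "XGBOOST")

DEFAULT_LABEL = "presence"


# --------------------------------------------------------------------------
# Surface range envelope
# --------------------------------------------------------------------------

@dataclass
class SREnvelope:
    """Rectilinear quantile envelope fitted to presence rows only.

    For each covariate the envelope is the closed interval
    [Q(q), Q(1-q)] of the presence values (linear interpolation between
    order statistics). A row is suitable (1) iff every covariate lies
    inside its interval. With q=0 the envelope is the presence min-max,
    so every training presence is classified suitable.
    """

    lower: dict[str, float]
    upper: dict[str, float]

    @classmethod
    def fit(cls, presence_rows: pd.DataFrame, covariates: Sequence[str], q: float = 0.025):
        if not 0 <= q < 0.5:
            raise ValueError("q must lie in [0, 0.5)")
        if len(presence_rows) == 0:
            raise ValueError("SRE needs at least one presence row")
        lower, upper = {}, {}
        for c in covariates:
            x = np.asarray(presence_rows[c], dtype=float)
            x = x[np.isfinite(x)]
            if x.size == 0:
                raise ValueError(f"no finite presence values for covariate {c!r}")
            lower[c] = float(np.quantile(x, q))
            upper[c] = float(np.quantile(x, 1.0 - q))
        return cls(lower=lower, upper=upper)

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        inside = np.ones(len(rows), dtype=float)
        for c in self.lower:
            x = np.asarray(rows[c], dtype=float)
            ok = (x >= self.lower[c]) & (x <= self.upper[c])
            inside = inside * ok.astype(float)
            inside[~np.isfinite(x)] = np.nan
        return inside


def sre_envelope(
    presence_rows: pd.DataFrame,
    covariates: Sequence[str] | None = None,
    q: float = 0.025,
) -> SREnvelope:
    """Fit a surface range envelope to presence rows; see :class:`SREnvelope`."""
    if covariates is None:
        covariates = [c for c in presence_rows.columns if c != DEFAULT_LABEL]
    return SREnvelope.fit(presence_rows, covariates, q=q)


# --------------------------------------------------------------------------
# MARS hinge basis (shared by MARS and FDA)
# --------------------------------------------------------------------------

@dataclass
class HingeBasis:
    """Hinge-function basis selected by a forward/backward MARS pass.

    Terms are ('hinge', j, knot, +1) for max(0, x_j - knot) and
    ('hinge', j, knot, -1) for max(0, knot - x_j). The forward pass adds
    reflected hinge pairs greedily by least-squares residual reduction;
    the backward pass prunes terms by a generalized cross-validation
    criterion (smoothing penalty 3 per knot, the conventional value).
    """

    terms: list[tuple] = field(default_factory=list)

    def transform(self, X: np.ndarray) -> np.ndarray:
        cols = [np.ones(X.shape[0])]
        for kind, j, knot, sign in self.terms:
            z = sign * (X[:, j] - knot)
            cols.append(np.maximum(z, 0.0))
        return np.column_stack(cols)


def _fit_hinge_basis(
    X: np.ndarray,
    y: np.ndarray,
    max_pairs: int = 8,
    n_knots: int = 5,
    penalty: float = 3.0,
) -> HingeBasis:
    n, p = X.shape
    candidates: list[tuple] = []
    for j in range(p):
        knots = np.quantile(X[:, j], np.linspace(0.1, 0.9, n_knots))
        for t in np.unique(knots):
            candidates.append((j, float(t)))

    def rss(design: np.ndarray) -> float:
        coef, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        pred = design @ coef
        return float(np.sum((y - pred) ** 2))

    basis = HingeBasis()
    current = basis.transform(X)
    current_rss = rss(current)
    used: set[tuple] = set()
    for _ in range(max_pairs):
        best = None
        for j, t in candidates:
            if (j, t) in used:
                continue
            plus = np.maximum(X[:, j] - t, 0.0)
            minus = np.maximum(t - X[:, j], 0.0)
            trial = np.column_stack([current, plus, minus])
            r = rss(trial)
            if best is None or r < best[0]:
                best = (r, j, t, trial)
        if best is None or best[0] >= current_rss * (1 - 1e-9):
            break
        current_rss, j, t, current = best[0], best[1], best[2], best[3]
        used.add((j, t))
        basis.terms.append(("hinge", j, t, +1))
        basis.terms.append(("hinge", j, t, -1))

    # backward pruning by GCV
    def gcv(terms: list[tuple]) -> float:
        b = HingeBasis(terms=list(terms))
        design = b.transform(X)
        r = rss(design)
        m = design.shape[1]
        c_eff = m + penalty * (m - 1) / 2.0
        denom = (1.0 - min(c_eff, n - 1) / n) ** 2
        return r / n / denom

    best_terms = list(basis.terms)
    best_gcv = gcv(best_terms)
    terms = list(basis.terms)
    while terms:
        scored = []
        for i in range(len(terms)):
            trial = terms[:i] + terms[i + 1:]
            scored.append((gcv(trial), i))
        g, i = min(scored)
        terms = terms[:i] + terms[i + 1:]
        if g < best_gcv:
            best_gcv, best_terms = g, list(terms)
    basis.terms = best_terms
    return basis


class _MarsLogistic:
    """MARS basis + logistic link for probability output."""

    def __init__(self, max_pairs: int = 8, n_knots: int = 5):
        self.max_pairs = max_pairs
        self.n_knots = n_knots

    def fit(self, X: np.ndarray, y: np.ndarray):
        self.basis_ = _fit_hinge_basis(X, y, self.max_pairs, self.n_knots)
        design = self.basis_.transform(X)[:, 1:]  # logistic adds its own intercept
        if design.shape[1] == 0:
            design = X[:, :1] * 0.0
        self.logit_ = LogisticRegression(C=1e4, max_iter=5000)
        self.logit_.fit(design, y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        design = self.basis_.transform(X)[:, 1:]
        if design.shape[1] == 0:
            design = X[:, :1] * 0.0
        return self.logit_.predict_proba(design)


class _FDAClassifier:
    """Flexible discriminant analysis: LDA on the MARS hinge basis."""

    def __init__(self, max_pairs: int = 8, n_knots: int = 5):
        self.max_pairs = max_pairs
        self.n_knots = n_knots

    def fit(self, X: np.ndarray, y: np.ndarray):
        self.basis_ = _fit_hinge_basis(X, y, self.max_pairs, self.n_knots)
        design = self.basis_.transform(X)[:, 1:]
        if design.shape[1] == 0:
            design = X
        self._use_raw = self.basis_.terms == []
        self.lda_ = LinearDiscriminantAnalysis()
        self.lda_.fit(design, y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        design = self.basis_.transform(X)[:, 1:]
        if design.shape[1] == 0:
            design = X
        return self.lda_.predict_proba(design)


# --------------------------------------------------------------------------
# Estimator factory
# --------------------------------------------------------------------------

def _quadratic_expand(X: np.ndarray) -> np.ndarray:
    return np.column_stack([X, X**2])


def _make_estimator(algorithm: str, n_covariates: int, hp: dict[str, Any], seed: int):
    if algorithm == "GLM":
        return Pipeline([
            ("quad", FunctionTransformer(_quadratic_expand)),
            ("scale", StandardScaler()),
            ("logit", LogisticRegression(
                C=hp.get("C", 1e4), max_iter=5000,
                class_weight=hp.get("class_weight"),
            )),
        ])
    if algorithm == "GAM":
        return Pipeline([
            ("spline", SplineTransformer(
                n_knots=hp.get("n_knots", 5), degree=3, include_bias=False,
            )),
            ("logit", LogisticRegression(
                C=hp.get("C", 1.0), max_iter=5000,
                class_weight=hp.get("class_weight"),
            )),
        ])
    if algorithm == "GBM":
        return GradientBoostingClassifier(
            n_estimators=hp.get("n_estimators", 500),
            max_depth=hp.get("max_depth", 3),
            learning_rate=hp.get("learning_rate", 0.05),
            random_state=seed,
        )
    if algorithm == "XGBOOST":
        return HistGradientBoostingClassifier(
            max_iter=hp.get("max_iter", 200),
            random_state=seed,
        )
    if algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 500),
            random_state=seed,
            class_weight=hp.get("class_weight"),
            n_jobs=1,
        )
    if algorithm == "CTA":
        return _PrunedTree(seed=seed, class_weight=hp.get("class_weight"))
    if algorithm == "ANN":
        return Pipeline([
            ("scale", StandardScaler()),
            ("mlp", MLPClassifier(
                hidden_layer_sizes=hp.get("hidden_layer_sizes", (8,)),
                max_iter=hp.get("max_iter", 2000),
                random_state=seed,
            )),
        ])
    if algorithm == "MARS":
        return _MarsLogistic(
            max_pairs=hp.get("max_pairs", 8), n_knots=hp.get("n_knots", 5)
        )
    if algorithm == "FDA":
        return _FDAClassifier(
            max_pairs=hp.get("max_pairs", 8), n_knots=hp.get("n_knots", 5)
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHM_IDS}")


class _PrunedTree:
    """Classification tree with cost-complexity pruning, alpha chosen by
    a small seeded stratified cross-validation over the pruning path."""

    def __init__(self, seed: int = 0, class_weight=None):
        self.seed = seed
        self.class_weight = class_weight

    def fit(self, X: np.ndarray, y: np.ndarray):
        base = DecisionTreeClassifier(random_state=self.seed, class_weight=self.class_weight)
        path = base.cost_complexity_pruning_path(X, y)
        alphas = np.unique(np.clip(path.ccp_alphas, 0, None))
        if alphas.size > 12:
            alphas = np.quantile(alphas, np.linspace(0, 1, 12))
        n_min = int(np.bincount(y.astype(int)).min())
        n_splits = max(2, min(3, n_min))
        best_alpha, best_score = 0.0, -np.inf
        if n_min >= 2 and alphas.size > 1:
            cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=self.seed)
            for a in alphas[:-1]:  # last alpha collapses the root
                tree = DecisionTreeClassifier(
                    random_state=self.seed, ccp_alpha=float(a),
                    class_weight=self.class_weight,
                )
                score = cross_val_score(tree, X, y, cv=cv, scoring="accuracy").mean()
                if score > best_score:
                    best_alpha, best_score = float(a), score
        self.tree_ = DecisionTreeClassifier(
            random_state=self.seed, ccp_alpha=best_alpha, class_weight=self.class_weight
        )
        self.tree_.fit(X, y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.tree_.predict_proba(X)


# --------------------------------------------------------------------------
# Unified fit / predict
# --------------------------------------------------------------------------

@dataclass
class SDMModel:
    """A fitted presence/absence model with its covariate contract."""

    algorithm: str
    covariates: list[str]
    estimator: Any
    seed: int
    training_range: dict[str, tuple[float, float]]
    classes_: np.ndarray | None = None

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        return predict(self, rows)


def fit(
    algorithm: str,
    table: pd.DataFrame,
    covariates: Sequence[str],
    hyperparams: dict[str, Any] | None = None,
    seed: int = 0,
    label: str = DEFAULT_LABEL,
) -> SDMModel:
    """Fit one algorithm on an occurrence table.

    ``table`` must carry the 0/1 label column (except for SRE, which uses
    presences only: rows labelled 1, or the whole table if the label
    column is absent) and every covariate. Deterministic given ``seed``.
    """
    if algorithm not in ALGORITHM_IDS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHM_IDS}")
    hyperparams = dict(hyperparams or {})
    missing = [c for c in covariates if c not in table.columns]
    if missing:
        raise ValueError(f"covariates missing from table: {missing}")
    covariates = list(covariates)

    if algorithm == "SRE":
        if label in table.columns:
            presences = table[table[label] == 1]
        else:
            presences = table
        q = hyperparams.get("q", 0.025)
        env = SREnvelope.fit(presences, covariates, q=q)
        ranges = {c: (env.lower[c], env.upper[c]) for c in covariates}
        return SDMModel("SRE", covariates, env, seed, ranges)

    if label not in table.columns:
        raise ValueError(f"label column {label!r} missing")
    y = np.asarray(table[label], dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("occurrence table must contain both classes (0 and 1)")
    X = table[covariates].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("training covariates contain missing values")

    est = _make_estimator(algorithm, len(covariates), hyperparams, seed)
    est.fit(X, y)
    ranges = {
        c: (float(X[:, i].min()), float(X[:, i].max()))
        for i, c in enumerate(covariates)
    }
    return SDMModel(algorithm, covariates, est, seed, ranges, classes_=np.array([0, 1]))


def predict(model: SDMModel, rows: pd.DataFrame) -> np.ndarray:
    """Probability of presence for each row, NaN where covariates are missing."""
    missing = [c for c in model.covariates if c not in rows.columns]
    if missing:
        raise ValueError(f"rows lack covariates: {missing}")
    if model.algorithm == "SRE":
        return model.estimator.predict(rows)
    X = rows[model.covariates].to_numpy(dtype=float)
    ok = np.all(np.isfinite(X), axis=1)
    out = np.full(X.shape[0], np.nan)
    if ok.any():
        proba = model.estimator.predict_proba(X[ok])
        out[ok] = np.clip(proba[:, 1], 0.0, 1.0)
    return out
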