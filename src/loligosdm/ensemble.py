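"""AUC-gated weighted-average ensembling with importance and response curves.

Only algorithms whose held-out AUC strictly exceeds the gate (0.8 by
default) enter the ensemble; their predictions are combined as a weighted
mean with weights proportional to AUC. The ensemble's own binarization
threshold is the max-TSS threshold of its combined scores on held-out
data. Diagnostics follow ensemble-platform conventions: permutation
variable importance (1 minus the Pearson correlation between original and
permuted-column predictions) and evaluation-strip response curves
(non-focal covariates held at their training means).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from loligosdm.evaluation import EvalReport, max_tss
from loligosdm.models import SDMModel, predict


class EmptyEnsembleError(RuntimeError):
    """No algorithm cleared the AUC gate."""


def select_members(reports: list[EvalReport], auc_min: float = 0.8) -> list[EvalReport]:
    """Reports whose AUC strictly exceeds the gate; error if none do."""
    if not reports:
        raise ValueError("no evaluation reports supplied")
    selected = [r for r in reports if r.auc > auc_min]
    if not selected:
        aucs = {r.algorithm: round(r.auc, 3) for r in reports}
        raise EmptyEnsembleError(
            f"no algorithm exceeded the AUC gate {auc_min}; observed {aucs}"
        )
    return selected


@dataclass
class EnsembleModel:
    """Weighted-average committee of gate-passing members."""

    members: list[SDMModel]
    weights: np.ndarray
    auc_gate: float = 0.8
    threshold: float | None = None
    member_aucs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.members) != self.weights.size:
            raise ValueError("one weight per member required")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("weights must sum to a positive value")
        self.weights = self.weights / total

    @property
    def covariates(self) -> list[str]:
        return self.members[0].covariates

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        return ensemble_predict(self.members, self.weights, rows)


def ensemble_predict(members: list[SDMModel], weights, rows: pd.DataFrame) -> np.ndarray:
    """Weighted mean of member probabilities; stays inside the member envelope."""
    if not members:
        raise ValueError("ensemble has no members")
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    preds = np.stack([predict(m, rows) for m in members])
    return np.einsum("m,mn->n", weights, preds)


def build_ensemble(
    models: dict[str, SDMModel],
    reports: list[EvalReport],
    test_table: pd.DataFrame,
    auc_min: float = 0.8,
    label: str = "presence",
) -> EnsembleModel:
    """Gate by AUC, weight by AUC, and set the max-TSS threshold.

    ``test_table`` is the held-out split used to compute the ensemble's
    own binarization threshold.
    """
    selected = select_members(reports, auc_min=auc_min)
    members = [models[r.algorithm] for r in selected]
    weights = np.array([r.auc for r in selected], dtype=float)
    ens = EnsembleModel(
        members=members,
        weights=weights,
        auc_gate=auc_min,
        member_aucs={r.algorithm: r.auc for r in selected},
    )
    scores = ens.predict(test_table)
    labels = np.asarray(test_table[label], dtype=int)
    ok = np.isfinite(scores)
    _, thr = max_tss(labels[ok], scores[ok])
    ens.threshold = thr
    return ens


def variable_importance(
    model,
    rows: pd.DataFrame,
    covariate: str,
    n_perm: int = 10,
    seed: int = 0,
) -> float:
    """Permutation importance of one covariate, in [0, 1].

    One minus the Pearson correlation between predictions on the original
    rows and on rows with the covariate's column permuted, averaged over
    ``n_perm`` seeded permutations. A covariate the model ignores scores
    0; a sole driver approaches 1. Constant predictions (correlation
    undefined) score 0 by convention.
    """
    if covariate not in rows.columns:
        raise ValueError(f"unknown covariate {covariate!r}")
    if len(rows) < 2:
        raise ValueError("need at least two rows")
    rng = np.random.default_rng(seed)
    base = model.predict(rows)
    ok = np.isfinite(base)
    base = base[ok]
    rows = rows.loc[ok].reset_index(drop=True)
    if np.std(base) == 0:
        return 0.0
    vals = []
    for _ in range(n_perm):
        shuffled = rows.copy()
        shuffled[covariate] = rng.permutation(shuffled[covariate].to_numpy())
        perm = model.predict(shuffled)
        if np.std(perm) == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(base, perm)[0, 1])
        vals.append(1.0 - r)
    return float(np.clip(np.mean(vals), 0.0, 1.0))


def importance_table(
    models: dict[str, object],
    rows: pd.DataFrame,
    covariates: list[str],
    n_perm: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Importance of every covariate for every model (rows: model id)."""
    out = {}
    for name, model in models.items():
        out[name] = {
            c: variable_importance(model, rows, c, n_perm=n_perm, seed=seed)
            for c in covariates
        }
    return pd.DataFrame.from_dict(out, orient="index")[covariates]


def response_curve(
    model,
    background: pd.DataFrame,
    covariate: str,
    grid: np.ndarray | None = None,
    n_points: int = 50,
) -> pd.DataFrame:
    """Evaluation-strip response: suitability along one covariate.

    All non-focal covariates are fixed at their background means; the
    focal covariate sweeps ``grid`` (default: the background min-max over
    ``n_points`` values). Returns a DataFrame with columns ``value`` and
    ``suitability``.
    """
    covs = list(model.covariates)
    if covariate not in covs:
        raise ValueError(f"unknown covariate {covariate!r}")
    if grid is None:
        x = background[covariate].to_numpy(dtype=float)
        grid = np.linspace(np.nanmin(x), np.nanmax(x), n_points)
    grid = np.asarray(grid, dtype=float)
    strip = pd.DataFrame(
        {c: np.full(grid.size, float(background[c].mean())) for c in covs}
    )
    strip[covariate] = grid
    suit = model.predict(strip)
    return pd.DataFrame({"value": grid, "suitability": suit})
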