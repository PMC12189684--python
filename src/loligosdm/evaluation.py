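"""Train/test splitting, ROC-AUC, and true-skill-statistic evaluation.

The evaluation protocol holds out a random 20% of stations (stratified by
class so both presences and absences appear on each side whenever
feasible), scores each fitted algorithm by ROC-AUC on the held-out set,
and selects the probability threshold maximizing the true skill statistic
TSS(t) = sensitivity(t) + specificity(t) - 1, classifying score >= t as
presence. Ties in TSS break to the smallest threshold for
reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score


@dataclass
class EvalReport:
    """Held-out performance of one algorithm."""

    algorithm: str
    auc: float
    tss: float
    optimal_threshold: float
    split_seed: int
    test_fraction: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def split(
    table: pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
    label: str = "presence",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random stratified partition into (train, test).

    The test set holds round(test_fraction * n) rows, allocated across the
    two classes proportionally (largest-remainder), keeping at least one
    row of each class on each side when the class has >= 2 rows. The two
    parts are disjoint and exhaustive, and the split is deterministic
    given ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    n = len(table)
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    y = np.asarray(table[label], dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes required for a stratified split")

    n_test = int(round(test_fraction * n))
    n_test = min(max(n_test, 1), n - 1)

    # largest-remainder apportionment of the test quota across classes
    exact = counts * n_test / n
    base = np.floor(exact).astype(int)
    rem = exact - base
    shortfall = n_test - base.sum()
    order = np.argsort(-rem)
    for i in order[:shortfall]:
        base[i] += 1
    # keep both classes represented on both sides where feasible
    for i in range(classes.size):
        if counts[i] >= 2:
            base[i] = min(max(base[i], 1), counts[i] - 1)
        else:
            base[i] = min(base[i], counts[i])
    # re-balance to the quota without violating the feasibility bounds
    while base.sum() > n_test:
        candidates = [i for i in range(classes.size) if base[i] > (1 if counts[i] >= 2 else 0)]
        if not candidates:
            break
        j = max(candidates, key=lambda i: base[i])
        base[j] -= 1
    while base.sum() < n_test:
        candidates = [
            i for i in range(classes.size)
            if base[i] < (counts[i] - 1 if counts[i] >= 2 else counts[i])
        ]
        if not candidates:
            break
        j = max(candidates, key=lambda i: counts[i] - base[i])
        base[j] += 1

    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    positions = np.arange(n)
    for cls, quota in zip(classes, base):
        pos = positions[y == cls]
        chosen = rng.choice(pos, size=int(quota), replace=False)
        test_idx.extend(chosen.tolist())
    test_mask = np.zeros(n, dtype=bool)
    test_mask[test_idx] = True
    return table.iloc[~test_mask].copy(), table.iloc[test_mask].copy()


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve (Mann-Whitney form, ties count 1/2)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("both classes required to compute AUC")
    return float(roc_auc_score(labels, scores))


def max_tss(labels, scores) -> tuple[float, float]:
    """Maximum true skill statistic and its (smallest) optimal threshold.

    Candidate thresholds are every distinct score plus the midpoints
    between consecutive distinct scores; classification is score >= t.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("both classes required to compute TSS")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    candidates = np.sort(np.concatenate([uniq, mids]))
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    best_tss, best_t = -np.inf, candidates[0]
    for t in candidates:
        pred = scores >= t
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        tss = sens + spec - 1.0
        if tss > best_tss + 1e-12:
            best_tss, best_t = tss, t
    return float(best_tss), float(best_t)


def evaluate(
    model,
    test_table: pd.DataFrame,
    split_seed: int = 0,
    test_fraction: float = 0.2,
    label: str = "presence",
) -> EvalReport:
    """Score a fitted model (or ensemble) on held-out rows by AUC and max-TSS."""
    scores = model.predict(test_table)
    labels = np.asarray(test_table[label], dtype=int)
    ok = np.isfinite(scores)
    auc = roc_auc(labels[ok], scores[ok])
    tss, thr = max_tss(labels[ok], scores[ok])
    return EvalReport(
        algorithm=getattr(model, "algorithm", "ensemble"),
        auc=auc,
        tss=tss,
        optimal_threshold=thr,
        split_seed=split_seed,
        test_fraction=test_fraction,
    )
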