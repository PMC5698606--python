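"""Random-forest classification, evaluation and feature selection.

The classifier is a conventional bootstrap random forest voting by
majority, ``H(x) = argmax_Y sum_i I(h_i(x) = Y)``.  Evaluation reports
accuracy, sensitivity and specificity from the binary confusion matrix
with HCC as the positive class.  Feature selection follows two seeded,
cross-validated sweeps: ranking the shape-library nuclei by their
individual discriminative power and growing the library from the top of
the ranking, and ranking boundary landmarks by how often they occur in the
best-performing triangles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FeatureTable",
    "EvalMetrics",
    "VotingEnsemble",
    "train_classifier",
    "evaluate",
    "cross_validate",
    "rank_library_nuclei",
    "grow_library_subset",
    "rank_boundary_points",
    "select_top_landmarks",
    "paper_split",
]

POSITIVE = "HCC"


@dataclass
class FeatureTable:
    """Feature matrix (one row per nucleus) plus class labels."""

    features: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels disagree in length")
        vals = self.features.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("feature table contains non-finite values")

    def subset(self, columns) -> "FeatureTable":
        return FeatureTable(self.features[list(columns)], self.labels)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion counts and derived rates; HCC is the positive class."""

    TP: int
    FN: int
    TN: int
    FP: int
    ACC: float
    SEN: float | None  # None when TP+FN == 0 (undefined, not silently 0)
    SPE: float | None


@dataclass
class VotingEnsemble:
    """Fitted forest exposing both the sklearn prediction and the explicit
    per-tree majority vote (they coincide for fully grown trees, up to
    ties; use an odd tree count to avoid ties)."""

    model: RandomForestClassifier
    columns: tuple[str, ...]

    @property
    def n_trees(self) -> int:
        return len(self.model.estimators_)

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.columns)]
        return np.asarray(X, dtype=float)

    def predict(self, X) -> np.ndarray:
        return self.model.predict(self._matrix(X))

    def tree_votes(self, X) -> np.ndarray:
        """(n_trees, n_samples) matrix of individual tree predictions."""
        Xm = self._matrix(X)
        cls = self.model.classes_
        return np.stack([cls[t.predict(Xm).astype(int)]
                         for t in self.model.estimators_])

    def vote_predict(self, X) -> np.ndarray:
        """Explicit majority vote over the trees (ties go to the class
        listed first in ``classes_``)."""
        votes = self.tree_votes(X)
        cls = self.model.classes_
        counts = np.stack([(votes == c).sum(axis=0) for c in cls])
        return cls[counts.argmax(axis=0)]


def train_classifier(table: FeatureTable, n_trees: int = 500,
                     seed: int = 0) -> VotingEnsemble:
    """Train the bootstrap voting forest (sqrt(d) features per split,
    unlimited depth, deterministic for a given seed)."""
    classes = np.unique(table.labels)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    model = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", bootstrap=True,
        random_state=seed, n_jobs=1,
    )
    model.fit(table.features.to_numpy(dtype=float), table.labels)
    return VotingEnsemble(model=model, columns=tuple(table.features.columns))


def evaluate(predictions, labels, positive: str = POSITIVE) -> EvalMetrics:
    """Confusion counts and ACC/SEN/SPE for binary predictions."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if len(predictions) == 0:
        raise ValueError("empty prediction vector")
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels disagree in length")
    pos = labels == positive
    tp = int(((predictions == positive) & pos).sum())
    fn = int(((predictions != positive) & pos).sum())
    tn = int(((predictions != positive) & ~pos).sum())
    fp = int(((predictions == positive) & ~pos).sum())
    acc = (tp + tn) / (tp + fn + tn + fp)
    sen = tp / (tp + fn) if (tp + fn) else None
    spe = tn / (tn + fp) if (tn + fp) else None
    return EvalMetrics(TP=tp, FN=fn, TN=tn, FP=fp, ACC=acc, SEN=sen, SPE=spe)


def cross_validate(table: FeatureTable, folds: int = 10, repeats: int = 1,
                   seed: int = 0, n_trees: int = 500) -> dict:
    """Stratified k-fold cross-validation of the voting forest.

    Returns mean and standard deviation of ACC/SEN/SPE over all folds
    (and repeats), plus the per-fold metrics.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = pd.Series(table.labels).value_counts()
    if counts.min() < folds:
        raise ValueError("fewer samples in a class than folds")
    per_fold: list[EvalMetrics] = []
    X = table.features
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=seed + 1000 * rep)
        for tr_idx, te_idx in skf.split(X, table.labels):
            sub = FeatureTable(X.iloc[tr_idx], table.labels[tr_idx])
            ens = train_classifier(sub, n_trees=n_trees, seed=seed)
            pred = ens.predict(X.iloc[te_idx])
            per_fold.append(evaluate(pred, table.labels[te_idx]))
    def agg(name):
        vals = [getattr(m, name) for m in per_fold if getattr(m, name) is not None]
        return float(np.mean(vals)), float(np.std(vals))
    out = {"folds": per_fold}
    for name in ("ACC", "SEN", "SPE"):
        out[name], out[name + "_sd"] = agg(name)
    return out


def _single_column_acc(table: FeatureTable, column: str, folds: int,
                       seed: int, n_trees: int) -> float:
    return cross_validate(table.subset([column]), folds=folds, seed=seed,
                          n_trees=n_trees)["ACC"]


def rank_library_nuclei(table: FeatureTable, folds: int = 10, seed: int = 0,
                        n_trees: int = 50) -> pd.DataFrame:
    """Rank shape-library nuclei by their individual discriminative power.

    ``table`` must hold exactly one feature column per library nucleus
    (e.g. the JI features).  Each column is cross-validated on its own;
    columns are returned sorted by ACC descending, ties broken by the
    original column order.  Few trees suffice for single-feature learners.
    """
    cols = list(table.features.columns)
    accs = [_single_column_acc(table, c, folds, seed, n_trees) for c in cols]
    df = pd.DataFrame({"column": cols, "acc": accs,
                       "order": np.arange(len(cols))})
    df = df.sort_values(["acc", "order"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    return df[["column", "acc"]]


def grow_library_subset(ranked: pd.DataFrame, table: FeatureTable,
                        start: int = 30, step: int = 10, folds: int = 10,
                        seed: int = 0, n_trees: int = 200,
                        repeats: int = 1, rule: str = "one_se") -> dict:
    """Grow the library from the top of the ranking and pick the best size.

    Cross-validated ACC is measured with the first ``start, start+step,
    ...`` ranked columns.  ``rule="one_se"`` (default) returns the
    smallest size whose mean ACC is within one standard error of the
    curve's maximum — on the plateaued curves this sweep produces, the
    plain argmax is decided by cross-validation noise, whereas the 1-SE
    rule recovers the compact library the sweep is after.  ``rule="max"``
    returns the argmax (first maximum, i.e. smaller size on exact ties).
    The full ACC curve and the argmax are always returned.
    """
    if rule not in ("one_se", "max"):
        raise ValueError("rule must be 'one_se' or 'max'")
    cols = list(ranked["column"])
    if start > len(cols):
        raise ValueError(f"start={start} exceeds the {len(cols)} ranked ids")
    sizes = list(range(start, len(cols) + 1, step))
    accs, ses = [], []
    for s in sizes:
        res = cross_validate(table.subset(cols[:s]), folds=folds, seed=seed,
                             repeats=repeats, n_trees=n_trees)
        accs.append(res["ACC"])
        ses.append(res["ACC_sd"] / math.sqrt(folds * repeats))
    curve = pd.DataFrame({"size": sizes, "acc": accs, "se": ses})
    i_max = int(curve["acc"].idxmax())  # idxmax: first max
    argmax_size = int(curve.loc[i_max, "size"])
    if rule == "max":
        best = argmax_size
    else:
        # pooled SE: per-size SEs on a plateau are themselves noisy
        thresh = accs[i_max] - float(np.mean(ses))
        best = int(next(s for s, a in zip(sizes, accs) if a >= thresh))
    return {"best_size": best, "argmax_size": argmax_size, "curve": curve,
            "best_columns": cols[:best]}


def _parse_triple(name: str) -> tuple[int, int, int]:
    parts = name.split(".")
    return int(parts[1]), int(parts[2]), int(parts[3])


def rank_boundary_points(table: FeatureTable, k: int = 12, folds: int = 10,
                         seed: int = 0, n_trees: int = 50,
                         top_fraction: float = 0.5) -> dict:
    """Rank boundary landmarks by occurrence in the best triangles.

    Each triangle column (named ``bf.i.j.k``) is cross-validated on its
    own; among the top ``top_fraction`` of triangles by ACC, each vertex
    occurrence is counted, and landmarks are ranked by count (descending,
    ties by landmark id).  Returns the ranking, per-landmark counts and
    the per-triangle ACC table.
    """
    cols = [c for c in table.features.columns if c.startswith("bf.")]
    if not cols:
        raise ValueError("no triangle (bf.*) columns in the table")
    accs = [_single_column_acc(table, c, folds, seed, n_trees) for c in cols]
    tri = pd.DataFrame({"column": cols, "acc": accs,
                        "order": np.arange(len(cols))})
    tri = tri.sort_values(["acc", "order"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)
    n_top = max(1, int(round(top_fraction * len(tri))))
    counts = np.zeros(k, dtype=int)
    for name in tri["column"].head(n_top):
        for v in _parse_triple(name):
            counts[v] += 1
    order = sorted(range(k), key=lambda v: (-counts[v], v))
    return {"ranked_points": order, "counts": counts,
            "triangle_acc": tri[["column", "acc"]]}


def select_top_landmarks(table: FeatureTable, ranked_points: list[int],
                         p: int) -> FeatureTable:
    """Keep the C(p,3) triangle columns whose vertices all lie within the
    top ``p`` ranked landmarks."""
    if p < 3:
        raise ValueError("need at least 3 boundary points")
    keep = set(ranked_points[:p])
    cols = [c for c in table.features.columns
            if c.startswith("bf.") and set(_parse_triple(c)) <= keep]
    expected = math.comb(p, 3)
    if len(cols) != expected:
        raise ValueError(
            f"found {len(cols)} triangle columns for {p} points, "
            f"expected C({p},3) = {expected}"
        )
    return table.subset(cols)


def paper_split(labels, train_per_class: int = 2600,
                test_per_class: int = 2260, seed: int = 0,
                classes: tuple[str, str] = ("normal", POSITIVE)):
    """Seeded balanced train/test split (per-class sampling without
    replacement), reproducing the 2600/2600 train and 2260/2260 test
    bookkeeping at full scale.  Returns (train_idx, test_idx)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in classes:
        pool = np.flatnonzero(labels == cls)
        need = train_per_class + test_per_class
        if len(pool) < need:
            raise ValueError(
                f"class '{cls}' has {len(pool)} samples, needs {need}"
            )
        pick = rng.permutation(pool)[:need]
        train_idx.append(pick[:train_per_class])
        test_idx.append(pick[train_per_class:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))
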