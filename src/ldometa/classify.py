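"""Voting baseline, linear SVM ensemble training with nested CV, and performance metrics.

The meta-classifier is a weighted vote: for a candidate pair c with K-bit call
signature x^c, the raw score is

    raw(c) = sum_i w_i * x_i^c - b

With unit weights and zero offset this is exactly the vote count, so the SVM is
simple voting with weights tuned against the reference labels.  The penalty C
is selected by nested cross-validation with folds grouped by query gene and
stratified by class.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.svm import LinearSVC

from ldometa.pool import GenePair, Label, LabeledPool

#: penalty grid used for model selection: 4^-2 .. 4^2
DEFAULT_C_GRID: tuple[float, ...] = (4.0**-2, 4.0**-1, 4.0**0, 4.0**1, 4.0**2)

SOLVER_TOL = 1e-6


# ---------------------------------------------------------------------------
# model


@dataclass
class LinearModel:
    """Linear decision rule raw(c) = w . x^c - b over call signatures."""

    weights: np.ndarray
    offset: float
    C: float
    species_pair: tuple[str, str] = ("query", "target")
    direction: str = "forward"
    fingerprint: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("weights must be a 1-D vector")

    @property
    def K(self) -> int:
        return len(self.weights)

    def to_json(self, path: str | Path, manifest_names: Sequence[str] | None = None) -> None:
        record = {
            "weights": self.weights.tolist(),
            "offset": self.offset,
            "C": self.C,
            "species_pair": list(self.species_pair),
            "direction": self.direction,
            "fingerprint": self.fingerprint,
        }
        if manifest_names is not None:
            record["manifest"] = list(manifest_names)
        with open(path, "w") as fh:
            json.dump(record, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearModel":
        with open(path) as fh:
            rec = json.load(fh)
        return cls(
            weights=np.array(rec["weights"], dtype=float),
            offset=float(rec["offset"]),
            C=float(rec["C"]),
            species_pair=tuple(rec.get("species_pair", ("query", "target"))),
            direction=rec.get("direction", "forward"),
            fingerprint=rec.get("fingerprint", ""),
        )


def vote_count(signature: Sequence[int] | np.ndarray) -> int:
    """Number of constituent algorithms calling the pair (count of 1-bits)."""
    sig = np.asarray(signature)
    return int(sig.sum())


def raw_score(model: LinearModel, signature: Sequence[int] | np.ndarray) -> float:
    """w . x - b for one signature."""
    sig = np.asarray(signature, dtype=float)
    if sig.shape != model.weights.shape:
        raise ValueError(f"signature length {sig.shape} != model K {model.weights.shape}")
    return float(model.weights @ sig - model.offset)


def raw_scores(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Vectorized raw scores for an n x K signature matrix."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.K:
        raise ValueError(f"matrix has {X.shape[1]} columns, model expects {model.K}")
    return X @ model.weights - model.offset


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X, dtype=np.uint8).tobytes())
    h.update(np.ascontiguousarray(y, dtype=np.int8).tobytes())
    return h.hexdigest()[:16]


def fit_linear_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    seed: int = 0,
    *,
    class_weight: str | None = None,
    tol: float = SOLVER_TOL,
) -> LinearModel:
    """Fit the soft-margin linear SVM (hinge loss, penalty C) on binary signatures.

    Features are left unstandardized: they are 0/1 calls and scaling them would
    break the voting-equivalence identity of the unit-weight model.  No class
    reweighting is applied by default; imbalance is handled upstream by
    stratified fold construction (``class_weight="balanced"`` is available as
    an explicit opt-in).
    """
    X = np.asarray(X)
    y = np.asarray(y).astype(int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different lengths")
    if X.shape[0] < 2:
        raise ValueError("need at least two training examples")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if C <= 0:
        raise ValueError("C must be positive")
    # signatures are K-bit vectors, so training rows repeat heavily; collapsing
    # duplicates into multiplicity weights leaves the hinge objective unchanged
    Xy = np.column_stack([X.astype(np.int64), y])
    uniq, counts = np.unique(Xy, axis=0, return_counts=True)
    Xu, yu = uniq[:, :-1], uniq[:, -1]
    clf = LinearSVC(
        C=C,
        loss="hinge",
        dual=True,
        tol=tol,
        max_iter=100_000,
        random_state=seed,
        class_weight=class_weight,
    )
    clf.fit(Xu, yu, sample_weight=counts.astype(float))
    return LinearModel(
        weights=clf.coef_.ravel().copy(),
        offset=float(-clf.intercept_[0]),
        C=C,
        fingerprint=_fingerprint(X, y),
    )


# ---------------------------------------------------------------------------
# confusion counts and P/R/F


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int | None = None

    def __post_init__(self) -> None:
        if self.TP < 0 or self.FP < 0 or self.FN < 0 or (self.TN is not None and self.TN < 0):
            raise ValueError("confusion counts must be non-negative")


def confusion(predicted: Iterable, reference: Iterable) -> ConfusionCounts:
    """TP/FP/FN of a predicted set against a reference set."""
    pred = set(predicted)
    ref = set(reference)
    return ConfusionCounts(TP=len(pred & ref), FP=len(pred - ref), FN=len(ref - pred))


def precision_recall_f(counts: ConfusionCounts, beta: float = 1.0) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F_beta = (1+beta^2)PR/(beta^2 P + R).

    Empty denominators give 0 (a classifier that predicts nothing has
    precision 0 by convention here, so curves stay well defined).
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    P = counts.TP / (counts.TP + counts.FP) if (counts.TP + counts.FP) else 0.0
    R = counts.TP / (counts.TP + counts.FN) if (counts.TP + counts.FN) else 0.0
    b2 = beta * beta
    F = (1 + b2) * P * R / (b2 * P + R) if (P > 0 or R > 0) else 0.0
    return P, R, F


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """|A n B| / |A u B| — agreement between two algorithms' predicted pair sets."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(union)


def weight_correlation(model_a: LinearModel, model_b: LinearModel) -> float:
    """Pearson correlation between two models' weight vectors."""
    if model_a.K != model_b.K:
        raise ValueError("models have different K")
    wa, wb = model_a.weights, model_b.weights
    if np.std(wa) == 0 or np.std(wb) == 0:
        raise ValueError("Pearson correlation undefined for a constant weight vector")
    return float(stats.pearsonr(wa, wb).statistic)


# ---------------------------------------------------------------------------
# precision-recall curves


def pr_curve(
    scores: Mapping[GenePair, float],
    labels: Mapping[GenePair, bool],
    reference_total: int | None = None,
) -> pd.DataFrame:
    """One point per distinct score threshold T (predicted = score >= T).

    ``reference_total`` is the recall denominator; it defaults to the number of
    positive labels but may be larger when reference pairs exist that no
    algorithm pooled (they are permanent false negatives).
    Returns a DataFrame with columns threshold, precision, recall, f — sorted
    by increasing threshold.
    """
    if not scores:
        raise ValueError("empty score map")
    items = sorted(scores.items(), key=lambda kv: kv[1])
    vals = np.array([v for _, v in items], dtype=float)
    pos = np.array([bool(labels[p]) for p, _ in items])
    n_pos = int(pos.sum())
    total = n_pos if reference_total is None else int(reference_total)
    if total < n_pos:
        raise ValueError("reference_total smaller than the number of positive labels")
    # cumulative counts from the top: at threshold vals[i], predictions are items[i:]
    thresholds, first_idx = np.unique(vals, return_index=True)
    tp_above = np.cumsum(pos[::-1])[::-1]  # tp_above[i] = positives with score >= vals[i]
    n = len(vals)
    rows = []
    for t, i in zip(thresholds, first_idx):
        tp = int(tp_above[i])
        npred = n - i
        fp = npred - tp
        P, R, F = precision_recall_f(ConfusionCounts(TP=tp, FP=fp, FN=total - tp))
        rows.append((float(t), P, R, F))
    return pd.DataFrame(rows, columns=["threshold", "precision", "recall", "f"])


# ---------------------------------------------------------------------------
# fold construction


@dataclass
class FoldPlan:
    """Assignment of labeled pairs to folds 1..n_folds, grouped by gene and stratified by class."""

    assignment: dict[GenePair, int]
    n_folds: int
    seed: int

    def fold_pairs(self, fold: int) -> set[GenePair]:
        return {p for p, f in self.assignment.items() if f == fold}

    def validate(
        self,
        labels: Mapping[GenePair, bool],
        groups: Mapping[GenePair, str],
        rel_tol: float = 0.2,
    ) -> None:
        """Check the fold-plan invariants: exact partition, exact grouping, and
        per-fold positive fractions within ``rel_tol`` relative deviation of the
        global fraction (grouping makes exact stratification impossible)."""
        if set(self.assignment) != set(labels):
            raise ValueError("fold plan does not partition the labeled pairs")
        fold_of_group: dict[str, int] = {}
        for p, f in self.assignment.items():
            g = groups[p]
            if fold_of_group.setdefault(g, f) != f:
                raise ValueError(f"group {g!r} spans folds")
        global_frac = sum(labels.values()) / len(labels)
        for fold in range(1, self.n_folds + 1):
            members = self.fold_pairs(fold)
            if not members:
                raise ValueError(f"fold {fold} is empty")
            frac = sum(labels[p] for p in members) / len(members)
            if abs(frac - global_frac) > rel_tol * global_frac:
                raise ValueError(
                    f"fold {fold} positive fraction {frac:.3f} deviates more than "
                    f"{rel_tol:.0%} from global {global_frac:.3f}"
                )


def _group_key(pair: GenePair, direction: str) -> str:
    if direction == "forward":
        return pair.query
    if direction == "reverse":
        return pair.target
    raise ValueError(f"direction must be 'forward' or 'reverse', got {direction!r}")


def make_folds(
    labeled_pairs: Mapping[GenePair, bool],
    n_folds: int,
    seed: int,
    *,
    direction: str = "forward",
) -> FoldPlan:
    """Grouped, stratified fold assignment.

    All pairs sharing a query gene (target gene for the reverse direction)
    land in one fold, and per-fold class proportions track the global
    proportions as closely as the grouping constraint allows.  Deterministic
    under ``seed``.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    pairs = sorted(labeled_pairs)
    y = np.array([int(labeled_pairs[p]) for p in pairs])
    groups = np.array([_group_key(p, direction) for p in pairs])
    for cls in np.unique(y):
        n_groups_cls = len(np.unique(groups[y == cls]))
        if n_groups_cls < n_folds:
            raise ValueError(
                f"class {cls} spans only {n_groups_cls} distinct genes; "
                f"cannot build {n_folds} folds"
            )
    splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment: dict[GenePair, int] = {}
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((len(pairs), 1)), y, groups), start=1):
        for i in test_idx:
            assignment[pairs[i]] = fold
    return FoldPlan(assignment=assignment, n_folds=n_folds, seed=seed)


# ---------------------------------------------------------------------------
# nested cross-validation


def _training_arrays(
    labeled: LabeledPool, pairs: Sequence[GenePair]
) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([labeled.pool.signatures[p] for p in pairs])
    y = np.array([1 if labeled.labels[p] is Label.KNOWN_LDO else 0 for p in pairs])
    return X, y


def inner_cv_select_C(
    labeled: LabeledPool,
    train_pairs: Sequence[GenePair],
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    n_inner: int = 10,
    seed: int = 0,
    *,
    direction: str = "forward",
) -> tuple[float, dict[float, float]]:
    """Pick C from the grid by mean held-out accuracy over inner folds.

    Ties break toward the smaller C (strongest regularization).
    """
    if not C_grid:
        raise ValueError("empty C grid")
    train_pairs = sorted(train_pairs)
    label_map = {p: labeled.labels[p] is Label.KNOWN_LDO for p in train_pairs}
    plan = make_folds(label_map, n_inner, seed, direction=direction)
    accs: dict[float, list[float]] = {C: [] for C in C_grid}
    for fold in range(1, n_inner + 1):
        test = sorted(plan.fold_pairs(fold))
        train = [p for p in train_pairs if plan.assignment[p] != fold]
        Xtr, ytr = _training_arrays(labeled, train)
        Xte, yte = _training_arrays(labeled, test)
        for C in C_grid:
            model = fit_linear_svm(Xtr, ytr, C, seed=seed)
            pred = (raw_scores(model, Xte) >= 0).astype(int)
            accs[C].append(float(np.mean(pred == yte)))
    mean_acc = {C: float(np.mean(a)) for C, a in accs.items()}
    best = min(mean_acc, key=lambda C: (-mean_acc[C], C))
    return best, mean_acc


@dataclass
class FoldResult:
    fold: int
    C: float
    precision: float
    recall: float
    f: float
    max_f: float
    vote_max_f: float


@dataclass
class CVReport:
    """Per-outer-fold selection and held-out performance, plus out-of-fold raw scores."""

    folds: list[FoldResult]
    oof_scores: dict[GenePair, float]
    oof_votes: dict[GenePair, int]
    direction: str
    seed: int
    n_reference_unpooled: int = 0

    def aggregate(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(f) for f in self.folds]).set_index("fold")
        mean = df.mean(numeric_only=True)
        sem = df.std(numeric_only=True, ddof=1) / np.sqrt(len(df))
        return pd.DataFrame({"mean": mean, "sem": sem})

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame([vars(f) for f in self.folds])
        agg = self.aggregate()
        with open(path, "w") as fh:
            df.to_csv(fh, sep="\t", index=False, float_format="%.6f")
            fh.write("# aggregate (mean, sem across folds)\n")
            agg.to_csv(fh, sep="\t", float_format="%.6f")


def nested_cv(
    labeled: LabeledPool,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    n_outer: int = 10,
    n_inner: int = 10,
    seed: int = 0,
    *,
    direction: str = "forward",
) -> CVReport:
    """Nested cross-validation over the labeled (known LDO / known non-LDO) pairs.

    For each outer fold, C is chosen by an inner CV on the remaining folds, a
    model is refit on that training portion, and held-out raw scores and P/R/F
    are recorded (operating point: raw score >= 0; ``max_f`` is the maximum F
    along the held-out PR curve, with the same quantity for vote counts as the
    baseline).  Unclassified pairs are never trained on.
    """
    labeled_map = {
        p: labeled.labels[p] is Label.KNOWN_LDO
        for p in labeled.pool.signatures
        if labeled.labels[p] is not Label.UNCLASSIFIED
    }
    if not labeled_map:
        raise ValueError("no labeled pairs to cross-validate")
    plan = make_folds(labeled_map, n_outer, seed, direction=direction)
    all_pairs = sorted(labeled_map)
    folds: list[FoldResult] = []
    oof_scores: dict[GenePair, float] = {}
    oof_votes: dict[GenePair, int] = {}
    for fold in range(1, n_outer + 1):
        test = sorted(plan.fold_pairs(fold))
        train = [p for p in all_pairs if plan.assignment[p] != fold]
        C, _ = inner_cv_select_C(
            labeled, train, C_grid, n_inner, seed + fold, direction=direction
        )
        Xtr, ytr = _training_arrays(labeled, train)
        model = fit_linear_svm(Xtr, ytr, C, seed=seed)
        Xte, yte = _training_arrays(labeled, test)
        s = raw_scores(model, Xte)
        score_map = {p: float(v) for p, v in zip(test, s)}
        vote_map = {p: vote_count(labeled.pool.signatures[p]) for p in test}
        label_map = {p: bool(v) for p, v in zip(test, yte)}
        oof_scores.update(score_map)
        oof_votes.update(vote_map)
        pred = {p for p, v in score_map.items() if v >= 0}
        pos = {p for p, v in label_map.items() if v}
        P, R, F = precision_recall_f(confusion(pred, pos))
        curve = pr_curve(score_map, label_map)
        vcurve = pr_curve({p: float(v) for p, v in vote_map.items()}, label_map)
        folds.append(
            FoldResult(
                fold=fold,
                C=C,
                precision=P,
                recall=R,
                f=F,
                max_f=float(curve["f"].max()),
                vote_max_f=float(vcurve["f"].max()),
            )
        )
    return CVReport(
        folds=folds,
        oof_scores=oof_scores,
        oof_votes=oof_votes,
        direction=direction,
        seed=seed,
        n_reference_unpooled=labeled.n_reference_unpooled,
    )
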