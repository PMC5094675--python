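"""F-beta anchored confidence calibration of raw scores onto [0, 1].

Raw SVM decision values (or vote counts) are not comparable across species
pairs, so they are mapped to a common confidence scale that is tied to
classifier performance: the raw threshold maximizing F_beta is pinned to a
fixed confidence for each beta in {0.125, 0.25, 0.5, 1, 2, 4, 8} — the
confidences 0.9375, 0.875, 0.75, 0.5, 0.25, 0.125, 0.0625 respectively, so
that doubling beta halves the remaining distance toward 0 or 1 and the
balanced-F threshold always lands at confidence 0.5.  Between anchors the map
is a monotone cubic Hermite interpolant (Fritsch–Carlson tangents); outside
the observed score range it clamps to 0/1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from ldometa.classify import ConfusionCounts, precision_recall_f
from ldometa.pool import GenePair

#: (beta, confidence) anchor pairs; doubling beta halves the distance to 0/1.
BETA_CONFIDENCE_TABLE: tuple[tuple[float, float], ...] = (
    (0.125, 0.9375),
    (0.25, 0.875),
    (0.5, 0.75),
    (1.0, 0.5),
    (2.0, 0.25),
    (4.0, 0.125),
    (8.0, 0.0625),
)

DEFAULT_BETAS: tuple[float, ...] = tuple(b for b, _ in BETA_CONFIDENCE_TABLE)


def beta_confidence(beta: float, *, extended: bool = False) -> float:
    """Confidence anchor for a given beta.

    In strict mode (default) beta must be one of the seven tabulated values.
    Extended mode evaluates the closed form 1 - beta/2 for beta <= 1 and
    1/(2 beta) for beta >= 1, which reproduces the table exactly.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    for b, conf in BETA_CONFIDENCE_TABLE:
        if beta == b:
            return conf
    if not extended:
        raise ValueError(f"beta {beta} not in the anchor table (pass extended=True for the closed form)")
    return 1.0 - beta / 2.0 if beta <= 1.0 else 1.0 / (2.0 * beta)


# consistency of the closed form with the printed table, checked at import
for _b, _c in BETA_CONFIDENCE_TABLE:
    _cf = 1.0 - _b / 2.0 if _b <= 1.0 else 1.0 / (2.0 * _b)
    assert _cf == _c, f"closed form disagrees with anchor table at beta={_b}"


def _fbeta_by_threshold(
    scores: Mapping[GenePair, float] | Mapping[object, float],
    labels: Mapping,
    reference_total: int | None,
    beta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Distinct thresholds (ascending) and F_beta at each (predicted = score >= T)."""
    items = sorted(scores.items(), key=lambda kv: kv[1])
    vals = np.array([v for _, v in items], dtype=float)
    pos = np.array([bool(labels[k]) for k, _ in items])
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError("no positive labels: F_beta thresholds undefined")
    total = n_pos if reference_total is None else int(reference_total)
    thresholds, first_idx = np.unique(vals, return_index=True)
    tp_above = np.cumsum(pos[::-1])[::-1]
    n = len(vals)
    fbetas = np.empty(len(thresholds))
    for j, i in enumerate(first_idx):
        tp = int(tp_above[i])
        fp = (n - i) - tp
        _, _, f = precision_recall_f(ConfusionCounts(TP=tp, FP=fp, FN=total - tp), beta=beta)
        fbetas[j] = f
    return thresholds, fbetas


def find_fbeta_threshold(
    scores: Mapping,
    labels: Mapping,
    reference_total: int | None,
    beta: float,
) -> float:
    """Raw threshold maximizing F_beta; ties break toward the lower threshold."""
    thresholds, fbetas = _fbeta_by_threshold(scores, labels, reference_total, beta)
    return float(thresholds[int(np.argmax(fbetas))])


@dataclass
class AnchorSet:
    """Strictly increasing (raw threshold, confidence) anchors including 0/1 endpoints."""

    thresholds: np.ndarray
    confidences: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.confidences = np.asarray(self.confidences, dtype=float)
        if len(self.thresholds) != len(self.confidences):
            raise ValueError("threshold/confidence length mismatch")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("anchor thresholds must be strictly increasing")
        if np.any(np.diff(self.confidences) <= 0):
            raise ValueError("anchor confidences must be strictly increasing")


def build_anchor_set(
    scores: Mapping,
    labels: Mapping,
    reference_total: int | None = None,
    betas: Sequence[float] = DEFAULT_BETAS,
) -> AnchorSet:
    """Locate the F_beta-maximizing threshold for each beta and pin its confidence.

    Degeneracies (common for heavily tied scores such as vote counts) are
    resolved by collapsing anchors that share a threshold to the mean of their
    confidences, then scanning outward from the beta=1 anchor and dropping any
    anchor that breaks strict joint monotonicity.  Endpoints (min observed raw
    score -> 0, max -> 1) are appended, nudged outward if they collide with a
    surviving anchor.
    """
    raw_anchors: list[tuple[float, float]] = []
    for beta in betas:
        t = find_fbeta_threshold(scores, labels, reference_total, beta)
        raw_anchors.append((t, beta_confidence(beta, extended=True)))
    # collapse identical thresholds to the mean confidence
    by_t: dict[float, list[float]] = {}
    for t, conf in raw_anchors:
        by_t.setdefault(t, []).append(conf)
    collapsed = sorted((t, float(np.mean(confs))) for t, confs in by_t.items())
    # scan outward from the anchor nearest confidence 0.5 (the beta=1 anchor,
    # possibly absorbed into a collapsed one)
    pivot = int(np.argmin([abs(c - 0.5) for _, c in collapsed]))
    kept = [collapsed[pivot]]
    for t, c in collapsed[pivot + 1 :]:
        if c > kept[-1][1]:
            kept.append((t, c))
    lower: list[tuple[float, float]] = []
    head = collapsed[pivot][1]
    for t, c in reversed(collapsed[:pivot]):
        if c < head:
            lower.append((t, c))
            head = c
    anchors = list(reversed(lower)) + kept
    if len(anchors) < 2:
        raise ValueError("fewer than two surviving anchors; cannot calibrate")
    vals = np.array([v for v in dict(scores).values()], dtype=float)
    lo, hi = float(vals.min()), float(vals.max())
    span = max(hi - lo, 1.0)
    eps = np.finfo(float).eps * 64 * span
    if lo >= anchors[0][0]:
        lo = anchors[0][0] - eps
    if hi <= anchors[-1][0]:
        hi = anchors[-1][0] + eps
    full = [(lo, 0.0)] + anchors + [(hi, 1.0)]
    ts = np.array([t for t, _ in full])
    cs = np.array([c for _, c in full])
    return AnchorSet(thresholds=ts, confidences=cs)


@dataclass
class ScoreScaler:
    """Monotone map raw score -> [0, 1] confidence through the anchor set."""

    anchors: AnchorSet
    method: str = "fritsch-carlson"

    def __post_init__(self) -> None:
        self._interp = PchipInterpolator(self.anchors.thresholds, self.anchors.confidences)

    def scale(self, raw: float | np.ndarray) -> float | np.ndarray:
        raw_arr = np.asarray(raw, dtype=float)
        out = np.clip(self._interp(raw_arr), 0.0, 1.0)
        out = np.where(raw_arr <= self.anchors.thresholds[0], 0.0, out)
        out = np.where(raw_arr >= self.anchors.thresholds[-1], 1.0, out)
        if np.isscalar(raw) or raw_arr.ndim == 0:
            return float(out)
        return out

    def __call__(self, raw: float | np.ndarray) -> float | np.ndarray:
        return self.scale(raw)

    def to_json(self, path: str | Path) -> None:
        rec = {
            "anchors": [
                [float(t), float(c)]
                for t, c in zip(self.anchors.thresholds, self.anchors.confidences)
            ],
            "method": self.method,
            "clamp": True,
        }
        with open(path, "w") as fh:
            json.dump(rec, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoreScaler":
        with open(path) as fh:
            rec = json.load(fh)
        ts = np.array([a[0] for a in rec["anchors"]])
        cs = np.array([a[1] for a in rec["anchors"]])
        return cls(anchors=AnchorSet(thresholds=ts, confidences=cs), method=rec.get("method", "fritsch-carlson"))


def fit_scaler(anchors: AnchorSet) -> ScoreScaler:
    """Monotone cubic Hermite interpolant through the anchors, clamped to [0, 1]."""
    return ScoreScaler(anchors=anchors)


def calibrate_scores(
    scores: Mapping,
    labels: Mapping,
    reference_total: int | None = None,
    betas: Sequence[float] = DEFAULT_BETAS,
) -> ScoreScaler:
    """Convenience: build anchors from a labeled score set and fit the scaler."""
    return fit_scaler(build_anchor_set(scores, labels, reference_total, betas))


def harmonize(score_forward: float, score_reverse: float) -> float:
    """Average the scaled confidences of the two directed models for one pair."""
    for s in (score_forward, score_reverse):
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"scaled score {s} outside [0, 1]")
    return 0.5 * (score_forward + score_reverse)
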