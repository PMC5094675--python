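"""End-to-end training and scoring: nested CV, calibration, bidirectional averaging.

`train_meta` runs, for each direction (folds grouped by query gene, then by
target gene), a nested cross-validation over the labeled pairs, refits a
production model on all labeled data with C selected by one full CV, and
calibrates a score scaler on the *out-of-fold* raw scores so that calibration
never sees a score produced by a model trained on the same pair.  A vote-count
scaler is calibrated the same way.  `score_pool` applies both directed models
to every pooled pair, scales, and averages the two directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ldometa.classify import (
    DEFAULT_C_GRID,
    CVReport,
    LinearModel,
    fit_linear_svm,
    inner_cv_select_C,
    nested_cv,
    raw_scores,
    vote_count,
)
from ldometa.pool import CandidatePool, Label, LabeledPool, ReferenceLDOSet, label_pool
from ldometa.scaling import ScoreScaler, build_anchor_set, fit_scaler, harmonize
from ldometa.selection import ScoredPool

DIRECTIONS = ("forward", "reverse")


@dataclass
class TrainedMeta:
    """Directed models, their calibrated scalers, the vote scaler, and CV reports."""

    models: dict[str, LinearModel]
    scalers: dict[str, ScoreScaler]
    vote_scaler: ScoreScaler
    reports: dict[str, CVReport]
    labeled: LabeledPool

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for d in DIRECTIONS:
            self.models[d].to_json(out / f"model_{d}.json", self.labeled.pool.manifest.names)
            self.scalers[d].to_json(out / f"scaler_{d}.json")
            self.reports[d].to_tsv(out / f"cv_report_{d}.tsv")
        self.vote_scaler.to_json(out / "scaler_vote.json")


def _oof_label_map(labeled: LabeledPool) -> dict:
    return {
        p: labeled.labels[p] is Label.KNOWN_LDO
        for p in labeled.pool.signatures
        if labeled.labels[p] is not Label.UNCLASSIFIED
    }


def train_meta(
    pool: CandidatePool,
    reference: ReferenceLDOSet,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    n_outer: int = 10,
    n_inner: int = 10,
    seed: int = 0,
) -> TrainedMeta:
    """Nested-CV training of both directed models plus out-of-fold calibration."""
    labeled = label_pool(pool, reference)
    label_map = _oof_label_map(labeled)
    # reference pairs no algorithm pooled stay in the recall denominator
    reference_total = sum(label_map.values()) + labeled.n_reference_unpooled
    models: dict[str, LinearModel] = {}
    scalers: dict[str, ScoreScaler] = {}
    reports: dict[str, CVReport] = {}
    vote_scaler: ScoreScaler | None = None
    for direction in DIRECTIONS:
        report = nested_cv(
            labeled, C_grid, n_outer, n_inner, seed, direction=direction
        )
        reports[direction] = report
        scalers[direction] = fit_scaler(
            build_anchor_set(report.oof_scores, label_map, reference_total)
        )
        if vote_scaler is None:
            vote_map = {p: float(v) for p, v in report.oof_votes.items()}
            vote_scaler = fit_scaler(
                build_anchor_set(vote_map, label_map, reference_total)
            )
        # production model: C by one full CV on all labeled data, refit on all
        all_pairs = sorted(label_map)
        C, _ = inner_cv_select_C(
            labeled, all_pairs, C_grid, n_inner, seed, direction=direction
        )
        X = np.vstack([pool.signatures[p] for p in all_pairs])
        y = np.array([int(label_map[p]) for p in all_pairs])
        model = fit_linear_svm(X, y, C, seed=seed)
        model.direction = direction
        model.species_pair = pool.species_pair
        models[direction] = model
    assert vote_scaler is not None
    return TrainedMeta(
        models=models,
        scalers=scalers,
        vote_scaler=vote_scaler,
        reports=reports,
        labeled=labeled,
    )


def score_pool(trained: TrainedMeta, pool: CandidatePool | None = None) -> ScoredPool:
    """Harmonized confidence for every pooled pair (mean of the two directed scaled scores)."""
    if pool is None:
        pool = trained.labeled.pool
    pairs, X = pool.signature_matrix()
    scaled = {}
    for d in DIRECTIONS:
        scaled[d] = trained.scalers[d].scale(raw_scores(trained.models[d], X))
    scores = {
        p: harmonize(float(scaled["forward"][i]), float(scaled["reverse"][i]))
        for i, p in enumerate(pairs)
    }
    return ScoredPool(pool=pool, scores=scores)


def vote_scores(trained: TrainedMeta, pool: CandidatePool | None = None) -> dict:
    """Calibrated vote confidence per pooled pair (direction-free by construction)."""
    if pool is None:
        pool = trained.labeled.pool
    return {
        p: float(trained.vote_scaler.scale(float(vote_count(sig))))
        for p, sig in pool.signatures.items()
    }
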