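"""Turning calibrated confidences into LDO call sets.

Thresholding (score >= 0.5 by default), per-query best hits, reciprocal best
hits (RBHs), multiple-mapping statistics, and reference-overlap summaries.
An RBH is a pair scoring at least 0.5 in which each gene attains the maximal
confidence among the other gene's partners; exact ties admit all tied pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ldometa.pool import CandidatePool, GenePair, ReferenceLDOSet

#: confidences are compared after rounding to this many decimals, so that ties
#: arising from identical call signatures are exact while float noise cannot
#: create or destroy a tie
SCORE_DECIMALS = 6


@dataclass
class ScoredPool:
    """A candidate pool with one harmonized confidence in [0, 1] per pair."""

    pool: CandidatePool
    scores: dict[GenePair, float]

    def __post_init__(self) -> None:
        if set(self.scores) != self.pool.pairs:
            raise ValueError("every pooled pair must be scored exactly once")
        for p, s in self.scores.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"score {s} for {p} outside [0, 1]")

    def rounded(self, pair: GenePair) -> float:
        return round(self.scores[pair], SCORE_DECIMALS)


def select_ldos(scored: ScoredPool, threshold: float = 0.5) -> set[GenePair]:
    """All pairs with confidence >= threshold (inclusive boundary)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    return {p for p, s in scored.scores.items() if s >= threshold}


def _max_by_gene(scored: ScoredPool, side: str) -> dict[str, float]:
    best: dict[str, float] = {}
    for p in scored.pool.signatures:
        g = p.query if side == "q" else p.target
        s = scored.rounded(p)
        if g not in best or s > best[g]:
            best[g] = s
    return best


def best_hits(scored: ScoredPool) -> set[GenePair]:
    """Keep, for each query gene, its maximal-confidence partner(s) (ties kept)."""
    best_q = _max_by_gene(scored, "q")
    return {p for p in scored.pool.signatures if scored.rounded(p) == best_q[p.query]}


def extract_rbh(scored: ScoredPool) -> set[GenePair]:
    """Reciprocal best hits: confidence >= 0.5 and mutually maximal scores.

    When several partners of a gene share the exact maximal confidence, all
    qualifying pairs are retained rather than arbitrarily picking one.
    """
    best_q = _max_by_gene(scored, "q")
    best_t = _max_by_gene(scored, "t")
    out: set[GenePair] = set()
    for p in scored.pool.signatures:
        s = scored.rounded(p)
        if s >= 0.5 and s == best_q[p.query] and s == best_t[p.target]:
            out.add(p)
    return out


def multiple_mapping_counts(
    scored: ScoredPool, thresholds: Sequence[float]
) -> list[int]:
    """Per threshold, the number of query genes with more than one surviving prediction."""
    counts = []
    for t in thresholds:
        surviving = select_ldos(scored, t)
        deg: dict[str, int] = {}
        for p in surviving:
            deg[p.query] = deg.get(p.query, 0) + 1
        counts.append(sum(1 for d in deg.values() if d > 1))
    return counts


@dataclass(frozen=True)
class OverlapRecord:
    n_both: int
    n_predicted_only: int
    n_reference_only: int
    pct_represented: float
    pct_expansion: float


def reference_overlap(
    predictions: Iterable[GenePair], reference: ReferenceLDOSet
) -> OverlapRecord:
    """How a prediction set covers and expands the reference LDO set.

    pct_represented = |pred n ref| / |ref|; pct_expansion = |pred - ref| / |ref|
    (both as percentages).
    """
    ref = reference.pairs
    if not ref:
        raise ValueError("empty reference set")
    pred = set(predictions)
    both = len(pred & ref)
    pred_only = len(pred - ref)
    ref_only = len(ref - pred)
    return OverlapRecord(
        n_both=both,
        n_predicted_only=pred_only,
        n_reference_only=ref_only,
        pct_represented=100.0 * both / len(ref),
        pct_expansion=100.0 * pred_only / len(ref),
    )


def write_scored_tsv(
    scored: ScoredPool,
    path: str | Path,
    *,
    vote_scores: Mapping[GenePair, float] | None = None,
    labels: Mapping[GenePair, object] | None = None,
) -> None:
    """Scored pairs sorted by confidence descending (then lexicographically)."""
    rbhs = extract_rbh(scored)
    rows = sorted(scored.pool.signatures, key=lambda p: (-scored.rounded(p), p))
    with open(path, "w") as fh:
        fh.write("#query\ttarget\tsignature\tscore\tvote_score\tis_rbh\tlabel\n")
        for p in rows:
            vs = f"{vote_scores[p]:.6f}" if vote_scores is not None else "NA"
            lab = str(getattr(labels[p], "value", labels[p])) if labels is not None else "NA"
            fh.write(
                f"{p.query}\t{p.target}\t{scored.pool.signature_string(p)}\t"
                f"{scored.rounded(p):.6f}\t{vs}\t{int(p in rbhs)}\t{lab}\n"
            )
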