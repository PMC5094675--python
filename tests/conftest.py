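import warnings

import numpy as np
import pytest
from sklearn.exceptions import ConvergenceWarning

import ldometa as lm

warnings.filterwarnings("ignore", category=ConvergenceWarning)


@pytest.fixture(scope="session")
def small_sim():
    """A small heterogeneous-17 draw shared by slower integration tests."""
    cfg = lm.heterogeneous17_config(seed=7, n_query_genes=700, n_target_genes=700)
    pool, reference, truth = lm.simulate(cfg)
    return cfg, pool, reference, truth


@pytest.fixture(scope="session")
def trained_small(small_sim):
    cfg, pool, reference, _ = small_sim
    return lm.train_meta(pool, reference, n_outer=5, n_inner=5, seed=7)


def random_scored_pool(rng: np.random.Generator, n_pairs: int = 60, tie_prob: float = 0.4):
    """A random scored pool with deliberate exact score ties (for RBH oracles)."""
    # grid must comfortably exceed n_pairs so distinct pairs can be drawn
    n_q = max(3, -(-n_pairs // 2))
    n_t = max(3, -(-n_pairs // 2))
    manifest = lm.AlgorithmManifest(names=("A",))
    seen = set()
    sigs = {}
    scores = {}
    score_levels = np.round(rng.random(8), 6)
    while len(sigs) < n_pairs:
        p = lm.GenePair(f"q{rng.integers(n_q)}", f"t{rng.integers(n_t)}")
        if p in seen:
            continue
        seen.add(p)
        sigs[p] = np.array([1], dtype=np.uint8)
        if rng.random() < tie_prob:
            scores[p] = float(score_levels[rng.integers(len(score_levels))])
        else:
            scores[p] = float(np.round(rng.random(), 6))
    pool = lm.CandidatePool(species_pair=("q", "t"), manifest=manifest, signatures=sigs)
    return lm.ScoredPool(pool=pool, scores=scores)


def brute_force_rbh(scored) -> set:
    """Independent RBH oracle: double maximum scan with the exact-tie clause."""
    pairs = list(scored.pool.signatures)
    by_query: dict[str, list] = {}
    by_target: dict[str, list] = {}
    for o in pairs:
        by_query.setdefault(o.query, []).append(round(scored.scores[o], 6))
        by_target.setdefault(o.target, []).append(round(scored.scores[o], 6))
    out = set()
    for p in pairs:
        s = round(scored.scores[p], 6)
        if s < 0.5:
            continue
        if s == max(by_query[p.query]) and s == max(by_target[p.target]):
            out.add(p)
    return out
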