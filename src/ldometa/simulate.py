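"""Generative benchmark: synthetic candidate pools with planted LDO truth.

The generator emulates the statistical regime the meta-predictor assumes:

* cross-species gene families, each with at most one true LDO pair and a halo
  of within-family paralog pairs;
* K constituent algorithms of heterogeneous reliability — algorithm k calls a
  candidate pair with probability logistic(a_k + b_k * I[true LDO] +
  paralog_boost * I[same-family non-LDO] + z_pair), where z_pair ~ N(0,
  latent_sd^2) is shared across algorithms and induces inter-algorithm
  correlation;
* a conservative, incomplete reference: only a fraction of true LDOs enter the
  reference set, and a small fraction of its entries are swapped to a
  same-family non-LDO partner.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from ldometa.pool import (
    AlgorithmManifest,
    CandidatePool,
    GenePair,
    ReferenceLDOSet,
)

TRUE_LDO = "TRUE_LDO"
FAMILY_NON_LDO = "FAMILY_NON_LDO"
BACKGROUND = "BACKGROUND"


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class SimConfig:
    """Parameters of the generative model; see the module docstring."""

    n_query_genes: int = 3000
    n_target_genes: int = 3000
    #: family-size distribution (per species side): size -> probability
    family_size_distribution: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.60, 2: 0.25, 3: 0.10, 4: 0.05}
    )
    frac_families_with_true_ldo: float = 0.9
    K: int = 17
    #: baseline log-odds of calling any candidate pair, one per algorithm
    a: tuple[float, ...] = ()
    #: extra log-odds for the true LDO pair, one per algorithm
    b: tuple[float, ...] = ()
    #: extra log-odds for same-family non-LDO pairs (all algorithms)
    paralog_boost: float = 2.0
    #: std-dev of the pair-level latent shared across algorithms
    latent_sd: float = 1.0
    #: expected background (cross-family) pairs as a multiple of family count
    background_rate: float = 0.5
    #: fraction of true LDOs included in the reference
    reference_recall: float = 0.8
    #: fraction of reference entries swapped to a same-family non-LDO
    reference_fpr: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.array(list(self.family_size_distribution.values()), dtype=float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("family_size_distribution probabilities must be >= 0 and sum to 1")
        if any(s < 1 for s in self.family_size_distribution):
            raise ValueError("family sizes must be >= 1")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not self.a:
            self.a = tuple(float(v) for v in np.linspace(-6.9, -3.0, self.K))
        if not self.b:
            # reliabilities spanning true-LDO recall ~0.3..0.95
            targets = np.linspace(np.log(0.3 / 0.7), np.log(0.95 / 0.05), self.K)
            self.b = tuple(float(v) for v in targets - np.asarray(self.a))
        if len(self.a) != self.K or len(self.b) != self.K:
            raise ValueError("a and b must have length K")
        for name, v in (
            ("frac_families_with_true_ldo", self.frac_families_with_true_ldo),
            ("reference_recall", self.reference_recall),
            ("reference_fpr", self.reference_fpr),
        ):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.latent_sd < 0:
            raise ValueError("latent_sd must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "seed" not in doc:
            raise ValueError("simulation config must state a seed")
        if "family_size_distribution" in doc:
            doc["family_size_distribution"] = {
                int(k): float(v) for k, v in doc["family_size_distribution"].items()
            }
        for key in ("a", "b"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(float(v) for v in doc[key])
        return cls(**doc)

    def manifest(self) -> AlgorithmManifest:
        return AlgorithmManifest(names=tuple(f"alg{k+1:02d}" for k in range(self.K)))


@dataclass
class SimTruth:
    """Planted ground truth of one simulation."""

    family_of_gene: dict[tuple[str, str], int]  # (side 'q'/'t', gene) -> family id
    ldo_map: dict[str, str]  # query gene -> target gene of true LDO pairs
    pair_class: dict[GenePair, str]  # candidate pair -> TRUE_LDO / FAMILY_NON_LDO / BACKGROUND

    @property
    def true_ldo_pairs(self) -> set[GenePair]:
        return {GenePair(q, t) for q, t in self.ldo_map.items()}


def heterogeneous17_config(seed: int = 0, **overrides) -> SimConfig:
    """The default benchmark regime: K = 17 algorithms of widely varying reliability.

    Baseline call rates span roughly 0.001–0.05 of candidates, true-LDO recall
    spans roughly 0.3–0.95, a shared latent (sd 1.0) correlates the calls, and
    the reference covers 80% of planted LDOs with a 2% contamination rate.
    A fixed interleaving decouples each algorithm's baseline rate from its
    reliability so that weight recovery is not confounded with call volume.
    """
    K = 17
    a = np.linspace(np.log(0.001 / 0.999), np.log(0.05 / 0.95), K)
    targets = np.linspace(np.log(0.3 / 0.7), np.log(0.95 / 0.05), K)
    # deterministic interleave: reliabilities are not aligned with baselines
    order = np.argsort([(i * 7) % K for i in range(K)])
    b = targets[order] - a
    cfg = SimConfig(
        K=K, a=tuple(float(v) for v in a), b=tuple(float(v) for v in b), seed=seed
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def simulate(config: SimConfig) -> tuple[CandidatePool, ReferenceLDOSet, SimTruth]:
    """Draw a candidate pool, an (incomplete, slightly noisy) reference, and the truth."""
    rng = np.random.default_rng(config.seed)
    sizes = np.array(sorted(config.family_size_distribution), dtype=int)
    probs = np.array([config.family_size_distribution[int(s)] for s in sizes])

    # build families until either gene budget runs out
    fam_q: list[list[str]] = []
    fam_t: list[list[str]] = []
    q_used = t_used = 0
    fam = 0
    while q_used < config.n_query_genes and t_used < config.n_target_genes:
        sq = int(min(rng.choice(sizes, p=probs), config.n_query_genes - q_used))
        st = int(min(rng.choice(sizes, p=probs), config.n_target_genes - t_used))
        fam_q.append([f"q{q_used + i:06d}" for i in range(sq)])
        fam_t.append([f"t{t_used + i:06d}" for i in range(st)])
        q_used += sq
        t_used += st
        fam += 1
    n_fam = fam

    family_of_gene: dict[tuple[str, str], int] = {}
    for f in range(n_fam):
        for g in fam_q[f]:
            family_of_gene[("q", g)] = f
        for g in fam_t[f]:
            family_of_gene[("t", g)] = f

    ldo_map: dict[str, str] = {}
    pair_class: dict[GenePair, str] = {}
    for f in range(n_fam):
        qs, ts = fam_q[f], fam_t[f]
        has_ldo = qs and ts and rng.random() < config.frac_families_with_true_ldo
        if has_ldo:
            lq = qs[int(rng.integers(len(qs)))]
            lt = ts[int(rng.integers(len(ts)))]
            ldo_map[lq] = lt
        for q in qs:
            for t in ts:
                pair = GenePair(q, t)
                if has_ldo and q == lq and t == lt:
                    pair_class[pair] = TRUE_LDO
                else:
                    pair_class[pair] = FAMILY_NON_LDO

    # Poisson background pairs across families
    n_bg = int(rng.poisson(config.background_rate * n_fam))
    all_q = [g for f in fam_q for g in f]
    all_t = [g for f in fam_t for g in f]
    for _ in range(n_bg):
        q = all_q[int(rng.integers(len(all_q)))]
        t = all_t[int(rng.integers(len(all_t)))]
        pair = GenePair(q, t)
        if pair in pair_class:
            continue
        if family_of_gene[("q", q)] == family_of_gene[("t", t)]:
            continue
        pair_class[pair] = BACKGROUND

    # per-algorithm calls with a shared pair-level latent
    pairs = sorted(pair_class)
    n = len(pairs)
    a = np.asarray(config.a)
    b = np.asarray(config.b)
    is_ldo = np.array([pair_class[p] == TRUE_LDO for p in pairs])
    is_fam = np.array([pair_class[p] == FAMILY_NON_LDO for p in pairs])
    z = rng.normal(0.0, config.latent_sd, size=n) if config.latent_sd > 0 else np.zeros(n)
    logits = (
        a[None, :]
        + b[None, :] * is_ldo[:, None]
        + config.paralog_boost * is_fam[:, None]
        + z[:, None]
    )
    calls = (rng.random(size=(n, config.K)) < _logistic(logits)).astype(np.uint8)
    keep = calls.any(axis=1)
    signatures = {p: calls[i] for i, p in enumerate(pairs) if keep[i]}
    if not signatures:
        raise ValueError("simulation produced an empty pool; raise call rates")
    pool = CandidatePool(
        species_pair=("simq", "simt"), manifest=config.manifest(), signatures=signatures
    )

    # conservative reference: subset of true LDOs, some swapped within family
    true_pairs = sorted(GenePair(q, t) for q, t in ldo_map.items())
    n_ref = int(round(config.reference_recall * len(true_pairs)))
    ref_idx = rng.choice(len(true_pairs), size=n_ref, replace=False) if true_pairs else []
    ref_pairs: set[GenePair] = set()
    for i in sorted(ref_idx):
        p = true_pairs[i]
        if rng.random() < config.reference_fpr:
            f = family_of_gene[("t", p.target)]
            others = [t for t in fam_t[f] if t != p.target]
            if others:
                p = GenePair(p.query, others[int(rng.integers(len(others)))])
        ref_pairs.add(p)
    reference = ReferenceLDOSet(pairs=ref_pairs)
    truth = SimTruth(family_of_gene=family_of_gene, ldo_map=ldo_map, pair_class=pair_class)
    return pool, reference, truth


def truth_performance(pool: CandidatePool, truth: SimTruth) -> "np.ndarray":
    """Per-algorithm precision/recall against the planted TRUE_LDO pairs.

    Returns a structured array with fields name, precision, recall; the recall
    denominator is all planted LDO pairs, pooled or not.
    """
    import pandas as pd

    true_pairs = truth.true_ldo_pairs
    rows = []
    for name in pool.manifest.names:
        pred = pool.algorithm_pairs(name)
        tp = len(pred & true_pairs)
        prec = tp / len(pred) if pred else 0.0
        rec = tp / len(true_pairs) if true_pairs else 0.0
        rows.append((name, prec, rec))
    return pd.DataFrame(rows, columns=["name", "precision", "recall"])


def write_simulation(
    config: SimConfig, out_dir: str | Path
) -> tuple[CandidatePool, ReferenceLDOSet, SimTruth]:
    """Run `simulate` and write per-algorithm TSVs, reference, truth, and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pool, reference, truth = simulate(config)
    manifest = pool.manifest
    entries = []
    for name in manifest.names:
        path = out / f"{name}.tsv"
        with open(path, "w") as fh:
            for p in sorted(pool.algorithm_pairs(name)):
                fh.write(f"{p.query}\t{p.target}\n")
        entries.append({"name": name, "path": str(path.name)})
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)
    with open(out / "reference.tsv", "w") as fh:
        for p in sorted(reference.pairs):
            fh.write(f"{p.query}\t{p.target}\n")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("#query\ttarget\tclass\n")
        for p in sorted(truth.pair_class):
            fh.write(f"{p.query}\t{p.target}\t{truth.pair_class[p]}\n")
    return pool, reference, truth
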