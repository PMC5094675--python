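"""Candidate ortholog pools: data model, TSV I/O, call signatures, reference labeling.

A *candidate LDO* (cLDO) is any gene pair predicted orthologous by at least one
constituent algorithm.  Each pooled pair carries a K-bit call signature whose
i-th bit records whether algorithm i called the pair.  Against a one-to-one
reference LDO set, every pooled pair falls into exactly one of three classes:
a known LDO (the pair is in the reference), a known non-LDO (at least one gene
has a *different* reference partner), or unclassified (neither gene occurs in
the reference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

logger = logging.getLogger(__name__)


class PairListParseError(ValueError):
    """A pair-list line could not be parsed."""


@dataclass(frozen=True, order=True)
class GenePair:
    """A (query gene, target gene) pair within a declared species pair.

    Identifiers are opaque, case-sensitive strings; no ID mapping is applied.
    """

    query: str
    target: str

    def __post_init__(self) -> None:
        if not self.query or not self.target:
            raise ValueError(f"gene identifiers must be non-empty: {self!r}")

    def swapped(self) -> "GenePair":
        return GenePair(self.target, self.query)


@dataclass(frozen=True)
class AlgorithmManifest:
    """Ordered list of unique constituent-algorithm names; order fixes signature bit positions."""

    names: tuple[str, ...]
    metadata: Mapping[str, Mapping[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if not names:
            raise ValueError("manifest must name at least one algorithm")
        if any(not n for n in names):
            raise ValueError("algorithm names must be non-empty")
        if len(set(names)) != len(names):
            raise ValueError("algorithm names must be unique")

    @property
    def K(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"algorithm {name!r} not in manifest") from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AlgorithmManifest":
        """Load a manifest file.

        Accepted layouts: a plain list of names; a list of ``{name: ..., ...}``
        records; or a mapping with a top-level ``sources`` list in which each
        source may expand to several datasets (``datasets: [a, b]``), the way a
        single project can ship multiple ortholog categories.
        """
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        names: list[str] = []
        meta: dict[str, dict[str, str]] = {}
        if isinstance(doc, dict) and "sources" in doc:
            entries = doc["sources"]
            for src in entries:
                datasets = src.get("datasets") or [src["name"]]
                for ds in datasets:
                    names.append(str(ds))
                    meta[str(ds)] = {
                        k: str(v) for k, v in src.items() if k not in ("datasets",)
                    }
        elif isinstance(doc, list):
            for item in doc:
                if isinstance(item, str):
                    names.append(item)
                else:
                    names.append(str(item["name"]))
                    meta[str(item["name"])] = {
                        k: str(v) for k, v in item.items() if k != "name"
                    }
        else:
            raise ValueError(f"unrecognized manifest layout in {path}")
        return cls(names=tuple(names), metadata=meta)


@dataclass
class CandidatePool:
    """Union of all constituent predictions for one species pair, with call signatures."""

    species_pair: tuple[str, str]
    manifest: AlgorithmManifest
    signatures: dict[GenePair, np.ndarray]

    def __post_init__(self) -> None:
        K = self.manifest.K
        for pair, sig in self.signatures.items():
            sig = np.asarray(sig, dtype=np.uint8)
            if sig.shape != (K,):
                raise ValueError(f"signature length {sig.shape} != K={K} for {pair}")
            if not sig.any():
                raise ValueError(f"pooled pair {pair} has an all-zero signature")
            self.signatures[pair] = sig

    def __len__(self) -> int:
        return len(self.signatures)

    def __contains__(self, pair: GenePair) -> bool:
        return pair in self.signatures

    @property
    def pairs(self) -> set[GenePair]:
        return set(self.signatures)

    def sorted_pairs(self) -> list[GenePair]:
        """Pairs in deterministic lexicographic order."""
        return sorted(self.signatures)

    def signature_matrix(self) -> tuple[list[GenePair], np.ndarray]:
        """Pairs (sorted) and the corresponding n x K 0/1 matrix."""
        pairs = self.sorted_pairs()
        X = np.vstack([self.signatures[p] for p in pairs]) if pairs else np.empty((0, self.manifest.K), np.uint8)
        return pairs, X

    def algorithm_pairs(self, name: str) -> set[GenePair]:
        """Recover the pair set called by one constituent algorithm."""
        i = self.manifest.index(name)
        return {p for p, s in self.signatures.items() if s[i]}

    def signature_string(self, pair: GenePair) -> str:
        return "".join(str(int(b)) for b in self.signatures[pair])


@dataclass
class ReferenceLDOSet:
    """One-to-one reference LDO mapping (each gene occurs in at most one pair)."""

    pairs: set[GenePair]

    def __post_init__(self) -> None:
        self.pairs = set(self.pairs)
        self.validate()

    def validate(self) -> None:
        seen_q: set[str] = set()
        seen_t: set[str] = set()
        for p in self.pairs:
            if p.query in seen_q:
                raise ValueError(f"reference is not one-to-one: query gene {p.query!r} repeated")
            if p.target in seen_t:
                raise ValueError(f"reference is not one-to-one: target gene {p.target!r} repeated")
            seen_q.add(p.query)
            seen_t.add(p.target)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def query_partner(self) -> dict[str, str]:
        return {p.query: p.target for p in self.pairs}

    @property
    def target_partner(self) -> dict[str, str]:
        return {p.target: p.query for p in self.pairs}


def packaged_manifest() -> AlgorithmManifest:
    """The manifest of constituent ortholog datasets shipped with the package.

    13 public data sources expand to 17 constituent datasets (some sources ship
    several ortholog categories, each used as an independent signature bit).
    """
    return AlgorithmManifest.from_yaml(
        Path(__file__).parent / "data" / "constituent_manifest.yaml"
    )


class Label(Enum):
    KNOWN_LDO = "KNOWN_LDO"
    KNOWN_NON_LDO = "KNOWN_NON_LDO"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class LabeledPool:
    """A candidate pool with a three-class reference label per pair."""

    pool: CandidatePool
    labels: dict[GenePair, Label]
    reference: ReferenceLDOSet

    def __post_init__(self) -> None:
        if set(self.labels) != self.pool.pairs:
            raise ValueError("labels must cover exactly the pooled pairs")

    def pairs_with_label(self, label: Label) -> set[GenePair]:
        return {p for p, l in self.labels.items() if l is label}

    @property
    def n_reference_unpooled(self) -> int:
        """Reference pairs no constituent algorithm called; unscoreable, but they
        count as false negatives in recall denominators."""
        return sum(1 for p in self.reference.pairs if p not in self.pool)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#query\ttarget\tsignature\tlabel\n")
            for p in self.pool.sorted_pairs():
                fh.write(
                    f"{p.query}\t{p.target}\t{self.pool.signature_string(p)}\t{self.labels[p].value}\n"
                )


def read_pair_list(path: str | Path, *, comment: str = "#", header: bool = False) -> set[GenePair]:
    """Read a two-column TSV of (query gene, target gene) into a deduplicated pair set.

    Comment lines (``#``-prefixed by default) are ignored; duplicate lines
    collapse silently with a logged count.  A malformed line (fewer than two
    fields or an empty identifier) raises :class:`PairListParseError` naming
    the line number.
    """
    pairs: set[GenePair] = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip() or (comment and line.startswith(comment)):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise PairListParseError(
                    f"{path}: line {lineno}: expected two non-empty tab-separated fields, got {line!r}"
                )
            pair = GenePair(fields[0], fields[1])
            if pair in pairs:
                n_dup += 1
            else:
                pairs.add(pair)
    if n_dup:
        logger.info("%s: collapsed %d duplicate pair line(s)", path, n_dup)
    if not pairs:
        logger.warning("%s: empty pair list", path)
    return pairs


def build_pool(
    per_algorithm_pairs: Mapping[str, Iterable[GenePair]],
    manifest: AlgorithmManifest,
    *,
    species_pair: tuple[str, str] = ("query", "target"),
    allow_missing: bool = False,
) -> CandidatePool:
    """Union per-algorithm pair sets into a candidate pool with call signatures.

    Bit i of a pair's signature is 1 iff manifest algorithm i predicted the
    pair.  Every key of ``per_algorithm_pairs`` must be in the manifest;
    manifest algorithms absent from the mapping contribute all-zero columns
    only when ``allow_missing`` is set, otherwise this is an error.
    """
    unknown = set(per_algorithm_pairs) - set(manifest.names)
    if unknown:
        raise ValueError(f"algorithm name(s) not in manifest: {sorted(unknown)}")
    missing = set(manifest.names) - set(per_algorithm_pairs)
    if missing and not allow_missing:
        raise ValueError(
            f"manifest algorithm(s) without predictions: {sorted(missing)} "
            "(pass allow_missing=True for all-zero columns)"
        )
    signatures: dict[GenePair, np.ndarray] = {}
    for name, pair_set in per_algorithm_pairs.items():
        i = manifest.index(name)
        for pair in pair_set:
            sig = signatures.get(pair)
            if sig is None:
                sig = np.zeros(manifest.K, dtype=np.uint8)
                signatures[pair] = sig
            sig[i] = 1
    if not signatures:
        raise ValueError("empty pool: no algorithm predicted any pair")
    return CandidatePool(species_pair=species_pair, manifest=manifest, signatures=signatures)


def label_pool(pool: CandidatePool, reference: ReferenceLDOSet) -> LabeledPool:
    """Assign each pooled pair one of three reference classes.

    KNOWN_LDO iff the pair is in the reference; KNOWN_NON_LDO iff the query or
    the target gene has a reference partner that is not the other gene of the
    pair; UNCLASSIFIED iff neither gene occurs in the reference.
    """
    reference.validate()
    qp = reference.query_partner
    tp = reference.target_partner
    labels: dict[GenePair, Label] = {}
    for pair in pool.signatures:
        if pair in reference.pairs:
            labels[pair] = Label.KNOWN_LDO
        elif pair.query in qp or pair.target in tp:
            labels[pair] = Label.KNOWN_NON_LDO
        else:
            labels[pair] = Label.UNCLASSIFIED
    return LabeledPool(pool=pool, labels=labels, reference=reference)


@dataclass(frozen=True)
class PoolSummary:
    n_pairs: int
    n_genes: int
    n_genes_multiple: int
    mean_orthologs_per_gene: float
    pct_genes_multiple: float


def pool_summary(pairs: Iterable[GenePair]) -> PoolSummary:
    """Pair/gene counts and multiple-mapping statistics for a pair set.

    Genes are counted on both sides (query-side and target-side identifiers are
    distinct populations); a gene "has multiple orthologs" when it occurs in
    more than one pair on its side.
    """
    degree: dict[tuple[str, str], int] = {}
    n_pairs = 0
    for p in set(pairs):
        n_pairs += 1
        degree[("q", p.query)] = degree.get(("q", p.query), 0) + 1
        degree[("t", p.target)] = degree.get(("t", p.target), 0) + 1
    n_genes = len(degree)
    n_multi = sum(1 for d in degree.values() if d > 1)
    mean_per_gene = (sum(degree.values()) / n_genes) if n_genes else 0.0
    pct_multi = (100.0 * n_multi / n_genes) if n_genes else 0.0
    return PoolSummary(
        n_pairs=n_pairs,
        n_genes=n_genes,
        n_genes_multiple=n_multi,
        mean_orthologs_per_gene=mean_per_gene,
        pct_genes_multiple=pct_multi,
    )
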