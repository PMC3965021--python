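"""Core data types and I/O for cofunctional gene networks.

The central objects are undirected, weighted gene-gene association networks
(:class:`DataNetwork`), pathway-derived gold standards of positive and
negative cofunctional pairs (:class:`GoldStandard`), and named gene-set
collections (:class:`GeneSetCollection`).  Gene pairs are always stored in
canonical (lexicographically sorted, uppercase) order so that (x, y) and
(y, x) denote the same link, and self-links are rejected everywhere.

File dialects are deliberately plain: three-column TSV edge lists
(geneA, geneB, score) as distributed by functional-network databases, GMT
gene-set files, and TSV matrices with gene rows and condition columns.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

GenePair = tuple[str, str]

#: The nine evidence channels of the yeast network lineage.  User-defined
#: tags are equally valid; this list is informational, not an enum.
KNOWN_TAGS = ("CC", "CX", "DC", "GN", "GT", "HT", "LC", "PG", "TS")


def canonical_pair(a: str, b: str) -> GenePair:
    """Return the canonical form of an unordered gene pair.

    Identifiers are upper-cased and sorted lexicographically.  Self-links
    are invalid by construction.
    """
    a, b = str(a).strip().upper(), str(b).strip().upper()
    if not a or not b:
        raise ValidationError("empty gene identifier in pair")
    if a == b:
        raise ValidationError(f"self-link {a}-{b} is not allowed")
    return (a, b) if a < b else (b, a)


@dataclass
class DataNetwork:
    """An undirected gene network with real-valued edge weights.

    Parameters
    ----------
    tag
        Data-type label (e.g. one of ``CC, CX, DC, GN, GT, HT, LC, PG, TS``,
        or any user string such as ``"integrated"``).
    edges
        Mapping from canonical gene pair to a finite weight in natural-log
        odds units (log-likelihood scores after calibration).
    """

    tag: str
    edges: dict[GenePair, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        checked: dict[GenePair, float] = {}
        for (a, b), w in self.edges.items():
            pair = canonical_pair(a, b)
            w = float(w)
            if not math.isfinite(w):
                raise ValidationError(f"non-finite weight for {pair}")
            if pair in checked and checked[pair] != w:
                raise ValidationError(
                    f"duplicate pair {pair} with conflicting weights"
                )
            checked[pair] = w
        self.edges = checked

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[str, dict[str, float]]:
        """Neighbor map: gene -> {neighbor: weight}."""
        adj: dict[str, dict[str, float]] = defaultdict(dict)
        for (a, b), w in self.edges.items():
            adj[a][b] = w
            adj[b][a] = w
        return dict(adj)

    def neighbors(self, gene: str) -> dict[str, float]:
        gene = gene.strip().upper()
        out: dict[str, float] = {}
        for (a, b), w in self.edges.items():
            if a == gene:
                out[b] = w
            elif b == gene:
                out[a] = w
        return out

    def sorted_edges(self) -> list[tuple[GenePair, float]]:
        """Edges by descending weight, ties in canonical pair order."""
        return sorted(self.edges.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass
class GoldStandard:
    """Disjoint positive / negative reference pair sets.

    Positives are pairs co-annotated to at least one pathway; negatives are
    pairs of annotated genes that never share a pathway.
    """

    positives: set[GenePair]
    negatives: set[GenePair]

    def __post_init__(self) -> None:
        self.positives = {canonical_pair(*p) for p in self.positives}
        self.negatives = {canonical_pair(*p) for p in self.negatives}
        clash = self.positives & self.negatives
        if clash:
            raise ValidationError(
                f"{len(clash)} pairs appear as both positive and negative"
            )

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)

    def label(self, pair: GenePair) -> bool | None:
        """True for a positive, False for a negative, None if not evaluable."""
        if pair in self.positives:
            return True
        if pair in self.negatives:
            return False
        return None


@dataclass
class GeneSetCollection:
    """Named gene sets: pathways, GO terms, phenotype sets, DEG lists..."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for name, members in self.sets.items():
            members = frozenset(str(g).strip().upper() for g in members)
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            clean[name] = members
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return out


@dataclass
class ExpressionMatrix:
    """A genes x conditions real matrix; NaN marks missing observations."""

    genes: list[str]
    conditions: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [str(g).strip().upper() for g in self.genes]
        self.conditions = [str(c) for c in self.conditions]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene identifiers in matrix")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValidationError("duplicate condition labels in matrix")
        if self.values.shape != (len(self.genes), len(self.conditions)):
            raise ValidationError(
                f"value grid {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.conditions)} conditions"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.conditions)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, tag: str = "edges",
                   header: bool = False) -> DataNetwork:
    """Read a 3-column TSV edge list (geneA, geneB, score) into a network.

    Pairs are canonicalized; self-links and duplicate pairs carrying
    conflicting scores are rejected.  Set ``header=True`` to skip a leading
    header row.
    """
    edges: dict[GenePair, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if header and lineno == 1:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"expected 3 tab-separated columns, got {len(fields)}",
                    line=lineno,
                )
            a, b, raw_score = fields
            try:
                score = float(raw_score)
            except ValueError:
                raise ParseError(
                    f"non-numeric score {raw_score!r}", line=lineno
                ) from None
            if not math.isfinite(score):
                raise ParseError(f"non-finite score {raw_score!r}", line=lineno)
            try:
                pair = canonical_pair(a, b)
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from None
            if pair in edges and edges[pair] != score:
                raise ValidationError(
                    f"line {lineno}: duplicate pair {pair} with conflicting scores"
                )
            edges[pair] = score
    return DataNetwork(tag=tag, edges=edges)


def write_edge_list(net: DataNetwork, path: str | Path) -> None:
    """Write a network as 3-column TSV, rows by descending weight then pair order."""
    with open(path, "w") as fh:
        for (a, b), w in net.sorted_edges():
            fh.write(f"{a}\t{b}\t{w:g}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: name TAB description TAB member genes...

    Duplicate member genes within a line are collapsed; duplicate set names
    are an error.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"expected >=3 tab-separated fields, got {len(fields)}",
                    line=lineno,
                )
            name, desc, *members = fields
            if name in sets:
                raise ValidationError(f"line {lineno}: duplicate set name {name!r}")
            members = [m for m in members if m.strip()]
            if not members:
                raise ParseError(f"set {name!r} has no member genes", line=lineno)
            sets[name] = frozenset(m.strip().upper() for m in members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV matrix with gene rows and condition-header columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        genes=list(df.index.astype(str)),
        conditions=list(df.columns.astype(str)),
        values=df.to_numpy(dtype=float),
    )


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def read_gold(path: str | Path) -> GoldStandard:
    """Read a gold standard from TSV: geneA, geneB, label (1 positive / 0 negative)."""
    positives: set[GenePair] = set()
    negatives: set[GenePair] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"expected 3 tab-separated columns, got {len(fields)}",
                    line=lineno,
                )
            a, b, label = fields
            pair = canonical_pair(a, b)
            if label == "1":
                positives.add(pair)
            elif label == "0":
                negatives.add(pair)
            else:
                raise ParseError(f"label must be 0 or 1, got {label!r}", line=lineno)
    return GoldStandard(positives=positives, negatives=negatives)


def write_gold(gold: GoldStandard, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(gold.positives):
            fh.write(f"{a}\t{b}\t1\n")
        for a, b in sorted(gold.negatives):
            fh.write(f"{a}\t{b}\t0\n")


# ---------------------------------------------------------------------------
# Gold-standard construction
# ---------------------------------------------------------------------------

def gold_from_annotations(pathways: GeneSetCollection) -> GoldStandard:
    """Derive a gold standard from pathway annotations.

    Positives are all distinct-gene pairs co-annotated to at least one set;
    negatives are pairs where both genes carry some annotation but never
    share a set.
    """
    if len(pathways) == 0:
        raise ValidationError("empty gene-set collection")
    annotated = sorted(pathways.all_genes())
    if len(annotated) < 2:
        raise ValidationError("need at least 2 annotated genes")
    positives: set[GenePair] = set()
    for members in pathways.sets.values():
        genes = sorted(members)
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                positives.add(canonical_pair(a, b))
    negatives: set[GenePair] = set()
    for i, a in enumerate(annotated):
        for b in annotated[i + 1:]:
            pair = canonical_pair(a, b)
            if pair not in positives:
                negatives.add(pair)
    return GoldStandard(positives=positives, negatives=negatives)


class OverlapResult(NamedTuple):
    """Overlap between gold positives and network edges.

    ``fraction_of_positives`` divides by all gold positives;
    ``fraction_of_evaluable`` divides by gold positives whose two genes both
    occur in the network (the two candidate denominators for an overlap
    statistic).
    """

    count: int
    n_positives: int
    n_evaluable_positives: int
    fraction_of_positives: float
    fraction_of_evaluable: float


def overlap_fraction(gold: GoldStandard, net: DataNetwork) -> OverlapResult:
    """Count gold-positive pairs that are also network edges."""
    if gold.n_pos == 0 or net.n_edges == 0:
        raise ValidationError("gold standard and network must both be nonempty")
    genes = net.genes
    evaluable = [p for p in gold.positives if p[0] in genes and p[1] in genes]
    count = sum(1 for p in gold.positives if p in net.edges)
    return OverlapResult(
        count=count,
        n_positives=gold.n_pos,
        n_evaluable_positives=len(evaluable),
        fraction_of_positives=count / gold.n_pos,
        fraction_of_evaluable=(count / len(evaluable)) if evaluable else float("nan"),
    )
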