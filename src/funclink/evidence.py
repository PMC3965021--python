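"""Raw-evidence scorers: expression, phyletic profiles, literature co-citation.

Each scorer turns one primary data modality into a ranked table of gene-pair
evidence scores (:class:`EvidenceTable`), the substrate that rank-binned
benchmarking later calibrates into log-likelihood scores.  Three standard
scorers are provided:

* co-expression (CX): Pearson correlation over shared observed conditions;
* phylogenetic profiles (PG): mutual information between binary
  presence/absence vectors across reference genomes;
* co-citation (CC): hypergeometric surprise of shared literature citations.

Other evidence channels (genetic interaction, PPI, domain co-occurrence,
gene neighborhood, protein structure...) enter the pipeline as externally
supplied evidence tables or pre-calibrated networks in the same formats.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .netio import ExpressionMatrix, GenePair, canonical_pair

logger = logging.getLogger(__name__)


@dataclass
class EvidenceTable:
    """Ranked gene-pair evidence: (pair, raw score) rows under one data tag."""

    tag: str
    rows: list[tuple[GenePair, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[GenePair] = set()
        clean: list[tuple[GenePair, float]] = []
        for (a, b), score in self.rows:
            pair = canonical_pair(a, b)
            score = float(score)
            if not math.isfinite(score):
                raise ValidationError(f"non-finite raw score for {pair}")
            if pair in seen:
                raise ValidationError(f"duplicate pair {pair} in evidence table")
            seen.add(pair)
            clean.append((pair, score))
        self.rows = clean

    def __len__(self) -> int:
        return len(self.rows)

    def sorted_rows(self) -> list[tuple[GenePair, float]]:
        """Rows by descending raw score, ties in canonical pair order."""
        return sorted(self.rows, key=lambda r: (-r[1], r[0]))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for (a, b), score in self.sorted_rows():
                fh.write(f"{a}\t{b}\t{score:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, tag: str = "evidence") -> "EvidenceTable":
        rows: list[tuple[GenePair, float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                a, b, score = line.split("\t")
                rows.append((canonical_pair(a, b), float(score)))
        return cls(tag=tag, rows=rows)


@dataclass
class PhyleticProfiles:
    """Binary presence/absence of genes across reference genomes."""

    genes: list[str]
    genomes: list[str]
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [str(g).strip().upper() for g in self.genes]
        self.presence = np.asarray(self.presence)
        if len(self.genomes) < 2:
            raise ValidationError("need >=2 reference genomes")
        if self.presence.shape != (len(self.genes), len(self.genomes)):
            raise ValidationError("presence grid does not match labels")
        if not np.isin(self.presence, (0, 1)).all():
            raise ValidationError("presence entries must be 0 or 1")
        self.presence = self.presence.astype(np.int8)


@dataclass
class CitationIndex:
    """Documents citing each gene, over a corpus of known total size."""

    docs_by_gene: dict[str, frozenset]
    corpus_size: int

    def __post_init__(self) -> None:
        if self.corpus_size < 1:
            raise ValidationError("corpus_size must be >= 1")
        clean: dict[str, frozenset] = {}
        for gene, docs in self.docs_by_gene.items():
            docs = frozenset(docs)
            if len(docs) > self.corpus_size:
                raise ValidationError(
                    f"gene {gene} cites {len(docs)} documents, "
                    f"more than corpus_size={self.corpus_size}"
                )
            clean[str(gene).strip().upper()] = docs
        self.docs_by_gene = clean


# ---------------------------------------------------------------------------
# Scorers
# ---------------------------------------------------------------------------

def coexpression_scores(expr: ExpressionMatrix, min_pairs: int = 10) -> EvidenceTable:
    """Pearson co-expression evidence over complete condition pairs.

    For each gene pair, the correlation is computed over conditions where
    both genes are observed; pairs with fewer than ``min_pairs`` complete
    observations, or with a zero-variance profile over those observations,
    are omitted (and logged).
    """
    if len(expr.conditions) < 3:
        raise ValidationError("need >=3 conditions for co-expression")
    if min_pairs < 3:
        raise ValidationError("min_pairs must be >= 3")
    values = expr.values
    observed = np.isfinite(values)
    rows: list[tuple[GenePair, float]] = []
    n_skipped = 0
    for i, j in combinations(range(len(expr.genes)), 2):
        both = observed[i] & observed[j]
        if both.sum() < min_pairs:
            n_skipped += 1
            continue
        x, y = values[i, both], values[j, both]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            n_skipped += 1
            logger.debug(
                "zero variance over complete pairs for (%s, %s); pair omitted",
                expr.genes[i], expr.genes[j],
            )
            continue
        r = float(stats.pearsonr(x, y).statistic)
        rows.append((canonical_pair(expr.genes[i], expr.genes[j]), r))
    if n_skipped:
        logger.info("co-expression: omitted %d undefined pairs", n_skipped)
    return EvidenceTable(tag="CX", rows=rows)


def _mutual_information_bits(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) of two binary vectors."""
    n = x.size
    mi = 0.0
    for a in (0, 1):
        px = np.count_nonzero(x == a) / n
        if px == 0:
            continue
        for b in (0, 1):
            py = np.count_nonzero(y == b) / n
            pxy = np.count_nonzero((x == a) & (y == b)) / n
            if pxy == 0 or py == 0:
                continue
            mi += pxy * math.log2(pxy / (px * py))
    return max(mi, 0.0)


def phyletic_scores(profiles: PhyleticProfiles) -> EvidenceTable:
    """Phylogenetic-profile evidence: plug-in MI of binary presence vectors.

    A constant profile (present in all or none of the genomes) carries no
    co-inheritance information; its pairs score 0 by convention.
    """
    rows: list[tuple[GenePair, float]] = []
    pres = profiles.presence
    constant = [bool(p.min() == p.max()) for p in pres]
    for i, j in combinations(range(len(profiles.genes)), 2):
        if constant[i] or constant[j]:
            mi = 0.0
            logger.debug(
                "constant phyletic profile in (%s, %s); MI set to 0",
                profiles.genes[i], profiles.genes[j],
            )
        else:
            mi = _mutual_information_bits(pres[i], pres[j])
        rows.append((canonical_pair(profiles.genes[i], profiles.genes[j]), mi))
    return EvidenceTable(tag="PG", rows=rows)


def cocitation_scores(index: CitationIndex) -> EvidenceTable:
    """Co-citation evidence: -log10 hypergeometric tail of shared documents.

    For genes citing ``ka`` and ``kb`` documents out of a corpus of ``N``,
    sharing ``s`` documents, the raw score is ``-log10 P(X >= s)`` with
    ``X ~ Hypergeom(N, ka, kb)``.  Pairs sharing no document are omitted.
    """
    rows: list[tuple[GenePair, float]] = []
    genes = sorted(index.docs_by_gene)
    N = index.corpus_size
    for ga, gb in combinations(genes, 2):
        da, db = index.docs_by_gene[ga], index.docs_by_gene[gb]
        shared = len(da & db)
        if shared == 0:
            continue
        logp = stats.hypergeom.logsf(shared - 1, N, len(da), len(db))
        score = -logp / math.log(10)
        rows.append((canonical_pair(ga, gb), max(score, 0.0)))
    return EvidenceTable(tag="CC", rows=rows)
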