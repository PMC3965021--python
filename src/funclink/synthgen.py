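"""Seeded generators for synthetic networks, expression data and queries.

Everything downstream of raw data can be exercised without any external
download: networks with planted functional modules, expression matrices
with module-correlated profiles, phyletic profiles with co-inherited
modules, gold standards derived from the planted modules, and DEG-style
query sets around a planted modulator hub.  All generators are
deterministic under their seed and use one local random source per call
(no global random state).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import GenerationError, ValidationError
from .evidence import PhyleticProfiles
from .netio import (DataNetwork, ExpressionMatrix, GeneSetCollection,
                    GoldStandard, canonical_pair, gold_from_annotations)


def gene_name(i: int) -> str:
    """Systematic-style synthetic gene identifier for index ``i``."""
    return f"G{i:04d}"


@dataclass
class PlantedModel:
    """A planted-module network model.

    Module gene pairs are linked with probability ``p_in`` and weights from
    the ``weight_in`` normal (truncated at 0); all other pairs with
    probability ``p_out`` and ``weight_out`` weights.  Weight defaults
    (2.0 +/- 0.5 within modules, 0.5 +/- 0.5 background) only set the
    ordering scale; analyses should depend on ordering, not the constants.
    """

    n_genes: int
    modules: list[set[int]]
    p_in: float = 0.9
    p_out: float = 0.02
    weight_in: tuple[float, float] = (2.0, 0.5)
    weight_out: tuple[float, float] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValidationError("need >=2 genes")
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValidationError("need 0 <= p_out < p_in <= 1")
        seen: set[int] = set()
        for module in self.modules:
            if seen & module:
                raise ValidationError("modules must be disjoint")
            if module and (min(module) < 0 or max(module) >= self.n_genes):
                raise ValidationError("module index out of range")
            seen |= module

    def module_gene_sets(self) -> list[set[str]]:
        return [{gene_name(i) for i in m} for m in self.modules]


def _truncated_normal(rng: np.random.Generator, loc: float, scale: float,
                      size: int) -> np.ndarray:
    """Normal(loc, scale) truncated below at 0."""
    if size == 0:
        return np.empty(0)
    a = (0.0 - loc) / scale
    return stats.truncnorm.rvs(a, np.inf, loc=loc, scale=scale,
                               size=size, random_state=rng)


def make_network(model: PlantedModel) -> DataNetwork:
    """Sample a planted-module network; identical seed, identical output."""
    rng = np.random.default_rng(model.seed)
    module_of = {}
    for m_idx, module in enumerate(model.modules):
        for g in module:
            module_of[g] = m_idx
    pairs = [(i, j) for i in range(model.n_genes)
             for j in range(i + 1, model.n_genes)]
    within = np.array([
        module_of.get(i) is not None and module_of.get(i) == module_of.get(j)
        for i, j in pairs
    ])
    u = rng.random(len(pairs))
    present = np.where(within, u < model.p_in, u < model.p_out)
    w_in = _truncated_normal(rng, *model.weight_in, size=len(pairs))
    w_out = _truncated_normal(rng, *model.weight_out, size=len(pairs))
    weights = np.where(within, w_in, w_out)
    edges = {
        canonical_pair(gene_name(i), gene_name(j)): float(w)
        for (i, j), keep, w in zip(pairs, present, weights)
        if keep
    }
    return DataNetwork(tag=f"planted(seed={model.seed})", edges=edges)


def make_expression(
    modules: list[set[str]],
    n_conditions: int,
    rho: float,
    seed: int,
    background_genes: list[str] | None = None,
) -> ExpressionMatrix:
    """Expression matrix with module-correlated gene profiles.

    Genes within a module share a latent per-condition factor so that the
    expected pairwise Pearson correlation is ``rho``; background genes are
    independent standard normal noise.
    """
    if not (0 <= rho < 1):
        raise ValidationError("need 0 <= rho < 1")
    if n_conditions < 3:
        raise ValidationError("need >=3 conditions")
    rng = np.random.default_rng(seed)
    genes: list[str] = []
    for module in modules:
        genes.extend(sorted(module))
    genes.extend(sorted(background_genes or []))
    if len(set(genes)) != len(genes):
        raise ValidationError("module/background gene lists overlap")
    values = np.empty((len(genes), n_conditions))
    row = 0
    for module in modules:
        factor = rng.standard_normal(n_conditions)
        for _ in sorted(module):
            noise = rng.standard_normal(n_conditions)
            values[row] = np.sqrt(rho) * factor + np.sqrt(1 - rho) * noise
            row += 1
    for _ in sorted(background_genes or []):
        values[row] = rng.standard_normal(n_conditions)
        row += 1
    conditions = [f"C{j:04d}" for j in range(n_conditions)]
    return ExpressionMatrix(genes=genes, conditions=conditions, values=values)


def make_phyletic(
    modules: list[set[str]],
    n_genomes: int,
    flip_rate: float,
    seed: int,
    background_genes: list[str] | None = None,
) -> PhyleticProfiles:
    """Binary phyletic profiles with co-inherited modules.

    Each module shares one ancestral presence/absence pattern across the
    reference genomes; each gene's observed profile flips every genome
    state independently with ``flip_rate``.  Background genes draw
    independent fair-coin profiles.
    """
    if not (0 <= flip_rate < 0.5):
        raise ValidationError("need 0 <= flip_rate < 0.5")
    if n_genomes < 2:
        raise ValidationError("need >=2 genomes")
    rng = np.random.default_rng(seed)
    genes: list[str] = []
    rows: list[np.ndarray] = []
    for module in modules:
        ancestral = rng.integers(0, 2, size=n_genomes)
        for g in sorted(module):
            flips = rng.random(n_genomes) < flip_rate
            rows.append(np.where(flips, 1 - ancestral, ancestral))
            genes.append(g)
    for g in sorted(background_genes or []):
        rows.append(rng.integers(0, 2, size=n_genomes))
        genes.append(g)
    genomes = [f"genome{j:04d}" for j in range(n_genomes)]
    return PhyleticProfiles(genes=genes, genomes=genomes,
                            presence=np.vstack(rows))


def make_gold(modules: list[set[str]]) -> GoldStandard:
    """Gold standard from planted modules: co-module pairs are positives."""
    if not modules:
        raise ValidationError("need >=1 module")
    sets = {f"M{i}": frozenset(m) for i, m in enumerate(modules)}
    return gold_from_annotations(GeneSetCollection(sets=sets))


def make_deg_query(
    net: DataNetwork,
    hub: str,
    fraction: float,
    n_noise: int,
    seed: int,
) -> set[str]:
    """A DEG-style query set around a planted modulator hub.

    Returns the stated fraction of the hub's neighbors plus ``n_noise``
    random non-neighbor genes.  The hub itself is excluded, emulating a
    modulator that shows no transcriptional response of its own.
    """
    hub = str(hub).strip().upper()
    if hub not in net.genes:
        raise GenerationError(f"hub {hub} not in network")
    if not (0 < fraction <= 1):
        raise ValidationError("need 0 < fraction <= 1")
    neighbors = sorted(net.neighbors(hub))
    if not neighbors:
        raise GenerationError(f"hub {hub} is isolated")
    rng = np.random.default_rng(seed)
    k = max(1, round(fraction * len(neighbors)))
    chosen = set(rng.choice(neighbors, size=k, replace=False))
    others = sorted(net.genes - set(neighbors) - {hub})
    if n_noise > len(others):
        raise GenerationError(
            f"requested {n_noise} noise genes but only {len(others)} available"
        )
    if n_noise:
        chosen |= set(rng.choice(others, size=n_noise, replace=False))
    return {str(g) for g in chosen}
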