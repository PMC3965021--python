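"""Weighted-sum integration of data-specific LLS networks.

Each gene pair may carry one log-likelihood score per evidence type.  The
integrated score sums them in descending order with rank-decayed weights::

    WS = L0 + sum_{i>=1} Li / (D * i)        (linear decay, the default)

where L0 >= L1 >= ... are the pair's per-type LLS values and D >= 1 controls
how much weaker lines of evidence contribute: D = 1 is a plain sum, D -> inf
keeps only the single best evidence type.  A geometric decay Li / D**i is
available as an alternative.  Edges whose weighted sum falls below a
threshold T are dropped (default T = 0, i.e. keep any pair with positive
integrated log odds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .exceptions import EvaluationError, ValidationError
from .netio import DataNetwork, GenePair, GoldStandard

logger = logging.getLogger(__name__)

DECAYS = ("linear", "geometric")


@dataclass
class IntegrationConfig:
    """Free parameters of the weighted-sum scheme."""

    D: float = 1.0
    T: float = 0.0
    decay: str = "linear"

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValidationError("decay parameter D must be >= 1")
        if not (self.T == self.T and abs(self.T) != float("inf")):
            raise ValidationError("threshold T must be finite")
        if self.decay not in DECAYS:
            raise ValidationError(f"decay must be one of {DECAYS}")


def weighted_sum(lls_values: Sequence[float], D: float,
                 decay: str = "linear") -> float:
    """Rank-decayed weighted sum of one pair's per-type LLS values."""
    if len(lls_values) == 0:
        raise ValidationError("weighted_sum of an empty evidence list is undefined")
    if D < 1:
        raise ValidationError("decay parameter D must be >= 1")
    ordered = sorted(lls_values, reverse=True)
    total = ordered[0]
    for i, value in enumerate(ordered[1:], start=1):
        if decay == "linear":
            total += value / (D * i)
        elif decay == "geometric":
            total += value / D**i
        else:
            raise ValidationError(f"decay must be one of {DECAYS}")
    return total


def integrate_networks(
    nets: Sequence[DataNetwork], cfg: IntegrationConfig | None = None
) -> DataNetwork:
    """Combine data-specific networks into one integrated network.

    Every pair present in at least one input collects its per-type LLS
    values (each data-type tag contributes at most one value per pair) and
    is retained iff its weighted sum reaches ``cfg.T``.
    """
    if not nets:
        raise ValidationError("need at least one network to integrate")
    cfg = cfg or IntegrationConfig()
    tags = [net.tag for net in nets]
    if len(set(tags)) != len(tags):
        raise ValidationError(
            f"duplicate data-type tags among inputs: {sorted(tags)}; "
            "pre-integrate multiple datasets of one type first"
        )
    per_pair: dict[GenePair, list[float]] = {}
    for net in nets:
        for pair, w in net.edges.items():
            per_pair.setdefault(pair, []).append(w)
    edges = {}
    for pair, values in per_pair.items():
        ws = weighted_sum(values, cfg.D, cfg.decay)
        if ws >= cfg.T:
            edges[pair] = ws
    logger.info(
        "integrated %d networks (%s): %d candidate pairs -> %d edges "
        "(D=%g, T=%g, %s decay)",
        len(nets), ",".join(tags), len(per_pair), len(edges),
        cfg.D, cfg.T, cfg.decay,
    )
    return DataNetwork(tag="integrated", edges=edges)


def tune_D(
    nets: Sequence[DataNetwork],
    gold_validate: GoldStandard,
    grid: Sequence[float],
    T: float = 0.0,
    bin_size: int = 1000,
    genome_size: int | None = None,
    gold_train: GoldStandard | None = None,
    decay: str = "linear",
) -> float:
    """Pick the decay parameter maximizing validation PR area.

    For each candidate D, the networks are integrated and scored by the area
    under the cumulative precision-recall curve against ``gold_validate``;
    ties favor the smallest D.  When the calibration gold standard is also
    supplied, overlap between the two is rejected so that validation stays
    independent of training.
    """
    from .evaluate import pr_area, pr_curve  # deferred: avoids import cycle

    if not grid:
        raise ValidationError("empty tuning grid")
    if gold_train is not None:
        shared = (gold_train.positives & gold_validate.positives) | (
            gold_train.negatives & gold_validate.negatives
        )
        if shared:
            raise ValidationError(
                f"validation gold shares {len(shared)} pairs with training gold"
            )
    all_genes = set()
    for net in nets:
        all_genes |= net.genes
    genome_size = genome_size or len(all_genes)
    best_D: float | None = None
    best_area = float("-inf")
    for D in sorted(grid):
        integrated = integrate_networks(
            nets, IntegrationConfig(D=D, T=T, decay=decay)
        )
        try:
            curve = pr_curve(integrated, gold_validate, bin_size, genome_size)
        except EvaluationError:
            continue
        area = pr_area(curve)
        if area > best_area:
            best_area, best_D = area, D
    if best_D is None:
        raise EvaluationError(
            "no gold-evaluable integrated edges for any grid value"
        )
    return best_D
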