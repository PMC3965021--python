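"""Network assessment: binned precision-recall and guilt-by-association ROC.

Two complementary views of network quality are implemented:

* **Cumulative binned precision-recall** against a pathway-derived gold
  standard: edges are ranked by LLS, grouped into consecutive bins (1000
  pairs per bin by default), and after each bin precision is the fraction
  of gold-evaluable pairs so far that are positives, while recall is genome
  coverage - the fraction of the organism's coding genes touched by at
  least one edge so far.

* **Leave-one-out guilt-by-association (LOO-GBA)** for phenotype gene sets:
  in each cross-validation fold one member is held out, every gene is
  scored by the summed LLS of its links to the remaining members, and the
  held-out member competes against the non-members; pooling the folds
  yields a Mann-Whitney ROC AUC (ties counting half) with the members as
  positives.  An AUC of 1 is a perfect prediction; 0.5 is chance.

Utilities extract phenotype gene sets from the extreme tails of a
quantitative per-gene measure, and compare two networks' paired AUC
distributions by the Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import EvaluationError, ValidationError
from .netio import DataNetwork, GeneSetCollection, GoldStandard

logger = logging.getLogger(__name__)

#: Validated coding genes in the S. cerevisiae genome; the default recall
#: denominator.  Always pass an explicit genome size for other organisms.
YEAST_CODING_GENES = 5887


@dataclass
class PRCurve:
    """Cumulative precision-recall points over ranked network edges."""

    points: list[tuple[int, float, float]]  # (pairs_considered, precision, recall)
    genome_size: int

    def __post_init__(self) -> None:
        last_n = 0
        last_recall = -1.0
        for n, precision, recall in self.points:
            if n <= last_n:
                raise ValidationError("pairs_considered must be strictly increasing")
            if not (0.0 <= precision <= 1.0):
                raise ValidationError("precision out of [0, 1]")
            if recall < last_recall:
                raise ValidationError("recall must be non-decreasing")
            last_n, last_recall = n, recall


def pr_area(curve: PRCurve) -> float:
    """Trapezoidal area under precision vs recall."""
    recalls = [r for _, _, r in curve.points]
    precisions = [p for _, p, _ in curve.points]
    if len(recalls) < 2:
        return 0.0
    return float(np.trapezoid(precisions, recalls))


def pr_curve(
    net: DataNetwork,
    gold: GoldStandard,
    bin_size: int = 1000,
    genome_size: int = YEAST_CODING_GENES,
) -> PRCurve:
    """Cumulative binned precision-recall of a ranked network.

    One point per ``bin_size`` ranked edges plus a terminal point.
    Precision counts gold-evaluable pairs only; edges the gold standard
    cannot label still advance recall (gene coverage) but not precision.
    """
    if net.n_edges == 0:
        raise EvaluationError("empty network")
    if bin_size < 1:
        raise ValidationError("bin_size must be >= 1")
    if genome_size < net.n_genes:
        raise ValidationError(
            f"genome_size {genome_size} smaller than network gene count {net.n_genes}"
        )
    ranked = net.sorted_edges()
    pos_so_far = 0
    eval_so_far = 0
    covered: set[str] = set()
    points: list[tuple[int, float, float]] = []
    for rank, ((a, b), _w) in enumerate(ranked, start=1):
        label = gold.label((a, b))
        if label is not None:
            eval_so_far += 1
            pos_so_far += int(label)
        covered.add(a)
        covered.add(b)
        at_boundary = rank % bin_size == 0 or rank == len(ranked)
        if at_boundary and eval_so_far > 0:
            points.append(
                (rank, pos_so_far / eval_so_far, len(covered) / genome_size)
            )
    if eval_so_far == 0:
        raise EvaluationError("no gold-evaluable edges in network")
    return PRCurve(points=points, genome_size=genome_size)


# ---------------------------------------------------------------------------
# Guilt-by-association prioritization
# ---------------------------------------------------------------------------

@dataclass
class PrioritizationResult:
    """Ranked genes with the ROC AUC of recovering the phenotype members."""

    ranked: list[tuple[str, float]]
    positives: frozenset[str]
    auc: float


def midrank_auc(scores: np.ndarray, is_pos: np.ndarray) -> float:
    """Mann-Whitney AUC of one score vector, with midrank tie handling."""
    n_pos = int(is_pos.sum())
    n_neg = int(len(scores) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC needs both positive and negative genes")
    ranks = stats.rankdata(scores)  # midranks, ascending
    rank_sum = float(ranks[is_pos].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def loo_gba_scores(net: DataNetwork, phenotype: set[str]) -> PrioritizationResult:
    """Leave-one-out guilt-by-association prioritization for one gene set.

    The ``ranked`` list scores every network gene g by the summed edge
    weights from g to the phenotype members other than g itself - the
    candidate ranking a user browses.  The AUC follows strict leave-one-out
    cross-validation: in the fold that holds out member m, both m and every
    non-member are scored against the same remaining members, and the
    pooled Mann-Whitney statistic (ties counting half) over all
    member/non-member comparisons is reported.  Scoring each fold against
    an identical reference set keeps the AUC exactly 0.5 for an
    uninformative network regardless of set size.  Members present in the
    network are the positives; genes absent from the network are excluded.
    """
    phenotype = {str(g).strip().upper() for g in phenotype}
    net_genes = net.genes
    members = sorted(phenotype & net_genes)
    if len(members) < 2:
        missing = sorted(phenotype - net_genes)
        raise EvaluationError(
            f"phenotype has {len(members)} gene(s) in the network (need >=2); "
            f"absent: {missing}"
        )
    adj = net.adjacency()
    member_set = set(members)
    genes = sorted(net_genes)
    if len(genes) == len(members):
        raise EvaluationError("AUC needs both positive and negative genes")
    # weight matrix: gene x member link weights
    W = np.zeros((len(genes), len(members)))
    for i, g in enumerate(genes):
        neigh = adj.get(g, {})
        for j, m in enumerate(members):
            if m != g:
                W[i, j] = neigh.get(m, 0.0)
    totals = W.sum(axis=1)
    gene_index = {g: i for i, g in enumerate(genes)}
    non_idx = np.array([i for i, g in enumerate(genes)
                        if g not in member_set])
    wins = 0.0
    for j, m in enumerate(members):
        s_m = totals[gene_index[m]]  # links to the other members
        fold_scores = totals[non_idx] - W[non_idx, j]
        wins += float((s_m > fold_scores).sum())
        wins += 0.5 * float((s_m == fold_scores).sum())
    auc = wins / (len(members) * len(non_idx))
    order = sorted(zip(genes, totals), key=lambda gs: (-gs[1], gs[0]))
    return PrioritizationResult(
        ranked=[(g, float(s)) for g, s in order],
        positives=frozenset(members),
        auc=auc,
    )


def auc_batch(net: DataNetwork, phenotypes: GeneSetCollection) -> dict[str, float]:
    """LOO-GBA AUC for every usable phenotype set; unusable sets are skipped."""
    aucs: dict[str, float] = {}
    for name, members in phenotypes:
        try:
            aucs[name] = loo_gba_scores(net, set(members)).auc
        except EvaluationError as exc:
            logger.info("skipping phenotype set %r: %s", name, exc)
    if not aucs:
        raise EvaluationError("no usable phenotype sets")
    return aucs


# ---------------------------------------------------------------------------
# Extreme-tail phenotype set extraction
# ---------------------------------------------------------------------------

@dataclass
class TailSetConfig:
    """Extraction thresholds for extreme-tail phenotype sets.

    ``p_threshold`` is the per-side tail probability (e.g. 1e-4 for
    morphology screens, 1e-7 for sensitivity screens); ``min_size`` drops
    candidate sets with too few member genes (5 in the screens above).
    """

    p_threshold: float = 1e-4
    min_size: int = 5
    mode: str = "normal"  # or "empirical"

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 0.5):
            raise ValidationError("p_threshold must lie in (0, 0.5)")
        if self.min_size < 1:
            raise ValidationError("min_size must be >= 1")
        if self.mode not in ("normal", "empirical"):
            raise ValidationError("mode must be 'normal' or 'empirical'")


def extreme_tail_sets(
    values: dict[str, float],
    cfg: TailSetConfig,
    name: str = "param",
) -> GeneSetCollection:
    """Extract up to two gene sets from the tails of a quantitative measure.

    In ``normal`` mode a location/scale normal is fitted to the per-gene
    values and genes whose one-sided tail probability falls below
    ``p_threshold`` form the upper and lower candidate sets (named
    ``{name}_upper`` / ``{name}_lower``); ``empirical`` mode uses empirical
    quantile ranks instead.  Candidates smaller than ``min_size`` are
    dropped.
    """
    items = [(str(g).strip().upper(), float(v)) for g, v in values.items()
             if math.isfinite(float(v))]
    if len(items) < 10:
        raise EvaluationError("need >=10 genes with finite values")
    genes = [g for g, _ in items]
    x = np.array([v for _, v in items])
    if np.ptp(x) == 0:
        raise EvaluationError("zero variance: no distribution tails to cut")
    if cfg.mode == "normal":
        mu, sd = float(x.mean()), float(x.std(ddof=1))
        upper_p = stats.norm.sf(x, loc=mu, scale=sd)
        lower_p = stats.norm.cdf(x, loc=mu, scale=sd)
    else:
        n = len(x)
        ranks = stats.rankdata(x)
        upper_p = (n - ranks + 1) / n
        lower_p = ranks / n
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for side, p in (("upper", upper_p), ("lower", lower_p)):
        members = frozenset(g for g, pv in zip(genes, p) if pv < cfg.p_threshold)
        if len(members) >= cfg.min_size:
            sets[f"{name}_{side}"] = members
            descriptions[f"{name}_{side}"] = (
                f"{side} tail of {name} at p<{cfg.p_threshold:g} ({cfg.mode})"
            )
    return GeneSetCollection(sets=sets, descriptions=descriptions)


# ---------------------------------------------------------------------------
# Paired network comparison
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(auc_a: list[float], auc_b: list[float]) -> float:
    """One-sided Wilcoxon signed-rank p-value that the b scores exceed a.

    Differences of zero are dropped; the null distribution is enumerated
    exactly for n <= 25 nonzero tie-free differences, with a tie-corrected
    normal approximation otherwise.
    """
    if len(auc_a) != len(auc_b):
        raise ValidationError("paired AUC lists must have equal length")
    if len(auc_a) < 5:
        raise ValidationError("need >=5 paired AUC values")
    d = np.asarray(auc_b, dtype=float) - np.asarray(auc_a, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise EvaluationError("all paired differences are zero")
    has_ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative="greater", method=method,
                         zero_method="wilcox")
    return float(res.pvalue)
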