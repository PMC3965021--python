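"""Rank-binned benchmarking: calibrate raw evidence into log-likelihood scores.

The log-likelihood score (LLS) of an evidence level measures how much more
likely a gene pair at that level is to be cofunctional than a random pair::

    LLS = ln( (p/n) / (P/N) )

where ``p`` and ``n`` count gold-standard positive and negative pairs among
the pairs at that evidence level, and ``P``/``N`` are the total positives
and negatives of the gold standard (the prior odds).  Calibration proceeds
by ranking evidence pairs by raw score, binning consecutive gold-evaluable
pairs (1000 per bin by default), scoring each bin, and enforcing a monotone
non-increasing score-to-LLS mapping by pooling adjacent violating bins
(pool-adjacent-violators; a pooled bin's LLS is the LLS of its merged
counts).  The fitted mapping then assigns an LLS to every pair - including
pairs the gold standard cannot label - by interpolating on raw score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .exceptions import CalibrationError, ValidationError
from .evidence import EvidenceTable
from .netio import DataNetwork, GoldStandard

DEFAULT_BIN_SIZE = 1000
DEFAULT_PSEUDOCOUNT = 0.5


def lls(p: float, n: float, P: float, N: float, pseudocount: float = 0.0) -> float:
    """Log-likelihood score of a bin with ``p`` positives and ``n`` negatives.

    ``P`` and ``N`` are the gold standard's total positive and negative pair
    counts.  A symmetric pseudocount keeps the score finite when a bin has a
    zero cell.
    """
    if P <= 0 or N <= 0:
        raise ValidationError("gold-standard totals P and N must be positive")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if p + n <= 0:
        raise ValidationError("bin must contain at least one evaluable pair")
    if pseudocount == 0 and (p == 0 or n == 0):
        raise ValidationError(
            "zero cell with zero pseudocount gives an infinite LLS"
        )
    return math.log(((p + pseudocount) / (n + pseudocount)) / (P / N))


@dataclass
class BinStat:
    """One rank bin of the benchmarking process."""

    bin_index: int
    pair_count: int
    pos: int
    neg: int
    mean_raw: float
    lls: float


@dataclass
class CalibrationModel:
    """A fitted raw-score -> LLS mapping with its bin statistics.

    ``bins`` are the monotone (pooled) bins in rank order; the piecewise
    linear map interpolates LLS between bin mean raw scores and clamps
    beyond the first/last bin.
    """

    bins: list[BinStat]
    prior_pos: int
    prior_neg: int
    bin_size: int
    pseudocount: float
    tag: str = "evidence"
    # interpolation knots, ascending in raw score
    _knots_x: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    _knots_y: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def __post_init__(self) -> None:
        if len(self._knots_x) == 0 and self.bins:
            xs = [b.mean_raw for b in reversed(self.bins)]
            ys = [b.lls for b in reversed(self.bins)]
            self._knots_x = np.asarray(xs, dtype=float)
            self._knots_y = np.asarray(ys, dtype=float)

    def score(self, raw: float) -> float:
        """LLS for a raw evidence score via the monotone piecewise-linear map."""
        if len(self._knots_x) == 0:
            raise CalibrationError("model has no bins")
        return float(np.interp(raw, self._knots_x, self._knots_y))

    def score_many(self, raw: np.ndarray) -> np.ndarray:
        if len(self._knots_x) == 0:
            raise CalibrationError("model has no bins")
        return np.interp(np.asarray(raw, dtype=float), self._knots_x, self._knots_y)

    def save(self, path: str | Path) -> None:
        """Serialize as a YAML-commented header plus TSV bin rows."""
        head = yaml.safe_dump(
            {
                "prior_pos": self.prior_pos,
                "prior_neg": self.prior_neg,
                "bin_size": self.bin_size,
                "pseudocount": self.pseudocount,
                "tag": self.tag,
            },
            sort_keys=True,
        )
        with open(path, "w") as fh:
            for line in head.strip().splitlines():
                fh.write(f"# {line}\n")
            fh.write("# bin_index\tpair_count\tpos\tneg\tmean_raw\tlls\n")
            for b in self.bins:
                fh.write(
                    f"{b.bin_index}\t{b.pair_count}\t{b.pos}\t{b.neg}\t"
                    f"{b.mean_raw:.10g}\t{b.lls:.10g}\n"
                )

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        header_lines: list[str] = []
        bins: list[BinStat] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    stripped = line[1:].strip()
                    if "\t" not in stripped:  # column-name comment has tabs
                        header_lines.append(stripped)
                    continue
                idx, count, pos, neg, mean_raw, lls_val = line.split("\t")
                bins.append(
                    BinStat(int(idx), int(count), int(pos), int(neg),
                            float(mean_raw), float(lls_val))
                )
        meta = yaml.safe_load("\n".join(header_lines)) or {}
        return cls(
            bins=bins,
            prior_pos=int(meta["prior_pos"]),
            prior_neg=int(meta["prior_neg"]),
            bin_size=int(meta["bin_size"]),
            pseudocount=float(meta["pseudocount"]),
            tag=str(meta.get("tag", "evidence")),
        )


def _pool_adjacent_violators(
    blocks: list[dict], P: int, N: int, pseudocount: float
) -> list[dict]:
    """Merge adjacent bins until LLS is non-increasing in rank order.

    A merged block's LLS is recomputed from its summed positive/negative
    counts, and its raw-score knot is the count-weighted mean.
    """
    pooled: list[dict] = []
    for block in blocks:
        pooled.append(dict(block))
        while len(pooled) >= 2 and pooled[-1]["lls"] > pooled[-2]["lls"]:
            hi = pooled.pop()
            lo = pooled.pop()
            count = lo["pair_count"] + hi["pair_count"]
            merged = {
                "pair_count": count,
                "pos": lo["pos"] + hi["pos"],
                "neg": lo["neg"] + hi["neg"],
                "mean_raw": (
                    lo["mean_raw"] * lo["pair_count"]
                    + hi["mean_raw"] * hi["pair_count"]
                ) / count,
            }
            merged["lls"] = lls(merged["pos"], merged["neg"], P, N, pseudocount)
            pooled.append(merged)
    return pooled


def calibrate(
    ev: EvidenceTable,
    gold: GoldStandard,
    bin_size: int = DEFAULT_BIN_SIZE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> CalibrationModel:
    """Fit a monotone raw-score -> LLS calibration against a gold standard.

    Evidence pairs are sorted by descending raw score (ties broken by
    canonical pair order); gold-evaluable pairs are grouped into consecutive
    bins of ``bin_size``; each bin's LLS is computed against the gold
    priors; adjacent bins violating monotonicity are pooled.
    """
    if len(ev) == 0:
        raise CalibrationError("empty evidence table")
    if bin_size < 2:
        raise ValidationError("bin_size must be >= 2")
    if gold.n_pos == 0 or gold.n_neg == 0:
        raise CalibrationError(
            "gold standard must contain both positives and negatives"
        )
    evaluable = [
        (pair, raw, gold.label(pair))
        for pair, raw in ev.sorted_rows()
        if gold.label(pair) is not None
    ]
    if not evaluable:
        raise CalibrationError("no gold-evaluable pairs in evidence table")

    P, N = gold.n_pos, gold.n_neg
    blocks: list[dict] = []
    for start in range(0, len(evaluable), bin_size):
        chunk = evaluable[start:start + bin_size]
        pos = sum(1 for _, _, lab in chunk if lab)
        neg = len(chunk) - pos
        mean_raw = float(np.mean([raw for _, raw, _ in chunk]))
        blocks.append(
            {
                "pair_count": len(chunk),
                "pos": pos,
                "neg": neg,
                "mean_raw": mean_raw,
                "lls": lls(pos, neg, P, N, pseudocount),
            }
        )
    pooled = _pool_adjacent_violators(blocks, P, N, pseudocount)
    # collapse knots that landed on the same raw score so the map stays a function
    deduped: list[dict] = []
    for block in pooled:
        if deduped and math.isclose(block["mean_raw"], deduped[-1]["mean_raw"]):
            lo = deduped.pop()
            count = lo["pair_count"] + block["pair_count"]
            block = {
                "pair_count": count,
                "pos": lo["pos"] + block["pos"],
                "neg": lo["neg"] + block["neg"],
                "mean_raw": lo["mean_raw"],
                "lls": lls(lo["pos"] + block["pos"], lo["neg"] + block["neg"],
                           P, N, pseudocount),
            }
        deduped.append(block)
    bins = [
        BinStat(i, b["pair_count"], b["pos"], b["neg"], b["mean_raw"], b["lls"])
        for i, b in enumerate(deduped)
    ]
    return CalibrationModel(
        bins=bins,
        prior_pos=P,
        prior_neg=N,
        bin_size=bin_size,
        pseudocount=pseudocount,
        tag=ev.tag,
    )


def apply_calibration(model: CalibrationModel, ev: EvidenceTable) -> DataNetwork:
    """Score every evidence pair through the fitted map; keep LLS > 0 edges.

    Pairs the gold standard could not label inherit an LLS through the raw
    score, so calibration generalizes beyond the benchmark.  Edges with
    LLS <= 0 (no better than a random pair) are dropped.
    """
    if not model.bins:
        raise CalibrationError("model has no bins")
    edges = {}
    if len(ev) == 0:
        return DataNetwork(tag=model.tag, edges=edges)
    pairs = [pair for pair, _ in ev.rows]
    raws = np.array([raw for _, raw in ev.rows], dtype=float)
    scores = model.score_many(raws)
    for pair, score in zip(pairs, scores):
        if score > 0:
            edges[pair] = float(score)
    return DataNetwork(tag=model.tag, edges=edges)
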