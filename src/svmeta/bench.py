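"""Benchmarking SV call sets against a truth set.

The matching protocol mirrors standard SV benchmarking practice (Truvari
defaults with sequence comparison disabled): a call matches a truth record
of the same type when both breakpoints fall within ``ref_dist`` and the
size similarity min(len)/max(len) reaches ``size_similarity_min``.
Assignment is one-to-one and greedy by ascending breakpoint distance with
documented tie-breaks, so results are deterministic. A truth record missed
by every caller counts as a false negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import AUTOSOMES, GenomeRegions, SVType


class _Interval(Protocol):
    id: str
    chrom: str
    pos: int
    end: int
    svtype: SVType
    svlen: int


@dataclass(frozen=True)
class MatchParams:
    ref_dist: int = 500
    size_similarity_min: float = 0.7
    restrict_regions: Optional[GenomeRegions] = None
    autosomes_only: bool = False

    def __post_init__(self) -> None:
        if self.ref_dist < 0:
            raise ValueError("ref_dist must be >= 0")
        if not (0.0 <= self.size_similarity_min <= 1.0):
            raise ValueError("size_similarity_min must lie in [0, 1]")


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp != len(self.pairs):
            raise ValueError("tp must equal the number of matched pairs")


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class BenchmarkMetrics:
    precision: float
    recall: float
    f1: float
    auc: Optional[float] = None
    accuracy: Optional[float] = None

    def rounded(self) -> "BenchmarkMetrics":
        """Report-time half-up rounding to 2 decimals (full precision is
        kept internally)."""
        return BenchmarkMetrics(
            precision=_round2(self.precision),
            recall=_round2(self.recall),
            f1=_round2(self.f1),
            auc=None if self.auc is None else _round2(self.auc),
            accuracy=None if self.accuracy is None else _round2(self.accuracy),
        )


def _evaluated(records: Sequence[_Interval], params: MatchParams) -> list[_Interval]:
    out = []
    for r in records:
        if params.autosomes_only and r.chrom not in AUTOSOMES:
            continue
        if params.restrict_regions is not None and not params.restrict_regions.contains_call(
            r.chrom, r.pos, r.end
        ):
            continue
        out.append(r)
    return out


def match_to_truth(
    calls: Sequence[_Interval],
    truth: Sequence[_Interval],
    params: MatchParams = MatchParams(),
) -> MatchResult:
    """One-to-one assignment of calls to truth records.

    Candidate pairs require same contig and SV type, both breakpoint
    distances <= ``ref_dist`` and size similarity >= ``size_similarity_min``.
    Pairs are consumed by ascending total breakpoint distance
    (|Δpos| + |Δend|), ties resolved by smaller truth pos then smaller call
    pos, then record IDs.
    """
    truth_ids = [t.id for t in truth]
    if len(truth_ids) != len(set(truth_ids)):
        raise ValueError("duplicated truth record IDs")

    calls = _evaluated(calls, params)
    truth = _evaluated(truth, params)

    by_key: dict[tuple[str, str], list[tuple[int, _Interval]]] = {}
    for j, t in enumerate(truth):
        by_key.setdefault((t.chrom, t.svtype.value), []).append((j, t))
    for key in by_key:
        by_key[key].sort(key=lambda jt: jt[1].pos)

    candidates: list[tuple[int, int, int, str, str, int, int]] = []
    for i, c in enumerate(calls):
        for j, t in by_key.get((c.chrom, c.svtype.value), ()):
            dpos = abs(c.pos - t.pos)
            if dpos > params.ref_dist:
                continue
            dend = abs(c.end - t.end)
            if dend > params.ref_dist:
                continue
            lo, hi = sorted((c.svlen, t.svlen))
            if hi == 0 or lo / hi < params.size_similarity_min:
                continue
            candidates.append((dpos + dend, t.pos, c.pos, t.id, c.id, i, j))

    candidates.sort(key=lambda x: x[:5])
    used_calls: set[int] = set()
    used_truth: set[int] = set()
    pairs: list[tuple[str, str]] = []
    for _, _, _, tid, cid, i, j in candidates:
        if i in used_calls or j in used_truth:
            continue
        used_calls.add(i)
        used_truth.add(j)
        pairs.append((cid, tid))

    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(calls) - tp, fn=len(truth) - tp, pairs=pairs)


def compute_metrics(result: MatchResult) -> BenchmarkMetrics:
    """Precision, recall and F1 = 2·TP / (2·TP + FP + FN); empty
    denominators yield 0 by convention. Values are full precision; use
    :meth:`BenchmarkMetrics.rounded` for report formatting."""
    tp, fp, fn = result.tp, result.fp, result.fn
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else 0.0
    return BenchmarkMetrics(precision=precision, recall=recall, f1=f1)


def roc_auc(probabilities: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve via the rank-statistic (Mann-Whitney) form.

    Equals the probability that a random positive outranks a random
    negative, with ties counting one half.
    """
    scores = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC is undefined with a single class")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def decile_report(
    probabilities: Sequence[float], labels: Sequence[bool]
) -> pd.DataFrame:
    """Call counts and TP proportion per prediction-probability decile.

    Bins are [0,0.1), [0.1,0.2), ..., [0.9,1.0] with the top bin closed so a
    probability of exactly 1.0 lands in the highest decile. Bin sizes sum to
    n and fractions to 1.
    """
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    idx = np.minimum((probs * 10).astype(int), 9)
    rows = []
    n = probs.size
    for b in range(10):
        mask = idx == b
        n_bin = int(mask.sum())
        rows.append(
            {
                "decile": f"[{b / 10:.1f},{(b + 1) / 10:.1f}{']' if b == 9 else ')'}",
                "n_calls": n_bin,
                "fraction": n_bin / n if n else 0.0,
                "tp_proportion": float(y[mask].mean()) if n_bin else np.nan,
            }
        )
    return pd.DataFrame(rows)
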