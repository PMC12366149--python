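"""Breakpoint-proximity clustering of multi-caller SV calls.

Calls of identical type on the same contig are linked whenever *both*
breakpoints lie within ``max_dist`` of each other, and clusters are the
connected components of that link relation (transitive closure), the
graph-based contract of the SURVIVOR merge utility. Requiring both
breakpoints prevents chaining a short deletion to a long one that shares a
single breakpoint. The result is deterministic and independent of input
ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import ConsensusCall, SVCall, SVType
from .vcf_io import _chrom_sort_key


@dataclass(frozen=True)
class MergeParams:
    """Clustering parameters.

    max_dist:
        maximum breakpoint distance (bp) for two calls to be linked; applies
        to start and end independently.
    require_type_match:
        link only calls of identical SV type.
    min_support:
        minimum number of distinct callers per retained cluster; the default
        of 1 keeps single-caller calls in the union so the classifier — not
        a vote count — decides their fate.
    min_svlen:
        calls shorter than this never enter a cluster.
    """

    max_dist: int = 1000
    require_type_match: bool = True
    min_support: int = 1
    min_svlen: int = 50

    def __post_init__(self) -> None:
        if self.max_dist < 0:
            raise ValueError("max_dist must be >= 0")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _lower_median(values: list[int]) -> int:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def merge_calls(
    calls_by_caller: dict[str, list[SVCall]],
    params: MergeParams = MergeParams(),
) -> list[ConsensusCall]:
    """Cluster calls from multiple callers into consensus calls.

    Representative coordinates (pos, end, svlen) are the member-wise lower
    median. When one caller contributes several calls to a cluster, the one
    closest to the representative coordinates becomes that caller's feature
    source (``representatives``); every member ID is retained regardless.
    """
    # canonical ordering makes the clustering independent of dict/list order
    calls = sorted(
        (c for lst in calls_by_caller.values() for c in lst if c.svlen >= params.min_svlen),
        key=lambda c: (
            _chrom_sort_key(c.chrom), c.svtype.value, c.pos, c.end, c.caller, c.id,
        ),
    )

    groups: dict[tuple, list[int]] = {}
    for idx, call in enumerate(calls):
        key = (call.chrom, call.svtype.value) if params.require_type_match else (call.chrom,)
        groups.setdefault(key, []).append(idx)

    uf = _UnionFind(len(calls))
    for indices in groups.values():
        # indices are pos-sorted within a group; sweep a max_dist window
        for a, i in enumerate(indices):
            ci = calls[i]
            for j in indices[a + 1:]:
                cj = calls[j]
                if cj.pos - ci.pos > params.max_dist:
                    break
                if abs(cj.end - ci.end) <= params.max_dist:
                    uf.union(i, j)

    clusters: dict[int, list[SVCall]] = {}
    for idx in range(len(calls)):
        clusters.setdefault(uf.find(idx), []).append(calls[idx])

    out: list[ConsensusCall] = []
    for members in clusters.values():
        callers = {m.caller for m in members}
        if len(callers) < params.min_support:
            continue
        pos = _lower_median([m.pos for m in members])
        end = _lower_median([m.end for m in members])
        # DEL length follows the representative span so end - pos + 1 and
        # svlen stay mutually consistent; INS length is the member median
        if members[0].svtype is SVType.DEL:
            svlen = end - pos + 1
        else:
            svlen = _lower_median([m.svlen for m in members])
        reps: dict[str, SVCall] = {}
        for m in sorted(members, key=lambda m: (abs(m.pos - pos) + abs(m.end - end), m.id)):
            reps.setdefault(m.caller, m)
        out.append(
            ConsensusCall(
                id="",
                chrom=members[0].chrom,
                pos=pos,
                end=end,
                svtype=members[0].svtype,
                svlen=svlen,
                members=sorted((m.caller, m.id) for m in members),
                representatives=reps,
            )
        )

    out.sort(key=lambda c: (_chrom_sort_key(c.chrom), c.pos, c.end, c.svtype.value))
    for i, cons in enumerate(out):
        cons.id = f"cons_{cons.svtype.value}_{i:05d}"
    return out


def union_counts(consensus: list[ConsensusCall]) -> dict[str, int]:
    """Number of consensus entries per SV type (the "union" call counts)."""
    counts = {SVType.DEL.value: 0, SVType.INS.value: 0}
    for call in consensus:
        counts[call.svtype.value] += 1
    return counts
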