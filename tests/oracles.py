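"""Independent reference implementations used only to check the package."""

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


def brute_force_clusters(calls, max_dist, require_type_match=True):
    """All-pairs transitive-closure clustering, independent of the sweep
    implementation: build the full pairwise link matrix and take connected
    components. Returns a set of frozensets of call ids."""
    n = len(calls)
    if n == 0:
        return set()
    chrom = np.array([c.chrom for c in calls])
    svt = np.array([c.svtype.value for c in calls])
    pos = np.array([c.pos for c in calls])
    end = np.array([c.end for c in calls])
    link = (
        (chrom[:, None] == chrom[None, :])
        & (np.abs(pos[:, None] - pos[None, :]) <= max_dist)
        & (np.abs(end[:, None] - end[None, :]) <= max_dist)
    )
    if require_type_match:
        link &= svt[:, None] == svt[None, :]
    ii, jj = np.nonzero(link)
    graph = coo_matrix((np.ones_like(ii), (ii, jj)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    clusters = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(lab, set()).add(calls[idx].id)
    return {frozenset(s) for s in clusters.values()}


def random_calls(rng, n, max_dist=1000):
    """Random SV calls on a couple of contigs, dense enough to create
    nontrivial cluster structure at the given merge distance."""
    from svmeta.types import SVCall, SVType

    calls = []
    for i in range(n):
        chrom = str(rng.integers(1, 3))
        svtype = SVType.DEL if rng.random() < 0.6 else SVType.INS
        pos = int(rng.integers(1, 50_000))
        svlen = int(rng.integers(50, 5000))
        end = pos + svlen - 1 if svtype is SVType.DEL else pos
        calls.append(
            SVCall(
                id=f"r{i}",
                caller=f"caller{rng.integers(0, 4)}",
                chrom=chrom,
                pos=pos,
                end=end,
                svtype=svtype,
                svlen=svlen,
            )
        )
    return calls


def merged_cluster_ids(consensus):
    return {frozenset(mid for _, mid in c.members) for c in consensus}
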