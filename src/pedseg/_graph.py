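"""Thin min-cut wrapper shared by the surface search and the graph cut.

Capacities are given on explicit directed edges (antiparallel pairs and
duplicates allowed; duplicates add). Max-flow runs on integer capacities
(scipy's Dinic implementation): finite capacities are scaled so that their
sum fits a 2^30 budget, which keeps the total flow well inside int32 while
leaving ~7 significant digits per edge; hard-constraint capacities map to
the int32 maximum. Because capacities are integral, the residual graph is
exact, and a BFS over it yields the *minimal* source side — the
deterministic tie-break (minimal closed set / pointwise-smallest surface
in the Li-style reduction).
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

_BUDGET = float(2**30)
_HARD = np.int32(2**31 - 1)


def min_st_cut(n_nodes: int, tails: np.ndarray, heads: np.ndarray,
               caps: np.ndarray, source: int, sink: int,
               inf: float | None = None) -> np.ndarray:
    """Boolean array marking the minimal source side of a min s-t cut.

    ``caps >= inf`` (when ``inf`` is given) are treated as uncuttable hard
    constraints. The cut over finite capacities must be feasible, i.e. the
    hard constraints alone must not connect source to sink.
    """
    tails = np.asarray(tails, dtype=np.int64)
    heads = np.asarray(heads, dtype=np.int64)
    caps = np.asarray(caps, dtype=np.float64)

    hard = np.zeros(caps.shape, dtype=bool) if inf is None else caps >= inf
    finite_sum = caps[~hard].sum()
    scale = _BUDGET / finite_sum if finite_sum > 0 else 1.0
    ci = np.rint(caps * scale)
    ci[hard] = _HARD
    ci = np.clip(ci, 0, _HARD).astype(np.int64)

    keep = ci > 0
    cap_mat = csr_matrix(
        (ci[keep], (tails[keep], heads[keep])), shape=(n_nodes, n_nodes),
        dtype=np.int64,
    )
    cap_mat.sum_duplicates()
    cap_mat.data = np.minimum(cap_mat.data, np.int64(_HARD))  # overflow guard
    cap_mat = cap_mat.astype(np.int32)
    flow = maximum_flow(cap_mat, source, sink).flow

    # union sparsity: reverse residuals included; int64 guards against
    # overflow when a hard edge carries reverse flow
    residual = cap_mat.astype(np.int64) - flow.astype(np.int64)
    residual.data = np.where(residual.data > 0, residual.data, 0)
    residual.eliminate_zeros()
    order = breadth_first_order(residual, source, directed=True,
                                return_predecessors=False)
    side = np.zeros(n_nodes, dtype=bool)
    side[order] = True
    return side
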