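"""Low-level CTMC machinery: transition matrices and pruning.

The pruning (post-order) likelihood kernel is jitted with numba; it is
generic over the number of states, so the same kernel serves the 4-state
paired-trait models and the 2-state marginals used as cross-checks.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.linalg import expm

__all__ = ["transition_matrices", "prune", "tree_arrays"]


def transition_matrices(Q: np.ndarray, branch_lengths: np.ndarray) -> np.ndarray:
    """``expm(Q * b)`` for every branch length, via one eigendecomposition
    of ``Q`` (with an expm fallback when Q is near-defective)."""
    Q = np.asarray(Q, dtype=float)
    b = np.asarray(branch_lengths, dtype=float)
    k = Q.shape[0]
    try:
        w, U = np.linalg.eig(Q)
        Uinv = np.linalg.inv(U)
        recon = (U * w) @ Uinv
        if not np.allclose(recon.real, Q, atol=1e-8 * max(1.0, np.abs(Q).max())):
            raise np.linalg.LinAlgError
        E = np.exp(np.multiply.outer(b, w))          # (n_b, k)
        P = ((U[None, :, :] * E[:, None, :]) @ Uinv).real
    except np.linalg.LinAlgError:
        P = np.stack([expm(Q * bi) for bi in b])
    np.clip(P, 0.0, None, out=P)
    # renormalise rows (roundoff from the complex eigensystem)
    P /= P.sum(axis=2, keepdims=True)
    return P


def tree_arrays(phylo) -> dict:
    """Flatten a Phylogeny into postorder arrays for the pruning kernel.

    Returns node order (postorder, root last), per-node branch lengths,
    child adjacency in CSR-style (child_ptr, child_idx), leaf flags and
    the tip-label order of leaf nodes.
    """
    nodes = list(phylo.tree.postorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    blen = np.zeros(n)
    is_leaf = np.zeros(n, dtype=np.bool_)
    child_ptr = np.zeros(n + 1, dtype=np.int64)
    child_idx = []
    leaf_labels = []
    for i, node in enumerate(nodes):
        blen[i] = node.edge.length or 0.0
        kids = node.child_nodes()
        is_leaf[i] = not kids
        child_ptr[i + 1] = child_ptr[i] + len(kids)
        child_idx.extend(index[id(c)] for c in kids)
        if not kids:
            leaf_labels.append(node.taxon.label)
    return {"blen": blen, "is_leaf": is_leaf,
            "child_ptr": child_ptr,
            "child_idx": np.asarray(child_idx, dtype=np.int64),
            "leaf_labels": leaf_labels}


@njit(cache=True)
def prune(child_ptr, child_idx, is_leaf, tip_partials, P):
    """Felsenstein pruning over a postorder node array.

    ``tip_partials`` is (n_nodes, k) holding one-hot (or ambiguous)
    likelihoods at leaves; ``P[i]`` is the transition matrix on the edge
    above node ``i``. Returns the root partial-likelihood vector and the
    accumulated log scaling factor (log L_i = log(partial[i]) + logscale).
    """
    n, k = tip_partials.shape
    partial = np.zeros((n, k))
    logscale = 0.0
    for i in range(n):
        if is_leaf[i]:
            partial[i] = tip_partials[i]
        else:
            acc = np.ones(k)
            for c in range(child_ptr[i], child_ptr[i + 1]):
                j = child_idx[c]
                for a in range(k):
                    s = 0.0
                    for b in range(k):
                        s += P[j, a, b] * partial[j, b]
                    acc[a] *= s
            s = acc.sum()
            if s <= 0.0:
                return acc, -np.inf
            partial[i] = acc / s
            logscale += np.log(s)
    return partial[n - 1], logscale
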