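"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (exact integer arithmetic, exhaustive
enumeration, O(n^3) loops) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import scipy.linalg


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exact hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (exact integer
    comparison of numerators over the common denominator).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    num_obs = comb(r1, a) * comb(r2, c)
    total = 0
    for x in range(lo, hi + 1):
        num = comb(r1, x) * comb(r2, c1 - x)
        if num <= num_obs:
            total += num
    return total / comb(n, c1)


def pruning_loglik_bruteforce(tree, trait_matrix, model, root_prior="uniform"):
    """Tree likelihood by explicit summation over internal-node joint states."""
    from cooccur_phylo.markov import stationary_distribution

    Q = model.generator()
    nodes = list(tree.postorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    if root_prior == "uniform":
        prior = np.full(4, 0.25)
    else:
        prior = stationary_distribution(Q)
    x, y = trait_matrix.trait_ids
    tip_state = {
        g: 2 * int(trait_matrix.values[x][g]) + int(trait_matrix.values[y][g])
        for g in trait_matrix.genome_ids
    }
    edge_P = {
        id(nd): scipy.linalg.expm(Q * (nd.edge.length or 0.0))
        for nd in nodes
        if nd.parent_node is not None
    }
    root = tree.seed_node
    total = 0.0
    for assign in itertools.product(range(4), repeat=len(internal)):
        state = {id(nd): s for nd, s in zip(internal, assign)}
        for nd in nodes:
            if nd.is_leaf():
                state[id(nd)] = tip_state[nd.taxon.label]
        p = prior[state[id(root)]]
        for nd in nodes:
            if nd.parent_node is None:
                continue
            p *= edge_P[id(nd)][state[id(nd.parent_node)], state[id(nd)]]
        total += p
    return np.log(total) if total > 0 else -np.inf


def single_linkage_bruteforce(X: np.ndarray):
    """Naive O(n^3) single-linkage clustering on Euclidean distances.

    Returns (sorted merge distances, cophenetic distance matrix).  Both
    outputs are invariant to tie-breaking, so they can be compared against
    any correct single-linkage implementation.
    """
    n = X.shape[0]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    clusters = [{i} for i in range(n)]
    coph = np.zeros((n, n))
    merge_distances = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = min(D[a, b] for a in clusters[i] for b in clusters[j])
                if d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merge_distances.append(d)
        for a in clusters[i]:
            for b in clusters[j]:
                coph[a, b] = coph[b, a] = d
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return sorted(merge_distances), coph
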