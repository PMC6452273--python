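"""Simulation of trees and binary trait data for pipeline calibration.

The generators here emulate the statistical structure the association
pipeline assumes: a rooted ultrametric phylogeny (pure-birth), pairs of
binary traits evolving along it under independent or dependent gain/loss
Markov models, phylogeny-free background (control) genes at chosen
frequencies, and branch-length-jittered copies of a tree standing in for
bootstrap replicates of a phylogenetic reconstruction.

All generators are seeded: the same seed yields byte-identical output.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd

from cooccur_phylo.markov import PairRateModel, transition_matrices
from cooccur_phylo.trait_io import TraitMatrix

__all__ = [
    "PairRateModel",
    "simulate_tree",
    "simulate_pair_traits",
    "simulate_controls",
    "simulate_correlated_pair",
    "jitter_trees",
]


def simulate_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """Simulate a rooted ultrametric pure-birth (Yule) tree.

    Starting from two lineages at the root, each extant lineage splits at
    rate ``birth_rate``; once ``n_tips`` lineages exist the process runs for
    one further exponential waiting time (the time to the next, unrealised,
    split) and all tips are sampled at that instant.  Expected root-to-tip
    depth is therefore sum_{k=2..n} 1/(k*birth_rate).  Tips are labelled
    ``g1 .. g<n>``.
    """
    if n_tips < 2:
        raise ValueError(f"n_tips must be >= 2, got {n_tips}")
    if birth_rate <= 0:
        raise ValueError(f"birth_rate must be > 0, got {birth_rate}")
    rng = np.random.default_rng(seed)

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.is_rooted = True
    root = tree.seed_node

    t = 0.0
    # active lineage = (node, time at which its edge started)
    active = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, t))

    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        node, start = active.pop(idx)
        node.edge.length = t - start
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    # final waiting time with all n lineages extant
    t += rng.exponential(1.0 / (n_tips * birth_rate))

    for i, (node, start) in enumerate(active):
        node.edge.length = t - start
        node.taxon = taxon_namespace.new_taxon(label=f"g{i + 1}")
    root.edge.length = None
    return tree


def simulate_pair_traits(
    tree: dendropy.Tree,
    model: PairRateModel,
    root_state="uniform",
    seed: int = 0,
    trait_ids: tuple[str, str] = ("sys1", "cas1"),
    groups: tuple[str, str] = ("system", "cas"),
) -> TraitMatrix:
    """Evolve a pair of binary traits down a tree under a Markov model.

    The 4-state joint chain (states (0,0), (0,1), (1,0), (1,1)) starts at
    the root either from the uniform distribution (``root_state="uniform"``),
    from the model's stationary distribution (``"stationary"``), or from a
    fixed pair, e.g. ``root_state=(1, 1)``.  Each branch transitions with
    probability matrix exp(Q*t).
    """
    rng = np.random.default_rng(seed)
    Q = model.generator()

    if root_state == "uniform":
        probs = np.full(4, 0.25)
        state0 = int(rng.choice(4, p=probs))
    elif root_state == "stationary":
        from cooccur_phylo.markov import stationary_distribution

        probs = stationary_distribution(Q)
        state0 = int(rng.choice(4, p=probs))
    else:
        x, y = root_state
        if x not in (0, 1) or y not in (0, 1):
            raise ValueError(f"fixed root state must be binary pair, got {root_state}")
        state0 = 2 * int(x) + int(y)

    nodes = list(tree.preorder_node_iter())
    lengths = np.array(
        [n.edge.length or 0.0 for n in nodes[1:]], dtype=float
    )
    P = transition_matrices(Q, lengths)
    cum = P.cumsum(axis=2)

    state = {id(nodes[0]): state0}
    rows = {}
    for i, node in enumerate(nodes[1:]):
        s_parent = state[id(node.parent_node)]
        u = rng.random()
        s = int(np.searchsorted(cum[i, s_parent], u, side="right"))
        s = min(s, 3)
        state[id(node)] = s
        if node.is_leaf():
            rows[node.taxon.label] = (s >> 1, s & 1)
    if nodes[0].is_leaf():  # degenerate single-node tree is rejected upstream
        raise ValueError("tree has no branches")

    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    values = pd.DataFrame(
        [rows[g] for g in labels], index=labels, columns=list(trait_ids), dtype=int
    )
    return TraitMatrix(values, pd.Series(list(groups), index=list(trait_ids)))


def simulate_controls(
    genome_ids,
    frequencies,
    seed: int = 0,
    prefix: str = "ctrl",
    mode: str = "bernoulli",
    tree: dendropy.Tree | None = None,
    total_rate: float = 1.0,
) -> TraitMatrix:
    """Control genes at chosen frequencies.

    ``mode="bernoulli"`` (default): column ``j`` is drawn i.i.d.
    Bernoulli(frequencies[j]) across genomes — a phylogeny-free null that
    isolates the frequency-matching screen from the phylogenetic test.

    ``mode="on_tree"``: each control evolves down ``tree`` as a two-state
    chain with gain/loss rates tuned so its stationary frequency equals the
    target (gain = f*total_rate, loss = (1-f)*total_rate) and the root drawn
    from that stationary law, giving controls the same phylogenetic
    autocorrelation as real background genes.
    """
    genome_ids = list(genome_ids)
    frequencies = np.asarray(list(frequencies), dtype=float)
    if frequencies.ndim != 1:
        raise ValueError("frequencies must be a 1-d sequence")
    if np.any((frequencies < 0) | (frequencies > 1)):
        bad = frequencies[(frequencies < 0) | (frequencies > 1)][0]
        raise ValueError(f"frequency outside [0, 1]: {bad}")
    trait_ids = [f"{prefix}{j + 1}" for j in range(len(frequencies))]
    if mode == "bernoulli":
        rng = np.random.default_rng(seed)
        values = (
            rng.random((len(genome_ids), len(frequencies))) < frequencies
        ).astype(int)
        df = pd.DataFrame(values, index=genome_ids, columns=trait_ids)
        return TraitMatrix(df, pd.Series("control", index=trait_ids))
    if mode == "on_tree":
        if tree is None:
            raise ValueError("mode='on_tree' requires a tree")
        columns = {}
        for j, (f, trait) in enumerate(zip(frequencies, trait_ids)):
            # a single binary trait: embed as trait X of an independent pair
            m = simulate_pair_traits(
                tree,
                PairRateModel.independent(
                    f * total_rate, (1 - f) * total_rate, 1.0, 1.0
                ),
                root_state="stationary",
                seed=np.random.SeedSequence([int(seed), j]).generate_state(1)[0]
                & 0x7FFFFFFF,
                trait_ids=(trait, f"_{trait}_aux"),
            )
            columns[trait] = m.values[trait]
        df = pd.DataFrame(columns).loc[genome_ids]
        return TraitMatrix(df, pd.Series("control", index=trait_ids))
    raise ValueError(f"unknown mode {mode!r}; use 'bernoulli' or 'on_tree'")


def simulate_correlated_pair(
    genome_ids,
    p_x: float,
    p_y: float,
    phi: float,
    seed: int = 0,
    trait_ids: tuple[str, str] = ("sys1", "cas1"),
    groups: tuple[str, str] = ("system", "cas"),
) -> TraitMatrix:
    """Phylogeny-free pair of binary traits with a planted phi coefficient.

    Draws (X, Y) i.i.d. across genomes from the bivariate Bernoulli with
    marginals ``p_x``, ``p_y`` and correlation ``phi`` (cell probability
    P(X=1,Y=1) = p_x*p_y + phi*sqrt(p_x(1-p_x)p_y(1-p_y))).  Raises if the
    requested phi is infeasible for the given marginals.
    """
    genome_ids = list(genome_ids)
    sd = np.sqrt(p_x * (1 - p_x) * p_y * (1 - p_y))
    p11 = p_x * p_y + phi * sd
    p10 = p_x - p11
    p01 = p_y - p11
    p00 = 1.0 - p11 - p10 - p01
    cells = np.array([p00, p01, p10, p11])
    if np.any(cells < -1e-12):
        raise ValueError(
            f"phi={phi} infeasible for marginals p_x={p_x}, p_y={p_y}"
        )
    cells = np.clip(cells, 0.0, None)
    cells /= cells.sum()
    rng = np.random.default_rng(seed)
    states = rng.choice(4, size=len(genome_ids), p=cells)
    values = pd.DataFrame(
        {trait_ids[0]: (states >> 1) & 1, trait_ids[1]: states & 1},
        index=genome_ids,
        dtype=int,
    )
    return TraitMatrix(values, pd.Series(list(groups), index=list(trait_ids)))


def jitter_trees(
    tree: dendropy.Tree, n: int, length_cv: float, seed: int = 0
) -> list[dendropy.Tree]:
    """Branch-length-jittered copies of a tree (bootstrap stand-ins).

    Each branch length is multiplied by an independent lognormal factor with
    mean 1 and coefficient of variation ``length_cv``; topology is
    unchanged.  ``length_cv=0`` returns exact copies.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if length_cv < 0:
        raise ValueError(f"length_cv must be >= 0, got {length_cv}")
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(length_cv**2)
    sigma = np.sqrt(sigma2)
    mu = -0.5 * sigma2
    out = []
    for _ in range(n):
        copy = tree.clone(depth=1)
        for edge in copy.preorder_edge_iter():
            if edge.length is not None:
                factor = rng.lognormal(mean=mu, sigma=sigma) if sigma > 0 else 1.0
                edge.length = edge.length * factor
        out.append(copy)
    return out
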