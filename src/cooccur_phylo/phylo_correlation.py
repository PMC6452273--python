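"""Phylogeny-aware test of correlated evolution between two binary traits.

Implements the classic likelihood-ratio test for correlated evolution of
discrete characters: maximum-likelihood fits of the 4-parameter independent
and 8-parameter dependent gain/loss Markov models on a rooted tree
(likelihoods by Felsenstein pruning over the four joint states), a
likelihood-ratio test referenced to chi-square with 4 degrees of freedom,
and a bootstrap-tree decision rule that calls a pair significant when the
median LRT p-value across a set of trees falls below a threshold.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import scipy.optimize
import scipy.stats

from cooccur_phylo.markov import (
    PairRateModel,
    stationary_distribution,
    transition_matrices,
    two_state_transition_matrices,
    DEPENDENT_RATE_NAMES,
    INDEPENDENT_RATE_NAMES,
)
from cooccur_phylo.trait_io import TraitMatrix, reconcile

LOG_RATE_MIN = math.log(1e-8)
LOG_RATE_MAX = math.log(1e3)
_PENALTY = 1e12  # stands in for -inf log-likelihood inside the optimizer

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True)
def _prune_kernel(parent: np.ndarray, P: np.ndarray, L: np.ndarray) -> float:
    """Post-order pruning pass; returns accumulated log scaling factor.

    ``L`` holds partial likelihoods per node (tips pre-set to indicator
    rows, internal nodes to ones) in post-order numbering with the root
    last; ``P[i]`` is the transition matrix of the branch above node i.
    Mutates ``L``; returns -inf if the data are impossible.
    """
    n, k = L.shape
    logscale = 0.0
    for i in range(n - 1):
        mx = 0.0
        for j in range(k):
            if L[i, j] > mx:
                mx = L[i, j]
        if mx <= 0.0:
            return -np.inf
        for j in range(k):
            L[i, j] /= mx
        logscale += np.log(mx)
        p = parent[i]
        for r in range(k):
            acc = 0.0
            for j in range(k):
                acc += P[i, r, j] * L[i, j]
            L[p, r] *= acc
    return logscale


class TreeIndex:
    """Flattened post-order view of a dendropy tree for fast pruning."""

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.postorder_node_iter())
        if len(nodes) < 3:
            raise ValueError("tree must have at least 2 tips")
        pos = {id(nd): i for i, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.parent = np.array(
            [pos[id(nd.parent_node)] if nd.parent_node else -1 for nd in nodes],
            dtype=np.int64,
        )
        self.lengths = np.array(
            [nd.edge.length or 0.0 for nd in nodes], dtype=float
        )
        self.is_tip = np.array([nd.is_leaf() for nd in nodes], dtype=bool)
        self.tip_rows = np.flatnonzero(self.is_tip)
        self.tip_labels = [nodes[i].taxon.label for i in self.tip_rows]

    def tip_states(self, values: dict) -> np.ndarray:
        """States (ints) per tip row, from a label -> state mapping."""
        missing = [lab for lab in self.tip_labels if lab not in values]
        if missing:
            raise KeyError(f"tips missing from trait matrix: {missing[:5]}")
        return np.array([values[lab] for lab in self.tip_labels], dtype=np.int64)

    def loglik(self, P: np.ndarray, tip_states: np.ndarray, prior: np.ndarray) -> float:
        k = prior.shape[0]
        L = np.zeros((self.n_nodes, k))
        L[~self.is_tip] = 1.0
        L[self.tip_rows, tip_states] = 1.0
        logscale = _prune_kernel(self.parent, P, L)
        if not np.isfinite(logscale):
            return -math.inf
        lik = float(prior @ L[-1])
        if lik <= 0.0:
            return -math.inf
        return math.log(lik) + logscale


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model on one (tree, pair) dataset."""

    kind: str
    rates: dict
    loglik: float
    n_starts: int
    converged: bool
    best_start: int
    data_fingerprint: str
    trait_ids: tuple = ()

    def model(self) -> PairRateModel:
        return PairRateModel(self.kind, dict(self.rates))


@dataclass
class CorrelationTest:
    """Correlated-evolution LRT with the bootstrap-median decision rule."""

    trait_x: str
    trait_y: str
    lnl_indep: float
    lnl_dep: float
    statistic: float
    df: int
    p: float  # LRT p on the main tree
    bootstrap_ps: list = field(default_factory=list)
    median_p: float = float("nan")
    threshold: float = 0.01
    significant: bool = False


def build_generator(model: PairRateModel) -> np.ndarray:
    """4x4 generator matrix over joint states; double transitions are 0."""
    return model.generator()


def _pair_states(m: TraitMatrix) -> tuple[dict, tuple]:
    if len(m.trait_ids) != 2:
        raise ValueError(
            f"expected a 2-trait matrix, got {len(m.trait_ids)} traits"
        )
    x, y = m.trait_ids
    vx = m.values[x]
    vy = m.values[y]
    states = {g: 2 * int(vx[g]) + int(vy[g]) for g in m.genome_ids}
    return states, (x, y)


def _root_prior(kind: str, Q: np.ndarray | None, k: int) -> np.ndarray:
    if kind == "uniform":
        return np.full(k, 1.0 / k)
    if kind == "stationary":
        if Q is None:
            raise ValueError("stationary prior needs a generator")
        return stationary_distribution(Q)
    raise ValueError(f"unknown root prior {kind!r}")


def pruning_loglik(
    tree: dendropy.Tree,
    m: TraitMatrix,
    model: PairRateModel,
    root_prior: str = "uniform",
) -> float:
    """Log-likelihood of a 2-trait matrix on a tree under a pair model.

    Felsenstein pruning over the four joint states with per-branch
    transition matrices exp(Q*t); impossible data return -inf.
    """
    idx = TreeIndex(tree)
    states, _ = _pair_states(m)
    tip_states = idx.tip_states(states)
    Q = model.generator()
    P = transition_matrices(Q, idx.lengths)
    prior = _root_prior(root_prior, Q, 4)
    return idx.loglik(P, tip_states, prior)


def _fingerprint(idx: TreeIndex, tip_states: np.ndarray, trait_ids) -> str:
    h = hashlib.md5()
    h.update("|".join(idx.tip_labels).encode())
    h.update(tip_states.tobytes())
    h.update(idx.lengths.tobytes())
    h.update(idx.parent.tobytes())
    h.update("|".join(trait_ids).encode())
    return h.hexdigest()


def _neg_loglik_single(log_rates, idx, tip01, prior_kind):
    gain, loss = np.exp(log_rates)
    P = two_state_transition_matrices(gain, loss, idx.lengths)
    if prior_kind == "uniform":
        prior = np.full(2, 0.5)
    else:
        s = gain + loss
        prior = np.array([loss / s, gain / s]) if s > 0 else np.full(2, 0.5)
    ll = idx.loglik(P, tip01, prior)
    return _PENALTY if not np.isfinite(ll) else -ll


def _neg_loglik_joint(log_rates, idx, tip_states, prior_kind):
    rates = np.exp(log_rates)
    Q = np.zeros((4, 4))
    q12, q13, q21, q24, q31, q34, q42, q43 = rates
    Q[0, 1], Q[0, 2] = q12, q13
    Q[1, 0], Q[1, 3] = q21, q24
    Q[2, 0], Q[2, 3] = q31, q34
    Q[3, 1], Q[3, 2] = q42, q43
    np.fill_diagonal(Q, -Q.sum(axis=1))
    try:
        P = transition_matrices(Q, idx.lengths)
    except FloatingPointError:
        return _PENALTY
    prior = _root_prior(prior_kind, Q, 4)
    ll = idx.loglik(P, tip_states, prior)
    return _PENALTY if not np.isfinite(ll) else -ll


def _optimize(fun, starts, args):
    """Best L-BFGS-B solution over a list of starting points.

    The raw start values themselves also compete, so the returned optimum
    is never worse than the best supplied start.
    """
    best_x, best_f, best_i, converged = None, math.inf, -1, False
    for i, x0 in enumerate(starts):
        x0 = np.clip(x0, LOG_RATE_MIN, LOG_RATE_MAX)
        f0 = fun(x0, *args)
        if f0 < best_f:
            best_x, best_f, best_i = x0, f0, i
        res = scipy.optimize.minimize(
            fun,
            x0,
            args=args,
            method="L-BFGS-B",
            bounds=[(LOG_RATE_MIN, LOG_RATE_MAX)] * len(x0),
            options={"ftol": 1e-10, "gtol": 1e-6, "maxiter": 300},
        )
        if res.fun < best_f:
            best_x, best_f, best_i = res.x, res.fun, i
        converged = converged or bool(res.success)
    if best_x is None or best_f >= _PENALTY:
        raise RuntimeError("optimizer failed to find a finite likelihood")
    return np.asarray(best_x), float(best_f), best_i, converged


def _moment_starts_single(tip01: np.ndarray, depth: float) -> list[np.ndarray]:
    """Frequency-informed starts over a ladder of overall rate scales.

    The 2-state likelihood has a flat plateau at very large rates (tip
    states decorrelate from the tree and the likelihood saturates at the
    binomial value), which can trap a single-start quasi-Newton run; a
    ladder of total-rate scales from slow to fast makes at least one start
    land in the basin of the interior optimum.
    """
    n = tip01.size
    f = (tip01.sum() + 1.0) / (n + 2.0)
    starts = []
    for scale in (0.5, 2.0, 8.0, 32.0):
        rate = scale / max(depth, 1e-6)
        starts.append(
            np.log([max(f * rate, 1e-8), max((1 - f) * rate, 1e-8)])
        )
    return starts


def _mean_depth(idx: TreeIndex) -> float:
    depth = np.zeros(idx.n_nodes)
    for i in range(idx.n_nodes - 2, -1, -1):
        depth[i] = depth[idx.parent[i]] + idx.lengths[i]
    d = depth[idx.tip_rows].mean()
    return float(max(d, 1e-9))


def fit_model(
    tree: dendropy.Tree,
    m: TraitMatrix,
    kind: str = "dependent",
    n_starts: int = 5,
    seed: int = 0,
    root_prior: str = "uniform",
    extra_starts=None,
    _index: TreeIndex | None = None,
) -> FitResult:
    """Maximum-likelihood fit of the independent or dependent pair model.

    Optimizes over log-rates (bounds [1e-8, 1e3]) with multi-start
    L-BFGS-B: one moment-based start plus ``n_starts - 1`` seeded random
    starts.  For the dependent model the embedding of the independent MLE
    is always included as an additional start, which guarantees the nesting
    inequality lnL_dep >= lnL_indep.  ``extra_starts`` (rate vectors on the
    natural scale) can warm-start the fit, e.g. from a neighbouring
    bootstrap tree.
    """
    if kind not in ("independent", "dependent"):
        raise ValueError(f"unknown model kind {kind!r}")
    idx = _index if _index is not None else TreeIndex(tree)
    states, trait_ids = _pair_states(m)
    tip_states = idx.tip_states(states)
    fp = _fingerprint(idx, tip_states, trait_ids)
    rng = np.random.default_rng(seed)
    depth = _mean_depth(idx)
    log_lo, log_hi = math.log(0.01 / depth), math.log(30.0 / depth)
    extras = [np.asarray(v, dtype=float) for v in (extra_starts or [])]

    if kind == "independent":
        # Under both priors the joint likelihood factorizes per trait, so
        # the two traits are fitted separately (2 params each).
        total_ll = 0.0
        rates = {}
        converged_all = True
        best_start = 0
        for t, (gain_name, loss_name) in enumerate(
            (("alpha1", "beta1"), ("alpha2", "beta2"))
        ):
            tip01 = (tip_states >> (1 - t)) & 1
            starts = _moment_starts_single(tip01, depth)
            starts += [
                rng.uniform(log_lo, log_hi, size=2) for _ in range(n_starts - 1)
            ]
            for v in extras:
                starts.append(np.log(np.maximum(v[2 * t : 2 * t + 2], 1e-8)))
            x, f, i, conv = _optimize(
                _neg_loglik_single, starts, (idx, tip01, root_prior)
            )
            gain, loss = np.exp(x)
            rates[gain_name] = float(gain)
            rates[loss_name] = float(loss)
            total_ll += -f
            converged_all = converged_all and conv
            best_start = max(best_start, i)
        return FitResult(
            "independent", rates, total_ll, n_starts, converged_all, best_start,
            fp, trait_ids,
        )

    # dependent model: start from the embedded independent MLE
    indep = fit_model(
        tree, m, "independent", n_starts=n_starts, seed=seed,
        root_prior=root_prior, _index=idx,
    )
    embedded = np.log(
        np.maximum(indep.model().as_dependent().rate_vector(), 1e-8)
    )
    starts = [embedded]
    starts += [
        embedded + rng.normal(0.0, 1.5, size=8) for _ in range(n_starts - 1)
    ]
    for v in extras:
        starts.append(np.log(np.maximum(v, 1e-8)))
    x, f, i, conv = _optimize(
        _neg_loglik_joint, starts, (idx, tip_states, root_prior)
    )
    rates = {name: float(r) for name, r in zip(DEPENDENT_RATE_NAMES, np.exp(x))}
    loglik = max(-f, indep.loglik)  # nesting: never below the embedded start
    return FitResult(
        "dependent", rates, loglik, n_starts, conv, i, fp, trait_ids
    )


def lrt(fit_indep: FitResult, fit_dep: FitResult) -> tuple[float, float]:
    """Likelihood-ratio test of dependent vs independent evolution.

    Statistic 2*(lnL_dep - lnL_indep), clipped at 0 (negative values are
    optimizer noise under nesting), referenced to chi-square with 4 df.
    """
    if fit_indep.kind != "independent" or fit_dep.kind != "dependent":
        raise ValueError("lrt() expects (independent fit, dependent fit)")
    if fit_indep.data_fingerprint != fit_dep.data_fingerprint:
        raise ValueError("fits come from different data (fingerprint mismatch)")
    stat = max(0.0, 2.0 * (fit_dep.loglik - fit_indep.loglik))
    p = float(scipy.stats.chi2.sf(stat, df=4))
    return stat, max(min(p, 1.0), 0.0)


def _tree_seed(seed: int, i: int) -> int:
    return int(
        np.random.SeedSequence([int(seed), int(i)]).generate_state(1)[0]
        & 0x7FFFFFFF
    )


def correlation_test_single(
    tree: dendropy.Tree,
    m: TraitMatrix,
    n_starts: int = 5,
    seed: int = 0,
    root_prior: str = "uniform",
    extra_starts=None,
) -> tuple[float, float, FitResult, FitResult]:
    """(statistic, p, fit_indep, fit_dep) for one tree and one pair."""
    fit_i = fit_model(
        tree, m, "independent", n_starts=n_starts, seed=seed,
        root_prior=root_prior, extra_starts=extra_starts,
    )
    dep_extras = None
    if extra_starts is not None:
        dep_extras = [v for v in extra_starts if len(v) == 8]
    fit_d = fit_model(
        tree, m, "dependent", n_starts=n_starts, seed=seed,
        root_prior=root_prior, extra_starts=dep_extras,
    )
    stat, p = lrt(fit_i, fit_d)
    return stat, p, fit_i, fit_d


def bootstrap_median_decision(
    trees,
    m: TraitMatrix,
    n_starts: int = 5,
    threshold: float = 0.01,
    seed: int = 0,
    root_prior: str = "uniform",
    main_tree: dendropy.Tree | None = None,
    boot_n_starts: int = 1,
    policy: str = "intersect",
) -> CorrelationTest:
    """Correlated-evolution call from the median LRT p over a tree set.

    The LRT is computed on ``main_tree`` (default: the first tree) for the
    headline statistic, then on every tree in ``trees``; the pair is called
    significant when the median of those p-values is strictly below
    ``threshold``.  Bootstrap-tree fits are warm-started from the main-tree
    MLE with ``boot_n_starts`` fresh starts.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("need at least one tree")
    main = main_tree if main_tree is not None else trees[0]

    tree0, m0 = reconcile(main, m, policy)
    main_seed = _tree_seed(seed, len(trees)) if main_tree is not None else _tree_seed(seed, 0)
    stat, p_main, fit_i, fit_d = correlation_test_single(
        tree0, m0, n_starts=n_starts, seed=main_seed, root_prior=root_prior,
    )
    warm = [
        fit_i.model().rate_vector(),
        fit_d.model().rate_vector(),
    ]

    ps = []
    for i, tree in enumerate(trees):
        if main_tree is None and i == 0:
            ps.append(p_main)
            continue
        try:
            tree_i, m_i = reconcile(tree, m, policy)
        except Exception as exc:
            raise ValueError(f"tree {i}: reconcile failed: {exc}") from exc
        _, p_i, _, _ = correlation_test_single(
            tree_i, m_i, n_starts=boot_n_starts,
            seed=_tree_seed(seed, i), root_prior=root_prior, extra_starts=warm,
        )
        ps.append(p_i)

    median_p = float(np.median(ps))
    x, y = m0.trait_ids
    return CorrelationTest(
        trait_x=x,
        trait_y=y,
        lnl_indep=fit_i.loglik,
        lnl_dep=fit_d.loglik,
        statistic=stat,
        df=4,
        p=p_main,
        bootstrap_ps=ps,
        median_p=median_p,
        threshold=threshold,
        significant=bool(median_p < threshold),
    )
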