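"""Two-trait continuous-time Markov models over joint presence/absence states.

Two binary traits X and Y define four joint states, ordered

    0 = (X=0, Y=0),  1 = (X=0, Y=1),  2 = (X=1, Y=0),  3 = (X=1, Y=1).

Under the *independent* model each trait gains and loses with its own pair
of rates (4 free parameters).  Under the *dependent* model the eight single
-trait transition rates may differ according to the partner's state (8 free
parameters).  Double transitions (both traits changing in one instant) have
rate 0 in both models, so the dependent generator has exactly eight free
off-diagonal entries and the independent model embeds as the special case
where each trait's rates do not depend on the partner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

INDEPENDENT_RATE_NAMES = ("alpha1", "beta1", "alpha2", "beta2")
# q{ij} = rate from joint state i to joint state j in the 1-based state
# numbering 1=(0,0), 2=(0,1), 3=(1,0), 4=(1,1).
DEPENDENT_RATE_NAMES = ("q12", "q13", "q21", "q24", "q31", "q34", "q42", "q43")

# (row, col) of each dependent rate in the 0-based 4x4 generator.
_DEP_POSITIONS = {
    "q12": (0, 1),
    "q13": (0, 2),
    "q21": (1, 0),
    "q24": (1, 3),
    "q31": (2, 0),
    "q34": (2, 3),
    "q42": (3, 1),
    "q43": (3, 2),
}

# Embedding of the independent parameterisation into the dependent one:
# trait X gains at alpha1 regardless of Y (q13 and q24), etc.
INDEPENDENT_EMBEDDING = {
    "q13": "alpha1",
    "q24": "alpha1",
    "q31": "beta1",
    "q42": "beta1",
    "q12": "alpha2",
    "q34": "alpha2",
    "q21": "beta2",
    "q43": "beta2",
}


@dataclass(frozen=True)
class PairRateModel:
    """Gain/loss rate model for a pair of binary traits.

    ``kind`` is ``"independent"`` (rates ``alpha1, beta1, alpha2, beta2``:
    gain/loss of X and of Y, per unit branch length) or ``"dependent"``
    (rates ``q12 ... q43`` over the four joint states).
    """

    kind: str
    rates: dict

    def __post_init__(self) -> None:
        if self.kind == "independent":
            expected = INDEPENDENT_RATE_NAMES
        elif self.kind == "dependent":
            expected = DEPENDENT_RATE_NAMES
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if set(self.rates) != set(expected):
            raise ValueError(
                f"{self.kind} model needs rates {expected}, got {tuple(self.rates)}"
            )
        for name, value in self.rates.items():
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {value}")

    @classmethod
    def independent(
        cls, alpha1: float, beta1: float, alpha2: float, beta2: float
    ) -> "PairRateModel":
        return cls(
            "independent",
            {"alpha1": alpha1, "beta1": beta1, "alpha2": alpha2, "beta2": beta2},
        )

    @classmethod
    def dependent(cls, **rates: float) -> "PairRateModel":
        return cls("dependent", dict(rates))

    def as_dependent(self) -> "PairRateModel":
        """Embed an independent model in the 8-rate dependent form."""
        if self.kind == "dependent":
            return self
        rates = {q: self.rates[src] for q, src in INDEPENDENT_EMBEDDING.items()}
        return PairRateModel("dependent", rates)

    def rate_vector(self) -> np.ndarray:
        names = (
            INDEPENDENT_RATE_NAMES
            if self.kind == "independent"
            else DEPENDENT_RATE_NAMES
        )
        return np.array([self.rates[n] for n in names], dtype=float)

    def generator(self) -> np.ndarray:
        """4x4 generator matrix Q over joint states (rows sum to zero)."""
        dep = self.as_dependent()
        Q = np.zeros((4, 4))
        for name, (i, j) in _DEP_POSITIONS.items():
            Q[i, j] = dep.rates[name]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


def transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Stack of transition matrices exp(Q*t) for each branch length.

    Uses an eigendecomposition of Q shared across branches, falling back to
    scaling-and-squaring (``scipy.linalg.expm``) when Q is close to
    defective.  Rows of each matrix sum to 1 within 1e-10; zero-length
    branches map to the exact identity.
    """
    lengths = np.asarray(lengths, dtype=float)
    k = Q.shape[0]
    if np.any(lengths < 0):
        raise ValueError("negative branch length")
    P = _eig_propagate(Q, lengths)
    if P is None:
        P = np.stack([scipy.linalg.expm(Q * t) for t in lengths])
    P = np.clip(P, 0.0, None)
    rowsums = P.sum(axis=2)
    if np.any(np.abs(rowsums - 1.0) > 1e-8):
        raise FloatingPointError("transition matrix rows do not sum to 1")
    P /= rowsums[:, :, None]
    P[lengths == 0.0] = np.eye(k)
    return P


def _eig_propagate(Q: np.ndarray, lengths: np.ndarray):
    w, V = np.linalg.eig(Q)
    try:
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:
        return None
    if not np.isfinite(cond) or cond > 1e10:
        return None
    Vinv = np.linalg.inv(V)
    ew = np.exp(np.outer(lengths, w))  # (n_branches, k)
    P = np.einsum("ij,ej,jk->eik", V, ew, Vinv).real
    # sanity: eigen route can lose accuracy for stiff generators
    if not np.all(np.isfinite(P)):
        return None
    rowsums = P.sum(axis=2)
    if np.any(np.abs(rowsums - 1.0) > 1e-10):
        return None
    return P


def two_state_transition_matrices(
    gain: float, loss: float, lengths: np.ndarray
) -> np.ndarray:
    """Closed-form 2-state transition matrices for a single binary trait."""
    lengths = np.asarray(lengths, dtype=float)
    n = lengths.shape[0]
    P = np.empty((n, 2, 2))
    s = gain + loss
    if s == 0.0:
        P[:] = np.eye(2)
        return P
    pi1 = gain / s
    decay = np.exp(-s * lengths)
    p01 = pi1 * (1.0 - decay)
    p10 = (1.0 - pi1) * (1.0 - decay)
    P[:, 0, 0] = 1.0 - p01
    P[:, 0, 1] = p01
    P[:, 1, 0] = p10
    P[:, 1, 1] = 1.0 - p10
    return P


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi @ Q = 0 and sum(pi) = 1.

    For reducible generators (some rates zero) this returns one stationary
    vector (the least-squares solution); callers needing a unique prior
    should use the uniform prior instead.
    """
    k = Q.shape[0]
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    total = pi.sum()
    if total <= 0:
        raise ValueError("could not compute a stationary distribution")
    return pi / total
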