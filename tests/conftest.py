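import numpy as np
import pytest

import cooccur_phylo as cp


@pytest.fixture
def small_tree():
    """Deterministic 10-tip Yule tree."""
    return cp.simulate_tree(10, 1.0, seed=101)


@pytest.fixture
def pair_matrix(small_tree):
    """Two-trait matrix simulated under a symmetric independent model."""
    model = cp.PairRateModel.independent(1.0, 1.0, 1.0, 1.0)
    return cp.simulate_pair_traits(small_tree, model, seed=102)


def random_contingency(rng, n_max=60, positive_margins=True):
    """Random 2x2 table of counts; optionally guarantees nonzero margins."""
    while True:
        a, b, c, d = rng.integers(0, n_max // 3, size=4)
        if a + b + c + d == 0:
            continue
        t = cp.ContingencyTable(int(a), int(b), int(c), int(d))
        if not positive_margins or all(mg > 0 for mg in t.margins()):
            return t


def random_pair_model(rng):
    """Random independent or dependent rate model with lognormal rates."""
    if rng.random() < 0.5:
        return cp.PairRateModel.independent(*np.exp(rng.normal(0, 1, size=4)))
    names = ("q12", "q13", "q21", "q24", "q31", "q34", "q42", "q43")
    return cp.PairRateModel.dependent(
        **{k: float(v) for k, v in zip(names, np.exp(rng.normal(0, 1, size=8)))}
    )
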