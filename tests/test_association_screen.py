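import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cooccur_phylo as cp
from cooccur_phylo.association_screen import (
    DeltaPhiResult,
    UndefinedPhiError,
    delta_phi_test,
)
from tests.conftest import random_contingency
from tests.oracles import fisher_two_sided


def matrix_from_columns(columns: dict, groups: dict) -> cp.TraitMatrix:
    values = pd.DataFrame(columns)
    values.index = [f"g{i}" for i in range(len(values))]
    return cp.TraitMatrix(values, pd.Series(groups))


class TestContingency:
    def test_exhaustive_small_case(self):
        m = matrix_from_columns(
            {"x": [1, 1, 0, 0], "y": [1, 0, 1, 0]},
            {"x": "system", "y": "cas"},
        )
        t = cp.contingency(m, "x", "y")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_identical_columns(self):
        m = matrix_from_columns(
            {"x": [1, 0], "y": [1, 0]}, {"x": "system", "y": "cas"}
        )
        t = cp.contingency(m, "x", "y")
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)

    def test_swapping_traits_transposes_table(self):
        rng = np.random.default_rng(3)
        cols = {
            "x": rng.integers(0, 2, size=30),
            "y": rng.integers(0, 2, size=30),
        }
        m = matrix_from_columns(cols, {"x": "system", "y": "cas"})
        t_xy = cp.contingency(m, "x", "y")
        t_yx = cp.contingency(m, "y", "x")
        assert (t_yx.a, t_yx.b, t_yx.c, t_yx.d) == (t_xy.a, t_xy.c, t_xy.b, t_xy.d)

    def test_unknown_trait_rejected(self, pair_matrix):
        with pytest.raises(KeyError):
            cp.contingency(pair_matrix, "sys1", "nope")


class TestPhi:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((1, 1, 1, 1), 0.0),
            ((5, 0, 0, 5), 1.0),
            ((0, 5, 5, 0), -1.0),
            ((40, 10, 10, 40), 0.6),
        ],
    )
    def test_known_values(self, table, expected):
        assert cp.phi(cp.ContingencyTable(*table)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_zero_margin_raises_undefined_signal(self):
        with pytest.raises(UndefinedPhiError):
            cp.phi(cp.ContingencyTable(3, 0, 5, 0))

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(st.integers(0, 1_000_000))
    def test_phi_equals_pearson_correlation(self, seed):
        t = random_contingency(np.random.default_rng(seed))
        x = [1] * (t.a + t.b) + [0] * (t.c + t.d)
        y = [1] * t.a + [0] * t.b + [1] * t.c + [0] * t.d
        assert cp.phi(t) == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(st.integers(0, 1_000_000))
    def test_phi_antisymmetric_under_complement(self, seed):
        t = random_contingency(np.random.default_rng(seed))
        complemented = cp.ContingencyTable(t.b, t.a, t.d, t.c)  # X -> 1-X
        assert cp.phi(complemented) == pytest.approx(-cp.phi(t), abs=1e-12)
        assert cp.phi(t.swapped()) == pytest.approx(cp.phi(t), abs=1e-12)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((1, 1, 1, 1), 1.0),
            ((3, 1, 1, 3), 34 / 70),
            ((5, 0, 0, 5), 2 / 252),
        ],
    )
    def test_known_values(self, table, expected):
        assert cp.fisher_exact(cp.ContingencyTable(*table)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            t = random_contingency(rng, n_max=40, positive_margins=False)
            expected = fisher_two_sided(t.a, t.b, t.c, t.d)
            assert cp.fisher_exact(t) == pytest.approx(expected, abs=1e-12)


class TestDeltaPhiTest:
    def test_textbook_example(self):
        res = delta_phi_test([0.1, 0.2, 0.3])
        assert res.t == pytest.approx(3.4641016, abs=1e-6)
        assert res.p == pytest.approx(0.0371, abs=1e-4)

    def test_zero_variance_conventions(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert delta_phi_test([0.0, 0.0, 0.0]).p == 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            assert delta_phi_test([0.2, 0.2]).p == 0.0

    def test_symmetric_sample_gives_half(self):
        res = delta_phi_test([-0.3, 0.3])
        assert res.t == 0.0
        assert res.p == 0.5

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            delta_phi_test([0.1])


class TestBonferroni:
    def test_threshold_arithmetic_at_246_tests(self):
        pvals = {f"p{i}": 0.5 for i in range(244)}
        pvals["hit"] = 0.0001
        pvals["miss"] = 0.001
        calls = cp.bonferroni(pvals, alpha=0.05)
        assert calls["hit"] is True  # 1e-4 <= 0.05/246
        assert calls["miss"] is False  # 1e-3 > 0.05/246

    def test_single_test_reduces_to_alpha(self):
        assert cp.bonferroni({"x": 0.04}, alpha=0.05) == {"x": True}
        assert cp.bonferroni({"x": 0.06}, alpha=0.05) == {"x": False}

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=2, max_size=20),
        st.integers(0, 19),
    )
    def test_monotone_in_p(self, ps, which):
        which = which % len(ps)
        pvals = {i: p for i, p in enumerate(ps)}
        before = cp.bonferroni(pvals, alpha=0.05)
        pvals2 = dict(pvals)
        pvals2[which] = pvals2[which] / 2
        after = cp.bonferroni(pvals2, alpha=0.05)
        for key in pvals:
            if before[key]:
                assert after[key]


class TestFrequencyFilter:
    def test_strict_boundaries(self):
        n = 200
        cols = {
            "rare": [1] * 1 + [0] * (n - 1),          # f = 0.005
            "edge": [1] * 2 + [0] * (n - 2),          # f = 0.01 exactly
            "mid": [1] * 100 + [0] * (n - 100),       # f = 0.5
            "top": [1] * 198 + [0] * 2,               # f = 0.99 exactly
        }
        m = matrix_from_columns(cols, {k: "system" for k in cols})
        kept = cp.frequency_filter(m, lo=0.01, hi=0.99)
        assert kept == ["mid"]

    def test_invalid_bounds_rejected(self, pair_matrix):
        with pytest.raises(ValueError):
            cp.frequency_filter(pair_matrix, lo=0.5, hi=0.5)


class TestMatchControls:
    def _matrix(self, freqs, target_freq=0.5, n=200):
        cols = {"target": [1] * int(target_freq * n) + [0] * (n - int(target_freq * n))}
        groups = {"target": "system"}
        for i, f in enumerate(freqs):
            k = int(round(f * n))
            cols[f"ctrl{i}"] = [1] * k + [0] * (n - k)
            groups[f"ctrl{i}"] = "control"
        return cp.TraitMatrix(
            pd.DataFrame(cols, index=[f"g{j}" for j in range(n)]),
            pd.Series(groups),
        )

    def test_direct_filter_at_default_margin(self):
        m = self._matrix([0.495, 0.505, 0.60])
        got = cp.match_controls("target", ["ctrl0", "ctrl1", "ctrl2"], m, k=2, seed=0)
        assert sorted(got) == ["ctrl0", "ctrl1"]

    def test_whole_pool_when_k_equals_pool(self):
        m = self._matrix([0.5, 0.5, 0.5])
        for seed in (0, 1, 2):
            got = cp.match_controls(
                "target", ["ctrl0", "ctrl1", "ctrl2"], m, k=3, seed=seed
            )
            assert sorted(got) == ["ctrl0", "ctrl1", "ctrl2"]

    def test_same_seed_same_selection(self):
        m = self._matrix([0.5] * 10)
        pool = [f"ctrl{i}" for i in range(10)]
        a = cp.match_controls("target", pool, m, k=4, seed=42)
        b = cp.match_controls("target", pool, m, k=4, seed=42)
        assert a == b

    def test_margin_widens_until_enough(self):
        m = self._matrix([0.505, 0.56, 0.60])
        got = cp.match_controls("target", ["ctrl0", "ctrl1", "ctrl2"], m, k=3, seed=1)
        assert sorted(got) == ["ctrl0", "ctrl1", "ctrl2"]

    def test_small_pool_rejected(self):
        m = self._matrix([0.5])
        with pytest.raises(ValueError):
            cp.match_controls("target", ["ctrl0"], m, k=2, seed=0)


class TestScreen:
    def _planted_matrix(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        genome_ids = [f"g{i}" for i in range(n)]
        blocks = [
            cp.simulate_correlated_pair(
                genome_ids, 0.5, 0.5, 0.9, seed=seed + i,
                trait_ids=(f"sys{i}", f"cas{i}"),
            )
            for i in range(3)
        ]
        blocks.append(
            cp.simulate_controls(
                genome_ids, rng.uniform(0.3, 0.7, size=12), seed=seed + 50
            )
        )
        return cp.TraitMatrix.concat(blocks)

    def test_planted_pairs_dominate_screen(self):
        m = self._planted_matrix()
        records, dp = cp.screen(m, k_controls=5, seed=3)
        by_pair = {(r.system_id, r.cas_id): r for r in records}
        for i in range(3):
            planted = by_pair[(f"sys{i}", f"cas{i}")]
            assert planted.phi > 0.8
            assert planted.bonferroni_significant
            assert planted.sign == 1
        best = min(records, key=lambda r: r.fisher_p)
        assert best.system_id.replace("sys", "") == best.cas_id.replace("cas", "")
        # 3 planted + 6 cross pairs: the aggregate delta-phi must be positive
        assert dp.n == 9
        assert dp.mean > 0.1 and dp.t > 0

    def test_record_sign_is_zero_unless_significant(self):
        m = self._planted_matrix(seed=5)
        records, _ = cp.screen(m, k_controls=5, seed=3)
        for r in records:
            if not r.bonferroni_significant:
                assert r.sign == 0
            elif r.sign != 0:
                assert r.sign == (1 if r.phi > 0 else -1)

    def test_screen_deterministic_given_seed(self):
        m = self._planted_matrix(seed=7)
        r1, dp1 = cp.screen(m, k_controls=5, seed=11)
        r2, dp2 = cp.screen(m, k_controls=5, seed=11)
        assert dp1 == dp2
        assert [(r.system_id, r.cas_id, r.phi, r.fisher_p, r.control_phis)
                for r in r1] == [
            (r.system_id, r.cas_id, r.phi, r.fisher_p, r.control_phis)
            for r in r2
        ]

    def test_global_null_family_wise_error_controlled(self):
        # fraction of runs with any Bonferroni call should stay near alpha
        hits = 0
        n_reps = 200
        for rep in range(n_reps):
            rng = np.random.default_rng(10_000 + rep)
            genome_ids = [f"g{i}" for i in range(100)]
            blocks = [
                cp.simulate_controls(genome_ids, rng.uniform(0.2, 0.8, 21),
                                     seed=20_000 + rep)
            ]
            values = blocks[0].values
            groups = ["system"] * 3 + ["cas"] * 3 + ["control"] * 15
            m = cp.TraitMatrix(values.copy(), pd.Series(groups, index=values.columns))
            records, _ = cp.screen(m, k_controls=5, seed=rep)
            if any(r.bonferroni_significant for r in records):
                hits += 1
        rate = hits / n_reps
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_reps)
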