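"""Exact two-library test, BH FDR and DE calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from energyomics.detest import (
    ac_pmf_conditional,
    ac_two_sided_p,
    bh_fdr,
    call_de_table,
    fold_change,
)

from _oracles import ac_two_sided_oracle, bh_bruteforce

N = 10_000_000


class TestConditionalPmf:
    @pytest.mark.parametrize(
        "x,i,ratio,expected",
        [
            (0, 0, 1.0, 0.5),
            (1, 1, 1.0, 0.25),
            (2, 0, 1.0, 0.125),
        ],
    )
    def test_hand_values(self, x, i, ratio, expected):
        assert ac_pmf_conditional(x, i, ratio) == pytest.approx(
            expected, rel=1e-12
        )

    def test_equals_negative_binomial(self):
        # p(i|x) is nbinom(size=x+1, p=1/(1+r)) — independent cross-check
        for x, i, r in [(3, 7, 0.5), (10, 2, 2.0), (0, 40, 1.0)]:
            assert ac_pmf_conditional(x, i, r) == pytest.approx(
                stats.nbinom.pmf(i, x + 1, 1 / (1 + r)), rel=1e-10
            )

    @pytest.mark.parametrize("x", [0, 5, 50])
    @pytest.mark.parametrize("ratio", [0.5, 1.0, 2.0])
    def test_normalization(self, x, ratio):
        k = 5000  # far beyond the mass for these x
        total = sum(ac_pmf_conditional(x, i, ratio) for i in range(k))
        assert abs(total - 1.0) < 1e-12

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError):
            ac_pmf_conditional(1, 1, 0.0)
        with pytest.raises(ValueError):
            ac_pmf_conditional(1, 1, -2.0)


class TestTwoSidedP:
    def test_empty_libraries_give_p_one(self):
        assert ac_two_sided_p(0, 0, N, N) == 1.0

    @pytest.mark.parametrize("x", [0, 1, 3, 10, 47, 100])
    def test_equal_counts_equal_libraries_p_one(self, x):
        assert ac_two_sided_p(x, x, N, N) == pytest.approx(1.0, abs=1e-12)

    def test_geometric_closed_form(self):
        # x=0, equal libraries: p(i|0) = 2^-(i+1); upper tail at 10 is 2^-10
        assert ac_two_sided_p(0, 10, N, N) == pytest.approx(2.0**-9, rel=1e-12)

    def test_extinction_scenario(self):
        # a ~1300-count gene dropping to zero reads is overwhelmingly DE
        assert ac_two_sided_p(1300, 0, N, N) < 1e-10

    @pytest.mark.parametrize("ratio", [0.5, 1.0, 2.0])
    def test_oracle_equivalence_subgrid(self, ratio):
        n2 = int(N * ratio)
        for x in range(0, 201, 13):
            for y in range(0, 201, 7):
                p = ac_two_sided_p(x, y, N, n2)
                o = ac_two_sided_oracle(x, y, n2 / N)
                assert p == pytest.approx(o, rel=1e-10), (x, y, ratio)

    def test_mpmath_spot_checks(self):
        mpmath = pytest.importorskip("mpmath")
        mpmath.mp.dps = 40
        for x, y, r in [(5, 30, 1.0), (80, 40, 2.0), (0, 60, 0.5)]:
            terms = [
                mpmath.power(r, i)
                * mpmath.binomial(x + i, i)
                / mpmath.power(1 + r, x + i + 1)
                for i in range(y + 1)
            ]
            s = mpmath.fsum(terms)
            if s <= 0.5:
                expected = 2 * s
            else:
                expected = 2 * (1 - s + terms[-1])
            assert ac_two_sided_p(x, y, N, int(N * r)) == pytest.approx(
                float(expected), rel=1e-10
            )

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        x=st.integers(0, 300),
        y=st.integers(0, 300),
        ratio=st.sampled_from([0.25, 0.5, 1.0, 2.0, 4.0]),
    )
    def test_exchange_symmetry_of_exclusive_variant(self, x, y, ratio):
        # Swapping (x, N1) with (y, N2) flips the conditional lower tail
        # into the exclusive upper tail (I_q(x+1, y+1) identity), so the
        # 2*(1-S) variant is exactly exchange-symmetric.  The default
        # observed-inclusive test is deliberately not: it keeps the
        # discrete tails conservative, at the price of exact symmetry.
        n2 = int(N * ratio)
        p_fwd = ac_two_sided_p(x, y, N, n2, include_observed=False)
        p_rev = ac_two_sided_p(y, x, n2, N, include_observed=False)
        assert p_fwd == pytest.approx(p_rev, rel=1e-10, abs=1e-300)

    def test_inclusive_default_symmetric_at_equal_counts(self):
        for x in (0, 3, 40):
            assert ac_two_sided_p(x, x, N, N) == ac_two_sided_p(x, x, N, N)
            assert ac_two_sided_p(x, x, N, N) == pytest.approx(1.0, abs=1e-12)

    def test_unimodal_tails(self):
        # moving y away from the conditional median never increases p
        for x, ratio in [(10, 1.0), (25, 2.0), (40, 0.5)]:
            n2 = int(N * ratio)
            ps = np.array(
                [ac_two_sided_p(x, y, N, n2) for y in range(0, 4 * x + 20)]
            )
            peak = int(np.argmax(ps))
            assert np.all(np.diff(ps[: peak + 1]) >= -1e-15)
            assert np.all(np.diff(ps[peak:]) <= 1e-15)

    def test_exclusive_upper_tail_variant_smaller(self):
        p_incl = ac_two_sided_p(5, 40, N, N, include_observed=True)
        p_excl = ac_two_sided_p(5, 40, N, N, include_observed=False)
        assert p_excl < p_incl

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ac_two_sided_p(1, 1, 0, N)
        with pytest.raises(ValueError):
            ac_two_sided_p(-1, 1, N, N)


class TestBhFdr:
    def test_constant_pvector_unchanged(self):
        p = np.full(7, 0.03)
        assert np.allclose(bh_fdr(p), p)

    def test_worked_example(self):
        q = bh_fdr([0.001, 0.01, 0.02, 0.8])
        assert np.allclose(q, [0.004, 0.02, 0.0266666667, 0.8], atol=1e-9)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=200))
    def test_matches_bruteforce_definition(self, pvals):
        assert np.allclose(bh_fdr(pvals), bh_bruteforce(pvals), atol=1e-12)

    def test_empty_and_invalid(self):
        assert bh_fdr([]).size == 0
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([1.5])


class TestFoldChangeAndCalls:
    @pytest.mark.parametrize(
        "x,y,n1,n2,expected",
        [
            (100, 100, N, N, 1.0),
            (100, 400, N, N, 4.0),
            (100, 100, N, 2 * N, 0.5),
            (0, 5, N, N, np.inf),
            (1300, 0, N, N, 0.0),
            (0, 0, N, N, 1.0),
        ],
    )
    def test_fold_change(self, x, y, n1, n2, expected):
        assert fold_change(x, y, n1, n2) == expected

    def test_identical_counts_all_ns(self):
        df = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(50)], "x": 100, "y": 100}
        )
        de = call_de_table(df, N, N)
        assert (de["call"] == "ns").all()

    def test_spike_in_called_up_at_both_thresholds(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["spike"] + [f"null{i}" for i in range(20)],
                "x": [50] + [100] * 20,
                "y": [800] + [100] * 20,
            }
        )
        for fc in (2.0, 1.5):
            de = call_de_table(genes, N, N, fc_threshold=fc)
            assert de.set_index("gene_id").loc["spike", "call"] == "up"

    def test_lower_threshold_calls_are_superset(self, small_sim_config):
        from energyomics.synthetic import gen_counts

        counts, _, _ = gen_counts(small_sim_config)
        df = counts.counts.reset_index().rename(
            columns={"lib1": "x", "lib2": "y"}
        )
        n1 = counts.library_sizes["lib1"]
        n2 = counts.library_sizes["lib2"]
        de2 = call_de_table(df, n1, n2, fc_threshold=2.0).set_index("gene_id")
        de15 = call_de_table(df, n1, n2, fc_threshold=1.5).set_index("gene_id")
        called2 = set(de2.index[de2["call"] != "ns"])
        called15 = set(de15.index[de15["call"] != "ns"])
        assert called2 <= called15

    def test_undetected_genes_excluded(self):
        df = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "x": [0, 10, 0], "y": [0, 12, 3]}
        )
        de = call_de_table(df, N, N)
        assert set(de["gene_id"]) == {"b", "c"}

    def test_null_calibration_conservative(self):
        # simulated Poisson nulls: the discrete test over-covers
        rng = np.random.default_rng(7)
        lam = np.exp(rng.uniform(np.log(1), np.log(1e3), 3000))
        x = rng.poisson(lam)
        y = rng.poisson(lam)
        keep = (x > 0) | (y > 0)
        p = np.array(
            [ac_two_sided_p(int(a), int(b), N, N) for a, b in zip(x[keep], y[keep])]
        )
        for alpha in (0.01, 0.05):
            se = np.sqrt(alpha * (1 - alpha) / p.size)
            assert (p <= alpha).mean() <= alpha + 3 * se
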