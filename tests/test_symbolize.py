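"""Delay embedding, ordinal encoding, binning and delay selection."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from pccc import (
    delay_embed,
    equidistant_bin,
    equiquantal_bin,
    ordinal_encode,
    select_delay_auto_mi,
)

from reference import brute_auto_mi_curve


class TestDelayEmbed:
    def test_unit_delay(self):
        emb = delay_embed([1, 2, 3, 4, 5], m=3, eta=1)
        assert emb.vectors.tolist() == [[1, 2, 3], [2, 3, 4], [3, 4, 5]]
        assert emb.t0 == 0

    def test_length_boundary(self):
        emb = delay_embed([1, 2, 3, 4, 5], m=3, eta=2)
        assert emb.vectors.tolist() == [[1, 3, 5]]

    def test_vector_count_arithmetic(self):
        n, m, eta = 2048, 3, 5
        emb = delay_embed(np.arange(n, dtype=float), m=m, eta=eta)
        assert len(emb) == n - (m - 1) * eta == 2038

    def test_backward_offsets(self):
        emb = delay_embed([10, 11, 12, 13, 14], m=3, eta=2, direction="backward")
        # anchored at t = (m-1)*eta = 4: (x(4), x(2), x(0))
        assert emb.vectors.tolist() == [[14, 12, 10]]
        assert emb.t0 == 4

    def test_insufficient_length(self):
        with pytest.raises(ValueError, match="insufficient length"):
            delay_embed([1, 2, 3], m=2, eta=3)


class TestOrdinalEncode:
    def test_tie_rule_worked_triples(self):
        """(3,5,5), (3,3,5), (3,3,3) all share the ascending pattern."""
        for vec in ([3, 5, 5], [3, 3, 5], [3, 3, 3], [1, 2, 3]):
            emb = delay_embed(vec, m=3, eta=1)
            sym = ordinal_encode(emb)
            assert sym.symbols.tolist() == [0]  # pattern (0,1,2)
        assert ordinal_encode(delay_embed([5, 3, 4], m=3, eta=1)).symbols.tolist() == [4]

    def test_alphabet_is_m_factorial(self):
        rng = np.random.default_rng(0)
        for m in (2, 3, 4):
            sym = ordinal_encode(delay_embed(rng.normal(size=500), m=m, eta=1))
            assert sym.alphabet_size == math.factorial(m)
            assert np.unique(sym.symbols).size <= math.factorial(m)

    def test_all_patterns_lexicographic_bijection(self):
        """Each of the 6 orderings of 3 distinct values maps to a distinct
        integer, in lexicographic order of the rank pattern."""
        import itertools

        seen = {}
        for vals in itertools.permutations((1.0, 2.0, 3.0)):
            code = ordinal_encode(delay_embed(list(vals), m=3, eta=1)).symbols[0]
            seen[vals] = int(code)
        assert sorted(seen.values()) == list(range(6))
        assert seen[(1.0, 2.0, 3.0)] == 0
        assert seen[(3.0, 2.0, 1.0)] == 5

    @given(
        st.lists(st.integers(-1000, 1000), min_size=5, max_size=60),
        st.sampled_from(["exp", "cube", "affine"]),
    )
    def test_monotone_transform_invariance(self, values, transform):
        # integer-valued inputs keep exact ties exact under the transforms
        arr = np.asarray(values, dtype=float)
        fn = {
            "exp": lambda a: np.exp(a / 1e6),
            "cube": lambda a: a**3,
            "affine": lambda a: 2.5 * a + 7.0,
        }[transform]
        before = ordinal_encode(delay_embed(arr, m=3, eta=1)).symbols
        after = ordinal_encode(delay_embed(fn(arr), m=3, eta=1)).symbols
        assert np.array_equal(before, after)

    def test_iid_patterns_equifrequent(self):
        """On iid data every one of the m! patterns is equally likely."""
        rng = np.random.default_rng(42)
        sym = ordinal_encode(delay_embed(rng.normal(size=100_000), m=3, eta=1))
        counts = np.bincount(sym.symbols, minlength=6)
        assert stats.chisquare(counts).pvalue > 0.01


class TestBinning:
    def test_equidistant_top_bin_closed(self):
        assert equidistant_bin([0.0, 0.5, 1.0], 2).symbols.tolist() == [0, 1, 1]

    def test_equidistant_constant_series(self):
        sym = equidistant_bin([3.5] * 10, 4)
        assert sym.symbols.tolist() == [0] * 10
        assert sym.alphabet_size == 4

    def test_equidistant_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="non-finite"):
            equidistant_bin([0.0, np.nan, 1.0], 2)

    def test_equiquantal_uniform_grid_quartiles(self):
        sym = equiquantal_bin(np.arange(1.0, 101.0), 4)
        assert np.bincount(sym.symbols).tolist() == [25, 25, 25, 25]

    def test_equiquantal_identity_ranking(self):
        sym = equiquantal_bin([10.0, 3.0, 7.0, 1.0, 9.0, 2.0, 5.0, 4.0], 8)
        order = np.argsort([10.0, 3.0, 7.0, 1.0, 9.0, 2.0, 5.0, 4.0])
        expect = np.empty(8, dtype=int)
        expect[order] = np.arange(8)
        assert sym.symbols.tolist() == expect.tolist()

    def test_equiquantal_balanced_on_gaussian(self):
        rng = np.random.default_rng(7)
        sym = equiquantal_bin(rng.normal(size=100_000), 8)
        freq = np.bincount(sym.symbols, minlength=8) / 100_000
        assert np.all(np.abs(freq - 1 / 8) < 0.01)

    def test_equiquantal_needs_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            equiquantal_bin([1.0, 1.0, 2.0], 4)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("scale, shift", [(2.5, 7.0), (0.3, -12.0), (10.0, 0.0)])
    def test_affine_invariance(self, seed, scale, shift):
        # continuous draws keep values away from exact bin boundaries, where
        # floating-point affine invariance cannot be guaranteed bit-exactly
        arr = np.random.default_rng(seed).normal(size=200)
        transformed = scale * arr + shift
        assert np.array_equal(
            equidistant_bin(arr, 5).symbols, equidistant_bin(transformed, 5).symbols
        )
        assert np.array_equal(
            equiquantal_bin(arr, 4).symbols, equiquantal_bin(transformed, 4).symbols
        )


class TestDelaySelection:
    def test_sinusoid_quarter_period(self):
        # a noise floor keeps all 16 quantile bins populated; a noise-free
        # sampled sinusoid only visits 20 phase values and flattens the curve
        rng = np.random.default_rng(0)
        t = np.arange(4000)
        series = np.sin(2 * np.pi * t / 20) + 0.1 * rng.normal(size=4000)
        sel = select_delay_auto_mi(series, max_lag=15, bins=16)
        assert sel.is_local_minimum
        assert sel.lag in (4, 5, 6)  # quarter period
        # independent oracle agrees on the location of the first minimum
        curve = brute_auto_mi_curve(series.tolist(), 15, 16)
        ref = next(
            k
            for k in range(1, 15)
            if curve[k] < curve[k - 1] and curve[k] < curve[k + 1]
        )
        assert abs(sel.lag - ref) <= 1

    def test_iid_noise_immediate_minimum(self):
        """The auto-MI of iid noise is flat at bias level beyond lag 0, so
        the first local minimum lands within the first few lags."""
        lags = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            lags.append(select_delay_auto_mi(rng.uniform(size=10_000), max_lag=10).lag)
        assert np.mean(np.asarray(lags) <= 2) >= 0.7
        assert max(lags) <= 4

    def test_max_lag_too_small(self):
        with pytest.raises(ValueError, match="max_lag"):
            select_delay_auto_mi(np.sin(np.arange(100.0)), max_lag=1)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            select_delay_auto_mi(np.ones(1000), max_lag=5)
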