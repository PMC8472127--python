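"""Rank statistics: brute-force permutation oracles and report hierarchy."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from effiq.compare import (
    FreqBinSpec,
    bin_curve,
    kruskal_wallis,
    mann_whitney,
    pairwise_report,
)
from effiq.exceptions import ValidationError
from effiq.io import FrequencySeries


def _curve(values, step=0.1):
    f = np.arange(len(values)) * step
    return FrequencySeries(f, np.asarray(values, dtype=float), plane="object", quantity="eDQE")


# -- independent oracles -----------------------------------------------------


def _kw_h_by_ranks(groups):
    """Tie-corrected Kruskal-Wallis H computed from first principles."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = pooled.size
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


def _mw_u_by_counting(a, b):
    """min-U by direct pair counting with half credit for ties."""
    u_a = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)
    return min(u_a, len(a) * len(b) - u_a)


def _mw_exact_p(a, b):
    """Two-sided exact permutation p: P(min-U <= observed) over all splits."""
    pooled = list(a) + list(b)
    n = len(a)
    u_obs = _mw_u_by_counting(a, b)
    total = count = 0
    for picks in combinations(range(len(pooled)), n):
        left = [pooled[i] for i in picks]
        right = [pooled[i] for i in range(len(pooled)) if i not in picks]
        total += 1
        if _mw_u_by_counting(left, right) <= u_obs + 1e-12:
            count += 1
    return count / total


class TestBinCurve:
    def test_published_bin_counts(self):
        c = _curve(np.arange(26))  # grid 0.0..2.5
        assert bin_curve(c, (0.0, 1.0)).size == 11
        assert bin_curve(c, (0.0, 1.25)).size == 13
        # offset high bin: grid points 1.2..2.1 fall inside [1.15, 2.15]
        assert bin_curve(c, (1.15, 2.15)).size == 10

    def test_empty_bin_rejected(self):
        with pytest.raises(ValidationError):
            bin_curve(_curve(np.arange(5)), (3.0, 4.0))


class TestKruskalWallis:
    def test_three_groups_df_two(self):
        h, df, p = kruskal_wallis([np.array([1.0, 2]), np.array([3.0, 4]), np.array([5.0, 6])])
        assert df == 2

    def test_identical_constant_groups(self):
        h, df, p = kruskal_wallis([np.ones(4), np.ones(4), np.ones(4)])
        assert h == 0.0 and p == 1.0

    @pytest.mark.parametrize(
        "groups",
        [
            ([1.0, 2.0], [3.0, 4.0], [5.0, 6.0]),
            ([1.0, 5.0, 9.0], [2.0, 6.0, 7.0], [3.0, 4.0, 8.0]),
            ([1.0, 1.0, 2.0], [2.0, 3.0, 3.0], [4.0, 5.0, 6.0]),  # ties
        ],
    )
    def test_matches_first_principles_rank_formula(self, groups):
        arrays = [np.array(g) for g in groups]
        h, _, _ = kruskal_wallis(arrays)
        assert h == pytest.approx(_kw_h_by_ranks(arrays), rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([np.array([1.0]), np.array([])])

    def test_two_group_h_equals_squared_z(self, rng):
        """With k = 2, tie-free KW H equals the squared MW Z (asymptotically)."""
        a, b = rng.normal(0, 1, 50), rng.normal(0.4, 1, 50)
        h, _, _ = kruskal_wallis([a, b])
        _, z, _ = mann_whitney(a, b)
        assert h == pytest.approx(z**2, rel=0.05)


class TestMannWhitney:
    def test_complete_separation_u_zero_at_n11(self):
        a = np.arange(11.0)
        b = np.arange(11.0) + 100
        u, z, p = mann_whitney(a, b)
        assert u == 0.0
        assert z < -3.9
        assert p < 0.001

    def test_identical_multisets(self):
        a = np.array([1.0, 2.0, 2.0, 3.0])
        u, z, p = mann_whitney(a, a.copy())
        assert z == 0.0 and p == 1.0

    def test_three_vs_three_exact_p(self):
        u, z, p = mann_whitney([1.0, 2, 3], [4.0, 5, 6], exact=True)
        assert u == 0.0
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 8, size=3).astype(float)
        b = rng.integers(0, 8, size=3).astype(float)
        u, _, p = mann_whitney(a, b, exact=True)
        assert u == pytest.approx(_mw_u_by_counting(a, b))
        assert p == pytest.approx(_mw_exact_p(a, b))

    def test_exact_and_normal_p_agree_for_moderate_n(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        _, _, p_norm = mann_whitney(a, b)
        _, _, p_exact = mann_whitney(a, b, exact=True)
        assert abs(p_norm - p_exact) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.data())
def test_u_properties(data):
    """U is the min convention and invariant under strictly monotone transforms."""
    ints = st.lists(st.integers(-50, 50), min_size=2, max_size=8)
    a = np.array(data.draw(ints), dtype=float)
    b = np.array(data.draw(ints), dtype=float)
    u, _, _ = mann_whitney(a, b)
    assert 0 <= u <= a.size * b.size / 2  # min convention
    # exp(x/25) is injective on these integer-valued inputs, preserving ranks
    u2, _, _ = mann_whitney(np.exp(a / 25), np.exp(b / 25))
    assert u == pytest.approx(u2)


class TestPairwiseReport:
    def test_identical_systems_suppress_pairwise(self):
        c = _curve(np.linspace(1, 0.1, 26))
        report = pairwise_report({"A": c, "B": c, "C": c}, FreqBinSpec("eDQE"))
        for b in report.bins:
            assert b.df == 2
            assert b.pairwise is None

    def test_shifted_system_separates_completely(self):
        base = np.linspace(1.0, 0.5, 26)
        sys_curves = {
            "LDSS": _curve(base + 10.0),
            "DR1": _curve(base),
            "DR2": _curve(base + 0.001),
        }
        report = pairwise_report(sys_curves, FreqBinSpec("eDQE"))
        low = report.bins[0]
        assert low.n_total == 33
        assert low.pairwise is not None
        us = {pr.pair: pr.u for pr in low.pairwise}
        assert us[("LDSS", "DR1")] == 0.0
        assert us[("LDSS", "DR2")] == 0.0

    def test_mismatched_grids_rejected(self):
        a = _curve(np.ones(26))
        b = _curve(np.ones(30))
        with pytest.raises(ValidationError, match="mismatched"):
            pairwise_report({"A": a, "B": b}, FreqBinSpec("eDQE"))

    def test_markdown_report_carries_caveat(self):
        c = _curve(np.linspace(1, 0.1, 26))
        text = pairwise_report({"A": c, "B": c, "C": c}).to_markdown()
        assert "anti-conservative" in text

    def test_default_bins(self):
        spec = FreqBinSpec("eNEQ")
        assert spec.low_range == (0.0, 1.25)
        assert spec.high_range == (1.35, 2.55)
        with pytest.raises(ValidationError):
            FreqBinSpec("eDQE", low_range=(0.0, 1.5), high_range=(1.0, 2.0))
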