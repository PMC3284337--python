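import numpy as np
import pytest
from hypothesis import given, strategies as st

from homeoscan.gc_trend import (
    DgcValue,
    P_EPSILON,
    P_GAMMA,
    UNDETERMINED,
    TrendCurve,
    assign_polarity,
    build_trend_curve,
    compute_dgc,
    detect_trend_exchange,
    gc_fraction,
    gc_profile,
)

from .oracles import brute_exchange_breakpoints, sliding_mean_oracle


class TestComputeDgc:
    @pytest.mark.parametrize(
        "gc1,gc2,expected",
        [
            ((0.40), 0.40, (1.0, 1.0)),
            (0.42, 0.38, (1.05, 0.95)),
        ],
    )
    def test_examples(self, gc1, gc2, expected):
        d1, d2 = compute_dgc(gc1, gc2)
        assert d1 == pytest.approx(expected[0])
        assert d2 == pytest.approx(expected[1])

    @given(
        st.floats(min_value=0.01, max_value=0.99),
        st.floats(min_value=0.01, max_value=0.99),
    )
    def test_sum_is_two(self, gc1, gc2):
        d1, d2 = compute_dgc(gc1, gc2)
        assert d1 + d2 == pytest.approx(2.0, abs=1e-9)
        assert d1 > 0 and d2 > 0

    def test_equal_gc_is_exactly_one(self):
        assert compute_dgc(0.123456, 0.123456) == (1.0, 1.0)

    def test_degenerate_pair_rejected(self):
        with pytest.raises(ValueError):
            compute_dgc(0.0, 0.0)


def test_gc_fraction_excludes_n():
    assert gc_fraction("GCGCNNNN") == 1.0
    assert gc_fraction("ATATN") == 0.0
    assert np.isnan(gc_fraction("NNN"))


def _values(series, start=0, spacing=1000):
    return [
        DgcValue(f"g{i}", v, 2.0 - v, start + i * spacing)
        for i, v in enumerate(series)
    ]


class TestTrendCurve:
    def test_constant_series_flat(self):
        curve = build_trend_curve(_values([1.006] * 20))
        assert np.allclose(curve.dgc_1, 1.006)
        assert np.allclose(curve.dgc_2, 0.994)
        assert len(curve) == 20 - 11 + 1

    def test_thirteen_value_toy_matches_oracle(self):
        rng = np.random.default_rng(3)
        series = list(1 + 0.02 * rng.standard_normal(13))
        curve = build_trend_curve(_values(series))
        assert len(curve) == 3
        assert np.allclose(curve.dgc_1, sliding_mean_oracle(series, 11))
        # anchored at the central (6th of 11) gene
        assert list(curve.positions) == [5000, 6000, 7000]

    def test_smoothing_preserves_pairwise_sum(self):
        rng = np.random.default_rng(4)
        series = list(1 + 0.02 * rng.standard_normal(40))
        curve = build_trend_curve(_values(series))
        assert np.allclose(curve.dgc_1 + curve.dgc_2, 2.0)

    def test_short_series_empty_with_warning(self):
        with pytest.warns(UserWarning):
            curve = build_trend_curve(_values([1.0] * 5))
        assert len(curve) == 0

    def test_homozygous_series_identically_one(self):
        curve = build_trend_curve(_values([1.0] * 15))
        assert np.allclose(curve.dgc_1, 1.0, atol=1e-12)
        assert np.allclose(curve.dgc_2, 1.0, atol=1e-12)


def _curve(d1, spacing=1000):
    d1 = np.asarray(d1, dtype=float)
    pos = np.arange(len(d1)) * spacing
    return TrendCurve(pos, d1, 2.0 - d1, 11, 1)


class TestPolarity:
    def test_study_scale_separation(self):
        """Curves at 1.006 / 0.994 label copy 1 as the GC-richer parent."""
        curve = _curve([1.006] * 30)
        call = assign_polarity(curve, (0, 30_000))
        assert (call.copy_1, call.copy_2) == (P_GAMMA, P_EPSILON)
        assert call.mean_dgc_1 == pytest.approx(1.006)

    def test_homozygous_region_undetermined(self):
        call = assign_polarity(_curve([1.0] * 30), (0, 30_000))
        assert call.copy_1 == UNDETERMINED and call.copy_2 == UNDETERMINED

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        d1 = 1.004 + 0.003 * rng.standard_normal(40)
        fwd = assign_polarity(_curve(d1), (0, 40_000))
        mirrored = TrendCurve(
            np.arange(40) * 1000, 2.0 - d1, d1, 11, 1
        )
        rev = assign_polarity(mirrored, (0, 40_000))
        assert (fwd.copy_1, fwd.copy_2) == (rev.copy_2, rev.copy_1)

    def test_region_without_points_errors(self):
        with pytest.raises(ValueError):
            assign_polarity(_curve([1.006] * 30), (500_000, 600_000))


class TestGcProfile:
    def test_uniform_sequences(self):
        assert np.allclose(gc_profile("GC" * 600, 1000, 100).gc, 1.0)
        assert np.allclose(gc_profile("ACGT" * 300, 1000, 100).gc, 0.5)

    def test_planted_at_island_is_local_minimum(self):
        rng = np.random.default_rng(6)
        base = "".join(rng.choice(list("ACGT"), size=20_000))
        island = "".join(rng.choice(list("AT"), size=3000))
        seq = base[:10_000] + island + base[10_000:]
        prof = gc_profile(seq, 1000, 200)
        lowest = prof.window_starts[np.argmin(prof.gc)]
        assert 10_000 <= lowest <= 13_000 - 1000

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            gc_profile("ACGT" * 100, 0, 1)

    def test_n_excluded_from_denominator(self):
        prof = gc_profile("GCGC" + "N" * 96 + "AT" * 50, 100, 100)
        assert prof.gc[0] == 1.0


class TestExchangeDetection:
    def test_constant_sign_no_breakpoint(self):
        assert detect_trend_exchange(_curve([1.005] * 120)) == []

    def test_single_clean_swap(self):
        """50 positive then 50 negative difference points yield exactly one
        breakpoint between points 49 and 50 (min_run scaled to the toy)."""
        d1 = [1.005] * 50 + [0.995] * 50
        bps = detect_trend_exchange(_curve(d1), min_run=20, min_amplitude=0.004)
        assert len(bps) == 1
        assert (bps[0].left_index, bps[0].right_index) == (49, 50)
        assert bps[0].start == 49_000 and bps[0].end == 50_000

    def test_matches_brute_force_runs(self):
        rng = np.random.default_rng(7)
        sign = np.concatenate(
            [np.full(60, 1.0), np.full(8, -1.0), np.full(60, 1.0), np.full(60, -1.0)]
        )
        d1 = 1 + 0.004 * sign + 0.001 * rng.standard_normal(len(sign))
        curve = _curve(d1)
        got = [(b.left_index, b.right_index) for b in detect_trend_exchange(curve, 30, 0.003)]
        expected = brute_exchange_breakpoints(list(curve.dgc_1 - curve.dgc_2), 30, 0.003)
        assert got == expected
        assert len(got) == 1  # the 8-point flip is noise, the 60-point swap real

    def test_short_flips_ignored(self):
        d1 = [1.005] * 40 + [0.995] * 5 + [1.005] * 40
        assert detect_trend_exchange(_curve(d1), min_run=20, min_amplitude=0.004) == []

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(8)
        d1 = np.concatenate([np.full(50, 1.006), np.full(50, 0.994)])
        d1 = d1 + 0.001 * rng.standard_normal(100)
        fwd = detect_trend_exchange(_curve(d1), 20, 0.003)
        mirrored = TrendCurve(np.arange(100) * 1000, 2.0 - d1, d1, 11, 1)
        rev = detect_trend_exchange(mirrored, 20, 0.003)
        assert [(b.start, b.end) for b in fwd] == [(b.start, b.end) for b in rev]

    def test_long_homozygous_stretch_separates_anchors(self):
        d1 = [1.005] * 40 + [1.0] * 40 + [0.995] * 40
        assert detect_trend_exchange(_curve(d1), min_run=20, min_amplitude=0.004) == []
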