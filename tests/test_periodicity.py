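"""Tests of binning, segmentation, the ACF estimators and the amplitude."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpskit import (
    AnalysisConfig,
    ConfigError,
    DegenerateSegmentError,
    LatticeParams,
    ParameterError,
    Positions1D,
    Profile1D,
    amplitude,
    average_acf,
    bin_profile,
    quantify_axon,
    quantify_profile,
    segment_acf,
    segment_profile,
    simulate_axon,
)
from conftest import table_from_xy


def circular_acf_oracle(counts, n_lags):
    """Direct double-loop circular autocorrelation (independent oracle)."""
    c = [float(v) for v in counts]
    n = len(c)
    m = sum(c) / n
    denom = sum((v - m) ** 2 for v in c)
    out = []
    for k in range(n_lags + 1):
        num = 0.0
        for i in range(n):
            num += (c[i] - m) * (c[(i + k) % n] - m)
        out.append(num / denom)
    return np.array(out)


def linear_acf_oracle(counts, n_lags):
    """Direct double-loop overlap-sum autocorrelation (independent oracle)."""
    c = [float(v) for v in counts]
    n = len(c)
    m = sum(c) / n
    denom = sum((v - m) ** 2 for v in c)
    out = []
    for k in range(n_lags + 1):
        num = 0.0
        for i in range(n - k):
            num += (c[i] - m) * (c[i + k] - m)
        out.append(num / denom)
    return np.array(out)


class TestAnalysisConfig:
    def test_defaults_follow_published_procedure(self, cfg):
        assert cfg.bin_nm == 10.0
        assert cfg.segment_nm == 1900.0
        assert cfg.max_window_nm == (150.0, 230.0)  # maximum sought around 190 nm
        assert cfg.min_window_nm == (50.0, 150.0)  # minimum sought around 95 nm

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"segment_nm": 1905.0},  # not a bin multiple
            {"bin_nm": -1.0},
            {"max_window_nm": (500.0, 700.0)},  # beyond max_lag
            {"min_window_nm": (0.0, 100.0)},
            {"acf_estimator": "fourier"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            AnalysisConfig(**kwargs)


class TestBinProfile:
    def test_hand_counted_histogram(self, cfg):
        pos = Positions1D(np.array([5.0, 15.0, 15.0, 25.0]), (0.0, 25.0))
        prof = bin_profile(pos, cfg)
        assert prof.counts.tolist() == [1, 2, 1]
        assert prof.bin_nm == 10.0

    def test_single_position(self, cfg):
        prof = bin_profile(Positions1D(np.array([42.0]), (0.0, 42.0)), cfg)
        assert prof.counts.sum() == 1
        assert prof.counts[4] == 1

    def test_bins_are_half_open(self, cfg):
        prof = bin_profile(Positions1D(np.array([10.0]), (0.0, 10.0)), cfg)
        assert prof.counts.tolist() == [0, 1]

    def test_total_count_preserved(self, cfg):
        rng = np.random.default_rng(1)
        s = rng.uniform(0, 5000, 1234)
        prof = bin_profile(Positions1D(s, (0.0, 5000.0)), cfg)
        assert prof.counts.sum() == 1234

    def test_empty_positions_rejected(self, cfg):
        with pytest.raises(ParameterError):
            bin_profile(Positions1D(np.array([]), (0.0, 0.0)), cfg)


class TestSegmentProfile:
    def test_integer_division_with_remainder_dropped(self, cfg):
        # 5000 nm profile -> 2 segments of 1900 nm, 1200 nm remainder dropped
        prof = Profile1D(np.full(500, 10), bin_nm=10.0)
        res = segment_profile(prof, cfg)
        assert len(res.segments) == 2
        assert not res.too_short
        assert [len(s.counts) for s in res.segments] == [190, 190]

    def test_exactly_one_segment(self, cfg):
        res = segment_profile(Profile1D(np.full(190, 10), 10.0), cfg)
        assert len(res.segments) == 1

    def test_just_short_profile_flagged(self, cfg):
        res = segment_profile(Profile1D(np.full(189, 10), 10.0), cfg)
        assert res.segments == []
        assert res.too_short

    def test_sparse_segments_dropped_and_counted(self, cfg):
        counts = np.concatenate([np.full(190, 10), np.zeros(190, int)])
        res = segment_profile(Profile1D(counts, 10.0), cfg)
        assert len(res.segments) == 1
        assert res.n_dropped == 1

    def test_segment_origins_are_adjacent(self, cfg):
        prof = Profile1D(np.full(380, 10), 10.0)
        res = segment_profile(prof, cfg)
        assert [s.origin_nm for s in res.segments] == [0.0, 1900.0]


class TestSegmentAcf:
    def test_alternating_fixture_matches_circular_oracle(self, cfg):
        seg = Profile1D(np.array([1, 0, 1, 0, 1, 0]), 10.0)
        acf = segment_acf(seg, cfg)
        # frozen from circular_acf_oracle on [1,0,1,0,1,0]
        assert acf[1] == pytest.approx(-1.0, abs=1e-12)
        assert acf[2] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(acf, circular_acf_oracle([1, 0, 1, 0, 1, 0], 5), atol=1e-12)

    def test_alternating_fixture_linear_estimator(self):
        cfg = AnalysisConfig(acf_estimator="linear")
        seg = Profile1D(np.array([1, 0, 1, 0, 1, 0]), 10.0)
        acf = segment_acf(seg, cfg)
        # frozen from linear_acf_oracle on [1,0,1,0,1,0]
        assert acf[1] == pytest.approx(-5.0 / 6.0, abs=1e-12)
        assert acf[2] == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert np.allclose(acf, linear_acf_oracle([1, 0, 1, 0, 1, 0], 5), atol=1e-12)

    def test_lag_zero_is_one(self, cfg):
        rng = np.random.default_rng(2)
        seg = Profile1D(rng.poisson(5, 190), 10.0)
        assert segment_acf(seg, cfg)[0] == 1.0

    def test_reflection_symmetry(self, cfg):
        rng = np.random.default_rng(3)
        counts = rng.poisson(5, 190)
        a = segment_acf(Profile1D(counts, 10.0), cfg)
        b = segment_acf(Profile1D(counts[::-1], 10.0), cfg)
        assert np.allclose(a, b, atol=1e-12)

    def test_scale_invariance(self, cfg):
        rng = np.random.default_rng(4)
        counts = rng.poisson(5, 190).astype(float)
        a = segment_acf(Profile1D(counts, 10.0), cfg)
        b = segment_acf(Profile1D(counts * 7.5, 10.0), cfg)
        assert np.allclose(a, b, atol=1e-12)

    def test_flat_segment_rejected(self, cfg):
        with pytest.raises(DegenerateSegmentError):
            segment_acf(Profile1D(np.full(190, 5), 10.0), cfg)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 32 - 1))
    def test_matches_double_loop_oracle_on_random_fixtures(self, seed):
        """Property: vectorized estimator equals the O(n^2) double loop, both modes."""
        cfg = AnalysisConfig()
        rng = np.random.default_rng(seed)
        counts = rng.poisson(5.0, 190)
        if counts.std() == 0:  # pragma: no cover - essentially impossible
            return
        seg = Profile1D(counts, 10.0)
        assert np.allclose(
            segment_acf(seg, cfg), circular_acf_oracle(counts, cfg.max_lag_bins),
            atol=1e-10,
        )
        lin = AnalysisConfig(acf_estimator="linear")
        assert np.allclose(
            segment_acf(seg, lin), linear_acf_oracle(counts, lin.max_lag_bins),
            atol=1e-10,
        )


class TestAverageAcf:
    def test_single_curve_identity(self):
        c = np.array([1.0, 0.5, -0.5])
        assert np.array_equal(average_acf([c]), c)

    def test_opposite_curves_cancel(self):
        c = np.array([1.0, 0.4, -0.3, 0.2])
        mean = average_acf([c, -c])
        assert np.allclose(mean, 0.0)

    def test_three_curve_hand_mean(self):
        curves = [
            np.array([1.0, 0.0, 0.0, 0.0]),
            np.array([1.0, 0.3, -0.3, 0.6]),
            np.array([1.0, 0.6, 0.3, -0.6]),
        ]
        assert np.allclose(average_acf(curves), [1.0, 0.3, 0.0, 0.0])

    def test_empty_or_mismatched_rejected(self):
        with pytest.raises(ParameterError):
            average_acf([])
        with pytest.raises(ParameterError):
            average_acf([np.ones(3), np.ones(4)])


class TestAmplitude:
    def test_sampled_cosine_gives_closed_form_amplitude(self, cfg):
        lags = cfg.lags_nm()
        acf = np.cos(2 * np.pi * lags / 190.0)
        amp, lag_max, lag_min = amplitude(acf, cfg)
        assert lag_max == 190.0
        assert lag_min in (90.0, 100.0)  # symmetric about the 95 nm half-period
        expected = 1.0 - np.cos(2 * np.pi * 90.0 / 190.0)
        assert amp == pytest.approx(expected, abs=1e-12)

    def test_flat_curve_amplitude_zero(self, cfg):
        acf = np.zeros(61)
        acf[0] = 1.0
        amp, _, _ = amplitude(acf, cfg)
        assert amp == 0.0

    def test_tie_broken_toward_window_center(self, cfg):
        acf = np.zeros(61)
        acf[0] = 1.0
        acf[16] = acf[22] = 0.5  # lags 160 and 220 tie; 190 is the window center
        _, lag_max, _ = amplitude(acf, cfg)
        assert lag_max == 160.0  # equidistant ties resolve to the smaller lag
        acf[19] = 0.5
        _, lag_max, _ = amplitude(acf, cfg)
        assert lag_max == 190.0

    def test_negative_amplitude_not_clamped(self):
        # default windows touch at 150 nm, which forces amplitude >= 0;
        # separate them to exercise the no-clamping contract
        cfg = AnalysisConfig(min_window_nm=(50.0, 140.0))
        acf = np.zeros(61)
        acf[0] = 1.0
        acf[15:24] = -0.4  # max window holds only negative values
        acf[5:15] = 0.2
        amp, _, _ = amplitude(acf, cfg)
        assert amp == pytest.approx(-0.6)

    def test_short_curve_rejected(self, cfg):
        with pytest.raises(ConfigError):
            amplitude(np.ones(10), cfg)


class TestQuantifyAxon:
    def test_clean_lattice_recovers_period(self, clean_lattice_params):
        hits = 0
        for s in range(20):
            r = quantify_axon(simulate_axon(clean_lattice_params, seed=s))
            assert r.status == "ok"
            if r.lag_max_nm == 190.0:
                hits += 1
        assert hits >= 19

    def test_single_localization_unquantifiable(self, cfg):
        r = quantify_axon(table_from_xy([5.0], [5.0]), cfg=cfg)
        assert r.status == "unquantifiable"
        assert np.isnan(r.amplitude)

    def test_short_axon_unquantifiable(self, cfg):
        p = LatticeParams(axon_length_um=1.0)  # under one 1900 nm segment
        r = quantify_axon(simulate_axon(p, seed=0), cfg=cfg)
        assert r.status == "unquantifiable"

    def test_acf_mean_starts_at_one_and_bookkeeping(self, clean_lattice_params):
        r = quantify_axon(simulate_axon(clean_lattice_params, seed=1))
        assert r.acf_mean[0] == 1.0
        assert r.n_segments_used == len(r.acf_segments) > 0
        assert r.amplitude == pytest.approx(
            r.acf_mean[int(r.lag_max_nm // 10)] - r.acf_mean[int(r.lag_min_nm // 10)]
        )

    def test_shift_by_whole_segment_changes_nothing(self, cfg):
        rng = np.random.default_rng(7)
        s = rng.uniform(0, 3800, 4000)
        base = quantify_profile(bin_profile(Positions1D(s, (0, 3800)), cfg), cfg)
        shifted = quantify_profile(
            bin_profile(Positions1D(s + 1900.0, (0, 5700)), cfg), cfg
        )
        assert shifted.amplitude == base.amplitude
        assert np.allclose(shifted.acf_mean, base.acf_mean)
        assert shifted.n_segments_dropped == base.n_segments_dropped + 1

    def test_reversed_profile_same_amplitude(self, cfg):
        rng = np.random.default_rng(8)
        counts = rng.poisson(5, 380)  # exactly two segments
        a = quantify_profile(Profile1D(counts, 10.0), cfg)
        b = quantify_profile(Profile1D(counts[::-1], 10.0), cfg)
        assert b.amplitude == pytest.approx(a.amplitude, abs=1e-12)

    def test_per_segment_amplitude_variant(self, clean_lattice_params, cfg):
        t = simulate_axon(clean_lattice_params, seed=2)
        mean_curve = quantify_axon(t, cfg=cfg)
        per_seg = quantify_axon(t, cfg=cfg, amplitude_from="per-segment")
        assert per_seg.status == "ok"
        assert per_seg.amplitude != mean_curve.amplitude  # distinct estimators

    def test_monotone_in_jitter_and_fraction(self):
        """Mean amplitude decreases with lattice disorder and increases with
        the periodic fraction (30 axons per grid point)."""
        n = 30

        def mean_amp(**kwargs):
            p = LatticeParams(axon_length_um=7.6, density_per_um=300.0, **kwargs)
            amps = [
                quantify_axon(simulate_axon(p, seed=100 * s)).amplitude
                for s in range(n)
            ]
            return float(np.mean(amps))

        # Below the 10 nm bin width the variance normalization makes the
        # amplitude rise slightly as rings broaden, so the disorder-dominated
        # decreasing regime starts around ring widths of two bins.
        jitter_means = [
            mean_amp(periodic_fraction=1.0, jitter_nm=j) for j in (20, 40, 80)
        ]
        assert all(a >= b for a, b in zip(jitter_means, jitter_means[1:]))
        f_means = [
            mean_amp(periodic_fraction=f, jitter_nm=10.0)
            for f in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(a <= b for a, b in zip(f_means, f_means[1:]))
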