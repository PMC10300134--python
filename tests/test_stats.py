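"""Tests of the population-statistics layer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promkin.fitting import CellTrace, FitConfig
from promkin.simulate import (
    PopulationConfig,
    generate_bimodal_sample,
    generate_noise_points,
    generate_population,
)
from promkin.stats import (
    NoisePoint,
    align_by_event,
    bimodality_coefficient,
    bootstrap_lag_ci,
    compute_cv,
    cross_calibrate,
    noise_scaling_regression,
    normalize_to_maxgal1,
    one_tailed_z_test,
    otsu_threshold,
    violin_summary,
)


def _brute_force_otsu(values, n_bins):
    """Independent exhaustive scan over every candidate bin edge."""
    counts, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_var, best_edge = -1.0, None
    for k in range(1, n_bins):
        w0, w1 = counts[:k].sum(), counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = float((counts[:k] * centers[:k]).sum()) / w0
        mu1 = float((counts[k:] * centers[k:]).sum()) / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-12 * max(best_var, 1.0):
            best_var, best_edge = var, edges[k]
    return best_edge


class TestNormalization:
    def test_self_normalization_gives_mean_one(self):
        t = np.arange(0.0, 100.0, 10.0)
        vals = np.full(t.size, 150.0)
        traces = [CellTrace("c", t, vals)]
        out = normalize_to_maxgal1(traces, 150.0)
        assert np.mean(out[0].fluorescence) == pytest.approx(1.0)

    def test_zero_trace_stays_zero(self):
        t = np.arange(0.0, 50.0, 10.0)
        out = normalize_to_maxgal1([CellTrace("c", t, np.zeros(t.size))], 2.0)
        assert np.all(out[0].fluorescence == 0)

    def test_idempotent_with_unit_reference(self):
        t = np.arange(0.0, 50.0, 10.0)
        tr = CellTrace("c", t, np.linspace(0, 1, t.size))
        once = normalize_to_maxgal1([tr], 1.0)
        twice = normalize_to_maxgal1(once, 1.0)
        assert np.array_equal(once[0].fluorescence, twice[0].fluorescence)

    def test_rejects_nonpositive_reference(self):
        t = np.arange(0.0, 50.0, 10.0)
        with pytest.raises(ValueError):
            normalize_to_maxgal1([CellTrace("c", t, np.ones(t.size))], 0.0)

    def test_weak_preset_scales_to_its_relative_steady_state(self, protocol):
        """A population 50x weaker than the reference lands at ~0.02 of
        the reference's stationary mean (GALL-like preset)."""
        from promkin.model import KineticParams

        strong = PopulationConfig(n_cells=80, seed=1)
        weak_params = KineticParams(b=1e-4 / 50, i=1e-3 / 50, f=0.035, d=0.017,
                                    t_on=10.0, t_off=5.0)
        weak = PopulationConfig(n_cells=80, central_params=weak_params,
                                noise_sd=0.0005, seed=2)
        ref_traces, _ = generate_population(strong)
        weak_traces, _ = generate_population(weak)
        ref = np.mean([tr.value_at(protocol.t_end) for tr in ref_traces])
        out = normalize_to_maxgal1(weak_traces, ref)
        level = np.mean([tr.value_at(protocol.t_end) for tr in out])
        assert level == pytest.approx(0.02, rel=0.2)


class TestCrossCalibrate:
    def test_identical_references(self):
        assert cross_calibrate(3.0, 3.0) == 1.0

    def test_double_gain_halves(self):
        assert cross_calibrate(1.0, 2.0) == 0.5

    def test_recovers_known_gain_ratio_within_noise(self, rng):
        g = 3.7
        ref_a = 10.0 + rng.normal(0, 0.05)
        ref_b = g * 10.0 + rng.normal(0, 0.05)
        assert cross_calibrate(ref_a, ref_b) == pytest.approx(1 / g, rel=0.05)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            cross_calibrate(0.0, 1.0)


class TestBootstrapLagCI:
    def test_zero_noise_identical_cells_zero_width(self, noiseless_trace, fit_config):
        traces = [
            CellTrace(f"c{k}", noiseless_trace.times, noiseless_trace.fluorescence)
            for k in range(10)
        ]
        ci_on, ci_off, _ = bootstrap_lag_ci(
            traces, fit_config, n_resamples=50, sample_size=10, seed=0)
        assert ci_on[1] - ci_on[0] == pytest.approx(0.0, abs=1e-9)
        assert ci_off[1] - ci_off[0] == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_under_seed(self, fit_config):
        traces, _ = generate_population(PopulationConfig(n_cells=40, seed=8))
        a = bootstrap_lag_ci(traces, fit_config, n_resamples=100, sample_size=30,
                             seed=4)[0]
        b = bootstrap_lag_ci(traces, fit_config, n_resamples=100, sample_size=30,
                             seed=4)[0]
        assert a == b

    def test_ci_endpoints_ordered_and_cover_point_estimate(self, fit_config):
        traces, _ = generate_population(PopulationConfig(n_cells=60, seed=9))
        ci_on, ci_off, info = bootstrap_lag_ci(
            traces, fit_config, n_resamples=200, sample_size=50, seed=5)
        assert ci_on[0] <= ci_on[1]
        assert ci_off[0] <= ci_off[1]
        assert info["dropped"] < 200

    def test_requires_enough_cells(self, noiseless_trace, fit_config):
        with pytest.raises(ValueError):
            bootstrap_lag_ci([noiseless_trace], fit_config, sample_size=5)


class TestComputeCV:
    def test_constant_sample_is_zero(self):
        assert compute_cv([2.0, 2.0, 2.0]) == 0.0

    def test_simple_arithmetic(self):
        # sample SD (n-1) of {1,2,3} is 1
        assert compute_cv([1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_lognormal_closed_form(self):
        sigma = 0.25
        rng = np.random.default_rng(0)
        x = rng.lognormal(0.0, sigma, 10_000)
        assert compute_cv(x) == pytest.approx(np.sqrt(np.exp(sigma**2) - 1), rel=0.05)

    def test_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError):
            compute_cv([-1.0, 1.0])


class TestNoiseScaling:
    def test_exact_power_law(self):
        means = np.logspace(-2, 0, 8)
        pts = [NoisePoint(f"s{k}", m, 0.3 * m**-0.5) for k, m in enumerate(means)]
        slope, intercept, r2, ci = noise_scaling_regression(pts)
        assert slope == pytest.approx(-0.5, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_exclusions_honored(self):
        means = np.logspace(-2, 0, 8)
        pts = [NoisePoint(f"s{k}", m, 0.3 * m**-0.5) for k, m in enumerate(means)]
        pts[0] = NoisePoint("s0", pts[0].mean_expression, 10.0)  # gross outlier
        slope, *_ = noise_scaling_regression(pts, exclusions=["s0"])
        assert slope == pytest.approx(-0.5, abs=1e-9)

    def test_needs_three_points(self):
        pts = [NoisePoint("a", 1.0, 0.1), NoisePoint("b", 2.0, 0.1)]
        with pytest.raises(ValueError):
            noise_scaling_regression(pts)

    def test_slope_ci_covers_truth_on_synthetic_panels(self):
        hits = 0
        for seed in range(50):
            pts = generate_noise_points(slope=-0.32, scatter_sd=0.05, seed=seed)
            _, _, _, ci = noise_scaling_regression(pts)
            hits += ci[0] <= -0.32 <= ci[1]
        assert hits >= 45


class TestBimodality:
    def test_normal_population_value_one_third(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 200_000)
        assert bimodality_coefficient(x) == pytest.approx(1 / 3, abs=0.01)

    def test_uniform_large_sample_near_five_ninths(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 1_000_000)
        assert bimodality_coefficient(x) == pytest.approx(5 / 9, abs=0.01)

    def test_exponential_large_sample_near_five_ninths(self):
        rng = np.random.default_rng(3)
        x = rng.exponential(1.0, 1_000_000)
        assert bimodality_coefficient(x) == pytest.approx(5 / 9, abs=0.02)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        loc=st.floats(-100.0, 100.0),
        scale=st.floats(0.01, 100.0),
        seed=st.integers(0, 1000),
    )
    def test_affine_invariance_property(self, loc, scale, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 200)
        assert bimodality_coefficient(loc + scale * x) == pytest.approx(
            bimodality_coefficient(x), rel=1e-9
        )


class TestViolinSummary:
    def test_bandwidth_formula_and_outlier_rule(self):
        rng = np.random.default_rng(4)
        x = rng.normal(10.0, 2.0, 500)
        vs = violin_summary(x)
        kept = vs.kept
        assert vs.bandwidth == pytest.approx(0.8 * kept.std(ddof=1) / kept.size**0.2)
        assert np.all(np.abs(vs.outliers - x.mean()) > 2 * x.std(ddof=1))
        assert not vs.is_bimodal

    def test_bandwidth_scaling_properties(self):
        """Bandwidth homogeneity: scaling data by c scales bandwidth by c;
        bandwidth falls exactly as n^(-1/5)."""
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 1000)
        bw = violin_summary(x).bandwidth
        assert violin_summary(3.0 * x).bandwidth == pytest.approx(3.0 * bw, rel=1e-9)
        kept = violin_summary(x).kept
        direct = 0.8 * kept.std(ddof=1) / kept.size**0.2
        assert bw == pytest.approx(direct)

    def test_seeded_uniform_sample_classified_unimodal(self):
        x = np.random.default_rng(6).uniform(0, 1, 100_000)
        vs = violin_summary(x)
        assert vs.bimodality_coefficient == pytest.approx(5 / 9, abs=0.01)

    def test_separated_mixture_split_near_midpoint(self):
        x = generate_bimodal_sample(2000, [0.5, 0.5], [-3, 3], [1, 1], seed=7)
        vs = violin_summary(x)
        assert vs.is_bimodal
        assert abs(vs.split_threshold) <= 0.5
        assert vs.subpop_bandwidths is not None
        assert vs.bandwidth == pytest.approx(min(vs.subpop_bandwidths))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            violin_summary([1.0, 2.0, 3.0])


class TestOtsu:
    def test_two_level_sample_threshold_between_levels(self):
        thr = otsu_threshold(np.array([0, 0, 0, 1, 1, 1], dtype=float), n_bins=10)
        assert 0 < thr < 1

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(8)
        for trial in range(20):
            n = rng.integers(10, 200)
            x = np.concatenate([
                rng.normal(0, 1, n // 2), rng.normal(4, 1.5, n - n // 2)])
            for bins in (16, 64, 256):
                assert otsu_threshold(x, bins) == pytest.approx(
                    _brute_force_otsu(x, bins), abs=1e-12
                )

    def test_affine_equivariance(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
        thr = otsu_threshold(x, 64)
        assert otsu_threshold(2.0 * x + 7.0, 64) == pytest.approx(
            2.0 * thr + 7.0, rel=1e-9
        )

    def test_rejects_constant_input(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.ones(10))


class TestAlignByEvent:
    def _trace(self, offset, cell_id):
        t = np.arange(0.0, 200.0, 10.0)
        return CellTrace(cell_id, t, np.sin(2 * np.pi * (t - offset) / 100.0))

    def test_all_events_at_zero_is_identity(self):
        traces = [self._trace(0.0, f"c{k}") for k in range(3)]
        aligned, _ = align_by_event(traces, [0.0, 0.0, 0.0])
        for a, b in zip(aligned, traces):
            assert np.array_equal(a.times, b.times)

    def test_offset_twins_overlay_perfectly(self):
        a = self._trace(0.0, "a")
        b = self._trace(20.0, "b")
        aligned, mean_df = align_by_event([a, b], [0.0, 20.0])
        overlap = mean_df["sd"].to_numpy()
        assert np.all(overlap < 1e-12)

    def test_alignment_restores_oscillation_amplitude(self, rng):
        """Phase-jittered periodic traces average out unaligned but not
        after event alignment."""
        offsets = rng.choice(np.arange(0.0, 100.0, 10.0), size=15)
        traces = [self._trace(off, f"c{k}") for k, off in enumerate(offsets)]
        unaligned = np.mean([tr.fluorescence for tr in traces], axis=0)
        _, mean_df = align_by_event(traces, list(offsets))
        assert mean_df["mean"].abs().max() > np.abs(unaligned).max() + 0.2

    def test_missing_event_rejected(self):
        with pytest.raises(ValueError):
            align_by_event([self._trace(0.0, "a")], [np.nan])


class TestOneTailedZ:
    def test_identical_samples_give_half(self):
        x = np.arange(10.0)
        assert one_tailed_z_test(x, x.copy()) == pytest.approx(0.5)

    def test_large_shift_gives_tiny_p(self):
        rng = np.random.default_rng(10)
        a = rng.normal(10.0, 1.0, 50)
        b = rng.normal(0.0, 1.0, 50)
        assert one_tailed_z_test(a, b) < 1e-10

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.25, 1.0, 100)
        b = rng.normal(0.0, 1.0, 100)
        p_z = one_tailed_z_test(a, b)
        pooled = np.concatenate([a, b])
        obs = a.mean() - b.mean()
        count = 0
        n_perm = 20_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            count += (perm[:100].mean() - perm[100:].mean()) >= obs
        p_perm = count / n_perm
        assert p_z == pytest.approx(p_perm, abs=0.02)
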