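"""Phase estimation, model gaits, the metric tensor and gait distances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitspace as gs
from gaitspace.space import ConstantSignalError, LegOrdering, PhaseSeries

phase_vectors = st.lists(
    st.floats(0, 0.999), min_size=2, max_size=8
).map(np.array)


class TestStandardize:
    def test_sample_sd_normalization(self):
        np.testing.assert_allclose(gs.standardize([1.0, 2.0, 3.0]), [-1, 0, 1])

    def test_idempotent_on_standardized_input(self):
        x = gs.standardize(np.random.default_rng(0).normal(3, 2, 100))
        np.testing.assert_allclose(gs.standardize(x), x, atol=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ConstantSignalError):
            gs.standardize(np.full(10, 2.0))


class TestEstimatePhase:
    def test_recovers_linear_phase_of_a_cosine(self):
        f, fs = 6.0, 500.0
        t = np.arange(int(fs)) / fs  # integer number of cycles
        y = np.cos(2 * np.pi * f * t)
        v = -2 * np.pi * f * np.sin(2 * np.pi * f * t)
        phi = gs.estimate_phase(gs.standardize(y), gs.standardize(v))
        err = np.abs(gs.signed_circular_delta(phi, (f * t) % 1))
        assert err.max() < 1e-6

    def test_quarter_period_shift_moves_phase_by_quarter_cycle(self):
        f, fs = 5.0, 500.0
        t = np.arange(int(fs)) / fs
        shift = 1 / (4 * f)

        def phase_of(t0):
            y = np.cos(2 * np.pi * f * (t + t0))
            v = -2 * np.pi * f * np.sin(2 * np.pi * f * (t + t0))
            return gs.estimate_phase(gs.standardize(y), gs.standardize(v))

        d = gs.signed_circular_delta(phase_of(shift), phase_of(0.0))
        np.testing.assert_allclose(d, 0.25, atol=1e-9)

    def test_noisy_cosine_phase_error_is_small(self):
        """SNR-10 additive noise perturbs the phase by < 0.03 cycles RMS."""
        from gaitspace.trackio import local_quadratic_derivative

        f, fs = 6.0, 500.0
        t = np.arange(int(2 * fs)) / fs
        rng = np.random.default_rng(0)
        y = np.cos(2 * np.pi * f * t) + rng.normal(0, 1 / np.sqrt(20), t.size)
        v = local_quadratic_derivative(y, 40.0, fs)
        phi = gs.estimate_phase(gs.standardize(y), gs.standardize(v))
        err = gs.signed_circular_delta(phi, (f * t) % 1)[10:-10]
        assert np.sqrt((err**2).mean()) < 0.03


class TestPhaseDifferences:
    def test_alternating_phases_give_all_half(self):
        phases = np.tile([[0.0], [0.5]], (4, 1))[:8]  # 0, .5, 0, .5, ...
        series = PhaseSeries(
            LegOrdering(gs.CANONICAL_LEGS), np.repeat(phases, 10, axis=1)
        )
        dphi = gs.phase_differences(series)
        np.testing.assert_allclose(dphi, 0.5)
        assert dphi.shape == (10, 7)

    def test_in_phase_legs_give_zero(self):
        series = PhaseSeries(
            LegOrdering(("L1", "L2", "L3")), np.full((3, 5), 0.37)
        )
        np.testing.assert_allclose(gs.phase_differences(series), 0.0)

    @given(phase_vectors, st.floats(-2, 2))
    @settings(max_examples=50, deadline=None)
    def test_common_phase_invariance(self, phases, shift):
        a = PhaseSeries(
            LegOrdering(gs.CANONICAL_LEGS[: len(phases)]), phases[:, None]
        )
        b = PhaseSeries(
            LegOrdering(gs.CANONICAL_LEGS[: len(phases)]),
            (phases[:, None] + shift) % 1.0,
        )
        circ = gs.signed_circular_delta(
            gs.phase_differences(a), gs.phase_differences(b)
        )
        np.testing.assert_allclose(circ, 0.0, atol=1e-9)


class TestModelGaits:
    def test_eight_leg_alternating_tetrapod(self):
        (alt,) = gs.model_gaits(8)
        assert alt.name == "ALT"
        assert alt.point.dphi == (0.5,) * 7

    def test_six_leg_models(self):
        abt, mt = gs.model_gaits(6)
        assert abt.point.dphi == (0.5, 0.5, 0.0, 0.5, 0.5)
        assert mt.point.dphi == (0.5,) * 5

    def test_unsupported_combination(self):
        with pytest.raises(LookupError):
            gs.model_gaits(7)
        with pytest.raises(LookupError):
            gs.model_gaits(6, missing={"L1", "L2"})


class TestCircularDelta:
    @pytest.mark.parametrize(
        "a,b,expected", [(0.9, 0.1, 0.2), (0.25, 0.75, 0.5), (0.37, 0.37, 0.0)]
    )
    def test_wraparound_cases(self, a, b, expected):
        assert gs.circular_delta(a, b) == pytest.approx(expected)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_symmetry(self, a, b):
        d = gs.circular_delta(a, b)
        assert 0 <= d <= 0.5
        assert d == pytest.approx(gs.circular_delta(b, a))
        assert abs(gs.signed_circular_delta(a, b)) == pytest.approx(d)


class TestMetricTensor:
    def test_closed_form_values(self):
        m6 = gs.metric_tensor(6)
        assert m6.g[2, 2] == pytest.approx(1.5)
        assert m6.g.sum() == pytest.approx(17.5)
        assert m6.d_max == pytest.approx(0.5 * np.sqrt(17.5))
        m8 = gs.metric_tensor(8)
        assert m8.g.sum() == pytest.approx(42.0)
        assert m8.d_max == pytest.approx(0.5 * np.sqrt(42.0))

    @pytest.mark.parametrize("n", [2, 4, 6, 8, 10])
    def test_positive_definite_with_positive_entries(self, n):
        m = gs.metric_tensor(n)
        assert (m.g > 0).all()
        assert np.linalg.eigvalsh(m.g).min() > 0
        np.testing.assert_allclose(m.g, m.g.T)

    def test_too_few_legs(self):
        with pytest.raises(ValueError):
            gs.metric_tensor(1)


class TestGaitDistance:
    def test_self_distance_is_zero(self, metric6):
        p = gs.GaitPoint((0.1, 0.7, 0.3, 0.9, 0.5))
        d, delta = gs.gait_distance(p, p, metric6)
        assert d == 0.0 and delta == 0.0

    def test_ablated_tetrapod_to_modified_tripod(self, metric6, models6):
        abt, mt = models6
        _, delta = gs.gait_distance(abt, mt, metric6)
        assert round(delta, 2) == 0.29

    def test_antipodal_gaits_attain_unit_distance(self, metric6):
        a = np.zeros(5)
        b = np.full(5, 0.5)
        _, delta = gs.gait_distance(a, b, metric6)
        assert delta == pytest.approx(1.0)

    @given(phase_vectors, phase_vectors)
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_normalized_range(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        metric = gs.metric_tensor(n + 1)
        d_ab, delta_ab = gs.gait_distance(a, b, metric)
        d_ba, delta_ba = gs.gait_distance(b, a, metric)
        assert d_ab == pytest.approx(d_ba)
        assert 0 <= delta_ab <= 1 + 1e-9

    def test_triangle_inequality_on_fixed_lifts(self, metric6):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b, c = rng.uniform(0, 0.2, (3, 5))  # small separations: one branch
            dab = gs.gait_distance(a, b, metric6)[0]
            dbc = gs.gait_distance(b, c, metric6)[0]
            dac = gs.gait_distance(a, c, metric6)[0]
            assert dac <= dab + dbc + 1e-12

    def test_dimension_mismatch(self, metric6):
        with pytest.raises(ValueError):
            gs.gait_distance(np.zeros(7), np.zeros(7), metric6)


def brute_force_quotient_distance(dphi_a, dphi_b, n_grid=40001):
    """Leg-space distance minimized over a common phase, on a fine grid.

    Independent of the metric tensor: lift both gaits to per-leg phases,
    scan the common offset c, and sum squared per-leg minimal circular
    distances.  Valid as an oracle for nearby gaits.
    """
    pa = np.concatenate([[0.0], np.cumsum(dphi_a)])
    pb = np.concatenate([[0.0], np.cumsum(dphi_b)])
    c = np.linspace(0.0, 1.0, n_grid)
    d = np.abs(pa[None, :] - (pb[None, :] + c[:, None])) % 1.0
    d = np.minimum(d, 1.0 - d)
    return np.sqrt((d**2).sum(axis=1)).min()


class TestMetricOracle:
    def test_quadratic_form_matches_quotient_distance_near_field(self, metric6):
        """The metric tensor is the common-phase quotient of the flat leg metric.

        Draw gait pairs with per-coordinate separations below 0.25 cycles and
        within the ball |x|_g < lambda_min/2 (half the shortest lattice
        vector), where the single-branch quadratic form provably equals the
        brute-force quotient distance.
        """
        from itertools import product

        G = metric6.g
        lam = min(
            np.sqrt(m @ G @ m)
            for m in product(range(-2, 3), repeat=5)
            if any(m)
        )
        rng = np.random.default_rng(0)
        kept = 0
        while kept < 100:
            a = rng.uniform(0, 1, 5)
            x = rng.uniform(-0.25, 0.25, 5)
            if np.sqrt(x @ G @ x) >= lam / 2:
                continue
            b = (a + x) % 1.0
            d, _ = gs.gait_distance(a, b, metric6)
            oracle = brute_force_quotient_distance(a, b)
            assert abs(d - oracle) / oracle < 1e-3
            kept += 1


class TestDatasetToModel:
    def test_dataset_equal_to_model_has_zero_distance(self, metric6, models6):
        abt = models6[0]
        pts = np.tile(abt.point.as_array(), (5, 1))
        mean, (lo, hi) = gs.dataset_to_model(pts, abt, metric6, seed=0)
        assert mean == 0.0 and lo == 0.0 and hi == 0.0

    def test_von_mises_cloud_ci_brackets_the_mean(self, metric6, models6):
        mt = models6[1]
        pts = gs.sample_gait_points(mt, 8.0, 1000, seed=0)
        mean, (lo, hi) = gs.dataset_to_model(pts, mt, metric6, seed=0)
        assert lo <= mean <= hi
        assert mean < 0.2

    def test_same_seed_reproduces_ci(self, metric6, models6):
        pts = gs.sample_gait_points(models6[1], 4.0, 200, seed=1)
        r1 = gs.dataset_to_model(pts, models6[1], metric6, seed=42)
        r2 = gs.dataset_to_model(pts, models6[1], metric6, seed=42)
        assert r1 == r2

    def test_empty_dataset_rejected(self, metric6, models6):
        with pytest.raises(ValueError):
            gs.dataset_to_model(np.empty((0, 5)), models6[0], metric6)
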