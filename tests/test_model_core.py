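"""Sample-model construction, matching, classification and updating."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from devibe import (
    AlgoParams,
    BACKGROUND,
    FOREGROUND,
    classify,
    classify_frame,
    count_matches,
    init_model,
    simulate_sample_survival,
    stochastic_update,
    survival_probability,
    update_frame,
)


class TestInitModel:
    def test_uniform_frame_gives_uniform_samples(self, params, rng):
        frame = np.full((6, 7, 3), 50.0)
        model = init_model(frame, params, rng)
        assert model.samples.shape == (6, 7, 20, 3)
        assert np.all(model.samples == 50.0)

    def test_single_pixel_frame(self, params, rng):
        model = init_model(np.full((1, 1, 3), 13.0), params, rng)
        assert np.all(model.samples == 13.0)

    def test_center_samples_come_from_the_nine_neighborhood_values(self, params, rng):
        values = np.arange(9, dtype=float).reshape(3, 3) * 10
        model = init_model(values, params, rng)
        assert set(model.samples[1, 1].ravel()) <= set(values.ravel())

    def test_corner_samples_restricted_to_clipped_neighborhood(self, params, rng):
        values = np.arange(16, dtype=float).reshape(4, 4)
        model = init_model(values, params, rng)
        corner_allowed = {values[0, 0], values[0, 1], values[1, 0], values[1, 1]}
        assert set(model.samples[0, 0].ravel()) <= corner_allowed

    def test_empty_frame_rejected(self, params, rng):
        with pytest.raises(ValueError):
            init_model(np.empty((0, 0, 3)), params, rng)

    def test_every_sample_traceable_to_first_frame(self, params, rng):
        frame = np.random.default_rng(0).integers(0, 256, (8, 8)).astype(float)
        model = init_model(frame, params, rng)
        # provenance: each pixel's samples are values of its 3x3 window
        for r in range(8):
            for c in range(8):
                window = frame[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2]
                assert set(model.samples[r, c].ravel()) <= set(window.ravel())


class TestCountMatches:
    def test_all_identical_within_radius(self):
        assert count_matches((10, 10, 10), [(10, 10, 10)] * 20, 20.0) == 20

    def test_all_identical_outside_radius(self):
        # distance sqrt(3*90^2) ~ 155.88 >= 20
        assert count_matches((100, 100, 100), [(10, 10, 10)] * 20, 20.0) == 0

    def test_matches_brute_force_on_random_values(self):
        g = np.random.default_rng(7)
        value = g.uniform(0, 255, 3)
        samples = g.uniform(0, 255, (20, 3))
        expected = sum(
            1 for s in samples if np.sqrt(((s - value) ** 2).sum()) < 20.0
        )
        assert count_matches(value, samples, 20.0) == expected

    def test_strict_inequality_at_exact_radius(self):
        assert count_matches((0.0,), [(5.0,)], 5.0) == 0
        assert count_matches((0.0,), [(5.0,)], 5.0 + 1e-9) == 1

    def test_dimensionality_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_matches((1, 2), [(1, 2, 3)], 20.0)


class TestClassify:
    def test_exactly_min_matches_is_background(self, params):
        samples = [(0, 0, 0)] * 2 + [(200, 200, 200)] * 18
        assert classify((0, 0, 0), samples, params) == BACKGROUND

    def test_zero_matches_is_foreground(self, params):
        assert classify((0, 0, 0), [(200, 200, 200)] * 20, params) == FOREGROUND

    def test_oracle_equivalence_on_random_instances(self, params):
        g = np.random.default_rng(11)
        for _ in range(500):
            value = g.uniform(0, 255, 3)
            samples = g.uniform(0, 255, (20, 3))
            n = sum(1 for s in samples if np.linalg.norm(s - value) < params.radius)
            want = BACKGROUND if n >= params.min_matches else FOREGROUND
            assert classify(value, samples, params) == want

    def test_classify_frame_agrees_with_scalar_classify(self, params):
        g = np.random.default_rng(3)
        frame = g.uniform(0, 255, (5, 6, 3)).astype(np.float32)
        model = init_model(g.uniform(0, 255, (5, 6, 3)), params, g)
        fg = classify_frame(model, frame, params)
        for r in range(5):
            for c in range(6):
                scalar = classify(frame[r, c], model.samples[r, c], params)
                assert fg[r, c] == (scalar == FOREGROUND)


class TestStochasticUpdate:
    def test_phi_one_always_replaces_own_sample(self, rng):
        p = AlgoParams(subsample_factor=1)
        model = init_model(np.zeros((3, 3, 3)), p, rng)
        stochastic_update(model, (1, 1), (99, 99, 99), p, rng)
        assert (model.samples[1, 1] == 99).all(axis=-1).any()

    def test_huge_phi_never_replaces(self, rng):
        p = AlgoParams(subsample_factor=2**31)
        model = init_model(np.zeros((3, 3, 3)), p, rng)
        for _ in range(1000):
            stochastic_update(model, (1, 1), (99, 99, 99), p, rng)
        assert np.all(model.samples == 0)

    def test_self_replacement_frequency_matches_binomial_law(self):
        p = AlgoParams()  # phi = 16
        g = np.random.default_rng(5)
        n_calls, hits = 16000, 0
        model = init_model(np.zeros((3, 3, 1)), p, g)
        for _ in range(n_calls):
            model.samples[1, 1] = 0.0
            stochastic_update(model, (1, 1), (1.0,), p, g)
            hits += int((model.samples[1, 1] == 1.0).any())
        rate = 1 / 16
        sd = np.sqrt(rate * (1 - rate) / n_calls)
        assert abs(hits / n_calls - rate) < 3 * sd

    def test_sample_count_conserved_and_out_of_bounds_rejected(self, params, rng):
        model = init_model(np.zeros((4, 4, 3)), params, rng)
        for _ in range(200):
            stochastic_update(model, (2, 2), (7, 7, 7), params, rng)
        assert model.samples.shape == (4, 4, 20, 3)
        with pytest.raises(ValueError):
            stochastic_update(model, (4, 0), (7, 7, 7), params, rng)

    def test_neighbor_updates_store_current_value_in_a_neighbor(self, rng):
        p = AlgoParams(subsample_factor=1)
        model = init_model(np.zeros((3, 3, 1)), p, rng)
        stochastic_update(model, (0, 0), (42.0,), p, rng)
        neighbors = [(0, 1), (1, 0), (1, 1)]
        assert any((model.samples[r, c] == 42.0).any() for r, c in neighbors)


class TestUpdateFrame:
    def test_updates_confined_to_background_mask_neighborhood(self, rng):
        p = AlgoParams(subsample_factor=1)
        model = init_model(np.zeros((5, 5, 1)), p, rng)
        bg = np.zeros((5, 5), dtype=bool)
        bg[2, 2] = True
        update_frame(model, np.full((5, 5, 1), 9.0), bg, p, rng)
        changed = (model.samples == 9.0).any(axis=(2, 3))
        rows, cols = np.nonzero(changed)
        assert (abs(rows - 2) <= 1).all() and (abs(cols - 2) <= 1).all()
        assert changed[2, 2]

    def test_deterministic_under_seed(self, params):
        frame = np.random.default_rng(0).uniform(0, 255, (6, 6, 3))
        bg = np.ones((6, 6), dtype=bool)
        runs = []
        for _ in range(2):
            g = np.random.default_rng(123)
            model = init_model(frame, params, g)
            for _ in range(10):
                update_frame(model, frame, bg, params, g)
            runs.append(model.samples.copy())
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_tags_cleared_exactly_where_samples_replaced(self, rng):
        p = AlgoParams(subsample_factor=1)
        model = init_model(np.zeros((4, 4, 1)), p, rng)
        tags = np.ones((4, 4, p.n_samples), dtype=bool)
        bg = np.ones((4, 4), dtype=bool)
        update_frame(model, np.full((4, 4, 1), 5.0), bg, p, rng, tags=tags)
        replaced = (model.samples[..., 0] == 5.0)
        assert np.array_equal(~tags, replaced)


class TestLifespanLaw:
    def test_no_elapsed_time_means_certain_survival(self):
        assert survival_probability(20, 0) == 1.0

    def test_single_step_survival_is_nineteen_twentieths(self):
        assert survival_probability(20, 1) == pytest.approx(0.95)

    def test_power_and_exponential_forms_agree(self):
        for n in (2, 5, 20, 100):
            for dt in (0, 1, 7, 50, 320.5):
                a = survival_probability(n, dt, form="power")
                b = survival_probability(n, dt, form="exponential")
                assert a == pytest.approx(b, abs=1e-12)
        assert survival_probability(20, 50) == pytest.approx(
            np.exp(-np.log(20 / 19) * 50)
        )

    def test_degenerate_model_size_rejected(self):
        with pytest.raises(ValueError):
            survival_probability(1, 5)

    def test_empirical_survival_matches_law_and_decays_monotonically(self):
        p = AlgoParams()  # N=20, phi=16
        curve = simulate_sample_survival((100, 100), p, 320, np.random.default_rng(2))
        assert (np.diff(curve) <= 0).all()
        expected = (1 - 1 / (p.n_samples * p.subsample_factor)) ** 320
        n_tags = 100 * 100 * p.n_samples
        sd = np.sqrt(expected * (1 - expected) / n_tags)
        assert abs(curve[-1] - expected) < 3 * sd


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    value=st.lists(st.floats(0, 255), min_size=3, max_size=3),
    radius=st.floats(0.1, 300),
    data=st.lists(
        st.lists(st.floats(0, 255), min_size=3, max_size=3), min_size=1, max_size=30
    ),
)
def test_count_matches_bounded_and_matches_naive_loop(value, radius, data):
    n = count_matches(value, data, radius)
    assert 0 <= n <= len(data)
    naive = sum(
        1
        for s in data
        if np.sqrt(sum((a - b) ** 2 for a, b in zip(s, value))) < radius
    )
    assert n == naive
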