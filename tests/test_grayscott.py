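"""Gray-Scott simulator: initial conditions, update rule, stability,
parameter modulation, and pattern metrics."""

import numpy as np
import pytest

from protoelec import grayscott, synthetic
from protoelec.errors import InstabilityError, InvalidSpecError
from protoelec.grayscott import (
    ACTIN_GS,
    MIXTURE_GS,
    PROTEINOID_GS,
    GrayScottParams,
    GrayScottState,
    init_state,
    laplacian,
    modulate_params,
    pattern_metrics,
    simulate,
    step,
)


def step_loop_oracle(a, b, params, dt=1.0):
    """From-scratch double-loop Euler update with periodic boundaries."""
    n = a.shape[0]
    a_new = np.empty_like(a)
    b_new = np.empty_like(b)
    for i in range(n):
        for j in range(n):
            lap_a = (
                a[(i - 1) % n, j] + a[(i + 1) % n, j] + a[i, (j - 1) % n] + a[i, (j + 1) % n]
                - 4 * a[i, j]
            )
            lap_b = (
                b[(i - 1) % n, j] + b[(i + 1) % n, j] + b[i, (j - 1) % n] + b[i, (j + 1) % n]
                - 4 * b[i, j]
            )
            r = a[i, j] * b[i, j] ** 2
            a_new[i, j] = a[i, j] + dt * (params.d_a * lap_a - r + params.feed * (1 - a[i, j]))
            b_new[i, j] = b[i, j] + dt * (
                params.d_b * lap_b + r - (params.kill + params.feed) * b[i, j]
            )
    return a_new, b_new


class TestInitState:
    def test_seed_region_cell_count(self):
        state = init_state(100, seed_region_half_width=5)
        assert int(state.field_b.sum()) == 121  # (2*5+1)^2

    def test_substrate_sums_to_grid_area(self):
        state = init_state(64)
        assert state.field_a.sum() == pytest.approx(64 * 64)

    def test_zero_noise_is_seed_independent(self):
        s1 = init_state(32, noise_amp=0.0, seed=1)
        s2 = init_state(32, noise_amp=0.0, seed=999)
        assert np.array_equal(s1.field_a, s2.field_a)
        assert np.array_equal(s1.field_b, s2.field_b)

    def test_oversized_seed_region_rejected(self):
        with pytest.raises(InvalidSpecError):
            init_state(10, seed_region_half_width=6)


class TestLaplacian:
    def test_constant_field_has_zero_laplacian(self):
        assert np.allclose(laplacian(np.full((16, 16), 3.7)), 0.0)

    def test_sums_to_zero_over_torus(self):
        rng = np.random.default_rng(2)
        field = rng.standard_normal((20, 20))
        assert laplacian(field).sum() == pytest.approx(0.0, abs=1e-10)


class TestStep:
    def test_trivial_steady_state_preserved_exactly(self):
        for params in (ACTIN_GS, PROTEINOID_GS, MIXTURE_GS):
            state = GrayScottState(np.ones((16, 16)), np.zeros((16, 16)))
            out = step(state, params)
            assert np.array_equal(out.field_a, np.ones((16, 16)))
            assert np.array_equal(out.field_b, np.zeros((16, 16)))

    def test_single_step_matches_double_loop_oracle(self):
        state = init_state(24, seed_region_half_width=3, noise_amp=0.01, seed=5)
        out = step(state, ACTIN_GS)
        want_a, want_b = step_loop_oracle(state.field_a, state.field_b, ACTIN_GS)
        assert np.allclose(out.field_a, want_a, atol=1e-12, rtol=0)
        assert np.allclose(out.field_b, want_b, atol=1e-12, rtol=0)

    def test_uniform_fields_stay_uniform(self):
        params = GrayScottParams(0.1592, 0.0604, 0.0202, 0.0600)
        state = GrayScottState(np.full((32, 32), 0.5), np.full((32, 32), 0.25))
        out = step(state, params)
        assert np.ptp(out.field_a) == 0.0
        assert np.ptp(out.field_b) == 0.0

    def test_blow_up_raises_instability_error(self):
        state = GrayScottState(np.full((8, 8), 1e154), np.full((8, 8), 1e154))
        with pytest.raises(InstabilityError):
            step(state, ACTIN_GS)

    def test_unstable_diffusion_rejected_at_construction(self):
        with pytest.raises(InvalidSpecError):
            GrayScottParams(0.3, 0.06, 0.02, 0.06)


class TestSimulate:
    @pytest.mark.parametrize(
        "params", [ACTIN_GS, PROTEINOID_GS, MIXTURE_GS], ids=["actin", "proteinoid", "mixture"]
    )
    def test_published_parameters_produce_patterns(self, params):
        state = simulate(params, n_steps=5000, grid_size=100)
        sd, _, _ = pattern_metrics(state)
        assert sd > 0.01
        # numerical-stability regression: fields stay bounded
        assert state.field_a.min() >= -1e-6 and state.field_a.max() <= 1.5
        assert state.field_b.min() >= -1e-6 and state.field_b.max() <= 1.5

    def test_bit_reproducible_with_fixed_seed(self):
        s1 = simulate(ACTIN_GS, n_steps=200, grid_size=48, noise_amp=0.01, seed=9)
        s2 = simulate(ACTIN_GS, n_steps=200, grid_size=48, noise_amp=0.01, seed=9)
        assert np.array_equal(s1.field_b, s2.field_b)

    def test_compound_patterns_differ(self):
        a = simulate(ACTIN_GS, n_steps=2000, grid_size=64)
        p = simulate(PROTEINOID_GS, n_steps=2000, grid_size=64)
        corr = np.corrcoef(a.field_b.ravel(), p.field_b.ravel())[0, 1]
        assert corr < 0.99

    def test_translation_invariance_on_the_torus(self):
        state = init_state(32, seed_region_half_width=4)
        shifted = GrayScottState(
            np.roll(state.field_a, (5, -7), axis=(0, 1)),
            np.roll(state.field_b, (5, -7), axis=(0, 1)),
        )
        for _ in range(60):
            state = step(state, MIXTURE_GS)
            shifted = step(shifted, MIXTURE_GS)
        assert np.allclose(
            np.roll(state.field_b, (5, -7), axis=(0, 1)), shifted.field_b, atol=1e-10
        )


class TestModulateParams:
    def test_constant_capacitance_leaves_base_unchanged(self):
        schedule = modulate_params(ACTIN_GS, np.full(100, 2.2), beta=0.5)
        assert all(p == ACTIN_GS for p in schedule)

    def test_beta_zero_leaves_base_unchanged(self):
        c = synthetic.gen_capacitance_series(2.0, 1e-4, 0.02, seed=3, duration_s=500.0)
        schedule = modulate_params(ACTIN_GS, c, beta=0.0)
        assert all(p == ACTIN_GS for p in schedule)

    def test_sinusoidal_swing_maps_to_feed_span(self):
        t = np.linspace(0, 2 * np.pi, 1001)
        c = 1.0 + 0.1 * np.sin(t)  # 10% swing
        schedule = modulate_params(ACTIN_GS, c, beta=1.0)
        feeds = np.array([p.feed for p in schedule])
        mean_c = c.mean()
        lo = ACTIN_GS.feed * (1 + (c.min() - mean_c) / mean_c)
        hi = ACTIN_GS.feed * (1 + (c.max() - mean_c) / mean_c)
        assert feeds.min() == pytest.approx(lo, rel=1e-9)
        assert feeds.max() == pytest.approx(hi, rel=1e-9)
        assert all(p.kill == ACTIN_GS.kill for p in schedule)

    def test_generator_output_always_accepted(self):
        for compound, (c0, rate) in synthetic.CAPACITANCE_CONDITIONS.items():
            c = synthetic.gen_capacitance_series(c0, rate, 0.01 * c0, duration_s=2000.0, seed=1)
            schedule = modulate_params(ACTIN_GS, c, beta=0.5, n_steps=100)
            assert len(schedule) == 100

    def test_excessive_beta_rejected(self):
        c = np.array([1.0, 1.0, 10.0])  # mean 4 -> rel swing -0.75 at beta 2 -> factor < 0
        with pytest.raises(InvalidSpecError):
            modulate_params(ACTIN_GS, c, beta=2.0)


class TestPatternMetrics:
    def test_uniform_field_has_no_spots(self):
        state = GrayScottState(np.ones((30, 30)), np.full((30, 30), 0.2))
        sd, spots, mean = pattern_metrics(state)
        assert sd == 0.0
        assert spots == 0
        assert mean == pytest.approx(0.2)

    def test_two_disjoint_squares_counted(self):
        b = np.zeros((40, 40))
        b[5:10, 5:10] = 1.0
        b[25:30, 25:30] = 1.0
        state = GrayScottState(np.ones((40, 40)), b)
        _, spots, _ = pattern_metrics(state)
        assert spots == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_spot_count_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        b = (rng.random((30, 30)) > 0.7).astype(float)
        state = GrayScottState(np.ones((30, 30)), b)
        _, spots, _ = pattern_metrics(state)
        mask = b > b.mean() + b.std()
        assert spots == flood_fill_count(mask)


def flood_fill_count(mask):
    """Iterative 4-connected flood fill, independent of scipy labelling."""
    mask = mask.copy()
    n, m = mask.shape
    count = 0
    for i0 in range(n):
        for j0 in range(m):
            if not mask[i0, j0]:
                continue
            count += 1
            stack = [(i0, j0)]
            mask[i0, j0] = False
            while stack:
                i, j = stack.pop()
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < n and 0 <= jj < m and mask[ii, jj]:
                        mask[ii, jj] = False
                        stack.append((ii, jj))
    return count
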