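"""Phase scheduling, attention shifts, facilitation of return, center bias
and the oculomotor potential."""

import numpy as np
import pytest

from scenewalk.core import Grid, ModelParams, deg_to_cell, gaussian_map, normalize_map
from scenewalk.dynamics import attention_input, evolve_map
from scenewalk.engine import SceneWalkEngine
from scenewalk.perisaccadic import (
    apply_oculomotor,
    evolve_attention_with_FoR,
    initial_state_center_bias,
    oculomotor_map,
    presaccadic_gaussian,
    postsaccadic_gaussian,
    remap_location,
    schedule_phases,
)


class TestScheduling:
    def test_standard_fixation_phase_boundaries(self):
        sched = schedule_phases(0.30, 0.1, 0.05, True, (5.0, 5.0),
                                remap=(6.0, 5.0))
        spans = np.array([(p.start, p.end) for p in sched])
        assert np.allclose(spans, [(0.0, 0.05), (0.05, 0.20), (0.20, 0.30)],
                           atol=1e-12)
        assert all(p.f_center == (5.0, 5.0) for p in sched)
        assert sched.selection_time == pytest.approx(0.20)

    def test_zero_taus_single_effective_main_phase(self):
        sched = schedule_phases(0.4, 0.0, 0.0, True, (1.0, 1.0), remap=(2.0, 1.0))
        main = [p for p in sched if p.name == "main"][0]
        assert (main.start, main.end) == (0.0, 0.4)
        assert all(p.duration == 0 for p in sched if p.name != "main")

    def test_short_fixation_pre_phase_keeps_priority(self):
        sched = schedule_phases(0.12, 0.1, 0.05, True, (0.0, 0.0), remap=(1.0, 0.0))
        by_name = {p.name: p for p in sched}
        assert by_name["pre_shift"].duration == pytest.approx(0.10)
        assert by_name["post_shift"].duration == pytest.approx(0.02)
        assert by_name["main"].duration == pytest.approx(0.0)

    def test_first_fixation_has_no_post_phase(self):
        sched = schedule_phases(0.3, 0.1, 0.05, False, (0.0, 0.0))
        assert [p.name for p in sched] == ["main", "pre_shift"]

    def test_phases_partition_duration_exactly(self):
        for t_fix in (0.05, 0.11, 0.15, 0.2, 0.31, 1.0):
            sched = schedule_phases(t_fix, 0.1, 0.05, True, (0, 0), remap=(1, 0))
            assert sum(p.duration for p in sched) == pytest.approx(t_fix, abs=1e-12)
            assert sched.t_fix == pytest.approx(t_fix)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            schedule_phases(0.0, 0.1, 0.05, False, (0, 0))


class TestRemap:
    def test_horizontal_saccade_extended_by_eta(self):
        s = remap_location((0.0, 0.0), (3.0, 0.0), 0.415)
        assert s.pos == pytest.approx((3.415, 0.0))

    def test_remap_distance_equals_eta(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=2), rng.normal(size=2)
            if np.allclose(a, b):
                continue
            s = remap_location(a, b, 0.7)
            assert np.hypot(s.x - b[0], s.y - b[1]) == pytest.approx(0.7)

    def test_axis_aligned_case(self):
        assert remap_location((1.0, 1.0), (1.0, 4.0), 1.0).pos == pytest.approx((1.0, 5.0))

    def test_zero_length_saccade_rejected(self):
        with pytest.raises(ValueError):
            remap_location((2.0, 2.0), (2.0, 2.0), 0.5)


class TestShiftGaussians:
    def test_presaccadic_peak_at_next_fixation(self, grid32):
        nxt = (20.2, 6.1)
        G = presaccadic_gaussian(nxt, 3.0, grid32)
        assert np.unravel_index(G.argmax(), G.shape) == deg_to_cell(nxt, grid32)

    def test_degenerate_shift_equals_main_phase_window(self, grid32):
        fix = (10.0, 10.0)
        assert np.array_equal(presaccadic_gaussian(fix, 3.0, grid32),
                              gaussian_map(fix, 3.0, grid32))

    def test_postsaccadic_peak_at_shifted_location_not_fixation(self, grid32):
        s = remap_location((5.2, 10.3), (15.2, 10.3), 2.0)
        G = postsaccadic_gaussian(s, 3.0, grid32)
        assert np.unravel_index(G.argmax(), G.shape) == deg_to_cell(s.pos, grid32)
        assert np.unravel_index(G.argmax(), G.shape) != deg_to_cell((15.2, 10.3), grid32)

    def test_preshift_concentrates_activation_near_target(self, grid32, saliency32):
        # evolving A through a pre-shift phase moves mass into a 2-sigma
        # disc around the upcoming target
        sigma_A, omega_A = 3.0, 10.0
        nxt = (24.0, 18.0)
        A0 = attention_input(saliency32, gaussian_map((8.0, 8.0), sigma_A, grid32))
        target = attention_input(saliency32, presaccadic_gaussian(nxt, sigma_A, grid32))
        A1 = evolve_map(A0, target, omega_A, 0.1)
        X, Y = np.meshgrid(grid32.x, grid32.y, indexing="ij")
        disc = (X - nxt[0]) ** 2 + (Y - nxt[1]) ** 2 < (2 * sigma_A) ** 2
        assert A1[disc].sum() > A0[disc].sum()


class TestFacilitationOfReturn:
    def test_equal_rates_reduce_to_plain_evolution(self, grid32):
        rng = np.random.default_rng(1)
        A0 = rng.random(grid32.shape)
        target = normalize_map(rng.random(grid32.shape))
        out = evolve_attention_with_FoR(A0, target, 8.0, 8.0, (5.0, 5.0),
                                        2.0, 0.2, grid32)
        assert np.array_equal(out, evolve_map(A0, target, 8.0, 0.2))

    def test_window_cells_retain_more_excess_activation(self, grid32):
        A0 = np.ones(grid32.shape)
        target = np.zeros(grid32.shape)
        prev = (10.0, 10.0)
        out = evolve_attention_with_FoR(A0, target, 1.0, 0.1, prev, 2.0, 1.0, grid32)
        i_in, j_in = deg_to_cell(prev, grid32)
        i_out, j_out = deg_to_cell((25.0, 20.0), grid32)
        assert out[i_in, j_in] == pytest.approx(np.exp(-0.1), abs=1e-12)
        assert out[i_out, j_out] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_window_is_square_of_side_two_nu(self, grid32):
        A0 = np.ones(grid32.shape)
        target = np.zeros(grid32.shape)
        prev = (16.0, 12.0)
        nu = 2.0
        out = evolve_attention_with_FoR(A0, target, 1.0, 0.1, prev, nu, 1.0, grid32)
        X, Y = np.meshgrid(grid32.x, grid32.y, indexing="ij")
        inside = (np.abs(X - prev[0]) < nu) & (np.abs(Y - prev[1]) < nu)
        assert np.allclose(out[inside], np.exp(-0.1))
        assert np.allclose(out[~inside], np.exp(-1.0))

    def test_fixed_point_unchanged(self, grid32):
        rng = np.random.default_rng(2)
        A0 = rng.random(grid32.shape)
        target = normalize_map(rng.random(grid32.shape))
        out = evolve_attention_with_FoR(A0, target, 40.0, 4.0, (5.0, 5.0),
                                        2.0, 10.0, grid32)
        assert np.max(np.abs(out - target)) < 1e-10

    def test_slower_than_fast_rate_required(self, grid32):
        with pytest.raises(ValueError):
            evolve_attention_with_FoR(np.ones(grid32.shape), np.zeros(grid32.shape),
                                      1.0, 2.0, (5.0, 5.0), 2.0, 0.1, grid32)


class TestCenterBias:
    def test_initial_argmax_at_central_cell(self, grid32, saliency32, extended_params):
        st = initial_state_center_bias(saliency32, extended_params, grid32,
                                       first_fix=(5.0, 5.0), t=0.0)
        # on an even grid the exact center falls on a cell corner; the peak
        # must land on one of the cells touching it
        i, j = np.unravel_index(st.A.argmax(), st.A.shape)
        cx, cy = grid32.center
        assert abs(grid32.x[i] - cx) <= grid32.dx
        assert abs(grid32.y[j] - cy) <= grid32.dy
        assert np.all(st.F == 0)

    def test_long_time_recovers_local_saliency_target(self, grid32, saliency32,
                                                      extended_params):
        first = (7.0, 15.0)
        st = initial_state_center_bias(saliency32, extended_params, grid32,
                                       first_fix=first, t=40.0)
        target = attention_input(
            saliency32, gaussian_map(first, extended_params.sigma_A, grid32))
        assert np.max(np.abs(st.A - target)) < 1e-10

    def test_central_mass_decays_monotonically_on_uniform_image(self, grid32,
                                                                extended_params):
        S = np.full(grid32.shape, 1.0 / grid32.n_cells)
        first = (26.0, 20.0)  # off-center so mass actually leaves the middle
        X, Y = np.meshgrid(grid32.x, grid32.y, indexing="ij")
        cx, cy = grid32.center
        disc = (X - cx) ** 2 + (Y - cy) ** 2 < 4.3 ** 2
        masses = []
        for t in (0.0, 0.25, 0.5, 1.0, 2.0):
            st = initial_state_center_bias(S, extended_params, grid32, first, t)
            masses.append(st.A[disc].sum())
        assert all(a > b for a, b in zip(masses, masses[1:]))


class TestOculomotorPotential:
    def test_half_exponent_is_product_of_absolute_offsets(self, grid32):
        fix = (16.0, 12.0)
        omp = oculomotor_map(fix, 0.5, grid32)
        X, Y = np.meshgrid(grid32.x, grid32.y, indexing="ij")
        assert np.allclose(omp, np.abs(X - fix[0]) * np.abs(Y - fix[1]))

    def test_zero_on_cardinal_cross_through_fixation_cell(self):
        g = Grid(n_x=9, n_y=9, extent_x=9.0, extent_y=9.0)
        fix = (4.5, 4.5)  # exactly a cell center
        for chi in (0.0, 0.059, 0.5):
            omp = oculomotor_map(fix, chi, g)
            assert np.all(omp[4, :] == 0) and np.all(omp[:, 4] == 0)
            off = omp[np.arange(9) != 4][:, np.arange(9) != 4]
            assert (off > 0).all()

    def test_unit_offset_value_is_one_for_any_chi(self):
        g = Grid(n_x=9, n_y=9, extent_x=9.0, extent_y=9.0)
        omp = oculomotor_map((4.5, 4.5), 0.059, g)
        assert omp[5, 5] == pytest.approx(1.0)  # offset (1, 1) deg

    def test_zero_weight_is_identity(self, grid32):
        u = np.random.default_rng(3).random(grid32.shape) - 0.4
        omp = oculomotor_map((10.0, 10.0), 0.1, grid32)
        assert apply_oculomotor(u, omp, 0.0) is u

    def test_subtract_convention_spares_cross_and_penalizes_rest(self):
        g = Grid(n_x=9, n_y=9, extent_x=9.0, extent_y=9.0)
        u = np.ones(g.shape)
        omp = oculomotor_map((4.5, 4.5), 0.2, g)
        out = apply_oculomotor(u, omp, 0.5, sign="subtract")
        assert np.all(out[4, :] == 1.0) and np.all(out[:, 4] == 1.0)
        mask = omp > 0
        assert (out[mask] < 1.0).all()

    def test_literal_convention_adds_positive_weight(self):
        g = Grid(n_x=9, n_y=9, extent_x=9.0, extent_y=9.0)
        u = np.zeros(g.shape)
        omp = oculomotor_map((4.5, 4.5), 0.2, g)
        out = apply_oculomotor(u, omp, 0.5, sign="literal")
        assert (out >= 0).all() and out.max() > 0


class TestBaselineReduction:
    def test_neutral_extended_model_reproduces_baseline_pi_maps(
            self, grid32, saliency32, baseline_params):
        """With all extension parameters neutral the extended variant's
        selection maps equal the baseline's bit for bit."""
        neutral = ModelParams(
            omega_A=baseline_params.omega_A, sigma_A=baseline_params.sigma_A,
            sigma_F=baseline_params.sigma_F, gamma=baseline_params.gamma,
            log_zeta=baseline_params.log_zeta, variant="extended",
            tau_pre=0.0, tau_post=0.0, eta=0.415, log_psi=float("-inf"),
            chi=0.0, center_bias=False, facilitation=False)
        fixes = [(16.0, 12.0), (10.0, 8.0), (22.0, 15.0), (7.0, 18.0), (12.0, 5.0)]
        durs = [0.25, 0.31, 0.18, 0.27, 0.22]
        eb = SceneWalkEngine(saliency32, baseline_params, grid32)
        ee = SceneWalkEngine(saliency32, neutral, grid32)
        assert np.array_equal(eb.initial_selection_map(), ee.initial_selection_map())
        eb.begin(fixes[0]); ee.begin(fixes[0])
        for cur, dur, nxt in zip(fixes, durs, fixes[1:]):
            pib, _ = eb.step(dur, next_pos=nxt)
            pie, _ = ee.step(dur, next_pos=nxt)
            assert np.max(np.abs(pib - pie)) <= 1e-12
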