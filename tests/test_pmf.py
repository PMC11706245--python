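"""Probability -> free-energy pipeline: estimators, reductions, regions, L."""

import itertools

import numpy as np
import pytest

from codonpmf import (
    ABFState,
    GridSpec,
    average_trials,
    binding_free_energy,
    convergence_error,
    free_energy_from_mean_force,
    free_energy_from_probability,
    load_preset,
    pairing_penalty,
    probability_from_state,
    reduce_to_2d,
    region_free_energy,
    run_abf,
)
from codonpmf.pmf import (
    BOUND_WINDOW,
    UNBOUND_WINDOW,
    BindingResult,
    ProbabilityGrid,
    probability_from_free_energy,
)
from codonpmf.system import KB, DynamicsSpec, PotentialSpec, SystemSpec

KT = KB * 310.0
GRID = GridSpec()


def uniform_grid() -> ProbabilityGrid:
    return ProbabilityGrid(grid=GRID, p=np.full(GRID.shape, 1e-3))


def random_grid(rng) -> ProbabilityGrid:
    p = rng.random(GRID.shape)
    return ProbabilityGrid(grid=GRID, p=p / p.sum())


class TestProbabilityGrid:
    def test_normalization_enforced(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ProbabilityGrid(grid=GRID, p=np.full(GRID.shape, 2e-3))

    def test_negative_rejected(self):
        p = np.full(GRID.shape, 1e-3)
        p[0, 0, 0] = -p[0, 0, 0]
        with pytest.raises(ValueError, match="non-negative"):
            ProbabilityGrid(grid=GRID, p=p)


class TestProbabilityFromState:
    def test_unbiased_state_gives_raw_histogram(self, flat_spec):
        run = run_abf(flat_spec, DynamicsSpec(n_steps=50_000, seed=1), bias=False,
                      histogram_reset_fraction=0.0)
        P = probability_from_state(run.state, flat_spec)
        expected = run.state.counts / run.state.counts.sum()
        assert np.array_equal(P.p, expected)

    def test_empty_state_rejected(self, flat_spec):
        with pytest.raises(ValueError, match="empty"):
            probability_from_state(ABFState(grid=GRID), flat_spec)

    def test_flat_landscape_approximately_uniform(self, flat_spec):
        run = run_abf(flat_spec, DynamicsSpec(n_steps=2_000_000, seed=11))
        P = probability_from_state(run.state, flat_spec)
        assert P.p.min() > 0
        # every bin within a factor ~3 of uniform at this length
        assert P.p.max() / P.p.min() < 9.0


class TestFreeEnergyMaps:
    def test_uniform_probability_gives_zero_G(self):
        g = free_energy_from_probability(uniform_grid(), KT)
        assert np.allclose(g.values, 0.0, atol=1e-12)

    def test_probability_ratio_e_gives_kt(self):
        p = np.full(GRID.shape, 1.0)
        p[0, 0, 0] = np.e
        P = ProbabilityGrid(grid=GRID, p=p / p.sum())
        g = free_energy_from_probability(P, KT)
        assert g.values[0, 0, 0] == pytest.approx(0.0, abs=1e-12)
        assert g.values[5, 5, 5] == pytest.approx(KT, abs=1e-9)
        assert g.values[5, 5, 5] == pytest.approx(2.577, abs=2e-3)

    def test_zero_probability_bins_masked(self):
        p = np.zeros(GRID.shape)
        p[:5] = 1.0
        P = ProbabilityGrid(grid=GRID, p=p / p.sum())
        g = free_energy_from_probability(P, KT)
        assert not g.occupied[7, 0, 0]
        assert np.isnan(g.values[7, 0, 0])

    def test_round_trip_identity(self, rng):
        P = random_grid(rng)
        back = probability_from_free_energy(free_energy_from_probability(P, KT))
        assert np.allclose(back.p, P.p, atol=1e-9)


class TestMeanForceRoute:
    def test_zero_mean_force_gives_zero_G(self):
        state = ABFState(grid=GRID)
        state.counts[:] = 10
        g = free_energy_from_mean_force(state, KT)
        assert np.allclose(g.values, 0.0, atol=1e-9)

    def test_harmonic_gradient_integrates_to_harmonic_G(self):
        """Exact analytic gradients on the full grid recover U to < 0.1 kJ/mol."""
        k = 2.0
        center = 6.5
        state = ABFState(grid=GRID)
        state.counts[:] = 1
        centers = GRID.centers
        u = np.zeros(GRID.shape)
        for b in itertools.product(range(10), repeat=3):
            c = centers[list(b)]
            state.force_sum[b] = -k * (c - center)
            u[b] = 0.5 * k * np.sum((c - center) ** 2)
        g = free_energy_from_mean_force(state, KT)
        u -= u.min()
        rmse = float(np.sqrt(np.mean((g.values - u) ** 2)))
        assert rmse < 0.1

    def test_disconnected_mask_rejected(self):
        state = ABFState(grid=GRID)
        state.counts[0, 0, 0] = 5
        state.counts[9, 9, 9] = 5
        with pytest.raises(ValueError, match="disconnected"):
            free_energy_from_mean_force(state, KT)

    def test_route_agreement_on_validation_run(self, route_validation_run, smooth_spec):
        """Probability route and mean-force route agree on the documented run."""
        p_avg, merged = route_validation_run
        gp = free_energy_from_probability(p_avg, smooth_spec.kt)
        gf = free_energy_from_mean_force(merged, smooth_spec.kt)
        m = gp.occupied & gf.occupied
        rmse = float(np.sqrt(np.mean((gp.values[m] - gf.values[m]) ** 2)))
        assert rmse < 0.5


class TestReductions:
    def test_uniform_reduces_to_zero_surface(self):
        surf = reduce_to_2d(uniform_grid(), (1, 2), KT)
        assert np.allclose(surf.g, 0.0, atol=1e-12)

    def test_separable_probability(self, rng):
        p1, p2, p3 = (rng.random(10) + 0.1 for _ in range(3))
        p = p1[:, None, None] * p2[None, :, None] * p3[None, None, :]
        P = ProbabilityGrid(grid=GRID, p=p / p.sum())
        surf = reduce_to_2d(P, (1, 2), KT)
        expected = -KT * (np.log(p1)[:, None] + np.log(p2)[None, :])
        expected -= expected.min()
        assert np.allclose(surf.g, expected, atol=1e-9)

    @pytest.mark.parametrize("pair,axis", [((1, 2), 2), ((1, 3), 1), ((2, 3), 0)])
    def test_marginalization_matches_direct_sum(self, rng, pair, axis):
        P = random_grid(rng)
        surf = reduce_to_2d(P, pair, KT)
        assert np.allclose(surf.p, P.p.sum(axis=axis), atol=1e-15)

    def test_invalid_pair_rejected(self):
        with pytest.raises(ValueError):
            reduce_to_2d(uniform_grid(), (2, 1), KT)


class TestRegionsAndBinding:
    def test_uniform_bound_region_counts_bins(self):
        g = region_free_energy(uniform_grid(), BOUND_WINDOW, KT)
        assert g == pytest.approx(-KT * np.log(0.064), rel=1e-12)

    def test_full_grid_region_is_zero(self):
        window = ((4.0, 9.0),) * 3
        assert region_free_energy(uniform_grid(), window, KT) == pytest.approx(0.0, abs=1e-12)

    def test_misaligned_window_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            region_free_energy(uniform_grid(), ((4.1, 6.0), (4.0, 6.0), (4.0, 6.0)), KT)

    def test_empty_region_is_error_not_inf(self):
        p = np.zeros(GRID.shape)
        p[0, 0, 0] = 1.0
        P = ProbabilityGrid(grid=GRID, p=p)
        with pytest.raises(ValueError, match="zero probability"):
            region_free_energy(P, UNBOUND_WINDOW, KT)

    def test_uniform_binding_is_symmetric_zero(self):
        res = binding_free_energy(uniform_grid(), KT)
        assert res.delta_g == pytest.approx(0.0, abs=1e-12)
        assert res.g_bound == pytest.approx(res.g_unbound)

    def test_gap_bins_belong_to_neither_window(self):
        # all mass in the 6-7 A shell: both windows are empty
        p = np.zeros(GRID.shape)
        p[4, 4, 4] = 0.5  # bin [6.0, 6.5)
        p[5, 5, 5] = 0.5  # bin [6.5, 7.0)
        P = ProbabilityGrid(grid=GRID, p=p)
        with pytest.raises(ValueError):
            binding_free_energy(P, KT)


class TestPairingPenalty:
    def test_self_reference_is_zero(self):
        res = binding_free_energy(uniform_grid(), KT)
        assert pairing_penalty(res, res) == 0.0

    def test_sign_convention(self):
        assert pairing_penalty(-10.0, -15.0) == pytest.approx(5.0)

    def test_metadata_mismatch_rejected(self):
        a = binding_free_energy(uniform_grid(), KT)
        b = binding_free_energy(uniform_grid(), KT, n_trials=5)
        with pytest.raises(ValueError, match="n_trials"):
            pairing_penalty(a, b)
        c = BindingResult(g_bound=1.0, g_unbound=2.0, delta_g=-1.0,
                          grid=GridSpec(4.0, 9.0, 0.25), kt=KT)
        with pytest.raises(ValueError, match="grid"):
            pairing_penalty(a, c)


class TestConvergenceStatistic:
    def test_identical_grids_give_zero(self):
        P = uniform_grid()
        assert convergence_error(P, P).l_value == 0.0

    def test_uniform_vs_point_mass(self):
        point = np.zeros(GRID.shape)
        point[0, 0, 0] = 1.0
        P2 = ProbabilityGrid(grid=GRID, p=point)
        rec = convergence_error(uniform_grid(), P2)
        assert rec.l_value == pytest.approx((1 - 1e-3) ** 2 + 999 * 1e-6, rel=1e-12)
        assert rec.l_value == pytest.approx(0.999000, abs=1e-6)

    def test_symmetric(self, rng):
        P1, P2 = random_grid(rng), random_grid(rng)
        assert convergence_error(P1, P2).l_value == convergence_error(P2, P1).l_value

    def test_shape_mismatch_rejected(self):
        small = GridSpec(4.0, 9.0, 1.0)
        P2 = ProbabilityGrid(grid=small, p=np.full(small.shape, 1 / 125))
        with pytest.raises(ValueError, match="grid mismatch"):
            convergence_error(uniform_grid(), P2)

    def test_l_decreases_towards_final_checkpoint(self, aug_checkpoint_run):
        """On the documented converged run, L(tau_k, tau_final) trends down."""
        _, run = aug_checkpoint_run
        final = run.checkpoints[-1][1]
        ls = [convergence_error(P, final).l_value for _, P in run.checkpoints[:-1]]
        assert ls[-1] < ls[0]
        run_max = ls[0]
        for prev, nxt in zip(ls, ls[1:]):
            run_max = max(run_max, prev)
            # single-step rises must stay below 10% of the running level
            assert nxt - prev <= 0.1 * run_max


class TestTrialAveraging:
    def test_identical_grids_average_to_themselves(self):
        P = uniform_grid()
        avg = average_trials([P] * 5)
        assert np.allclose(avg.p, P.p, atol=1e-15)

    def test_two_point_masses(self):
        a = np.zeros(GRID.shape)
        a[0, 0, 0] = 1.0
        b = np.zeros(GRID.shape)
        b[9, 9, 9] = 1.0
        avg = average_trials([ProbabilityGrid(grid=GRID, p=a),
                              ProbabilityGrid(grid=GRID, p=b)])
        assert avg.p[0, 0, 0] == pytest.approx(0.5)
        assert avg.p[9, 9, 9] == pytest.approx(0.5)

    def test_mixed_grids_rejected(self):
        small = GridSpec(4.0, 9.0, 1.0)
        P2 = ProbabilityGrid(grid=small, p=np.full(small.shape, 1 / 125))
        with pytest.raises(ValueError, match="different grids"):
            average_trials([uniform_grid(), P2])

    def test_averaging_tightens_binding_estimate(self, smooth_spec):
        """Leave-one-out averages spread less than single trials do."""
        ps = []
        for t in range(5):
            run = run_abf(smooth_spec, DynamicsSpec(n_steps=500_000, seed=40 + t,
                                                    timestep=2e-3))
            ps.append(probability_from_state(run.state, smooth_spec))
        singles = [binding_free_energy(P, smooth_spec.kt).delta_g for P in ps]
        loo = [binding_free_energy(
            average_trials([p for j, p in enumerate(ps) if j != i]),
            smooth_spec.kt).delta_g for i in range(5)]
        assert np.std(loo) < np.std(singles)
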