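import numpy as np
import pytest

from luces import (
    ConstraintMask,
    CostMatrix,
    DemandVector,
    InertiaState,
    LandUseMap,
    NeighborhoodWeights,
    combined_probability,
    neighborhood_effect,
    roulette_select,
    run_simulation,
    update_inertia,
)
from luces.ca import INERTIA_MAX, INERTIA_MIN
from luces.exceptions import ArgumentError, SimulationError
from luces.suitability import SuitabilityCube

from conftest import lum


def flat_cube(lum_obj):
    probs = np.full((6,) + lum_obj.shape, 1 / 6)
    probs[:, ~lum_obj.active] = np.nan
    return SuitabilityCube(probs, lum_obj.active)


def brute_force_neighborhood(classes, k, omega_k):
    rows, cols = classes.shape
    out = np.zeros((rows, cols))
    for i in range(rows):
        for j in range(cols):
            cnt = 0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < rows and 0 <= jj < cols and classes[ii, jj] == k:
                        cnt += 1
            out[i, j] = cnt / 8 * omega_k
    return out


class TestNeighborhoodEffect:
    def test_uniform_map_interior_is_one(self):
        m = lum(np.full((5, 5), 2))
        eff = neighborhood_effect(m, 2, NeighborhoodWeights())
        assert eff[2, 2] == 1.0

    def test_uniform_map_corner_is_three_eighths(self):
        m = lum(np.full((5, 5), 2))
        eff = neighborhood_effect(m, 2, NeighborhoodWeights())
        assert eff[0, 0] == pytest.approx(3 / 8)

    def test_four_neighbors_with_weight(self):
        m = lum([[3, 1, 3], [1, 1, 1], [3, 1, 3]])
        w = NeighborhoodWeights(np.array([1, 1, 0.9, 1, 1, 1.0]))
        eff = neighborhood_effect(m, 3, w)
        assert eff[1, 1] == pytest.approx(4 / 8 * 0.9)

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(8)
        for _ in range(3):
            m = lum(rng.integers(1, 7, size=(12, 12)))
            w = NeighborhoodWeights(rng.random(6))
            for k in (1, 4, 6):
                np.testing.assert_allclose(
                    neighborhood_effect(m, k, w),
                    brute_force_neighborhood(m.classes, k, w.omega[k - 1]),
                )


class TestUpdateInertia:
    def _state(self, inertia, g1, g2):
        return InertiaState(
            np.full(6, float(inertia)), np.full(6, float(g1)), np.full(6, float(g2))
        )

    def test_stable_gap_leaves_inertia_unchanged(self):
        out = update_inertia(self._state(2.0, 5, 5))
        assert (out.inertia == 2.0).all()

    def test_worsening_undershoot_doubles(self):
        out = update_inertia(self._state(1.0, 10, 5))
        assert out.inertia[0] == pytest.approx(2.0)

    def test_worsening_overshoot_halves(self):
        out = update_inertia(self._state(1.0, -10, -5))
        assert out.inertia[0] == pytest.approx(0.5)

    def test_clamped_to_bounds(self):
        big = update_inertia(self._state(INERTIA_MAX, 10, 1))
        assert (big.inertia == INERTIA_MAX).all()
        small = update_inertia(self._state(INERTIA_MIN, -10, -1))
        assert (small.inertia == INERTIA_MIN).all()

    def test_zero_previous_gap_is_ratio_one(self):
        out = update_inertia(self._state(1.5, 4, 0))
        assert (out.inertia == 1.5).all()


class TestCombinedProbability:
    def test_forbidden_conversion_zeroes_score(self):
        m = lum([[1, 1], [1, 1]])
        sc = np.zeros((6, 6))
        sc[0, 4] = 1.0  # cultivated → built forbidden
        tprob = combined_probability(
            flat_cube(m), np.ones((6, 2, 2)), InertiaState(), CostMatrix(sc), m
        )
        assert (tprob[4] == 0).all()
        assert (tprob[0] > 0).all()

    def test_identity_factors_return_suitability(self):
        m = lum([[1, 2], [3, 4]])
        cube = flat_cube(m)
        tprob = combined_probability(
            cube, np.ones((6, 2, 2)), InertiaState(), CostMatrix.uniform(0.0), m
        )
        np.testing.assert_allclose(tprob, np.nan_to_num(cube.probs))

    def test_multiplicative_in_inertia(self):
        m = lum([[1, 2], [3, 4]])
        cube = flat_cube(m)
        base = combined_probability(
            cube, np.ones((6, 2, 2)), InertiaState(), CostMatrix.uniform(0.0), m
        )
        doubled_state = InertiaState(inertia=np.array([1, 1, 2, 1, 1, 1.0]))
        doubled = combined_probability(
            cube, np.ones((6, 2, 2)), doubled_state, CostMatrix.uniform(0.0), m
        )
        np.testing.assert_allclose(doubled[2], 2 * base[2])
        np.testing.assert_allclose(doubled[0], base[0])


class TestRouletteSelect:
    def test_single_nonzero_is_certain(self):
        rng = np.random.default_rng(0)
        scores = np.array([0, 0, 0, 7.0, 0, 0])
        assert all(roulette_select(scores, rng, 1) == 4 for _ in range(20))

    def test_all_zero_keeps_current(self):
        rng = np.random.default_rng(0)
        assert roulette_select(np.zeros(6), rng, 3) == 3

    def test_negative_score_rejected(self):
        with pytest.raises(ArgumentError):
            roulette_select(np.array([1, -1, 0, 0, 0, 0.0]), np.random.default_rng(0), 1)

    def test_even_scores_split_evenly(self):
        rng = np.random.default_rng(123)
        scores = np.array([1, 1, 0, 0, 0, 0.0])
        draws = np.array([roulette_select(scores, rng, 1) for _ in range(100_000)])
        frac1 = (draws == 1).mean()
        assert abs(frac1 - 0.5) < 0.01
        assert set(np.unique(draws)) == {1, 2}


class TestRunSimulation:
    def test_satisfied_demand_returns_map_unchanged(self, map_pair_small):
        t0, _ = map_pair_small
        dv = DemandVector(t0.class_counts())
        out = run_simulation(t0, flat_cube(t0), dv, tol=0, seed=0)
        assert np.array_equal(out.classes, t0.classes)

    def test_exact_shift_of_twenty_cells(self):
        rng = np.random.default_rng(4)
        m = lum(rng.choice([1, 2, 5], size=(16, 16), p=[0.5, 0.3, 0.2]))
        counts = m.class_counts()
        demand = counts.copy()
        demand[0] -= 20
        demand[4] += 20
        out = run_simulation(
            m, flat_cube(m), DemandVector(demand), cost=CostMatrix.uniform(0.0),
            tol=0, seed=1,
        )
        assert np.array_equal(out.class_counts(), demand)
        assert (out.classes != m.classes).sum() == 20

    def test_seeded_determinism(self, map_pair_small):
        t0, _ = map_pair_small
        counts = t0.class_counts()
        demand = counts.copy()
        demand[0] -= 10
        demand[4] += 10
        a = run_simulation(t0, flat_cube(t0), DemandVector(demand), tol=0, seed=7)
        b = run_simulation(t0, flat_cube(t0), DemandVector(demand), tol=0, seed=7)
        assert np.array_equal(a.classes, b.classes)

    def test_frozen_cells_never_change(self, map_pair_small):
        t0, _ = map_pair_small
        counts = t0.class_counts()
        demand = counts.copy()
        shift = counts[0] // 2
        demand[0] -= shift
        demand[4] += shift
        rng = np.random.default_rng(2)
        mask = ConstraintMask(rng.integers(0, 2, size=t0.shape).astype(np.uint8))
        # keep demand feasible against the frozen composition
        frozen_counts = np.array(
            [int(((t0.classes == c) & mask.frozen).sum()) for c in range(1, 7)]
        )
        demand = np.maximum(demand, frozen_counts)
        demand[4] += t0.n_active - demand.sum()
        out = run_simulation(
            t0, flat_cube(t0), DemandVector(demand), mask=mask, tol=0, seed=0
        )
        changed = out.classes != t0.classes
        assert not (changed & mask.frozen).any()

    def test_nodata_preserved(self):
        arr = np.full((8, 8), 1, dtype=np.int16)
        arr[0, :] = 0
        arr[4:, 4:] = 5
        m = LandUseMap(arr)
        counts = m.class_counts()
        demand = counts.copy()
        demand[0] -= 5
        demand[4] += 5
        out = run_simulation(m, flat_cube(m), DemandVector(demand), tol=0, seed=0)
        assert np.array_equal(out.classes == 0, m.classes == 0)

    def test_gaps_monotonically_shrink(self):
        rng = np.random.default_rng(9)
        m = lum(rng.integers(1, 7, size=(20, 20)))
        counts = m.class_counts()
        demand = counts + np.array([-15, 5, 5, 5, 5, -5])
        log: list = []
        run_simulation(
            m, flat_cube(m), DemandVector(demand), cost=CostMatrix.uniform(0.0),
            tol=0, seed=3, log=log,
        )
        gaps = np.array(
            [[e[f"gap_{n}"] for n in ("cultivated", "woodland", "grassland",
                                      "water", "built", "unused")] for e in log]
        )
        diffs = np.abs(gaps[1:]) - np.abs(gaps[:-1])
        assert (diffs <= 0).all()

    def test_demand_total_mismatch_rejected(self, map_pair_small):
        t0, _ = map_pair_small
        bad = DemandVector(t0.class_counts() + 1)
        with pytest.raises(ArgumentError):
            run_simulation(t0, flat_cube(t0), bad, seed=0)

    def test_infeasible_demand_names_class(self):
        m = lum(np.full((8, 8), 1))
        mask = ConstraintMask(np.zeros((8, 8), dtype=np.uint8))  # all frozen
        demand = np.array([34, 0, 0, 0, 30, 0])
        with pytest.raises(SimulationError, match="cultivated"):
            run_simulation(m, flat_cube(m), DemandVector(demand), mask=mask, seed=0)
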