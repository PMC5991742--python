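import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import pdist

from volescr.data import EncounterData, build_state_space
from volescr.detection import (DetectionParams, IndicatorConfig,
                               encounter_cell_probs)
from volescr.simulate import (SimOptions, TruePopulation, june_grid,
                              may_grid, simulate_captures,
                              simulate_population)


class TestGridGeometry:
    def test_may_counts(self):
        grid = may_grid()
        assert grid.n_nodes == 70
        assert grid.n_detectors == 140

    def test_may_extent(self):
        xmin, xmax, ymin, ymax = may_grid().bounding_box()
        assert (xmax - xmin, ymax - ymin) == (72.0, 135.0)

    def test_may_min_internode_distance(self):
        grid = may_grid()
        # one detector per node for the geometry check
        _, first = np.unique([str(n) for n in grid.node_id],
                             return_index=True)
        d = pdist(grid.coords[first])
        assert d.min() == pytest.approx(12.0)

    def test_may_paired_detectors_coincide(self):
        grid = may_grid()
        node = np.asarray([str(n) for n in grid.node_id])
        for n in np.unique(node)[:5]:
            pts = grid.coords[node == n]
            assert len(pts) == 2
            np.testing.assert_allclose(pts[0], pts[1])

    def test_june_counts_and_min_distance(self):
        grid = june_grid()
        assert grid.n_detectors == 124
        d = pdist(grid.coords)
        assert d.min() == pytest.approx(np.hypot(6.0, 7.5))
        assert round(d.min(), 1) == 9.6

    def test_june_nearest_neighbour_distances(self):
        grid = june_grid()
        pts = grid.coords
        dmat = np.hypot(pts[:, 0][:, None] - pts[:, 0][None, :],
                        pts[:, 1][:, None] - pts[:, 1][None, :])
        np.fill_diagonal(dmat, np.inf)
        nn = np.round(dmat.min(axis=1), 1)
        assert set(nn) == {9.6}
        # distinct short-range spacings present in the array: 9.6, 12, 15
        uniq = {round(v, 1) for v in np.unique(np.round(dmat, 1))
                if v <= 15.1}
        assert {9.6, 12.0, 15.0} <= uniq

    def test_same_footprint_as_may(self):
        assert may_grid().bounding_box() == june_grid().bounding_box()


class TestSimulatePopulation:
    def test_poisson_expectation(self):
        space = build_state_space(june_grid(), 30.0)
        par = DetectionParams()
        Ns = [simulate_population(space, 168.25, 0.25, par, seed=s).N
              for s in range(200)]
        # E[N] = 168.25 voles/ha * 2.574 ha = 433.1
        se = np.sqrt(433.1 / 200)
        assert np.mean(Ns) == pytest.approx(433.1, abs=4 * se)

    def test_all_female_when_pi_zero(self):
        space = build_state_space(june_grid(), 30.0)
        pop = simulate_population(space, 60.0, 0.0, DetectionParams(),
                                  seed=3)
        assert pop.sexes.sum() == 0

    def test_seed_reproducibility(self):
        space = build_state_space(june_grid(), 30.0)
        a = simulate_population(space, 60.0, 0.5, DetectionParams(), seed=11)
        b = simulate_population(space, 60.0, 0.5, DetectionParams(), seed=11)
        np.testing.assert_array_equal(a.centres, b.centres)
        np.testing.assert_array_equal(a.sexes, b.sexes)

    def test_centres_inside_space(self):
        space = build_state_space(june_grid(), 30.0)
        pop = simulate_population(space, 100.0, 0.5, DetectionParams(),
                                  seed=4)
        assert space.contains(pop.centres).all()


class TestSimulateCaptures:
    def _one_trap_setup(self):
        from volescr.data import TrapArray
        traps = TrapArray(np.array(["a"], dtype=object), np.array([0.0]),
                          np.array([0.0]), np.array(["a"], dtype=object))
        par = DetectionParams(alpha0_f=-1.0, sigma_f=4.0, sigma_m=4.0)
        pop = TruePopulation(np.array([[2.0, 0.0]]), np.array([0]), par,
                             IndicatorConfig())
        return traps, par, pop

    def test_no_deaths_when_death_prob_zero(self, june_setup):
        traps, space, params = june_setup
        pop = simulate_population(space, 60.0, 0.25, params, seed=31)
        data = simulate_captures(pop, traps, SimOptions(K=8, seed=32,
                                                        death_prob=0.0))
        assert (data.removal_occasion == -1).all()

    def test_death_rate_matches_probability(self, june_setup):
        traps, space, params = june_setup
        deaths = caps = 0
        for s in range(10):
            pop = simulate_population(space, 60.0, 0.25, params,
                                      seed=600 + s)
            d = simulate_captures(pop, traps,
                                  SimOptions(K=8, seed=700 + s,
                                             death_prob=0.03))
            deaths += int((d.removal_occasion >= 0).sum())
            caps += d.n_captures
        rate = deaths / caps
        se = np.sqrt(0.03 * 0.97 / caps)
        assert rate == pytest.approx(0.03, abs=4 * se)

    def test_single_trap_capture_frequency(self):
        """Empirical per-occasion capture rate of one individual at one
        trap matches the closed form h/(1+h) of the multinomial cells."""
        traps, par, pop = self._one_trap_setup()
        h = np.exp(par.alpha0_f - 2.0 ** 2 / (2 * par.sigma_f ** 2))
        p_expected = h / (1 + h)
        caught = 0
        reps = 4000
        for s in range(reps):
            d = simulate_captures(pop, traps,
                                  SimOptions(K=1, seed=s, death_prob=0.0,
                                             capture_mode="multinomial"))
            caught += d.n
        se = np.sqrt(p_expected * (1 - p_expected) / reps)
        assert caught / reps == pytest.approx(p_expected, abs=3 * se)

    def test_multinomial_outcome_frequencies_gof(self):
        """Chi-square goodness of fit of simulated occasion outcomes
        against the encounter cell probabilities."""
        from volescr.data import TrapArray
        traps = TrapArray(np.array(["a", "b"], dtype=object),
                          np.array([0.0, 8.0]), np.array([0.0, 0.0]),
                          np.array(["a", "b"], dtype=object))
        par = DetectionParams(alpha0_f=0.2, sigma_f=5.0, sigma_m=5.0)
        pop = TruePopulation(np.array([[3.0, 0.0]]), np.array([0]), par,
                             IndicatorConfig())
        cells = encounter_cell_probs((3.0, 0.0), traps, par.alpha0_f,
                                     par.sigma_f)
        counts = np.zeros(3)   # trap a, trap b, none
        reps = 5000
        for s in range(reps):
            d = simulate_captures(pop, traps,
                                  SimOptions(K=1, seed=s, death_prob=0.0,
                                             capture_mode="multinomial"))
            if d.n == 0:
                counts[2] += 1
            else:
                counts[d.y[0, 0]] += 1
        _, pval = stats.chisquare(counts, reps * cells)
        assert pval > 0.01

    def test_single_catch_matches_multinomial_at_low_rate(self):
        """With << 1 expected capture per occasion, trap competition is
        negligible and the two generators agree in capture counts."""
        from volescr.data import TrapArray
        traps = TrapArray(np.array(["a", "b"], dtype=object),
                          np.array([0.0, 8.0]), np.array([0.0, 0.0]),
                          np.array(["a", "b"], dtype=object))
        par = DetectionParams(alpha0_f=-4.0, sigma_f=5.0, sigma_m=5.0)
        pop = TruePopulation(np.array([[3.0, 0.0], [5.0, 1.0]]),
                             np.array([0, 0]), par, IndicatorConfig())
        counts = {}
        for mode in ("multinomial", "single_catch"):
            c = [simulate_captures(pop, traps,
                                   SimOptions(K=8, seed=s, death_prob=0.0,
                                              capture_mode=mode)).n_captures
                 for s in range(600)]
            counts[mode] = c
        _, pval = stats.mannwhitneyu(counts["multinomial"],
                                     counts["single_catch"])
        assert pval > 0.01

    def test_paired_node_shares_hazard_not_doubled(self):
        """Two co-located detectors at one node leave the per-occasion
        capture probability of an animal unchanged (a second box adds
        capacity, not attractiveness)."""
        from volescr.data import TrapArray
        par = DetectionParams(alpha0_f=-0.5, sigma_f=4.0, sigma_m=4.0)
        pop = TruePopulation(np.array([[1.0, 0.0]]), np.array([0]), par,
                             IndicatorConfig())
        h = np.exp(par.alpha0_f - 1.0 / (2 * par.sigma_f ** 2))
        p_expected = 1 - np.exp(-h)
        single = TrapArray(np.array(["a"], dtype=object), np.array([0.0]),
                           np.array([0.0]), np.array(["n1"], dtype=object))
        paired = TrapArray(np.array(["a", "b"], dtype=object),
                           np.array([0.0, 0.0]), np.array([0.0, 0.0]),
                           np.array(["n1", "n1"], dtype=object))
        reps = 3000
        for traps in (single, paired):
            caught = sum(simulate_captures(
                pop, traps, SimOptions(K=1, seed=s, death_prob=0.0)).n
                for s in range(reps))
            se = np.sqrt(p_expected * (1 - p_expected) / reps)
            assert caught / reps == pytest.approx(p_expected, abs=4 * se)

    def test_paired_node_has_capacity_two(self):
        """Two animals on top of a paired node can both be captured in
        one occasion, in different detectors of the node."""
        from volescr.data import TrapArray
        par = DetectionParams(alpha0_f=4.0, sigma_f=3.0, sigma_m=3.0)
        pop = TruePopulation(np.array([[0.0, 0.0], [0.1, 0.0]]),
                             np.array([0, 0]), par, IndicatorConfig())
        paired = TrapArray(np.array(["a", "b"], dtype=object),
                           np.array([0.0, 0.0]), np.array([0.0, 0.0]),
                           np.array(["n1", "n1"], dtype=object))
        both = 0
        for s in range(200):
            d = simulate_captures(pop, paired,
                                  SimOptions(K=1, seed=s, death_prob=0.0))
            if d.n == 2:
                both += 1
                assert set(d.y[:, 0].tolist()) == {0, 1}
        assert both > 150  # hazard ~ e^4: both nearly always arrive

    def test_single_catch_trap_takes_one_individual(self):
        """A trap never records two captures on one occasion."""
        traps = june_grid()
        space = build_state_space(traps, 30.0)
        par = DetectionParams(alpha0_f=1.0, sigma_f=6.0, sigma_m=6.0)
        pop = simulate_population(space, 200.0, 0.5, par, seed=5)
        d = simulate_captures(pop, traps, SimOptions(K=4, seed=6))
        for k in range(d.K):
            used = d.y[:, k][d.y[:, k] >= 0]
            assert len(used) == len(set(used.tolist()))

    @pytest.mark.parametrize("seed", range(6))
    def test_generated_data_satisfy_invariants(self, seed, june_setup):
        """EncounterData construction itself enforces the invariants; any
        violation raises in the constructor."""
        traps, space, params = june_setup
        pop = simulate_population(space, 50.0, 0.3, params, seed=seed)
        data = simulate_captures(pop, traps,
                                 SimOptions(K=8, seed=seed + 100,
                                            death_prob=0.05))
        assert isinstance(data, EncounterData)
        assert ((data.y != -1).sum(axis=1) >= 1).all()

    def test_truth_flags_match_observed_count(self, june_setup):
        traps, space, params = june_setup
        pop = simulate_population(space, 50.0, 0.3, params, seed=41)
        data, captured = simulate_captures(
            pop, traps, SimOptions(K=8, seed=42), return_truth=True)
        assert captured.sum() == data.n

    def test_saturation_in_realistic_band(self, june_setup):
        """June-like densities keep per-occasion saturation far below the
        86% level at which multinomial fitting of single-catch data
        degrades, and in the tens-of-percent order of real sessions."""
        from volescr.data import trap_saturation
        traps, space, params = june_setup
        mx = []
        for s in range(5):
            pop = simulate_population(space, 168.25, 0.25, params,
                                      seed=800 + s)
            d = simulate_captures(pop, traps, SimOptions(K=8, seed=900 + s))
            mx.append(trap_saturation(d, traps).global_pct.max())
        assert max(mx) < 50.0
        assert min(mx) > 1.0
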