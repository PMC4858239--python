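import numpy as np
import pytest

from paleodiff import (
    Seed,
    SimConfig,
    StateCorruptionError,
    apply_births,
    boundary_flux,
    build_sea_links,
    compute_habitability,
    effective_rating,
    run,
    seed_state,
    step,
)
from paleodiff.engine import PopulationState
from paleodiff.synthetic import TerrainSpec, make_terrain


class TestEffectiveRating:
    def test_empty_cell_rates_R_in(self):
        assert effective_rating(0.7, 0.0, 1000.0) == pytest.approx(0.7)

    def test_zero_at_twice_capacity(self):
        assert effective_rating(0.7, 2000.0, 1000.0) == 0.0
        assert effective_rating(0.7, 5000.0, 1000.0) == 0.0

    def test_half_at_capacity(self):
        assert effective_rating(0.8, 1000.0, 1000.0) == pytest.approx(0.4)

    def test_zero_capacity_rates_zero(self):
        assert effective_rating(0.9, 0.0, 0.0) == 0.0

    def test_literal_mode_endpoints(self):
        cfg = SimConfig(rating_mode="literal")
        # empty cell still rates R_in; at and beyond twice capacity rates 0
        assert effective_rating(0.6, 0.0, 1000.0, cfg) == pytest.approx(0.6)
        assert effective_rating(0.6, 2000.0, 1000.0, cfg) == 0.0
        # below capacity the literal rule rises with population
        low = effective_rating(0.6, 0.0, 1000.0, cfg)
        mid = effective_rating(0.6, 500.0, 1000.0, cfg)
        assert mid > low

    def test_monotone_non_increasing_canonical(self):
        P = np.linspace(0, 3000, 50)
        R = effective_rating(np.full_like(P, 0.7), P, np.full_like(P, 1000.0))
        assert np.all(np.diff(R) <= 1e-15)


class TestBoundaryFlux:
    def test_symmetric_cells_no_net_flux(self):
        R = np.array([[0.5, 0.5]])
        P = np.array([[100.0, 100.0]])
        cross, _ = boundary_flux(P, R, SimConfig())
        net = cross[(0, 1)][0, 0] - cross[(0, -1)][0, 1]
        assert net == pytest.approx(0.0)

    def test_boundary_split_ratio(self):
        """F_in : F_out = R_nbr : R_self — with ratings 0.6 vs 0.3 the
        better side receives 2/3 of each directed pool."""
        R = np.array([[0.3, 0.6]])
        P = np.array([[100.0, 100.0]])
        cfg = SimConfig(mu=0.25)
        cross, _ = boundary_flux(P, R, cfg)
        pool_a = cfg.mu * 100.0 * (1 - 0.3)  # cell a's full mobile pool
        assert cross[(0, 1)][0, 0] == pytest.approx(pool_a * 2 / 3)
        pool_b = cfg.mu * 100.0 * (1 - 0.6)
        assert cross[(0, -1)][0, 1] == pytest.approx(pool_b * 1 / 3)

    def test_outflow_capped_by_mobility(self):
        rng = np.random.default_rng(3)
        R = rng.random((6, 6))
        P = rng.random((6, 6)) * 1e4
        cfg = SimConfig(mu=0.25)
        cross, _ = boundary_flux(P, R, cfg)
        outflow = sum(cross.values())
        assert np.all(outflow <= cfg.mu * P + 1e-9)

    def test_crowded_neighbour_receives_nothing(self):
        # R = 0 encodes a cell at twice its carrying capacity
        R = np.array([[0.5, 0.0]])
        P = np.array([[100.0, 100.0]])
        cross, _ = boundary_flux(P, R, SimConfig())
        assert cross[(0, 1)][0, 0] == 0.0

    def test_all_zero_neighbours_nobody_moves(self):
        R = np.array([[0.5, 0.0, 0.0]])
        P = np.array([[100.0, 0.0, 0.0]])
        cross, _ = boundary_flux(P, R, SimConfig())
        assert all(np.all(c == 0) for c in cross.values())

    def test_monotone_attraction(self):
        """On a 3-cell line, raising the rating of the end cell strictly
        increases its one-step net inflow."""
        P = np.array([[100.0, 100.0, 100.0]])

        def net_inflow(rc):
            R = np.array([[0.5, 0.5, rc]])
            cross, _ = boundary_flux(P, R, SimConfig())
            inflow = cross[(0, 1)][0, 1]  # centre -> east
            outflow = cross[(0, -1)][0, 2]
            return inflow - outflow

        assert net_inflow(0.6) > net_inflow(0.4)


class TestBirths:
    @pytest.mark.parametrize(
        "P, R, expected_increment",
        [(1000.0, 1.0, 100.0), (1000.0, 0.5, 50.0), (1000.0, 0.0, 0.0)],
    )
    def test_birth_rule(self, P, R, expected_increment):
        cfg = SimConfig(g=0.1)
        out = apply_births(np.array([[[P]]]), np.array([[R]]), cfg)
        assert out[0, 0, 0] - P == pytest.approx(expected_increment)


class TestSeaLinks:
    @staticmethod
    def _islands(gap_km):
        spec = TerrainSpec(template="two_islands", shape=(30, 70), gap_km=gap_km, rng_seed=3)
        elev, water = make_terrain(spec)
        return compute_habitability(elev, water), elev

    def test_crossable_gap_yields_one_link(self):
        fld, elev = self._islands(10.0)
        links = build_sea_links(fld.classification, elev.cell_size_km)
        assert len(links) == 1
        assert links[0].gap_km == pytest.approx(10.0, abs=1.0)
        assert links[0].damping == pytest.approx(elev.cell_size_km / links[0].gap_km)

    def test_wide_gap_yields_none(self):
        fld, elev = self._islands(40.0)
        assert build_sea_links(fld.classification, elev.cell_size_km) == []

    def test_single_landmass_empty(self, valley):
        fx, fld = valley
        assert build_sea_links(fld.classification, fx.elev.cell_size_km) == []


class TestSeeding:
    def test_totals_conserved_after_seeding(self, valley):
        _, fld = valley
        seeds = [Seed("a", 25, 12, 1e5), Seed("b", 25, 38, 1e3)]
        state = seed_state(fld, seeds)
        assert state.total.sum() == pytest.approx(1e5 + 1e3)

    def test_seed_on_sea_rejected(self, valley):
        _, fld = valley
        with pytest.raises(ValueError, match="habitable"):
            seed_state(fld, [Seed("a", 0, 0, 10.0)])

    def test_duplicate_labels_rejected(self, valley):
        _, fld = valley
        with pytest.raises(ValueError, match="duplicate"):
            seed_state(fld, [Seed("a", 25, 12, 1.0), Seed("a", 25, 38, 1.0)])

    def test_delayed_entry(self, valley):
        fx, fld = valley
        seeds = [fx.seeds[0], Seed("late", fx.seeds[1].row, fx.seeds[1].col, 500.0, start_step=5)]
        cfg = SimConfig(g=0.0, steps_per_epoch=10, n_epochs=1)
        traj = run(fld, seeds, cfg, record_every=1)
        assert traj.snapshots[4][1][1].sum() == 0.0
        assert traj.snapshots[5][1][1].sum() > 0.0


class TestStep:
    def test_mass_conserved_without_births(self, valley):
        fx, fld = valley
        cfg = SimConfig(g=0.0, steps_per_epoch=200, n_epochs=1)
        traj = run(fld, fx.seeds, cfg)
        total0 = traj.totals[0]
        assert all(abs(t - total0) / total0 < 1e-6 for t in traj.totals)

    def test_positivity(self, valley):
        fx, fld = valley
        cfg = SimConfig(steps_per_epoch=100, n_epochs=1)
        traj = run(fld, fx.seeds, cfg)
        assert traj.final.min() >= 0.0

    def test_corrupt_state_detected(self, valley):
        _, fld = valley
        bad = PopulationState(["a"], np.full((1, *fld.shape), -1.0))
        with pytest.raises(StateCorruptionError):
            step(bad, fld)

    def test_mirror_symmetry(self, suite):
        """Mirror-symmetric terrain and seed stay mirror-symmetric."""
        fx = suite["mirror_island"]
        fld = compute_habitability(fx.elev, fx.water)
        assert np.allclose(fld.R_in, fld.R_in[:, ::-1], atol=1e-12)
        cfg = SimConfig(steps_per_epoch=100, n_epochs=1)
        traj = run(fld, fx.seeds, cfg)
        P = traj.final[0]
        assert np.allclose(P, P[:, ::-1], atol=1e-9)

    def test_four_fold_symmetry_uniform_plain(self):
        """Uniform terrain with a centred seed spreads with 4-fold mirror
        symmetry at every step."""
        import warnings

        from paleodiff.terrain_io import ElevationGrid

        elev = ElevationGrid(np.full((21, 21), 100.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fld = compute_habitability(elev, np.zeros((21, 21), bool))
        cfg = SimConfig(steps_per_epoch=30, n_epochs=1)
        traj = run(fld, [Seed("c", 10, 10, 5e6)], cfg)
        P = traj.final[0]
        assert np.allclose(P, P[::-1, :], atol=1e-9)
        assert np.allclose(P, P[:, ::-1], atol=1e-9)
        assert np.allclose(P, P.T, atol=1e-9)

    def test_crowded_cell_never_gains_from_migration(self, suite):
        fx = suite["two_cell"]
        fld = compute_habitability(fx.elev, fx.water)
        P = np.zeros((1, 1, 2))
        P[0, 0, 0] = 1000.0
        P[0, 0, 1] = 2.0 * fld.P_best[0, 1]  # exactly at the crowding cut-off
        state = PopulationState(["a"], P)
        cfg = SimConfig(g=0.0)
        new = step(state, fld, cfg)
        assert new.P[0, 0, 1] <= P[0, 0, 1] + 1e-9

    def test_two_cell_fixed_point_matches_scalar_iteration(self, suite):
        """The full engine on a 1x2 grid reproduces an independently coded
        scalar iteration of the same update rule."""
        fx = suite["two_cell"]
        fld = compute_habitability(fx.elev, fx.water)
        mu = 0.25
        cfg = SimConfig(g=0.0, mu=mu, steps_per_epoch=500, n_epochs=1)
        traj = run(fld, [Seed("a", 0, 0, 1e4)], cfg)

        Rin = fld.R_in[0]
        Pb = fld.P_best[0]
        x = np.array([1e4, 0.0])
        for _ in range(500):
            R = Rin * np.maximum(0.0, 1.0 - x / (2.0 * Pb))
            cross = np.zeros(2)
            for i, j in ((0, 1), (1, 0)):
                if R[j] > 0:
                    pool = mu * x[i] * (1.0 - R[i])
                    cross[i] = pool * R[j] / (R[i] + R[j])
            x = x - cross + cross[::-1]
        assert np.allclose(traj.final[0, 0], x, rtol=1e-9)
        # a near-stationary point has been reached
        assert abs(traj.totals[-1] - traj.totals[-2]) / traj.totals[-1] < 1e-6


class TestRun:
    def test_epoch_bookkeeping(self, valley):
        fx, fld = valley
        cfg = SimConfig(steps_per_epoch=50, n_epochs=4)
        traj = run(fld, fx.seeds, cfg)
        assert [s for s, _ in traj.snapshots] == [0, 50, 100, 150, 200]

    def test_empty_seed_list_all_zero(self, valley):
        _, fld = valley
        cfg = SimConfig(steps_per_epoch=10, n_epochs=1)
        traj = run(fld, [], cfg)
        assert all(P.size == 0 or P.sum() == 0 for _, P in traj.snapshots)

    def test_deterministic_reruns(self, valley):
        fx, fld = valley
        cfg = SimConfig(steps_per_epoch=100, n_epochs=2)
        t1 = run(fld, fx.seeds, cfg)
        t2 = run(fld, fx.seeds, cfg)
        assert t1.final.tobytes() == t2.final.tobytes()

    def test_isolated_component_stays_empty(self):
        spec = TerrainSpec(template="two_islands", shape=(30, 70), gap_km=40.0, rng_seed=3)
        elev, water = make_terrain(spec)
        fld = compute_habitability(elev, water)
        from scipy import ndimage

        comp, n = ndimage.label(fld.classification == 0)
        assert n == 2
        cells = np.argwhere(fld.habitable & (comp == 1))
        r, c = cells[len(cells) // 2]
        cfg = SimConfig(steps_per_epoch=100, n_epochs=1)
        traj = run(fld, [Seed("a", int(r), int(c), 1e5)], cfg)
        assert traj.final[0][comp == 2].sum() == 0.0

    def test_literal_mode_runs_and_conserves(self, valley):
        fx, fld = valley
        cfg = SimConfig(g=0.0, rating_mode="literal", steps_per_epoch=100, n_epochs=1)
        traj = run(fld, fx.seeds, cfg)
        assert abs(traj.totals[-1] - traj.totals[0]) / traj.totals[0] < 1e-6

    def test_moore_neighbourhood_runs(self, valley):
        fx, fld = valley
        cfg = SimConfig(g=0.0, neighborhood="moore9", steps_per_epoch=50, n_epochs=1)
        traj = run(fld, fx.seeds, cfg)
        assert abs(traj.totals[-1] - traj.totals[0]) / traj.totals[0] < 1e-6
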