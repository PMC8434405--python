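"""Geometric H-bond detection and population kinetics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hydrashell import (AnalysisError, HBondCriterion, HBondSeries,
                        ParameterError, continuous_lifetime, detect_hbonds,
                        gen_shell_system, gen_two_state_series,
                        hbond_count_series, hbond_existence, hbond_times,
                        intermittent_correlation, relaxation_time,
                        shell_water_count, two_state_correlation)
from hydrashell.trajectory import (Frame, Topology, Trajectory,
                                   assign_donor_acceptor_flags)

from conftest import make_water_topology


def donor_acceptor_topology():
    """One O-H donor group (molecule 0) plus a lone acceptor O (molecule 1)."""
    top = Topology(["O1", "H1", "O2"], ["O", "H", "O"], [1, 1, 2],
                   ["MOA", "MOA", "MOB"], [0, 0, 1], bonds=[[0, 1]])
    assign_donor_acceptor_flags(top)
    return top


def water_box_trajectory(n_waters, box_edge, n_frames=1, dt=1.0, seed=0):
    from hydrashell.synthetic import _water_site_offsets

    rng = np.random.default_rng(seed)
    top = make_water_topology(n_waters)
    sites = _water_site_offsets()
    coords = np.empty((n_frames, 3 * n_waters, 3))
    for f in range(n_frames):
        centres = rng.uniform(0, box_edge, size=(n_waters, 3))
        mats = Rotation.random(n_waters, random_state=rng).as_matrix()
        placed = np.einsum("mij,sj->msi", mats, sites)
        coords[f] = (centres[:, None, :] + placed).reshape(-1, 3)
    return Trajectory(top, coords, np.diag([box_edge] * 3),
                      np.arange(n_frames) * dt)


class TestCriterion:
    def test_defaults(self):
        c = HBondCriterion()
        assert c.da_cutoff == 0.35 and c.angle_cutoff == 30.0

    def test_invalid_rejected(self):
        with pytest.raises(ParameterError):
            HBondCriterion(da_cutoff=-0.1)
        with pytest.raises(ParameterError):
            HBondCriterion(angle_cutoff=95.0)


class TestDetectHBonds:
    def test_collinear_geometry_bonds(self):
        top = donor_acceptor_topology()
        f = Frame(np.array([[0, 0, 0], [0.1, 0, 0], [0.3, 0, 0.0]]))
        assert detect_hbonds(f, top) == [(0, 1, 2)]

    def test_distance_cutoff_strict(self):
        top = donor_acceptor_topology()
        f = Frame(np.array([[0, 0, 0], [0.1, 0, 0], [0.36, 0, 0.0]]))
        assert detect_hbonds(f, top) == []
        # exactly at the cutoff: excluded (strict inequality)
        f2 = Frame(np.array([[0, 0, 0], [0.1, 0, 0], [0.35, 0, 0.0]]))
        assert detect_hbonds(f2, top) == []

    def test_angle_cutoff(self):
        top = donor_acceptor_topology()
        a = np.deg2rad(45)
        f = Frame(np.array([[0, 0, 0], [0.1, 0, 0],
                            [0.3 * np.cos(a), 0.3 * np.sin(a), 0.0]]))
        assert detect_hbonds(f, top) == []

    def test_same_molecule_excluded(self):
        top = make_water_topology(1)
        f = Frame(np.array([[0, 0, 0], [0.1, 0, 0], [0, 0.1, 0.0]]))
        assert detect_hbonds(f, top) == []

    def test_matches_all_triples_oracle(self):
        """Oracle: independent exhaustive loop over all (D, H, A) triples."""
        crit = HBondCriterion()
        cos_cut = np.cos(np.deg2rad(crit.angle_cutoff))
        for seed in range(5):
            traj = water_box_trajectory(50, 2.2, seed=seed)
            top, box = traj.topology, traj.box
            pos = traj.coordinates[0]
            edges = np.diag(box)

            def mi(v):
                return v - edges * np.floor(v / edges + 0.5)

            expected = set()
            for d in range(top.n_atoms):
                if not top.donor_flag[d]:
                    continue
                for h in top.bonded_hydrogens(d):
                    for a in range(top.n_atoms):
                        if not top.acceptor_flag[a] or a == d:
                            continue
                        if top.molecule_id[a] == top.molecule_id[d]:
                            continue
                        da = mi(pos[a] - pos[d])
                        if np.linalg.norm(da) >= crit.da_cutoff:
                            continue
                        dh = mi(pos[h] - pos[d])
                        cosang = dh @ da / (np.linalg.norm(dh) * np.linalg.norm(da))
                        if cosang > cos_cut:
                            expected.add((d, int(h), a))
            got = set(detect_hbonds(Frame(pos, box), top, criterion=crit))
            assert got == expected

    def test_rigid_transform_invariance(self):
        traj = water_box_trajectory(30, 2.0, seed=3)
        top = traj.topology
        pos = traj.coordinates[0]
        bonds_a = detect_hbonds(Frame(pos, None), top)
        R = Rotation.from_euler("xyz", [20, 40, 60], degrees=True).as_matrix()
        bonds_b = detect_hbonds(Frame(pos @ R.T + 7.0, None), top)
        assert bonds_a == bonds_b

    def test_missing_hydrogen_on_donor_raises(self):
        top = Topology(["O1", "O2"], ["O", "O"], [1, 2], ["A", "B"], [0, 1])
        top.donor_flag = np.array([True, False])
        top.acceptor_flag = np.array([True, True])
        f = Frame(np.array([[0, 0, 0], [0.3, 0, 0.0]]))
        from hydrashell import TopologyError

        with pytest.raises(TopologyError):
            detect_hbonds(f, top)


class TestCountSeries:
    def test_permanent_bond(self):
        top = donor_acceptor_topology()
        coords = np.tile(np.array([[0, 0, 0], [0.1, 0, 0], [0.3, 0, 0.0]]), (100, 1, 1))
        traj = Trajectory(top, coords, None, np.arange(100.0))
        c = hbond_count_series(traj, [0, 1], [2])
        assert c.mean == 1.0 and c.sd == 0.0

    def test_nothing_in_range(self):
        top = donor_acceptor_topology()
        coords = np.tile(np.array([[0, 0, 0], [0.1, 0, 0], [2.0, 0, 0.0]]), (10, 1, 1))
        traj = Trajectory(top, coords, None, np.arange(10.0))
        assert hbond_count_series(traj, [0, 1], [2]).mean == 0.0

    def test_crafted_counts_mean_and_sd(self):
        """3 frames holding 2, 3, 4 bonds by construction: mean 3, sd 1."""
        n = 4  # donor groups, one shared acceptor row
        names, elems, resids, resnames, mols, bonds = [], [], [], [], [], []
        for m in range(n):
            b = 2 * m
            names += [f"O{m}", f"H{m}"]
            elems += ["O", "H"]
            resids += [m + 1] * 2
            resnames += ["DON"] * 2
            mols += [m] * 2
            bonds += [(b, b + 1)]
        names += ["OA"]
        elems += ["O"]
        resids += [n + 1]
        resnames += ["ACC"]
        mols += [n]
        top = Topology(names, elems, resids, resnames, mols, bonds)
        assign_donor_acceptor_flags(top)
        acc = 2 * n
        frames = []
        for n_bonds in (2, 3, 4):
            pos = np.zeros((2 * n + 1, 3))
            pos[acc] = [0, 0, 0]
            for m in range(n):
                if m < n_bonds:
                    centre = np.array([0.3, 0, 0])
                    direction = Rotation.from_euler("z", 90 * m, degrees=True).as_matrix()
                    pos[2 * m] = direction @ centre
                    pos[2 * m + 1] = direction @ (centre - [0.1, 0, 0])
                else:
                    pos[2 * m] = [2.0 + m, 0, 0]
                    pos[2 * m + 1] = [2.1 + m, 0, 0]
            frames.append(pos)
        traj = Trajectory(top, np.stack(frames), None, np.arange(3.0))
        c = hbond_count_series(traj, np.arange(2 * n), [acc])
        assert np.array_equal(c.counts, [2, 3, 4])
        assert c.mean == 3.0 and c.sd == 1.0


class TestExistence:
    def _traj_on_off(self, pattern):
        top = donor_acceptor_topology()
        near = np.array([[0, 0, 0], [0.1, 0, 0], [0.3, 0, 0.0]])
        far = np.array([[0, 0, 0], [0.1, 0, 0], [2.0, 0, 0.0]])
        coords = np.stack([near if p else far for p in pattern])
        return Trajectory(top, coords, None, np.arange(float(len(pattern))))

    def test_pattern_row(self):
        traj = self._traj_on_off([1, 0, 1])
        s = hbond_existence(traj, [0, 1], [2])
        assert s.pairs == [(0, 1, 2)]
        assert list(s.h[0]) == [1, 0, 1]

    def test_consistency_with_per_frame_detection(self):
        traj = water_box_trajectory(20, 1.8, n_frames=5, seed=9)
        water = np.arange(traj.n_atoms)
        s = hbond_existence(traj, water, water)
        for f in range(5):
            bonds = set(detect_hbonds(Frame(traj.coordinates[f], traj.box),
                                      traj.topology))
            from_series = {s.pairs[i] for i in np.flatnonzero(s.h[:, f])}
            assert from_series == bonds

    def test_no_bonds_raises(self):
        traj = self._traj_on_off([0, 0])
        with pytest.raises(AnalysisError):
            hbond_existence(traj, [0, 1], [2])


class TestContinuousLifetime:
    def test_single_run(self):
        s = HBondSeries.from_matrix(np.array([[0, 1, 1, 1, 0]]), dt=1.0)
        assert continuous_lifetime(s) == 3.0

    def test_two_run_mean(self):
        s = HBondSeries.from_matrix(np.array([[0, 1, 0, 1, 1, 1, 0]]), dt=1.0)
        assert continuous_lifetime(s) == 2.0

    def test_censored_runs_excluded(self):
        s = HBondSeries.from_matrix(np.array([[1, 1, 0, 1, 1, 0, 1]]), dt=1.0)
        # leading and trailing runs are censored; only the middle run counts
        assert continuous_lifetime(s) == 2.0

    def test_only_censored_raises(self):
        s = HBondSeries.from_matrix(np.ones((2, 5), dtype=int), dt=1.0)
        with pytest.raises(AnalysisError):
            continuous_lifetime(s)

    def test_two_state_dwell_law(self):
        h = gen_two_state_series(1000, 0.1, 1.0, 0.01, 10000, seed=31)
        tau = continuous_lifetime(HBondSeries.from_matrix(h, 0.01))
        assert abs(tau - 1.0) < 0.05


class TestIntermittentCorrelation:
    def test_permanent_bond_unity(self):
        s = HBondSeries.from_matrix(np.ones((3, 30), dtype=int), dt=1.0)
        c = intermittent_correlation(s, max_lag=10.0)
        assert np.allclose(c.value, 1.0)

    def test_matches_double_loop_oracle(self, rng):
        h = (rng.random((6, 100)) < 0.3).astype(np.uint8)
        h[0, 0] = 1
        s = HBondSeries.from_matrix(h, dt=0.5)
        c = intermittent_correlation(s, max_lag=20.0, origin_stride=3)
        for k in range(41):
            num = den = 0
            for t0 in range(0, 100 - k, 3):
                num += int((h[:, t0] & h[:, t0 + k]).sum())
                den += int(h[:, t0].sum())
            assert abs(c.value[k] - num / den) < 1e-10

    def test_two_state_closed_form(self):
        k_on, k_off, dt = 0.1, 1.0, 0.01
        h = gen_two_state_series(2000, k_on, k_off, dt, 5000, seed=32)
        s = HBondSeries.from_matrix(h, dt)
        c = intermittent_correlation(s, max_lag=20 * dt)
        theory = two_state_correlation(c.lag, k_on, k_off)
        assert np.abs(c.value - theory).max() < 0.01

    def test_bounds_and_normalization(self, rng):
        h = (rng.random((5, 60)) < 0.5).astype(np.uint8)
        h[0, 0] = 1
        c = intermittent_correlation(HBondSeries.from_matrix(h, 1.0), max_lag=30.0)
        assert c.value[0] == 1.0
        assert np.all((c.value >= 0) & (c.value <= 1))

    def test_all_zero_raises(self):
        s = HBondSeries.from_matrix(np.zeros((2, 10), dtype=int), dt=1.0)
        with pytest.raises(AnalysisError):
            intermittent_correlation(s, max_lag=5.0)


class TestRelaxationTime:
    def test_exact_exponential(self):
        from hydrashell import CorrelationSeries

        t = np.arange(0, 30.0, 0.5)
        c = CorrelationSeries(t, np.exp(-t / 10.0), np.ones(len(t), dtype=int))
        tau, flag = relaxation_time(c)
        assert abs(tau - 10.0) <= 0.05 and not flag

    def test_two_state_closed_form_root(self):
        """tau_R solves 1/e = p + (1-p) e^{-1.1 t}: 1.081 ps at k_on=0.1, k_off=1."""
        k_on, k_off, dt = 0.1, 1.0, 0.01
        h = gen_two_state_series(3000, k_on, k_off, dt, 8000, seed=33)
        c = intermittent_correlation(HBondSeries.from_matrix(h, dt),
                                     max_lag=2.5, origin_stride=10)
        tau, _ = relaxation_time(c)
        expect = np.log((np.exp(-1) - 1 / 11) * 11 / 10) / (-1.1)
        assert abs(tau - expect) / expect < 0.05

    def test_plateau_above_1_over_e_raises(self):
        h = gen_two_state_series(500, 0.5, 0.5, 0.05, 2000, seed=34)
        c = intermittent_correlation(HBondSeries.from_matrix(h, 0.05), max_lag=20.0)
        with pytest.raises(AnalysisError, match="plateau"):
            relaxation_time(c)

    def test_extrapolation_flagged(self):
        from hydrashell import CorrelationSeries

        t = np.arange(0, 5.0, 0.5)
        c = CorrelationSeries(t, np.exp(-t / 20.0), np.ones(len(t), dtype=int))
        tau, flag = relaxation_time(c, extrapolate=True)
        assert flag
        assert abs(tau - 20.0) < 0.5


class TestTimeScaleOrdering:
    def test_tau_hb_below_tau_r_on_markov(self):
        h = gen_two_state_series(2000, 0.1, 1.0, 0.01, 5000, seed=35)
        s = HBondSeries.from_matrix(h, 0.01)
        tau_hb = continuous_lifetime(s)
        c = intermittent_correlation(s, max_lag=3.0, origin_stride=10)
        tau_r, _ = relaxation_time(c)
        assert tau_hb <= tau_r


class TestShellWaterCount:
    def test_matches_membership_column_sums(self):
        from hydrashell import shell_membership

        t = gen_shell_system(15, 0.4, 0.6, 0.5, 4.0, 0.1, 50, seed=36)
        counts, mean = shell_water_count(t, [0], 0.5)
        m = shell_membership(t, [0], 0.5)
        assert np.array_equal(counts, m.occupancy.sum(axis=0))
        assert np.isclose(mean, counts.mean())

    def test_zero_cutoff_zero_counts(self):
        t = gen_shell_system(5, 0.5, 0.5, 0.5, 4.0, 0.1, 10, seed=37)
        counts, mean = shell_water_count(t, [0], 0.0)
        assert np.all(counts == 0) and mean == 0.0
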