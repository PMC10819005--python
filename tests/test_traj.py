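import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from thermomem import (InteractionParams, MolecularSystem, Trajectory,
                       area_per_lipid, axis_order_parameter, calpha_pca,
                       count_contacts, detect_hbonds, detect_salt_bridges,
                       deuterium_order_parameters, interaction_series,
                       membrane_thickness, min_distance,
                       per_residue_interactions)


def random_frame(n_atoms, box, seed):
    rng = np.random.default_rng(seed)
    return rng.uniform(0, 1, (n_atoms, 3)) * box


class TestPairMetrics:
    def test_direct_distance(self):
        pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.5]])
        assert min_distance(pos, np.array([10.0, 10.0, 10.0]), [0], [1]) == 0.5

    def test_periodic_wrap(self):
        pos = np.array([[0.0, 0.0, 0.1], [0.0, 0.0, 9.9]])
        d = min_distance(pos, np.array([10.0, 10.0, 10.0]), [0], [1])
        assert d == pytest.approx(0.2, abs=1e-12)

    def test_min_distance_matches_brute_force(self):
        box = np.array([3.0, 4.0, 5.0])
        pos = random_frame(200, box, seed=1)
        a, b = list(range(100)), list(range(100, 200))
        assert min_distance(pos, box, a, b) == pytest.approx(
            oracles.min_distance_bf(pos, box, a, b), abs=1e-12)

    def test_contact_counting_trivial_cases(self):
        box = np.array([10.0, 10.0, 10.0])
        pos = np.array([[0.0, 0.0, 0.0], [0.3, 0.0, 0.0]])
        assert count_contacts(pos, box, [0], [1], 0.6) == 1
        assert count_contacts(pos, box, [0], [1], 0.2) == 0

    def test_contacts_match_brute_force(self):
        box = np.array([3.0, 3.0, 3.0])
        pos = random_frame(150, box, seed=2)
        a, b = list(range(70)), list(range(70, 150))
        for cutoff in (0.3, 0.6, 1.0):
            assert count_contacts(pos, box, a, b, cutoff) == \
                oracles.count_contacts_bf(pos, box, a, b, cutoff)

    def test_oversized_cutoff_rejected(self):
        pos = random_frame(10, np.array([2.0, 2.0, 2.0]), seed=3)
        with pytest.raises(ValueError, match="half the smallest box"):
            count_contacts(pos, np.array([2.0, 2.0, 2.0]), [0], [1], 1.5)

    @settings(max_examples=25, deadline=None)
    @given(shift=st.tuples(*[st.floats(-20, 20) for _ in range(3)]),
           seed=st.integers(0, 100))
    def test_translation_and_wrapping_invariance(self, shift, seed):
        """Pairwise metrics are unchanged by rigid translation and by
        periodic re-wrapping of all coordinates."""
        box = np.array([3.0, 4.0, 5.0])
        pos = random_frame(40, box, seed=seed)
        moved = pos + np.asarray(shift)
        wrapped = moved % box
        a, b = list(range(20)), list(range(20, 40))
        d0 = min_distance(pos, box, a, b)
        assert min_distance(moved, box, a, b) == pytest.approx(d0, abs=1e-9)
        assert min_distance(wrapped, box, a, b) == pytest.approx(d0, abs=1e-9)
        c0 = count_contacts(pos, box, a, b, 0.8)
        assert count_contacts(wrapped, box, a, b, 0.8) == c0


def hb_test_system(n=6):
    """Minimal donor/hydrogen/acceptor system for geometric criteria."""
    return MolecularSystem(
        names=np.array(["N", "H", "O", "N2", "H2", "O2"][:n], dtype=object),
        elements=np.array(["N", "H", "O", "N", "H", "O"][:n], dtype=object),
        residue_index=np.arange(n) // 3,
        residue_name=np.array(["LYS"] * n, dtype=object),
        molecule_tag=np.array(["protein"] * n, dtype=object),
        hb_donor=np.array([True, False, False, True, False, False][:n]),
        hb_acceptor=np.array([False, False, True, False, False, True][:n]),
        hydrogen_donor_ref=np.array([-1, 0, -1, -1, 3, -1][:n]),
    )


class TestHydrogenBonds:
    box = np.array([10.0, 10.0, 10.0])

    def test_collinear_geometry_is_a_bond(self):
        sys_ = hb_test_system(3)
        pos = np.array([[0, 0, 0], [0, 0, 0.1], [0, 0, 0.30]], dtype=float)
        bonds = detect_hbonds(sys_, pos, self.box, [0], [2])
        assert bonds == [(0, 1, 2)]

    def test_wide_angle_rejected(self):
        sys_ = hb_test_system(3)
        theta = np.radians(45.0)
        pos = np.array([[0, 0, 0],
                        [0.1 * np.sin(theta), 0, 0.1 * np.cos(theta)],
                        [0, 0, 0.30]])
        assert detect_hbonds(sys_, pos, self.box, [0], [2]) == []

    def test_distance_cut_enforced(self):
        sys_ = hb_test_system(3)
        pos = np.array([[0, 0, 0], [0, 0, 0.1], [0, 0, 0.40]], dtype=float)
        assert detect_hbonds(sys_, pos, self.box, [0], [2]) == []

    def test_donor_without_hydrogen_rejected(self):
        sys_ = hb_test_system(3)
        sys_.hydrogen_donor_ref[1] = -1
        pos = np.zeros((3, 3))
        with pytest.raises(ValueError, match="without a referenced hydrogen"):
            detect_hbonds(sys_, pos, self.box, [0], [2])

    def test_randomized_frames_match_exhaustive_oracle(self):
        rng = np.random.default_rng(8)
        n_pairs = 30
        names, elements, donor, acceptor, href = [], [], [], [], []
        for k in range(n_pairs):
            names += ["N", "H", "O"]
            elements += ["N", "H", "O"]
            donor += [True, False, False]
            acceptor += [False, False, True]
            href += [-1, 3 * k, -1]
        sys_ = MolecularSystem(
            names=np.array(names, dtype=object),
            elements=np.array(elements, dtype=object),
            residue_index=np.arange(3 * n_pairs) // 3,
            residue_name=np.array(["LYS"] * (3 * n_pairs), dtype=object),
            molecule_tag=np.array(["protein"] * (3 * n_pairs), dtype=object),
            hb_donor=np.array(donor), hb_acceptor=np.array(acceptor),
            hydrogen_donor_ref=np.array(href),
        )
        donors = np.flatnonzero(sys_.hb_donor)
        acceptors = np.flatnonzero(sys_.hb_acceptor)
        hydrogens_of = {int(d): [int(d) + 1] for d in donors}
        box = np.array([2.0, 2.0, 2.0])
        for trial in range(5):
            pos = rng.uniform(0, 2.0, (3 * n_pairs, 3))
            pos[1::3] = pos[0::3] + rng.normal(0, 0.05, (n_pairs, 3))
            got = sorted(detect_hbonds(sys_, pos, box, donors, acceptors))
            want = sorted(oracles.hbonds_bf(pos, box, donors.tolist(),
                                            hydrogens_of, acceptors.tolist(),
                                            0.35, 30.0))
            assert got == want

    def test_hbond_pairs_are_subset_of_contacts(self):
        """Any detected H-bond donor-acceptor pair is also a contact at the
        same cutoff restricted to donor/acceptor atoms."""
        rng = np.random.default_rng(12)
        sys_ = hb_test_system(6)
        box = np.array([3.0, 3.0, 3.0])
        for _ in range(10):
            pos = rng.uniform(0, 3.0, (6, 3))
            pos[1] = pos[0] + rng.normal(0, 0.03, 3)
            pos[4] = pos[3] + rng.normal(0, 0.03, 3)
            bonds = detect_hbonds(sys_, pos, box, [0, 3], [2, 5], r_cut=0.5)
            for d, _, a in bonds:
                assert min_distance(pos, box, [d], [a]) <= 0.5


class TestSaltBridges:
    def test_close_nitrogen_oxygen_pair_detected(self):
        sys_ = MolecularSystem(
            names=np.array(["NZ", "O13"], dtype=object),
            elements=np.array(["N", "O"], dtype=object),
            residue_index=np.array([0, 1]),
            residue_name=np.array(["LYS", "DPPC"], dtype=object),
            molecule_tag=np.array(["protein", "lipid"], dtype=object),
            cationic_group=np.array([0, -1]),
            anionic_group=np.array([-1, 0]),
        )
        box = np.array([10.0, 10.0, 10.0])
        pos = np.array([[0, 0, 0.35], [0, 0, 0.0]])
        assert detect_salt_bridges(sys_, pos, box) == [(0, 0)]
        pos_far = np.array([[0, 0, 0.50], [0, 0, 0.0]])
        assert detect_salt_bridges(sys_, pos_far, box) == []

    def test_multi_group_frames_match_oracle(self):
        rng = np.random.default_rng(17)
        n_cat, n_an = 5, 6
        names, elements, cat, an, resi = [], [], [], [], []
        for k in range(n_cat):
            names += ["NZ"]; elements += ["N"]; cat += [k]; an += [-1]; resi += [k]
        for k in range(n_an):
            names += ["P", "O13"]
            elements += ["P", "O"]
            cat += [-1, -1]
            an += [k, k]
            resi += [n_cat + k, n_cat + k]
        sys_ = MolecularSystem(
            names=np.array(names, dtype=object),
            elements=np.array(elements, dtype=object),
            residue_index=np.array(resi),
            residue_name=np.array(["X"] * len(names), dtype=object),
            molecule_tag=np.array(["protein"] * n_cat + ["lipid"] * 2 * n_an,
                                  dtype=object),
            cationic_group=np.array(cat), anionic_group=np.array(an),
        )
        box = np.array([2.5, 2.5, 2.5])
        cat_atoms = {g: np.flatnonzero(sys_.cationic_group == g).tolist()
                     for g in range(n_cat)}
        an_atoms = {g: np.flatnonzero(sys_.anionic_group == g).tolist()
                    for g in range(n_an)}
        for trial in range(5):
            pos = rng.uniform(0, 2.5, (len(names), 3))
            got = sorted(detect_salt_bridges(sys_, pos, box))
            want = sorted(oracles.salt_bridges_bf(pos, box, cat_atoms, an_atoms, 0.40))
            assert got == want


class TestSeriesAndTable:
    def test_planted_contact_gives_constant_series(self, planted_toy):
        _, system, traj = planted_toy
        series = interaction_series(system, traj)
        assert np.all(series.min_distance == series.min_distance[0])
        assert np.all(series.n_contacts == series.n_contacts[0])
        assert np.all(series.n_hbonds >= 1)
        assert np.all(series.n_salt_bridges >= 1)

    def test_displaced_protein_zeroes_the_series(self, planted_toy):
        _, system, traj = planted_toy
        prot = system.select(molecule_tag="protein")
        positions = traj.positions.copy()
        positions[1:3, prot, 2] += 3.0  # lift the peptide far from the bilayer
        moved = Trajectory(positions, traj.box, traj.time)
        series = interaction_series(system, moved)
        assert series.n_contacts[1] == 0 and series.n_contacts[2] == 0
        assert series.n_hbonds[1] == 0 and series.n_salt_bridges[2] == 0
        assert series.n_contacts[0] > 0 and series.n_contacts[3] > 0

    def test_series_matches_single_frame_calls(self, planted_toy):
        _, system, traj = planted_toy
        series = interaction_series(system, traj)
        prot = system.select(molecule_tag="protein", heavy=True)
        lip = system.select(molecule_tag="lipid", heavy=True)
        f = 2
        assert series.min_distance[f] == min_distance(
            traj.positions[f], traj.box[f], prot, lip)
        assert series.n_contacts[f] == count_contacts(
            traj.positions[f], traj.box[f], prot, lip, 0.60)

    def test_per_residue_planted_bond_averages_one(self, planted_toy):
        _, system, traj = planted_toy
        table = per_residue_interactions(system, traj, window_ns=3.0)
        top = table.iloc[0]
        assert top["residue"].endswith("LYS")
        assert top["avg_hbonds"] == 1.0

    def test_window_of_contact_free_frames_is_all_zero(self, planted_toy):
        _, system, traj = planted_toy
        prot = system.select(molecule_tag="protein")
        positions = traj.positions.copy()
        positions[2:, prot, 2] += 3.0  # later frames contact-free
        moved = Trajectory(positions, traj.box, traj.time)
        table = per_residue_interactions(system, moved, window_ns=1.5)
        assert np.all(table["avg_hbonds"].to_numpy() == 0.0)
        assert np.all(table["avg_contacts"].to_numpy() == 0.0)

    def test_averages_equal_brute_force_recount(self, planted_toy):
        _, system, traj = planted_toy
        params = InteractionParams()
        table = per_residue_interactions(system, traj, window_ns=2.5,
                                         params=params)
        sel_frames = np.flatnonzero(traj.time > traj.time[-1] - 2.5)
        lip_heavy = system.select(molecule_tag="lipid", heavy=True)
        for _, row in table.iterrows():
            res = int(row["residue_index"]) - 1
            res_heavy = system.select(residue_index=res, heavy=True)
            counts = [oracles.count_contacts_bf(
                traj.positions[f], traj.box[f], res_heavy.tolist(),
                lip_heavy.tolist(), params.contact_cutoff) for f in sel_frames]
            assert row["avg_contacts"] == pytest.approx(np.mean(counts), abs=1e-12)

    def test_oversized_window_rejected(self, planted_toy):
        _, system, traj = planted_toy
        with pytest.raises(ValueError, match="window"):
            per_residue_interactions(system, traj, window_ns=100.0)


class TestMembraneGeometry:
    def test_area_per_lipid_arithmetic(self):
        assert area_per_lipid(np.array([10.0, 10.0, 12.0]), 200) == 0.5
        assert area_per_lipid(np.array([10.954, 10.954, 12.0]), 200) == \
            pytest.approx(0.6, abs=1e-3)
        assert area_per_lipid(np.array([20.0, 10.0, 12.0]), 200) == 1.0
        with pytest.raises(ValueError):
            area_per_lipid(np.array([10.0, 10.0, 12.0]), 0)

    def test_thickness_from_planes_and_translation_invariance(self, planted_toy):
        _, system, traj = planted_toy
        p_sel = system.select(flag="is_phosphorus")
        pos = traj.positions[0]
        assert membrane_thickness(pos, p_sel) == pytest.approx(4.8, abs=1e-12)
        assert membrane_thickness(pos + np.array([0, 0, 1.7]), p_sel) == \
            pytest.approx(4.8, abs=1e-12)

    def test_jittered_planes_average_to_truth(self):
        rng = np.random.default_rng(19)
        z = np.concatenate([np.full(50, 3.0), np.full(50, 7.8)])
        vals = []
        for _ in range(100):
            pos = np.zeros((100, 3))
            pos[:, 2] = z + rng.uniform(-0.05, 0.05, 100)
            vals.append(membrane_thickness(pos, np.arange(100)))
        assert np.mean(vals) == pytest.approx(4.8, abs=0.01)

    def test_single_leaflet_rejected(self):
        pos = np.zeros((10, 3))
        pos[:, 2] = 3.0
        with pytest.raises(ValueError, match="one leaflet"):
            membrane_thickness(pos, np.arange(10))


class TestOrderParameters:
    def test_upright_chains_give_minus_half(self, planted_toy):
        _, system, traj = planted_toy
        profiles = deuterium_order_parameters(system, traj)
        for chain in ("sn1", "sn2"):
            prof = profiles[chain]
            assert np.allclose(prof.s_cd, -0.5, atol=1e-12)
            # terminal carbons are absent
            assert 1 not in prof.carbon_positions
            assert prof.carbon_positions.max() < system.carbon_position.max() + 1

    def test_isotropic_axes_average_to_zero(self):
        rng = np.random.default_rng(23)
        v = rng.normal(size=(100_000, 3))
        s_axis = axis_order_parameter(v)
        assert -0.5 * s_axis == pytest.approx(0.0, abs=0.01)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(*[st.floats(-1, 1) for _ in range(3)]),
                    min_size=1, max_size=20))
    def test_s_cd_bounds_for_arbitrary_axes(self, vecs):
        v = np.array(vecs)
        norms = np.linalg.norm(v, axis=1)
        v = v[norms > 1e-6]
        if v.size == 0:
            return
        s_cd = -0.5 * axis_order_parameter(v)
        assert -0.5 - 1e-9 <= s_cd <= 1.0 + 1e-9


class TestCalphaPca:
    def make_traj(self, coords):
        coords = np.asarray(coords, float)
        nf = coords.shape[0]
        return Trajectory(coords, np.tile([10.0, 10.0, 10.0], (nf, 1)),
                          np.arange(nf, dtype=float))

    def test_identical_frames_give_zero_eigenvalues(self):
        frame = np.random.default_rng(1).uniform(0, 5, (6, 3))
        traj = self.make_traj(np.repeat(frame[None], 4, axis=0))
        res = calpha_pca(traj, np.arange(6))
        assert np.allclose(res.eigenvalues, 0.0, atol=1e-24)

    def test_symmetric_breathing_mode_is_single_eigenvalue(self):
        # two atoms moving apart along x: not representable by a rigid-body
        # motion, so the fit leaves one correlated degree of freedom
        amp = np.array([0.0, 0.1, 0.2, 0.3])
        frames = []
        for a in amp:
            frames.append([[-1.0 - a, 0, 0], [1.0 + a, 0, 0],
                           [0, 1.0, 0], [0, -1.0, 0]])
        traj = self.make_traj(np.array(frames) + 5.0)
        res = calpha_pca(traj, np.arange(4))
        assert res.eigenvalues[0] > 1e-6
        assert res.eigenvalues[1] < 1e-12 * res.eigenvalues[0] + 1e-18

    def test_matches_direct_covariance_oracle(self):
        rng = np.random.default_rng(31)
        coords = 5.0 + rng.normal(0, 0.1, (50, 5, 3))
        traj = self.make_traj(coords)
        res = calpha_pca(traj, np.arange(5), fit=False)
        X = coords.copy()
        X -= X.mean(axis=1, keepdims=True)            # translational fit
        flat = X.reshape(50, -1)
        flat -= flat.mean(axis=0)
        C = flat.T @ flat / 50
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        assert np.allclose(res.eigenvalues, evals, atol=1e-12)
        assert res.total_variance == pytest.approx(np.trace(C), rel=1e-10)

    def test_eigenvalue_sum_equals_total_fitted_variance(self):
        rng = np.random.default_rng(37)
        coords = 5.0 + rng.normal(0, 0.2, (30, 8, 3))
        traj = self.make_traj(coords)
        res = calpha_pca(traj, np.arange(8))
        # recompute the fitted coordinate variance from the projections
        total = float(np.sum(res.projections ** 2) / traj.n_frames)
        assert res.total_variance == pytest.approx(total, rel=1e-10)

    def test_single_frame_rejected(self):
        traj = self.make_traj(np.zeros((1, 4, 3)) + 1.0)
        with pytest.raises(ValueError, match="frames"):
            calpha_pca(traj, np.arange(4))
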