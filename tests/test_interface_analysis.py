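"""Pocket identification, H-bond/ion trajectory statistics, clustering,
and fpocket-based pocket selection."""

import numpy as np
import pytest

from mdpharm.interface_analysis import (
    HBondCounts,
    hbond_statistics,
    ion_statistics,
    normalize_by_sasa,
    parse_fpocket_pockets,
    pocket_from_reference,
    representative_frame,
    select_pocket_no_prior,
)
from mdpharm.structure_io import Structure, Trajectory, kabsch_superpose
from mdpharm.surface import harmonic_mean


def _structure(names, elements, resnames, chains, residx, coords):
    return Structure(
        atom_name=np.array(names),
        element=np.array(elements),
        residue_index=np.array(residx, dtype=int),
        residue_name=np.array(resnames),
        chain_id=np.array(chains),
        coords=np.array(coords, dtype=float),
    )


class TestPocketFromReference:
    def test_constructed_distances(self):
        # residue 0 at 4 A, residue 1 at 8 A from the reference point
        s = _structure(
            ["CA", "CA"], ["C", "C"], ["ALA", "ALA"], ["A", "B"], [0, 1],
            [[4.0, 0, 0], [8.0, 0, 0]],
        )
        with pytest.warns(UserWarning):
            p = pocket_from_reference(s, np.zeros((1, 3)), cutoff=5.0)
        assert p.residue_indices == [0]

    def test_empty_pocket_suggests_larger_cutoff(self):
        s = _structure(
            ["CA"], ["C"], ["ALA"], ["A"], [0], [[4.0, 0, 0]]
        )
        with pytest.raises(ValueError, match="larger cutoff"):
            pocket_from_reference(s, np.zeros((1, 3)), cutoff=0.1)

    def test_matches_all_pairs_bruteforce(self, recovery_fixture):
        _, traj, gt = recovery_fixture
        topo = traj.topology
        ref = np.array(gt["reference_coords"])
        pocket = pocket_from_reference(topo, ref, cutoff=5.0)
        heavy = np.flatnonzero(topo.heavy_mask & topo.is_protein)
        d = np.linalg.norm(
            topo.coords[heavy][:, None, :] - ref[None, :, :], axis=2
        ).min(axis=1)
        expected = sorted(set(topo.residue_index[heavy[d <= 5.0]].tolist()))
        assert pocket.residue_indices == expected


def _hbond_system(no_distance, angle_deg, donor_is_protein=True):
    """One protein N-H (or bare N/O) plus one water at a chosen geometry.

    The donor-H...acceptor angle is measured at the hydrogen.
    """
    nh = np.array([0.0, 0.0, 0.0])
    h = np.array([1.0, 0.0, 0.0])
    theta = np.radians(180.0 - angle_deg)
    # place acceptor at `no_distance` from the heavy atom along a direction
    # that realizes the requested angle at H
    # solve: point P with |P - nh| = no_distance and angle(nh, h, P) known
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    # find t so that |h + t*direction - nh| = no_distance
    a = 1.0
    b = 2.0 * np.dot(h - nh, direction)
    c = np.dot(h - nh, h - nh) - no_distance**2
    t = (-b + np.sqrt(b * b - 4 * a * c)) / 2.0
    wo = h + t * direction
    if donor_is_protein:
        names = ["N", "H", "O", "H1", "H2"]
        elements = ["N", "H", "O", "H", "H"]
        coords = [nh, h, wo, wo + [0.6, 0.76, 0], wo + [0.6, -0.76, 0]]
    else:
        # water donates: its hydrogen points at the protein oxygen
        u = (nh - wo) / np.linalg.norm(nh - wo)
        hw = wo + 0.98 * u
        names = ["O", "OW", "H1", "H2"]
        elements = ["O", "O", "H", "H"]
        coords = [nh, wo, hw, wo + [0.0, 0.98, 0.0]]
    resnames = ["SER"] * (2 if donor_is_protein else 1) + ["HOH"] * 3
    residx = [0] * (2 if donor_is_protein else 1) + [1] * 3
    chains = ["A"] * (2 if donor_is_protein else 1) + ["W"] * 3
    s = _structure(names, elements, resnames, chains, residx, coords)
    return Trajectory(topology=s, frames=s.coords[None])


class TestHBondGeometry:
    def test_linear_short_contact_is_donor_event(self):
        traj = _hbond_system(2.8, 180.0)
        c = hbond_statistics(traj, [0])
        assert c.donor_counts[0, 0] == 1
        assert c.acceptor_counts[0, 0] == 0

    def test_long_contact_rejected(self):
        c = hbond_statistics(_hbond_system(3.5, 180.0), [0])
        assert c.donor_counts[0, 0] == 0

    def test_bent_contact_rejected(self):
        c = hbond_statistics(_hbond_system(2.8, 120.0), [0])
        assert c.donor_counts[0, 0] == 0

    def test_water_donating_is_acceptor_event(self):
        traj = _hbond_system(2.8, 180.0, donor_is_protein=False)
        c = hbond_statistics(traj, [0])
        assert c.acceptor_counts[0, 0] == 1
        assert c.donor_counts[0, 0] == 0    # protein O has no hydrogen

    def test_no_water_errors(self):
        s = _structure(
            ["N", "H"], ["N", "H"], ["SER", "SER"], ["A", "A"], [0, 0],
            [[0, 0, 0], [1, 0, 0]],
        )
        traj = Trajectory(topology=s, frames=s.coords[None])
        with pytest.raises(ValueError, match="water"):
            hbond_statistics(traj, [0])


class TestPlantedOccupancies:
    def test_hbond_occupancy_matches_generator_bookkeeping(
        self, recovery_extraction
    ):
        gt = recovery_extraction["gt"]
        stats = recovery_extraction["stats"]
        n_frames = gt["n_frames"]
        for rec in gt["planted"]:
            if rec["kind"] not in ("donor", "acceptor"):
                continue
            occ = (
                stats.donor_occupancy_pct
                if rec["kind"] == "donor"
                else stats.acceptor_occupancy_pct
            )[rec["site_atom_index"]]
            planted = 100.0 * len(rec["bonded_frames"]) / n_frames
            assert abs(occ - planted) <= 100.0 * 2 / n_frames

    def test_ion_contact_percentages_match_generator(self, recovery_extraction):
        gt = recovery_extraction["gt"]
        stats = recovery_extraction["stats"]
        n_frames = gt["n_frames"]
        for rec in gt["planted"]:
            if rec["kind"] not in ("positive", "negative"):
                continue
            pct = (
                stats.cation_pct
                if rec["kind"] == "positive"
                else stats.anion_pct
            )[rec["site_atom_index"]]
            planted = 100.0 * len(rec["bonded_frames"]) / n_frames
            assert abs(pct - planted) <= 100.0 * 2 / n_frames

    @pytest.mark.parametrize("occupancy", [0.0, 0.25, 0.5, 0.8, 1.0])
    def test_occupancy_sweep_within_counting_precision(self, occupancy):
        from mdpharm.synthetic_fixtures import (
            FixtureSpec,
            make_complex_trajectory,
            PlannedSite,
        )

        plan = [
            PlannedSite("A", "donor", occupancy),
            PlannedSite("B", "acceptor", occupancy),
        ]
        spec = FixtureSpec(
            pocket_plan=plan, residues_per_chain=4, n_frames=16, seed=3
        )
        traj, gt = make_complex_trajectory(spec)
        atoms = [r["site_atom_index"] for r in gt["planted"]]
        counts = hbond_statistics(traj, atoms)
        don, acc = counts.occupancy_pct()
        for rec in gt["planted"]:
            measured = (don if rec["kind"] == "donor" else acc)[
                rec["site_atom_index"]
            ]
            assert measured == pytest.approx(
                100.0 * round(occupancy * 16) / 16, abs=1e-9
            )


class TestNormalization:
    def _counts(self, occupied_frames, n_frames=10):
        donor = np.zeros((1, n_frames), dtype=int)
        donor[0, :occupied_frames] = 1
        return HBondCounts(
            atom_indices=np.array([7]),
            donor_counts=donor,
            acceptor_counts=np.zeros((1, n_frames), dtype=int),
        )

    def test_normed_frequency_arithmetic(self):
        counts = self._counts(6)  # 60% occupancy
        donor, acceptor, excluded = normalize_by_sasa(counts, {7: 200.0})
        assert donor[7] == pytest.approx(30.0)   # 60 / 2.0 nm^2
        assert acceptor[7] == 0.0
        assert excluded == []

    def test_zero_occupancy_is_zero(self):
        donor, _, _ = normalize_by_sasa(self._counts(0), {7: 10.0})
        assert donor[7] == 0.0

    def test_low_exposure_atom_excluded_and_listed(self):
        donor, _, excluded = normalize_by_sasa(self._counts(6), {7: 0.5})
        assert excluded == [7]
        assert 7 not in donor


class TestIonStatistics:
    def _ion_system(self, ion_distance):
        s = _structure(
            ["CA", "NA"], ["C", "NA"], ["ALA", "NA"], ["A", "I"], [0, 1],
            [[0.0, 0, 0], [ion_distance, 0, 0]],
        )
        frames = np.repeat(s.coords[None], 5, axis=0)
        return Trajectory(topology=s, frames=frames)

    def test_persistent_contact_is_hundred_percent(self):
        cat, an = ion_statistics(self._ion_system(3.0), [0])
        assert cat[0] == 100.0 and an[0] == 0.0

    def test_beyond_cutoff_is_zero(self):
        cat, _ = ion_statistics(self._ion_system(4.5), [0])
        assert cat[0] == 0.0

    def test_empty_ion_groups_yield_zero(self):
        s = _structure(["CA"], ["C"], ["ALA"], ["A"], [0], [[0.0, 0, 0]])
        traj = Trajectory(topology=s, frames=s.coords[None])
        cat, an = ion_statistics(traj, [0])
        assert cat[0] == 0.0 and an[0] == 0.0


def test_statistics_invariant_under_frame_reordering(recovery_fixture):
    _, traj, gt = recovery_fixture
    atoms = [r["site_atom_index"] for r in gt["planted"]
             if r["kind"] in ("donor", "acceptor")]
    perm = np.random.default_rng(0).permutation(traj.n_frames)
    shuffled = Trajectory(topology=traj.topology, frames=traj.frames[perm])
    a = hbond_statistics(traj, atoms).occupancy_pct()
    b = hbond_statistics(shuffled, atoms).occupancy_pct()
    assert a == b
    ca, an_a = ion_statistics(traj, atoms)
    cb, an_b = ion_statistics(shuffled, atoms)
    assert ca == cb and an_a == an_b


class TestRepresentativeFrame:
    def _traj(self, frame_list):
        n = frame_list[0].shape[0]
        s = _structure(
            ["CA"] * n, ["C"] * n, ["ALA"] * n, ["A"] * n, list(range(n)),
            frame_list[0],
        )
        return Trajectory(topology=s, frames=np.array(frame_list))

    def test_identical_frames_tie_break_to_first(self):
        base = np.random.default_rng(0).normal(size=(5, 3))
        traj = self._traj([base] * 6)
        assert representative_frame(traj, range(5)) == 0

    def test_dominant_cluster_center_found(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(6, 3)) * 3
        tight = [base + rng.normal(scale=0.05, size=base.shape) for _ in range(10)]
        # genuinely deformed conformations (not mere rigid motions)
        outliers = [base * 1.8, base[::-1] * 0.5]
        frames = tight + outliers
        rep = representative_frame(self._traj(frames), range(6), rmsd_cutoff=1.0)
        assert rep < 10

    def test_infinite_cutoff_minimizes_total_rmsd(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(5, 3)) * 2
        frames = [base + rng.normal(scale=s, size=base.shape)
                  for s in (0.3, 0.05, 0.4, 0.2)]
        traj = self._traj(frames)
        rep = representative_frame(traj, range(5), rmsd_cutoff=1e9)
        # single cluster: the centre minimizes the total pairwise RMSD
        totals = [
            sum(kabsch_superpose(g, f)[2] for g in frames) for f in frames
        ]
        assert rep == int(np.argmin(totals))

    def test_equals_bruteforce_neighbor_counting(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(6, 3)) * 3
        frames = [base + rng.normal(scale=s, size=base.shape)
                  for s in rng.uniform(0.05, 1.5, size=18)]
        traj = self._traj(frames)
        cutoff = 0.8
        got = representative_frame(traj, range(6), rmsd_cutoff=cutoff)
        n = len(frames)
        counts = np.zeros(n, dtype=int)
        totals = np.zeros(n)
        for i in range(n):
            for j in range(n):
                r = kabsch_superpose(frames[j], frames[i])[2]
                counts[i] += r <= cutoff
                totals[i] += r
        best = min(range(n), key=lambda i: (-counts[i], totals[i], i))
        assert got == best


class TestNoPriorPocket:
    def test_single_partner_pocket_scores_zero(self):
        assert harmonic_mean(500.0, 0.0) == 0.0

    def test_balanced_burial_beats_lopsided(self):
        assert harmonic_mean(100.0, 100.0) > harmonic_mean(300.0, 10.0)
        assert harmonic_mean(300.0, 10.0) == pytest.approx(2 * 3000 / 310)

    def test_planted_interface_pocket_recovered(self, tmp_path, recovery_fixture):
        from mdpharm.synthetic_fixtures import write_fpocket_outputs

        spec, traj, gt = recovery_fixture
        write_fpocket_outputs(spec, str(tmp_path), frames=(0, 3))
        pockets = {
            f: parse_fpocket_pockets(str(tmp_path / f"frame_{f}"))
            for f in (0, 3)
        }
        pocket, detail = select_pocket_no_prior(
            traj, pockets, n_sphere_points=240
        )
        assert detail["winner"]["pocket"] == 2
        assert pocket.residue_indices == gt["pocket_residue_indices"]
        decoy_scores = [
            c["hm"] for c in detail["candidates"] if c["pocket"] == 1
        ]
        assert all(h == 0.0 for h in decoy_scores)

    def test_no_pockets_errors(self, tmp_path, recovery_fixture):
        _, traj, _ = recovery_fixture
        with pytest.raises(ValueError):
            select_pocket_no_prior(traj, {})
        with pytest.raises(ValueError):
            parse_fpocket_pockets(str(tmp_path))
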