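"""Feature thresholding, 3-D placement rules, master graph and JSON export."""

import json
import os

import numpy as np
import pytest

from mdpharm.interface_analysis import PocketDefinition, SiteStatistics
from mdpharm.pharmacophore_model import (
    Feature,
    PharmacophoreModel,
    SiteCandidate,
    Thresholds,
    assign_positions,
    build_master,
    model_from_json,
    threshold_sites,
    to_screening_json,
)
from mdpharm.structure_io import Structure
from mdpharm.surface import SolvationProfile

GOLDEN = os.path.join(os.path.dirname(__file__), "data", "golden_model.json")


def _structure(names, elements, resnames, chains, residx, coords):
    return Structure(
        atom_name=np.array(names),
        element=np.array(elements),
        residue_index=np.array(residx, dtype=int),
        residue_name=np.array(resnames),
        chain_id=np.array(chains),
        coords=np.array(coords, dtype=float),
    )


def _pocket(residues, center=(0.0, 0.0, 0.0)):
    return PocketDefinition(
        residue_indices=list(residues), source="manual",
        pocket_center=np.array(center),
    )


class TestThresholdSites:
    def test_aromatic_residue_reclassified(self):
        s = _structure(
            ["CA", "CA"], ["C", "C"], ["TRP", "LEU"], ["A", "B"], [0, 1],
            [[0, 0, 0], [5, 0, 0]],
        )
        stats = SiteStatistics(
            dgsol=SolvationProfile({0: 0.5, 1: 0.5}, {0: 0.0, 1: 0.0}, "t")
        )
        sites = threshold_sites(s, _pocket([0, 1]), stats)
        kinds = sorted(x.kind for x in sites)
        assert kinds == ["aromatic", "hydrophobic"]
        aro = next(x for x in sites if x.kind == "aromatic")
        assert aro.residue_name == "TRP"

    def test_no_residue_is_both_hydrophobic_and_aromatic(
        self, recovery_extraction
    ):
        s = recovery_extraction["traj"].topology
        sites = threshold_sites(
            s, recovery_extraction["pocket"], recovery_extraction["stats"]
        )
        hydro = {x.residue_index for x in sites if x.kind == "hydrophobic"}
        aro = {x.residue_index for x in sites if x.kind == "aromatic"}
        assert not hydro & aro

    def test_ion_difference_below_threshold_is_dropped(self):
        s = _structure(["OD1"], ["O"], ["ASP"], ["A"], [0], [[0, 0, 0]])
        stats = SiteStatistics(cation_pct={0: 40.0}, anion_pct={0: 20.0})
        assert threshold_sites(s, _pocket([0]), stats) == []
        stats2 = SiteStatistics(cation_pct={0: 50.0}, anion_pct={0: 20.0})
        sites = threshold_sites(s, _pocket([0]), stats2)
        assert [x.kind for x in sites] == ["positive"]
        assert sites[0].raw_score == pytest.approx(30.0)

    def test_donor_acceptor_per_atom_thresholds(self):
        s = _structure(
            ["N", "O"], ["N", "O"], ["SER", "SER"], ["A", "A"], [0, 0],
            [[0, 0, 0], [2, 0, 0]],
        )
        stats = SiteStatistics(
            donor_normed_freq={0: 31.0, 1: 29.0},
            acceptor_normed_freq={0: 10.0, 1: 35.0},
        )
        sites = threshold_sites(s, _pocket([0]), stats)
        assert {(x.kind, x.atom_index) for x in sites} == {
            ("donor", 0), ("acceptor", 1)
        }


class TestAssignPositions:
    def test_hydrophobic_com_translated_toward_center(self):
        s = _structure(["CB"], ["C"], ["LEU"], ["A"], [0], [[10.0, 0, 0]])
        feats = assign_positions(
            [SiteCandidate("hydrophobic", "A", 0, "LEU", 1.0)],
            s, np.zeros(3),
        )
        np.testing.assert_allclose(feats[0].position, [6.0, 0, 0], atol=1e-9)
        assert feats[0].directions == []

    def test_aromatic_normal_sign_chooses_pocket_side(self):
        # planar hexagon at z = 5, ring normal +-z, pocket centre at origin
        ring = [
            [np.cos(a), np.sin(a), 5.0]
            for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)
        ]
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        s = _structure(
            names, ["C"] * 6, ["PHE"] * 6, ["A"] * 6, [0] * 6, ring
        )
        feats = assign_positions(
            [SiteCandidate("aromatic", "A", 0, "PHE", 1.0)], s, np.zeros(3)
        )
        np.testing.assert_allclose(feats[0].position, [0, 0, 2.0], atol=1e-8)
        assert len(feats[0].directions) == 2
        np.testing.assert_allclose(
            feats[0].directions[0], -feats[0].directions[1], atol=1e-12
        )
        # the chosen side is strictly nearer the pocket centre
        alt = np.array([0, 0, 8.0])
        assert np.linalg.norm(feats[0].position) < np.linalg.norm(alt)

    def test_ring_plane_error_without_ring_atoms(self):
        s = _structure(["CB"], ["C"], ["PHE"], ["A"], [0], [[0, 0, 0]])
        with pytest.raises(ValueError, match="ring"):
            assign_positions(
                [SiteCandidate("aromatic", "A", 0, "PHE", 1.0)], s, np.zeros(3)
            )

    def _donor_frame(self, water_angle_deg, water_dist=3.5):
        """Protein O-H donor plus one water at a controlled angle."""
        oh = np.array([0.0, 0.0, 0.0])
        h = np.array([0.0, 0.97, 0.0])
        theta = np.radians(180.0 - water_angle_deg)
        d = np.array([np.sin(theta), np.cos(theta), 0.0])
        a = 1.0
        b = 2.0 * np.dot(h - oh, d)
        c = np.dot(h - oh, h - oh) - water_dist**2
        t = (-b + np.sqrt(b * b - 4 * a * c)) / 2
        wo = h + t * d
        s = _structure(
            ["OG", "HG", "O", "H1", "H2"],
            ["O", "H", "O", "H", "H"],
            ["SER", "SER", "HOH", "HOH", "HOH"],
            ["A", "A", "W", "W", "W"],
            [0, 0, 1, 1, 1],
            [oh, h, wo, wo + [0.7, 0.7, 0], wo + [-0.7, 0.7, 0]],
        )
        return s, wo

    def test_donor_takes_water_oxygen_position_and_direction(self):
        s, wo = self._donor_frame(160.0)
        feats = assign_positions(
            [SiteCandidate("donor", "A", 0, "SER", 50.0, atom_index=0)],
            s, np.array([0.0, 10.0, 0.0]),
        )
        np.testing.assert_allclose(feats[0].position, wo, atol=1e-9)
        expected_dir = wo / np.linalg.norm(wo)   # donor atom at the origin
        np.testing.assert_allclose(feats[0].directions[0], expected_dir, atol=1e-9)

    def test_angle_relaxation_down_to_110(self):
        s, wo = self._donor_frame(110.0)
        feats = assign_positions(
            [SiteCandidate("donor", "A", 0, "SER", 50.0, atom_index=0)],
            s, np.array([0.0, 10.0, 0.0]),
        )
        np.testing.assert_allclose(feats[0].position, wo, atol=1e-9)

    def test_hopeless_angle_falls_back_to_hydrophobic_rule(self):
        s, _ = self._donor_frame(60.0)
        center = np.array([0.0, 10.0, 0.0])
        feats = assign_positions(
            [SiteCandidate("donor", "A", 0, "SER", 50.0, atom_index=0)],
            s, center,
        )
        np.testing.assert_allclose(feats[0].position, [0.0, 4.0, 0.0], atol=1e-9)

    def test_electrostatic_takes_nearest_bound_ion(self):
        s = _structure(
            ["OD1", "NA", "NA"], ["O", "NA", "NA"], ["ASP", "NA", "NA"],
            ["A", "I", "I"], [0, 1, 2],
            [[0, 0, 0], [3.1, 0, 0], [4.4, 0, 0]],
        )
        feats = assign_positions(
            [SiteCandidate("positive", "A", 0, "ASP", 40.0, atom_index=0)],
            s, np.zeros(3),
        )
        np.testing.assert_allclose(feats[0].position, [3.1, 0, 0])


class TestMasterModel:
    def _features(self):
        return [
            Feature("donor", [0, 0, 0], [[0, 0, 1]], raw_score=50, partner="A"),
            Feature("hydrophobic", [3, 0, 0], raw_score=1.0, partner="A"),
            Feature("hydrophobic", [0, 4, 0], raw_score=0.5, partner="A"),
            Feature("acceptor", [0, 0, 5], [[1, 0, 0]], raw_score=40, partner="B"),
        ]

    def _frame(self, n_heavy=6):
        coords = np.column_stack(
            [np.arange(n_heavy) * 2.0, np.zeros(n_heavy), np.zeros(n_heavy)]
        )
        return _structure(
            ["CA"] * n_heavy, ["C"] * n_heavy, ["ALA"] * n_heavy,
            ["A"] * n_heavy, list(range(n_heavy)), coords,
        )

    def test_partner_counts_and_symmetry(self):
        master = build_master(self._features(), self._frame())
        assert (master.n_a, master.n_b) == (3, 1)
        assert master.symmetry_factor == pytest.approx(1 / 3)

    def test_edge_weights_are_distances(self):
        master = build_master(self._features(), self._frame())
        g = master.graph
        assert g.number_of_edges() == 6
        assert g.edges[0, 1]["distance"] == pytest.approx(3.0)
        assert g.edges[0, 3]["distance"] == pytest.approx(5.0)
        assert g.edges[1, 2]["distance"] == pytest.approx(5.0)

    def test_exclusion_sphere_per_heavy_atom(self):
        master = build_master(self._features(), self._frame(50))
        assert len(master.exclusion_centers) == 50

    def test_normalization_per_kind(self):
        master = build_master(self._features(), self._frame())
        by_kind = {}
        for f in master.features:
            by_kind.setdefault(f.kind, []).append(f.normalized_score)
        assert by_kind["donor"] == [1.0]
        assert sorted(by_kind["hydrophobic"]) == [0.5, 1.0]

    def test_empty_feature_list_rejected(self):
        with pytest.raises(ValueError):
            build_master([], self._frame())


class TestScreeningJson:
    def test_round_trip_identity(self, master_fixture):
        master = master_fixture["master"]
        doc = to_screening_json(master)
        back = model_from_json(doc)
        assert back.n_features == master.n_features
        for a, b in zip(master.features, back.features):
            assert a.kind == b.kind
            assert a.partner == b.partner
            np.testing.assert_allclose(a.position, b.position, atol=1e-3)
            for da, db in zip(a.directions, b.directions):
                np.testing.assert_allclose(da, db, atol=2e-3)
        assert len(back.exclusion_centers) == len(master.exclusion_centers)

    def test_point_counts_and_unit_vectors(self, master_fixture):
        master = master_fixture["master"]
        doc = json.loads(to_screening_json(master))
        points = doc["points"]
        enabled = [p for p in points if p["name"] != "ExclusionSphere"]
        assert len(enabled) == master.n_features
        assert all(p["enabled"] for p in points)
        n_excl = sum(1 for p in points if p["name"] == "ExclusionSphere")
        assert n_excl == len(master.exclusion_centers)
        for p in enabled:
            for v in p.get("vector", []):
                norm = np.linalg.norm([v["x"], v["y"], v["z"]])
                assert abs(norm - 1.0) <= 2e-3

    def test_directed_feature_counts(self, master_fixture):
        for f in master_fixture["master"].features:
            expected = {"donor": 1, "acceptor": 1, "aromatic": 2}.get(f.kind, 0)
            assert len(f.directions) == expected
            for d in f.directions:
                assert abs(np.linalg.norm(d) - 1.0) < 1e-6

    def test_golden_document_is_stable(self):
        feats = [
            Feature("donor", [1.0, 2.0, 3.0], [[0, 0, 1]],
                    raw_score=50.0, partner="A", residue_index=0, atom_index=5),
            Feature("aromatic", [4.0, 5.0, 6.0], [[0, 1, 0], [0, -1, 0]],
                    raw_score=0.5, partner="B", residue_index=1),
            Feature("hydrophobic", [7.0, 8.0, 9.0],
                    raw_score=0.4, partner="B", residue_index=2),
        ]
        frame = _structure(
            ["CA", "CA"], ["C", "C"], ["ALA", "ALA"], ["A", "B"], [0, 1],
            [[0.0, 0, 0], [10.0, 0, 0]],
        )
        doc = to_screening_json(build_master(feats, frame))
        with open(GOLDEN) as fh:
            assert json.loads(doc) == json.load(fh)
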