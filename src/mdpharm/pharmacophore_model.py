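"""Typed pharmacophore features, 3-D placement from a representative frame,
master-graph assembly, and screening-engine JSON export.

Feature kinds: donor, acceptor, hydrophobic, aromatic, positive, negative.
Aromatic and H-bond features carry unit-vector directions (two opposite ring
normals for aromatic, the donor-to-acceptor vector for H-bonds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .interface_analysis import PocketDefinition, SiteStatistics, pocket_heavy_atoms
from .structure_io import Structure

__all__ = [
    "FEATURE_KINDS",
    "Thresholds",
    "SiteCandidate",
    "Feature",
    "PharmacophoreModel",
    "threshold_sites",
    "assign_positions",
    "build_master",
    "to_screening_json",
    "model_from_json",
]

FEATURE_KINDS = ("donor", "acceptor", "hydrophobic", "aromatic", "positive", "negative")
AROMATIC_RESNAMES = ("PHE", "TYR", "TRP")

# Screening-engine (Pharmer-convention) type names.
KIND_TO_JSON = {
    "donor": "HydrogenDonor",
    "acceptor": "HydrogenAcceptor",
    "hydrophobic": "Hydrophobic",
    "aromatic": "Aromatic",
    "positive": "PositiveIon",
    "negative": "NegativeIon",
}
JSON_TO_KIND = {v: k for k, v in KIND_TO_JSON.items()}

DEFAULT_FEATURE_RADIUS = 1.0
DEFAULT_EXCLUSION_RADIUS = 1.0
HYDROPHOBIC_SHIFT = 4.0      # A toward pocket center
AROMATIC_SHIFT = 3.0         # A along the ring normal
WATER_PLACEMENT_CUTOFF = 4.0  # A
WATER_ANGLE_START = 150.0     # deg, relaxed in steps ...
WATER_ANGLE_STEP = 10.0
WATER_ANGLE_MIN = 100.0
ION_PLACEMENT_MIN = 2.0       # A, cutoff scan
ION_PLACEMENT_MAX = 5.0
ION_PLACEMENT_STEP = 0.5

RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}

_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


@dataclass
class Thresholds:
    """Site-selection cutoffs (Table-style semantics, all configurable)."""

    dgsol: float = 0.2           # kJ/mol, hydrophobic/aromatic
    hbond_donor: float = 30.0    # SASA-normed frequency
    hbond_acceptor: float = 30.0
    ion_pct: float = 25.0        # % cation/anion difference


@dataclass
class SiteCandidate:
    """A thresholded site before 3-D placement."""

    kind: str
    chain: str
    residue_index: int
    residue_name: str
    raw_score: float
    atom_index: int | None = None    # per-atom kinds only


@dataclass
class Feature:
    kind: str
    position: np.ndarray
    directions: list[np.ndarray] = field(default_factory=list)
    raw_score: float = 0.0
    normalized_score: float = 0.0
    partner: str = ""
    residue_index: int = -1
    atom_index: int | None = None
    radius: float = DEFAULT_FEATURE_RADIUS

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        self.position = np.asarray(self.position, dtype=float)
        self.directions = [
            np.asarray(d, dtype=float) / np.linalg.norm(d) for d in self.directions
        ]
        expected = {"donor": 1, "acceptor": 1, "aromatic": 2}.get(self.kind, 0)
        if len(self.directions) != expected:
            raise ValueError(
                f"{self.kind} feature needs {expected} direction(s), "
                f"got {len(self.directions)}"
            )


@dataclass
class PharmacophoreModel:
    """Feature graph with complete pairwise-distance edges plus exclusion
    spheres at every protein heavy atom."""

    features: list[Feature]
    exclusion_centers: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3))
    )
    exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS

    def __post_init__(self):
        self.exclusion_centers = np.asarray(
            self.exclusion_centers, dtype=float
        ).reshape(-1, 3)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_a(self) -> int:
        partners = sorted({f.partner for f in self.features})
        return sum(1 for f in self.features if partners and f.partner == partners[0])

    @property
    def n_b(self) -> int:
        return self.n_features - self.n_a

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, f in enumerate(self.features):
            g.add_node(i, feature=f)
        for i in range(self.n_features):
            for j in range(i + 1, self.n_features):
                g.add_edge(
                    i,
                    j,
                    distance=float(
                        np.linalg.norm(
                            self.features[i].position - self.features[j].position
                        )
                    ),
                )
        return g

    def partner_counts(self, subset=None) -> tuple[int, int]:
        feats = (
            self.features
            if subset is None
            else [self.features[i] for i in subset]
        )
        partners = sorted({f.partner for f in self.features})
        if len(partners) == 1:
            return len(feats), 0
        a = sum(1 for f in feats if f.partner == partners[0])
        return a, len(feats) - a

    @property
    def symmetry_factor(self) -> float:
        return symmetry_factor(*self.partner_counts())

    def positions(self, subset=None) -> np.ndarray:
        feats = (
            self.features
            if subset is None
            else [self.features[i] for i in subset]
        )
        return np.array([f.position for f in feats]).reshape(-1, 3)


def symmetry_factor(n_a: int, n_b: int) -> float:
    """min(N_A, N_B) / max(N_A, N_B); 0/0 -> 0."""
    hi = max(n_a, n_b)
    if hi == 0:
        return 0.0
    return min(n_a, n_b) / hi


def threshold_sites(
    structure: Structure,
    pocket: PocketDefinition,
    stats: SiteStatistics,
    thresholds: Thresholds | None = None,
) -> list[SiteCandidate]:
    """Apply kind-specific cutoffs to the site statistics.

    Hydrophobic: residue mean dGsol > threshold, reclassified aromatic for
    PHE/TYR/TRP.  Donor/acceptor: per-atom normed frequency > threshold.
    Electrostatic: |cation% - anion%| > threshold, signed by the dominant ion.
    """
    th = thresholds or Thresholds()
    sites: list[SiteCandidate] = []

    def res_meta(r):
        atoms = structure.residue_atoms(r)
        return str(structure.chain_id[atoms[0]]), str(structure.residue_name[atoms[0]])

    if stats.dgsol is not None:
        for r, dg in sorted(stats.dgsol.per_residue_dGsol_mean.items()):
            if dg > th.dgsol:
                chain, resname = res_meta(r)
                kind = "aromatic" if resname in AROMATIC_RESNAMES else "hydrophobic"
                sites.append(SiteCandidate(kind, chain, r, resname, float(dg)))

    def atom_meta(a):
        return (
            str(structure.chain_id[a]),
            int(structure.residue_index[a]),
            str(structure.residue_name[a]),
        )

    for a, v in sorted(stats.donor_normed_freq.items()):
        if v > th.hbond_donor:
            chain, r, resname = atom_meta(a)
            sites.append(SiteCandidate("donor", chain, r, resname, float(v), a))
    for a, v in sorted(stats.acceptor_normed_freq.items()):
        if v > th.hbond_acceptor:
            chain, r, resname = atom_meta(a)
            sites.append(SiteCandidate("acceptor", chain, r, resname, float(v), a))

    atoms = sorted(set(stats.cation_pct) | set(stats.anion_pct))
    for a in atoms:
        diff = stats.cation_pct.get(a, 0.0) - stats.anion_pct.get(a, 0.0)
        if abs(diff) > th.ion_pct:
            chain, r, resname = atom_meta(a)
            kind = "positive" if diff > 0 else "negative"
            sites.append(SiteCandidate(kind, chain, r, resname, abs(float(diff)), a))
    return sites


def _residue_center_of_mass(structure: Structure, residue_index: int) -> np.ndarray:
    atoms = structure.residue_atoms(residue_index)
    masses = np.array([_MASSES.get(e, 12.011) for e in structure.element[atoms]])
    return (structure.coords[atoms] * masses[:, None]).sum(axis=0) / masses.sum()


def _translate_toward(point: np.ndarray, target: np.ndarray, dist: float) -> np.ndarray:
    v = target - point
    n = np.linalg.norm(v)
    if n == 0:
        return point.copy()
    return point + (dist / n) * v


def _ring_plane(structure: Structure, residue_index: int) -> tuple[np.ndarray, np.ndarray]:
    atoms = structure.residue_atoms(residue_index)
    resname = str(structure.residue_name[atoms[0]])
    names = RING_ATOMS.get(resname)
    if names is None:
        raise ValueError(f"residue {resname} has no defined aromatic ring")
    ring = [a for a in atoms if structure.atom_name[a] in names]
    if len(ring) < 3:
        raise ValueError(
            f"cannot determine ring plane for residue {residue_index} ({resname})"
        )
    pts = structure.coords[ring]
    center = pts.mean(axis=0)
    # Normal = smallest principal component of the ring coordinates.
    _, _, vt = np.linalg.svd(pts - center)
    normal = vt[2] / np.linalg.norm(vt[2])
    return center, normal


def _fallback_position(
    source_point: np.ndarray, pocket_center: np.ndarray
) -> np.ndarray:
    """Hydrophobic-style placement applied to an arbitrary source point."""
    return _translate_toward(source_point, pocket_center, HYDROPHOBIC_SHIFT)


def _water_oxygen_for_site(
    structure: Structure,
    site_atom: int,
    as_donor: bool,
    d_cut: float = WATER_PLACEMENT_CUTOFF,
) -> int | None:
    """Water oxygen satisfying the placement H-bond criterion, relaxing the
    angle from 150 to 100 deg in 10 deg steps; nearest oxygen wins, ties by
    atom index."""
    from .interface_analysis import COVALENT_H_CUTOFF, _angle_deg

    water_o = np.flatnonzero(structure.is_water & (structure.element == "O"))
    if len(water_o) == 0:
        return None
    d = np.linalg.norm(structure.coords[water_o] - structure.coords[site_atom], axis=1)
    near = water_o[d <= d_cut]
    if len(near) == 0:
        return None

    h_idx = np.flatnonzero(structure.is_hydrogen)

    def site_hydrogens():
        dd = np.linalg.norm(
            structure.coords[h_idx] - structure.coords[site_atom], axis=1
        )
        return h_idx[dd <= COVALENT_H_CUTOFF]

    def water_hydrogens(o):
        res = structure.residue_index[o]
        return np.flatnonzero((structure.residue_index == res) & structure.is_hydrogen)

    angle = WATER_ANGLE_START
    while angle >= WATER_ANGLE_MIN - 1e-9:
        best = None
        for o in sorted(near, key=lambda o: (
            float(np.linalg.norm(structure.coords[o] - structure.coords[site_atom])),
            int(o),
        )):
            ok = False
            if as_donor:
                for h in site_hydrogens():
                    if _angle_deg(
                        structure.coords[site_atom],
                        structure.coords[h],
                        structure.coords[o],
                    ) >= angle:
                        ok = True
                        break
            else:
                for h in water_hydrogens(int(o)):
                    if _angle_deg(
                        structure.coords[o],
                        structure.coords[h],
                        structure.coords[site_atom],
                    ) >= angle:
                        ok = True
                        break
            if ok:
                best = int(o)
                break
        if best is not None:
            return best
        angle -= WATER_ANGLE_STEP
    return None


def _nearest_ion(
    structure: Structure, site_atom: int, positive: bool
) -> int | None:
    """Nearest bound ion, scanning the cutoff from 2.0 to 5.0 A."""
    from .structure_io import ANION_RESNAMES, CATION_RESNAMES

    names = CATION_RESNAMES if positive else ANION_RESNAMES
    ions = np.flatnonzero(np.isin(structure.residue_name, sorted(names)))
    if len(ions) == 0:
        return None
    d = np.linalg.norm(structure.coords[ions] - structure.coords[site_atom], axis=1)
    cutoff = ION_PLACEMENT_MIN
    while cutoff <= ION_PLACEMENT_MAX + 1e-9:
        inside = ions[d <= cutoff]
        if len(inside) > 0:
            di = d[d <= cutoff]
            order = np.lexsort((inside, di))
            return int(inside[order[0]])
        cutoff += ION_PLACEMENT_STEP
    return None


def assign_positions(
    sites: list[SiteCandidate],
    frame: Structure,
    pocket_center: np.ndarray,
    feature_radius: float = DEFAULT_FEATURE_RADIUS,
) -> list[Feature]:
    """Place thresholded sites in the representative frame (with solvent).

    Donor/acceptor: the bonded-water oxygen position, direction along the
    donor-to-acceptor axis.  Electrostatic: the bound-ion position, falling
    back to hydrophobic-style placement.  Hydrophobic: residue COM shifted
    4 A toward the pocket center.  Aromatic: ring center shifted 3 A along
    the normal that approaches the pocket center, directions = both normals.
    """
    pocket_center = np.asarray(pocket_center, dtype=float)
    features: list[Feature] = []
    for s in sites:
        if s.kind == "hydrophobic":
            com = _residue_center_of_mass(frame, s.residue_index)
            pos = _translate_toward(com, pocket_center, HYDROPHOBIC_SHIFT)
            dirs = []
        elif s.kind == "aromatic":
            center, normal = _ring_plane(frame, s.residue_index)
            cand = [center + AROMATIC_SHIFT * normal, center - AROMATIC_SHIFT * normal]
            dist = [np.linalg.norm(c - pocket_center) for c in cand]
            pos = cand[int(np.argmin(dist))]
            dirs = [normal, -normal]
        elif s.kind in ("donor", "acceptor"):
            o = _water_oxygen_for_site(frame, s.atom_index, as_donor=s.kind == "donor")
            if o is None:
                pos = _fallback_position(frame.coords[s.atom_index], pocket_center)
                dirs = [pocket_center - frame.coords[s.atom_index]]
                if np.linalg.norm(dirs[0]) == 0:
                    dirs = [np.array([0.0, 0.0, 1.0])]
            else:
                pos = frame.coords[o].copy()
                if s.kind == "donor":
                    # protein atom donates: donor -> acceptor(water O)
                    v = frame.coords[o] - frame.coords[s.atom_index]
                else:
                    # water donates: donor(water O) -> acceptor(protein atom)
                    v = frame.coords[s.atom_index] - frame.coords[o]
                dirs = [v]
        elif s.kind in ("positive", "negative"):
            ion = _nearest_ion(frame, s.atom_index, positive=s.kind == "positive")
            if ion is None:
                pos = _fallback_position(frame.coords[s.atom_index], pocket_center)
            else:
                pos = frame.coords[ion].copy()
            dirs = []
        else:  # pragma: no cover
            raise ValueError(f"unknown site kind {s.kind!r}")
        features.append(
            Feature(
                kind=s.kind,
                position=pos,
                directions=dirs,
                raw_score=s.raw_score,
                partner=s.chain,
                residue_index=s.residue_index,
                atom_index=s.atom_index,
                radius=feature_radius,
            )
        )
    return features


def build_master(
    features: list[Feature],
    frame: Structure,
    exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS,
) -> PharmacophoreModel:
    """Assemble the master pharmacophore: all features plus an exclusion
    sphere at every protein heavy atom of the representative frame."""
    if len(features) == 0:
        raise ValueError("need at least one feature")
    heavy = np.flatnonzero(frame.is_protein & frame.heavy_mask)
    model = PharmacophoreModel(
        features=list(features),
        exclusion_centers=frame.coords[heavy].copy(),
        exclusion_radius=exclusion_radius,
    )
    _normalize_scores(model)
    return model


def _normalize_scores(model: PharmacophoreModel) -> None:
    """Per-kind normalization by the master's maximum raw score."""
    maxima: dict[str, float] = {}
    for f in model.features:
        maxima[f.kind] = max(maxima.get(f.kind, 0.0), f.raw_score)
    for i, f in enumerate(model.features):
        m = maxima[f.kind]
        ns = 1.0 if m == 0 else f.raw_score / m
        model.features[i] = replace(f, normalized_score=float(ns))


def _round3(x) -> float:
    return float(np.round(float(x), 3))


def to_screening_json(model: PharmacophoreModel, path: str | None = None) -> str:
    """Serialize to the screening engine's points document.

    One enabled point per feature with Pharmer-convention type names, 3-decimal
    coordinates, radii, and unit ``vector`` entries for directed features,
    followed by the exclusion spheres.  Key order is deterministic.
    """
    points = []
    for f in model.features:
        p = {
            "name": KIND_TO_JSON[f.kind],
            "x": _round3(f.position[0]),
            "y": _round3(f.position[1]),
            "z": _round3(f.position[2]),
            "radius": _round3(f.radius),
            "enabled": True,
            "partner": f.partner,
            "raw_score": _round3(f.raw_score),
            "normalized_score": _round3(f.normalized_score),
            "residue_index": int(f.residue_index),
        }
        if f.atom_index is not None:
            p["atom_index"] = int(f.atom_index)
        if f.directions:
            p["vector"] = [
                {"x": _round3(d[0]), "y": _round3(d[1]), "z": _round3(d[2])}
                for d in f.directions
            ]
            p["vector_on"] = 1
        points.append(p)
    for c in model.exclusion_centers:
        points.append(
            {
                "name": "ExclusionSphere",
                "x": _round3(c[0]),
                "y": _round3(c[1]),
                "z": _round3(c[2]),
                "radius": _round3(model.exclusion_radius),
                "enabled": True,
            }
        )
    doc = json.dumps({"points": points}, indent=1, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(doc)
    return doc


def model_from_json(doc: str) -> PharmacophoreModel:
    """Inverse of :func:`to_screening_json` (positions to file precision)."""
    data = json.loads(doc)
    features = []
    exclusions = []
    excl_radius = DEFAULT_EXCLUSION_RADIUS
    for p in data["points"]:
        if p["name"] == "ExclusionSphere":
            exclusions.append([p["x"], p["y"], p["z"]])
            excl_radius = p["radius"]
            continue
        dirs = [
            np.array([v["x"], v["y"], v["z"]]) for v in p.get("vector", [])
        ]
        features.append(
            Feature(
                kind=JSON_TO_KIND[p["name"]],
                position=np.array([p["x"], p["y"], p["z"]]),
                directions=dirs,
                raw_score=p.get("raw_score", 0.0),
                normalized_score=p.get("normalized_score", 0.0),
                partner=p.get("partner", ""),
                residue_index=p.get("residue_index", -1),
                atom_index=p.get("atom_index"),
                radius=p["radius"],
            )
        )
    return PharmacophoreModel(
        features=features,
        exclusion_centers=np.array(exclusions).reshape(-1, 3),
        exclusion_radius=excl_radius,
    )
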