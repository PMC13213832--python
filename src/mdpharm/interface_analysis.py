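"""Interface pocket identification and trajectory interaction statistics.

Pocket residues are those within a cutoff of a reference (ligand atoms or
pocket probes).  Over the trajectory we collect, per pocket atom, water
hydrogen-bond donor/acceptor events and ion contacts, and per residue the
solvation free energy; a representative frame is picked by GROMOS-style
RMSD clustering of the pocket residues.
"""

from __future__ import annotations

import glob
import os
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (
    ANION_RESNAMES,
    CATION_RESNAMES,
    Structure,
    Trajectory,
    kabsch_superpose,
)
from .surface import (
    DEFAULT_N_SPHERE_POINTS,
    DEFAULT_PROBE_RADIUS,
    SolvationProfile,
    harmonic_mean,
    shrake_rupley,
    buried_surface_areas,
)

__all__ = [
    "PocketDefinition",
    "SiteStatistics",
    "HBondCounts",
    "pocket_from_reference",
    "pocket_heavy_atoms",
    "hbond_statistics",
    "mean_atom_sasa",
    "normalize_by_sasa",
    "ion_statistics",
    "representative_frame",
    "PocketProbes",
    "parse_fpocket_pockets",
    "select_pocket_no_prior",
    "extract_site_statistics",
]

HBOND_DISTANCE_CUTOFF = 3.0     # A, donor-heavy to acceptor oxygen
HBOND_ANGLE_CUTOFF = 150.0      # deg, at the hydrogen
ION_CONTACT_CUTOFF = 4.0        # A
POCKET_CUTOFF = 5.0             # A
COVALENT_H_CUTOFF = 1.25        # A, X-H bond inference
SASA_FLOOR_NM2 = 0.01           # nm^2; atoms less exposed are excluded


@dataclass
class PocketDefinition:
    residue_indices: list[int]
    source: str                       # {ligand, fpocket, manual}
    pocket_center: np.ndarray         # A
    frame_index: int = 0

    def __post_init__(self):
        if len(self.residue_indices) == 0:
            raise ValueError("pocket must contain at least one residue")
        self.pocket_center = np.asarray(self.pocket_center, dtype=float)


@dataclass
class SiteStatistics:
    """Per-atom and per-residue interaction statistics for a pocket."""

    donor_normed_freq: dict[int, float] = field(default_factory=dict)
    acceptor_normed_freq: dict[int, float] = field(default_factory=dict)
    cation_pct: dict[int, float] = field(default_factory=dict)
    anion_pct: dict[int, float] = field(default_factory=dict)
    dgsol: SolvationProfile | None = None
    excluded_atoms: list[int] = field(default_factory=list)
    donor_occupancy_pct: dict[int, float] = field(default_factory=dict)
    acceptor_occupancy_pct: dict[int, float] = field(default_factory=dict)


def pocket_from_reference(
    structure: Structure,
    reference_coords: np.ndarray,
    cutoff: float = POCKET_CUTOFF,
    frame_index: int = 0,
    source: str = "ligand",
) -> PocketDefinition:
    """Pocket = residues with any heavy atom within ``cutoff`` of the
    reference atoms; center = geometric center of pocket heavy atoms."""
    reference_coords = np.atleast_2d(np.asarray(reference_coords, dtype=float))
    if reference_coords.size == 0:
        raise ValueError("reference atom set is empty")
    heavy = np.flatnonzero(structure.heavy_mask & structure.is_protein)
    tree = cKDTree(reference_coords)
    d, _ = tree.query(structure.coords[heavy], k=1)
    hit = heavy[d <= cutoff]
    residues = sorted(set(structure.residue_index[hit].tolist()))
    if not residues:
        raise ValueError(
            f"no residues within {cutoff} A of the reference; try a larger cutoff"
        )
    pocket_atoms = np.flatnonzero(
        np.isin(structure.residue_index, residues) & structure.heavy_mask
    )
    center = structure.coords[pocket_atoms].mean(axis=0)
    chains = set(structure.chain_id[pocket_atoms])
    if len(chains) < 2:
        warnings.warn(
            "pocket residues come from a single chain; interface analyses "
            "expect both partners",
            stacklevel=2,
        )
    return PocketDefinition(
        residue_indices=[int(r) for r in residues],
        source=source,
        pocket_center=center,
        frame_index=frame_index,
    )


def pocket_heavy_atoms(structure: Structure, pocket: PocketDefinition) -> np.ndarray:
    return np.flatnonzero(
        np.isin(structure.residue_index, pocket.residue_indices)
        & structure.heavy_mask
        & structure.is_protein
    )


@dataclass
class HBondCounts:
    """Raw per-atom, per-frame water H-bond event counts for pocket N/O atoms."""

    atom_indices: np.ndarray          # pocket N/O atoms analyzed
    donor_counts: np.ndarray          # (n_atoms, n_frames) int
    acceptor_counts: np.ndarray       # (n_atoms, n_frames) int

    def occupancy_pct(self) -> tuple[dict[int, float], dict[int, float]]:
        don = {
            int(a): 100.0 * float(np.mean(self.donor_counts[k] >= 1))
            for k, a in enumerate(self.atom_indices)
        }
        acc = {
            int(a): 100.0 * float(np.mean(self.acceptor_counts[k] >= 1))
            for k, a in enumerate(self.atom_indices)
        }
        return don, acc


def _bonded_hydrogens(structure: Structure, heavy_index: int) -> np.ndarray:
    """Hydrogens within the covalent-bond distance of a heavy atom (frame 0
    topology geometry)."""
    h_idx = np.flatnonzero(structure.is_hydrogen)
    if len(h_idx) == 0:
        return h_idx
    d = np.linalg.norm(
        structure.coords[h_idx] - structure.coords[heavy_index], axis=1
    )
    return h_idx[d <= COVALENT_H_CUTOFF]


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1 = a - vertex
    v2 = b - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def hbond_statistics(
    traj: Trajectory,
    pocket_atoms,
    d_cut: float = HBOND_DISTANCE_CUTOFF,
    angle_cut: float = HBOND_ANGLE_CUTOFF,
    stride: int = 1,
) -> HBondCounts:
    """Count water hydrogen bonds for the pocket N/O atoms, per frame.

    Donor event: pocket N/O with a covalent H, heavy-to-water-oxygen distance
    <= ``d_cut`` and donor-H...O angle (vertex at H) >= ``angle_cut``.
    Acceptor event: mirrored, with the water as donor.
    """
    topo = traj.topology
    pocket_atoms = np.asarray(pocket_atoms, dtype=int)
    no_mask = np.isin(topo.element[pocket_atoms], ["N", "O"])
    site_atoms = pocket_atoms[no_mask]

    water_o = np.flatnonzero(topo.is_water & (topo.element == "O"))
    if len(water_o) == 0:
        raise ValueError("no water present in the trajectory")
    # Map each water oxygen to its hydrogens via residue membership.
    water_h_by_o: dict[int, np.ndarray] = {}
    for o in water_o:
        res = topo.residue_index[o]
        members = np.flatnonzero(
            (topo.residue_index == res) & topo.is_hydrogen
        )
        water_h_by_o[int(o)] = members

    site_h = {int(a): _bonded_hydrogens(topo, int(a)) for a in site_atoms}

    frames = range(0, traj.n_frames, stride)
    n_f = len(list(frames))
    donor_counts = np.zeros((len(site_atoms), n_f), dtype=int)
    acceptor_counts = np.zeros((len(site_atoms), n_f), dtype=int)

    for fi, f in enumerate(range(0, traj.n_frames, stride)):
        X = traj.frames[f]
        tree = cKDTree(X[water_o])
        for k, a in enumerate(site_atoms):
            near = tree.query_ball_point(X[a], d_cut)
            for wj in near:
                o = int(water_o[wj])
                # pocket atom as donor
                for h in site_h[int(a)]:
                    if _angle_deg(X[a], X[h], X[o]) >= angle_cut:
                        donor_counts[k, fi] += 1
                        break
                # water as donor, pocket atom as acceptor
                for h in water_h_by_o[o]:
                    if _angle_deg(X[o], X[h], X[a]) >= angle_cut:
                        acceptor_counts[k, fi] += 1
                        break
    return HBondCounts(
        atom_indices=site_atoms,
        donor_counts=donor_counts,
        acceptor_counts=acceptor_counts,
    )


def mean_atom_sasa(
    traj: Trajectory,
    atoms,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
    stride: int = 1,
) -> dict[int, float]:
    """Time-averaged per-atom SASA (A^2) on solvent-stripped heavy atoms."""
    topo = traj.topology
    atoms = np.asarray(atoms, dtype=int)
    prot_idx = np.flatnonzero(topo.is_protein & topo.heavy_mask)
    sub = topo.subset(prot_idx)
    pos_of = {int(g): k for k, g in enumerate(prot_idx)}
    local = np.array([pos_of[int(a)] for a in atoms])
    sums = np.zeros(len(atoms))
    count = 0
    for f in range(0, traj.n_frames, stride):
        res = shrake_rupley(
            traj.frames[f][prot_idx],
            sub.vdw,
            probe_radius=probe_radius,
            n_sphere_points=n_sphere_points,
            subset=local,
        )
        sums += res.per_atom_area[local]
        count += 1
    return {int(a): float(s / count) for a, s in zip(atoms, sums)}


def normalize_by_sasa(
    counts: HBondCounts,
    mean_sasa_A2: dict[int, float],
    floor_nm2: float = SASA_FLOOR_NM2,
) -> tuple[dict[int, float], dict[int, float], list[int]]:
    """SASA-normed H-bond frequencies.

    normed(atom) = occupancy% / mean SASA in nm^2.  Atoms whose mean SASA is
    below ``floor_nm2`` are excluded and listed (their exposure is too small
    for the normalization to be meaningful).
    """
    don_occ, acc_occ = counts.occupancy_pct()
    donor, acceptor, excluded = {}, {}, []
    for a in counts.atom_indices:
        a = int(a)
        sasa_nm2 = mean_sasa_A2[a] / 100.0
        if sasa_nm2 < floor_nm2:
            excluded.append(a)
            continue
        donor[a] = don_occ[a] / sasa_nm2
        acceptor[a] = acc_occ[a] / sasa_nm2
    return donor, acceptor, excluded


def ion_statistics(
    traj: Trajectory,
    pocket_atoms,
    cation_indices=None,
    anion_indices=None,
    cutoff: float = ION_CONTACT_CUTOFF,
    stride: int = 1,
) -> tuple[dict[int, float], dict[int, float]]:
    """Percentage of frames with >= 1 cation (resp. anion) within ``cutoff``
    of each pocket atom.  Empty ion groups yield 0%."""
    topo = traj.topology
    pocket_atoms = np.asarray(pocket_atoms, dtype=int)
    if cation_indices is None:
        cation_indices = np.flatnonzero(
            np.isin(topo.residue_name, sorted(CATION_RESNAMES))
        )
    if anion_indices is None:
        anion_indices = np.flatnonzero(
            np.isin(topo.residue_name, sorted(ANION_RESNAMES))
        )
    frames = list(range(0, traj.n_frames, stride))
    result = []
    for ions in (np.asarray(cation_indices, int), np.asarray(anion_indices, int)):
        hits = np.zeros((len(pocket_atoms), len(frames)), dtype=bool)
        if len(ions) > 0:
            for fi, f in enumerate(frames):
                X = traj.frames[f]
                tree = cKDTree(X[ions])
                d, _ = tree.query(X[pocket_atoms], k=1)
                hits[:, fi] = d <= cutoff
        pct = {
            int(a): 100.0 * float(np.mean(hits[k]))
            for k, a in enumerate(pocket_atoms)
        }
        result.append(pct)
    return result[0], result[1]


def representative_frame(
    traj: Trajectory,
    pocket_residues,
    rmsd_cutoff: float = 1.5,
    stride: int = 1,
) -> int:
    """GROMOS-style clustering on pocket-residue heavy-atom RMSD.

    Iteratively take the frame with the most neighbours within the cutoff
    (after pairwise superposition) as a cluster centre, remove the cluster,
    and return the centre of the first (largest) cluster.  Neighbour-count
    ties break to the frame with the smallest total RMSD, then to the lowest
    frame index.
    """
    topo = traj.topology
    atoms = np.flatnonzero(
        np.isin(topo.residue_index, list(pocket_residues))
        & topo.heavy_mask
        & topo.is_protein
    )
    frames = list(range(0, traj.n_frames, stride))
    n = len(frames)
    if n == 1:
        return frames[0]
    coords = [traj.frames[f][atoms] for f in frames]
    rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = kabsch_superpose(coords[j], coords[i])[2]
            rmsd[i, j] = rmsd[j, i] = r
    within = rmsd <= rmsd_cutoff
    counts = within.sum(axis=1)
    total = rmsd.sum(axis=1)
    order = sorted(range(n), key=lambda i: (-counts[i], total[i], i))
    return frames[order[0]]


def extract_site_statistics(
    traj: Trajectory,
    pocket: PocketDefinition,
    d_cut: float = HBOND_DISTANCE_CUTOFF,
    angle_cut: float = HBOND_ANGLE_CUTOFF,
    ion_cutoff: float = ION_CONTACT_CUTOFF,
    sasa_floor_nm2: float = SASA_FLOOR_NM2,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
    stride: int = 1,
) -> tuple[SiteStatistics, dict]:
    """Full per-site statistics pass for one pocket.

    Returns the populated SiteStatistics plus an extras dict with the raw
    counts and time-averaged atom SASA (same stride throughout).
    """
    from .surface import residue_solvation_energy

    topo = traj.topology
    atoms = pocket_heavy_atoms(topo, pocket)
    counts = hbond_statistics(traj, atoms, d_cut=d_cut, angle_cut=angle_cut, stride=stride)
    sasa = mean_atom_sasa(
        traj, counts.atom_indices, probe_radius=probe_radius,
        n_sphere_points=n_sphere_points, stride=stride,
    )
    donor, acceptor, excluded = normalize_by_sasa(counts, sasa, floor_nm2=sasa_floor_nm2)
    cation, anion = ion_statistics(traj, atoms, cutoff=ion_cutoff, stride=stride)
    dgsol = residue_solvation_energy(
        traj, pocket.residue_indices, probe_radius=probe_radius,
        n_sphere_points=n_sphere_points, stride=stride,
    )
    don_occ, acc_occ = counts.occupancy_pct()
    stats = SiteStatistics(
        donor_normed_freq=donor,
        acceptor_normed_freq=acceptor,
        cation_pct=cation,
        anion_pct=anion,
        dgsol=dgsol,
        excluded_atoms=excluded,
        donor_occupancy_pct=don_occ,
        acceptor_occupancy_pct=acc_occ,
    )
    return stats, {"counts": counts, "mean_sasa_A2": sasa, "pocket_atoms": atoms}


# ---------------------------------------------------------------------------
# Fpocket outputs and pocket selection without prior knowledge


@dataclass
class PocketProbes:
    """Probe spheres of one detected pocket (a pseudo-ligand)."""

    pocket_id: int
    coords: np.ndarray           # (n, 3) A
    radii: np.ndarray            # (n,) A


_VERT_RE = re.compile(r"pocket(\d+)_vert\.pqr$")
_ATM_RE = re.compile(r"pocket(\d+)_atm\.pdb$")


def _parse_pqr_spheres(path: str) -> tuple[np.ndarray, np.ndarray]:
    coords, radii = [], []
    with open(path) as fh:
        for line in fh:
            if not line.startswith(("ATOM", "HETATM")):
                continue
            parts = line.split()
            # PQR: ... x y z charge radius
            try:
                x, y, z = (float(v) for v in parts[-5:-2])
                r = float(parts[-1])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"malformed PQR line in {path!r}: {line!r}") from exc
            coords.append((x, y, z))
            radii.append(r)
    return np.asarray(coords, dtype=float), np.asarray(radii, dtype=float)


def parse_fpocket_pockets(out_dir: str, default_radius: float = 1.8) -> list[PocketProbes]:
    """Parse per-pocket probe spheres from an fpocket output directory.

    Accepts ``pocket<k>_vert.pqr`` (preferred: has radii) or
    ``pocket<k>_atm.pdb`` files, either directly in ``out_dir`` or under a
    ``pockets/`` subdirectory; tolerant to header variations.
    """
    roots = [out_dir, os.path.join(out_dir, "pockets")]
    found: dict[int, PocketProbes] = {}
    for root in roots:
        if not os.path.isdir(root):
            continue
        for path in sorted(glob.glob(os.path.join(root, "pocket*_vert.pqr"))):
            pid = int(_VERT_RE.search(os.path.basename(path)).group(1))
            coords, radii = _parse_pqr_spheres(path)
            if len(coords):
                found[pid] = PocketProbes(pid, coords, radii)
        for path in sorted(glob.glob(os.path.join(root, "pocket*_atm.pdb"))):
            pid = int(_ATM_RE.search(os.path.basename(path)).group(1))
            if pid in found:
                continue
            from .structure_io import read_structure

            s = read_structure(path, format="pdb")
            found[pid] = PocketProbes(
                pid, s.coords, np.full(s.n_atoms, default_radius)
            )
    if not found:
        raise ValueError(f"no fpocket pocket files parsed under {out_dir!r}")
    return [found[k] for k in sorted(found)]


def select_pocket_no_prior(
    traj: Trajectory,
    pockets_per_frame: dict[int, list[PocketProbes]],
    cutoff: float = POCKET_CUTOFF,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
) -> tuple[PocketDefinition, dict]:
    """Pick the (frame, pocket) maximizing HM(BSA_AL, BSA_BL) with the pocket
    probes treated as a pseudo-ligand; pocket residues are those within
    ``cutoff`` of the winning probes."""
    topo = traj.topology
    chains = sorted(set(topo.chain_id[topo.is_protein]))
    if len(chains) < 2:
        raise ValueError("need at least two protein chains")
    a_idx = np.flatnonzero(
        (topo.chain_id == chains[0]) & topo.is_protein & topo.heavy_mask
    )
    b_idx = np.flatnonzero(
        (topo.chain_id == chains[1]) & topo.is_protein & topo.heavy_mask
    )
    best = None
    scores = []
    for f, pockets in sorted(pockets_per_frame.items()):
        if not pockets:
            continue
        frame_struct = topo.with_coords(traj.frames[f])
        for p in pockets:
            bsa_al, bsa_bl = buried_surface_areas(
                frame_struct,
                a_idx,
                b_idx,
                None,
                ligand_coords=p.coords,
                ligand_radii=p.radii,
                probe_radius=probe_radius,
                n_sphere_points=n_sphere_points,
            )
            hm = harmonic_mean(bsa_al, bsa_bl)
            scores.append(
                {"frame": f, "pocket": p.pocket_id, "bsa_al": bsa_al,
                 "bsa_bl": bsa_bl, "hm": hm}
            )
            if best is None or hm > best[0]:
                best = (hm, f, p)
    if best is None:
        raise ValueError("no pockets parsed for any frame")
    _, f, p = best
    frame_struct = topo.with_coords(traj.frames[f])
    pocket = pocket_from_reference(
        frame_struct, p.coords, cutoff=cutoff, frame_index=f, source="fpocket"
    )
    return pocket, {"candidates": scores, "winner": {"frame": f, "pocket": p.pocket_id}}
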