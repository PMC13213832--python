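"""Self-contained toy systems for end-to-end testing: two-chain complexes
with an interface cleft, explicit waters/ions with planted interaction
occupancies, and ligand libraries with planted matches.

Chains are built from idealized residue templates (not real structures): two
rows of residues facing each other across a cleft, side chains pointing
inward.  Polar roles use carboxylate/ammonium-bearing templates so planted
hydrophobic/aromatic residues are the only ones with positive solvation free
energy under the built-in ASP table.  Every output is a deterministic
function of (spec, seed); a ground-truth sidecar records what was planted.

No physical realism is claimed; geometry is chosen so each planted
interaction satisfies its own cutoff while staying clear of every other
pocket atom's cutoff (asserted at build time).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .screening_filter import HitRecord, LigandFeatureSet, reference_match
from .structure_io import Structure, Trajectory, write_trajectory
from .pharmacophore_model import PharmacophoreModel

__all__ = [
    "FixtureError",
    "PlannedSite",
    "FixtureSpec",
    "default_fixture_plan",
    "minimal_fixture_plan",
    "composition_17_site_plan",
    "make_complex_trajectory",
    "make_ligand_library",
    "write_ligand_sdf",
    "read_ligand_sdf",
    "write_fpocket_outputs",
    "make_dual_binding_hits",
]


class FixtureError(RuntimeError):
    """The requested fixture cannot be built without overlapping placements."""


@dataclass
class PlannedSite:
    chain: str                  # "A" | "B"
    kind: str                   # feature kind or "scaffold"
    occupancy: float = 0.0      # fraction of frames bonded (H-bond/ion kinds)

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")


@dataclass
class FixtureSpec:
    pocket_plan: list[PlannedSite]
    residues_per_chain: int = 20
    n_frames: int = 50
    noise_amplitude: float = 0.05    # A, Gaussian per coordinate
    seed: int = 0
    spacing: float = 4.5             # A between residues along the cleft
    half_width: float = 7.5          # A, backbone row distance from cleft axis
    stagger: float = 2.25            # A, chain B offset along the cleft
    n_bulk_waters: int = 10
    n_bulk_ions: int = 2             # per species


def default_fixture_plan(occupancy: float = 0.8) -> list[PlannedSite]:
    """All five planted site classes on both chains (recovery fixture)."""
    plan = []
    for chain in ("A", "B"):
        plan += [
            PlannedSite(chain, "donor", occupancy),
            PlannedSite(chain, "donor", occupancy),
            PlannedSite(chain, "acceptor", occupancy),
            PlannedSite(chain, "hydrophobic"),
            PlannedSite(chain, "hydrophobic"),
            PlannedSite(chain, "aromatic"),
            PlannedSite(chain, "negative", occupancy),
            PlannedSite(chain, "positive", occupancy),
        ]
    return plan


def minimal_fixture_plan(occupancy: float = 1.0) -> list[PlannedSite]:
    """Compact 8-feature plan (one donor/acceptor/hydrophobic/aromatic per
    chain) for fast end-to-end runs."""
    plan = []
    for chain in ("A", "B"):
        plan += [
            PlannedSite(chain, "donor", occupancy),
            PlannedSite(chain, "acceptor", occupancy),
            PlannedSite(chain, "hydrophobic"),
            PlannedSite(chain, "aromatic"),
        ]
    return plan


def composition_17_site_plan(occupancy: float = 1.0) -> list[PlannedSite]:
    """6 donors + 2 acceptors + 6 hydrophobic + 3 aromatic = 17 sites,
    mirroring a bromodomain-dimer-like feature composition."""
    plan = []
    for chain, n_aro in (("A", 2), ("B", 1)):
        plan += [PlannedSite(chain, "donor", occupancy) for _ in range(3)]
        plan += [PlannedSite(chain, "acceptor", occupancy)]
        plan += [PlannedSite(chain, "hydrophobic") for _ in range(3)]
        plan += [PlannedSite(chain, "aromatic") for _ in range(n_aro)]
    return plan


# --------------------------------------------------------------------------
# Residue templates: local frame with the backbone row at y ~ +1.4 and the
# side chain extending toward -y (the cleft).  (name, element, xyz).

_BACKBONE = [
    ("N", "N", (-1.35, 1.40, 0.00)),
    ("H", "H", (-1.35, 2.38, 0.00)),
    ("CA", "C", (0.00, 1.40, 0.00)),
    ("C", "C", (1.30, 1.40, 0.45)),
    ("O", "O", (1.60, 2.55, 0.60)),
]

_TEMPLATES = {
    # role: (residue_name, sidechain atoms, site atom name or None)
    "donor": (
        "ASP",
        [
            ("CB", "C", (0.00, 0.00, 0.40)),
            ("CG", "C", (0.00, -1.50, 0.40)),
            ("OD1", "O", (1.05, -2.10, 0.40)),
            ("OD2", "O", (-1.05, -2.10, 0.40)),
            ("HD2", "H", (-1.05, -3.07, 0.40)),
        ],
        "OD2",
    ),
    "acceptor": (
        "ASP",
        [
            ("CB", "C", (0.00, 0.00, 0.40)),
            ("CG", "C", (0.00, -1.50, 0.40)),
            ("OD1", "O", (1.05, -2.10, 0.40)),
            ("OD2", "O", (-1.05, -2.10, 0.40)),
        ],
        "OD1",
    ),
    "hydrophobic": (
        "LEU",
        [
            ("CB", "C", (0.00, 0.00, 0.40)),
            ("CG", "C", (0.00, -1.50, 0.40)),
            ("CD1", "C", (1.10, -2.40, 0.70)),
            ("CD2", "C", (-1.10, -2.40, 0.70)),
        ],
        None,
    ),
    "aromatic": (
        "PHE",
        [
            ("CB", "C", (0.00, 0.00, 0.40)),
            ("CG", "C", (0.00, -1.50, 0.40)),
            ("CD1", "C", (1.21, -2.20, 0.40)),
            ("CD2", "C", (-1.21, -2.20, 0.40)),
            ("CE1", "C", (1.21, -3.60, 0.40)),
            ("CE2", "C", (-1.21, -3.60, 0.40)),
            ("CZ", "C", (0.00, -4.30, 0.40)),
        ],
        None,
    ),
    "positive": (
        "GLU",
        [
            ("CB", "C", (0.00, 0.00, 0.40)),
            ("CG", "C", (0.00, -1.50, 0.40)),
            ("CD", "C", (0.00, -3.00, 0.40)),
            ("OE1", "O", (1.05, -3.60, 0.40)),
            ("OE2", "O", (-1.05, -3.60, 0.40)),
        ],
        "OE1",
    ),
    "negative": (
        "LYS",
        [
            ("CB", "C", (0.00, 0.00, 0.40)),
            ("CG", "C", (0.00, -1.30, 0.40)),
            ("CD", "C", (0.00, -2.60, 0.40)),
            ("CE", "C", (0.00, -3.90, 0.40)),
            ("NZ", "N", (0.00, -5.00, 0.90)),
            ("HZ1", "H", (0.62, -5.72, 1.21)),
        ],
        "NZ",
    ),
    "scaffold": (
        "GLU",
        [
            ("CB", "C", (0.00, 0.00, 0.40)),
            ("CG", "C", (0.00, -1.50, 0.40)),
            ("CD", "C", (0.00, -3.00, 0.40)),
            ("OE1", "O", (1.05, -3.60, 0.40)),
            ("OE2", "O", (-1.05, -3.60, 0.40)),
        ],
        None,
    ),
}

# Local-frame companion placements relative to the site atom.
_WATER_DONOR = {          # water accepting from the site O-H
    "O": (0.00, -2.80, 0.00),
    "H1": (0.76, -3.39, 0.00),
    "H2": (-0.76, -3.39, 0.00),
}
_WATER_ACCEPTOR = {       # water donating to the site O
    "O": (0.00, -2.80, 0.00),
    "H1": (0.00, -1.82, 0.00),
    "H2": (0.93, -3.11, 0.00),
}
# Ion offsets chosen along the terminal-bond direction so that only the site
# atom is within the 4 A contact cutoff.
_CATION_OFFSET = (2.864, -1.637, 0.00)     # from GLU OE1
_ANION_OFFSET = (0.00, -3.007, 1.366)      # from LYS NZ


def _chain_transform(chain: str, slot: int, spec: FixtureSpec):
    if chain == "A":
        def tf(p):
            return np.array([p[0] + spec.spacing * slot, p[1] + spec.half_width, p[2]])
    else:
        def tf(p):
            return np.array(
                [
                    p[0] + spec.spacing * slot + spec.stagger,
                    -p[1] - spec.half_width,
                    -p[2],
                ]
            )
    return tf


def _assign_slots(spec: FixtureSpec) -> dict[str, list[tuple[int, PlannedSite]]]:
    """Distribute planned sites over residue slots.

    Ion-role residues need lateral escape room: 'positive' goes to the right
    terminus (its cation extends past the chain end) and 'negative' residues
    are kept ≥2 slots apart; other roles fill remaining slots, padded with
    scaffold residues.
    """
    out: dict[str, list[tuple[int, PlannedSite]]] = {}
    for chain in ("A", "B"):
        sites = [s for s in spec.pocket_plan if s.chain == chain]
        n = spec.residues_per_chain
        if len(sites) > n:
            raise FixtureError(
                f"chain {chain}: {len(sites)} planned sites exceed "
                f"{n} residues"
            )
        positives = [s for s in sites if s.kind == "positive"]
        if len(positives) > 1:
            raise FixtureError("at most one 'positive' site per chain (terminal slot)")
        others = [s for s in sites if s.kind != "positive"]
        slots: list[tuple[int, PlannedSite]] = []
        if positives:
            slots.append((n - 1, positives[0]))
        free = [i for i in range(n) if not positives or i != n - 1]
        # spread the rest evenly over the remaining slots
        step = max(1, len(free) // max(1, len(others)))
        used = []
        idx = 0
        for s in others:
            while idx in used or idx >= len(free):
                idx = (idx + 1) % len(free)
            slots.append((free[idx], s))
            used.append(idx)
            idx += step
        taken = {sl for sl, _ in slots}
        for i in range(n):
            if i not in taken:
                slots.append((i, PlannedSite(chain, "scaffold")))
        out[chain] = sorted(slots, key=lambda t: t[0])
    return out


def make_complex_trajectory(
    spec: FixtureSpec, out_dir: str | None = None
) -> tuple[Trajectory, dict]:
    """Build the fixture complex trajectory and its ground-truth sidecar.

    Returns the in-memory Trajectory and the sidecar dict; with ``out_dir``
    also writes ``complex.pdb`` (multi-model) and ``ground_truth.json``.
    """
    rng = np.random.default_rng(spec.seed)
    slots = _assign_slots(spec)

    names, elements, resnames, chains, residx = [], [], [], [], []
    coords = []
    res_counter = 0
    site_records = []

    def add_atom(name, element, xyz, resname, chain, rix):
        names.append(name)
        elements.append(element)
        resnames.append(resname)
        chains.append(chain)
        residx.append(rix)
        coords.append(np.asarray(xyz, dtype=float))

    # --- protein chains
    for chain in ("A", "B"):
        for slot, site in slots[chain]:
            resname, sidechain, site_atom = _TEMPLATES[site.kind]
            tf = _chain_transform(chain, slot, spec)
            rix = res_counter
            res_counter += 1
            site_atom_index = None
            for name, el, xyz in _BACKBONE + sidechain:
                if name == site_atom:
                    site_atom_index = len(coords)
                add_atom(name, el, tf(xyz), resname, chain, rix)
            site_records.append(
                {
                    "chain": chain,
                    "slot": slot,
                    "kind": site.kind,
                    "occupancy": site.occupancy,
                    "residue_index": rix,
                    "residue_name": resname,
                    "site_atom_index": site_atom_index,
                    "transform": tf,
                    "site_local": None,
                }
            )

    n_protein_atoms = len(coords)

    # --- planted waters and ions
    def site_local_pos(kind):
        resname, sidechain, site_atom = _TEMPLATES[kind]
        return next(np.array(x) for n, e, x in sidechain if n == site_atom)

    mobile = []   # (atom indices, home coords, park coords, bonded frame set)
    park_slot = 0

    def park(z_row):
        nonlocal park_slot
        p = np.array([3.0 * park_slot, 0.0, z_row])
        park_slot += 1
        return p

    water_res = []
    for rec in site_records:
        if rec["kind"] in ("donor", "acceptor"):
            base = site_local_pos(rec["kind"])
            layout = _WATER_DONOR if rec["kind"] == "donor" else _WATER_ACCEPTOR
            tf = rec["transform"]
            rix = res_counter
            res_counter += 1
            idxs = []
            home = []
            park_base = park(16.0)
            park_pos = []
            for k, (name, off) in enumerate(layout.items()):
                el = "O" if name == "O" else "H"
                pos = tf(base + np.asarray(off))
                idxs.append(len(coords))
                add_atom(name, el, pos, "HOH", "W", rix)
                home.append(pos)
                park_pos.append(park_base + np.array([0.0, 0.8 * k, 0.0]))
            n_bonded = int(round(rec["occupancy"] * spec.n_frames))
            bonded = set(
                rng.choice(spec.n_frames, size=n_bonded, replace=False).tolist()
            )
            rec["bonded_frames"] = sorted(bonded)
            mobile.append((idxs, np.array(home), np.array(park_pos), bonded))
            water_res.append(rix)
        elif rec["kind"] in ("positive", "negative"):
            base = site_local_pos(rec["kind"])
            off = _CATION_OFFSET if rec["kind"] == "positive" else _ANION_OFFSET
            tf = rec["transform"]
            rix = res_counter
            res_counter += 1
            pos = tf(base + np.asarray(off))
            idx = len(coords)
            ion_name = "NA" if rec["kind"] == "positive" else "CL"
            add_atom(ion_name, ion_name, pos, ion_name, "I", rix)
            n_bonded = int(round(rec["occupancy"] * spec.n_frames))
            bonded = set(
                rng.choice(spec.n_frames, size=n_bonded, replace=False).tolist()
            )
            rec["bonded_frames"] = sorted(bonded)
            mobile.append(
                ([idx], pos[None, :], park(-16.0)[None, :], bonded)
            )

    # --- bulk solvent far above/below the cleft
    for w in range(spec.n_bulk_waters):
        rix = res_counter
        res_counter += 1
        base = np.array([3.0 * w, 4.0, 21.0])
        add_atom("O", "O", base, "HOH", "W", rix)
        add_atom("H1", "H", base + (0.76, 0.59, 0.0), "HOH", "W", rix)
        add_atom("H2", "H", base + (-0.76, 0.59, 0.0), "HOH", "W", rix)
    for i in range(spec.n_bulk_ions):
        for ion_name, z in (("NA", -21.0), ("CL", -24.0)):
            rix = res_counter
            res_counter += 1
            add_atom(ion_name, ion_name, np.array([4.0 * i, 2.0, z]), ion_name, "I", rix)

    base_coords = np.array(coords)
    topo = Structure(
        atom_name=np.array(names),
        element=np.array(elements),
        residue_index=np.array(residx),
        residue_name=np.array(resnames),
        chain_id=np.array(chains),
        coords=base_coords,
    )
    _validate_geometry(topo, n_protein_atoms, site_records)

    # --- frames
    frames = np.empty((spec.n_frames, len(base_coords), 3))
    for f in range(spec.n_frames):
        X = base_coords.copy()
        for idxs, home, park_pos, bonded in mobile:
            if f not in bonded:
                X[np.asarray(idxs)] = park_pos
        if spec.noise_amplitude > 0:
            X = X + rng.normal(0.0, spec.noise_amplitude, size=X.shape)
        frames[f] = X
    traj = Trajectory(topology=topo, frames=frames)

    # --- ground truth sidecar
    ref_x = np.arange(0.0, spec.spacing * (spec.residues_per_chain - 1) + 2.26, 1.5)
    reference = np.array(
        [[x, y, 0.0] for x in ref_x for y in (-1.5, 0.0, 1.5)]
    )
    expected: dict[str, list] = {k: [] for k in
                                 ("donor", "acceptor", "hydrophobic",
                                  "aromatic", "positive", "negative")}
    for rec in site_records:
        if rec["kind"] == "scaffold":
            continue
        if rec["kind"] in ("hydrophobic", "aromatic"):
            expected[rec["kind"]].append(rec["residue_index"])
        else:
            expected[rec["kind"]].append(rec["site_atom_index"])
    sidecar = {
        "seed": spec.seed,
        "n_frames": spec.n_frames,
        "noise_amplitude": spec.noise_amplitude,
        "n_protein_atoms": n_protein_atoms,
        "pocket_residue_indices": sorted(
            {r["residue_index"] for r in site_records}
        ),
        "reference_coords": reference.tolist(),
        "expected_sites": expected,
        "planted": [
            {
                k: v
                for k, v in rec.items()
                if k not in ("transform", "site_local")
            }
            for rec in site_records
            if rec["kind"] != "scaffold"
        ],
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_trajectory(traj, os.path.join(out_dir, "complex.pdb"))
        with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)
    return traj, sidecar


_ION_CLEARANCE = 4.3        # A, planted ion to any non-target pocket atom


def _validate_geometry(topo: Structure, n_protein_atoms: int, site_records) -> None:
    """Assert planted waters/ions satisfy exactly their own site's cutoff.

    H-bond placements are checked with the full distance+angle event rule
    (a water may sit near a foreign polar atom as long as its orientation
    cannot produce an event); ion placements use a distance margin.
    """
    from .interface_analysis import hbond_statistics

    prot_heavy = np.flatnonzero(
        (np.arange(topo.n_atoms) < n_protein_atoms) & topo.heavy_mask
    )
    targets_hb = {
        rec["site_atom_index"]: rec["kind"]
        for rec in site_records
        if rec["kind"] in ("donor", "acceptor")
    }
    single = Trajectory(topology=topo, frames=topo.coords[None])
    counts = hbond_statistics(single, prot_heavy)
    for k, a in enumerate(counts.atom_indices):
        want = targets_hb.get(int(a))
        got_d = counts.donor_counts[k, 0] > 0
        got_a = counts.acceptor_counts[k, 0] > 0
        if got_d != (want == "donor") or got_a != (want == "acceptor"):
            raise FixtureError(
                f"atom {int(a)} ({topo.atom_name[a]}): H-bond events "
                f"(donor={bool(got_d)}, acceptor={bool(got_a)}) do not match "
                f"the planted role {want!r}"
            )
    for rec in site_records:
        if rec["kind"] not in ("positive", "negative"):
            continue
        target = rec["site_atom_index"]
        ion = _find_companion(topo, rec, None)
        d_target = np.linalg.norm(topo.coords[ion] - topo.coords[target])
        if not d_target <= 4.0:
            raise FixtureError(f"planted ion too far from site: {d_target:.2f}")
        dists = np.linalg.norm(topo.coords[prot_heavy] - topo.coords[ion], axis=1)
        dists[prot_heavy == target] = np.inf
        if np.min(dists) < _ION_CLEARANCE:
            raise FixtureError(
                f"planted ion for {rec['kind']} at residue "
                f"{rec['residue_index']} is {np.min(dists):.2f} A from a "
                "non-target pocket atom"
            )


def _find_companion(topo: Structure, rec, atom_name):
    """Locate the planted water oxygen / ion for a site record (the solvent
    residue added immediately for that site, nearest to the site atom)."""
    target = rec["site_atom_index"]
    if atom_name == "O":
        cand = np.flatnonzero(topo.is_water & (topo.element == "O"))
    else:
        cand = np.flatnonzero(topo.is_ion)
    d = np.linalg.norm(topo.coords[cand] - topo.coords[target], axis=1)
    return int(cand[np.argmin(d)])


# --------------------------------------------------------------------------
# Ligand libraries


def make_ligand_library(
    model: PharmacophoreModel,
    n_true: int = 5,
    n_decoys: int = 5,
    seed: int = 0,
    jitter: float = 0.3,
    max_subset: int = 6,
    exclusion_clearance: float = 0.6,
) -> tuple[list[LigandFeatureSet], dict]:
    """Ligands whose features reproduce random >=3-feature subsets of the
    model under random rigid motions (+ jitter), plus guaranteed non-matching
    decoys (kind swapped to an absent kind, or distances distorted).

    Subsets are drawn from features whose positions clear the model's
    exclusion spheres by ``exclusion_clearance`` beyond the sphere radius —
    a feature buried against the protein surface cannot host a ligand atom,
    so no library ligand could ever occupy it.  The sidecar records each
    ligand's source subset and whether it should match a model built on
    that subset.
    """
    rng = np.random.default_rng(seed)
    if len(model.exclusion_centers) > 0:
        from scipy.spatial import cKDTree

        tree = cKDTree(model.exclusion_centers)
        d, _ = tree.query(model.positions(), k=1)
        clear = [
            i
            for i in range(model.n_features)
            if d[i] >= model.exclusion_radius + exclusion_clearance
        ]
    else:
        clear = list(range(model.n_features))
    n = len(clear)
    if n < 3:
        raise FixtureError(
            "fewer than 3 exclusion-clear features; cannot plant matches"
        )
    ligands: list[LigandFeatureSet] = []
    sidecar = {"seed": seed, "ligands": []}

    def random_rigid(points):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        from scipy.spatial.transform import Rotation

        R = Rotation.from_quat(q).as_matrix()
        t = rng.uniform(-20, 20, size=3)
        return points @ R.T + t

    def random_subset():
        size = int(rng.integers(3, min(max_subset, n) + 1))
        pick = rng.choice(n, size=size, replace=False)
        return sorted(clear[i] for i in pick)

    for i in range(n_true):
        subset = random_subset()
        pos = model.positions(subset)
        pos = random_rigid(pos)
        if jitter > 0:
            direc = rng.normal(size=pos.shape)
            direc /= np.linalg.norm(direc, axis=1, keepdims=True)
            pos = pos + direc * rng.uniform(0, jitter, size=(len(pos), 1))
        kinds = [model.features[j].kind for j in subset]
        lig = LigandFeatureSet(
            ligand_id=f"true_{i}",
            features=list(zip(kinds, pos)),
            atoms=pos.copy(),
            atom_elements=["C"] * len(pos),
        )
        ligands.append(lig)
        sidecar["ligands"].append(
            {"ligand_id": lig.ligand_id, "source_subset": subset,
             "should_match": True, "decoy_type": None}
        )

    all_kinds = {f.kind for f in model.features}
    spare_kinds = [k for k in
                   ("positive", "negative", "aromatic", "hydrophobic", "donor")
                   if k not in all_kinds]
    for i in range(n_decoys):
        subset = random_subset()
        pos = random_rigid(model.positions(subset))
        kinds = [model.features[j].kind for j in subset]
        if i % 2 == 0 and spare_kinds:
            decoy_type = "kind_swap"
            kinds = list(kinds)
            kinds[int(rng.integers(len(kinds)))] = spare_kinds[
                int(rng.integers(len(spare_kinds)))
            ]
        else:
            decoy_type = "distance_distortion"
            pos = pos.copy()
            j = int(rng.integers(len(pos)))
            centroid = pos.mean(axis=0)
            v = pos[j] - centroid
            nv = np.linalg.norm(v)
            v = v / nv if nv > 0 else np.array([0.0, 0.0, 1.0])
            shift = 6.0
            for _ in range(6):   # push until genuinely unmatchable
                trial = pos.copy()
                trial[j] = pos[j] + shift * v
                probe = LigandFeatureSet(
                    ligand_id="probe", features=list(zip(kinds, trial))
                )
                sub_model = PharmacophoreModel(
                    features=[model.features[s] for s in subset]
                )
                if reference_match(sub_model, probe) is None:
                    pos = trial
                    break
                shift *= 2.0
            else:
                raise FixtureError("could not build a distance-distorted decoy")
        lig = LigandFeatureSet(
            ligand_id=f"decoy_{i}",
            features=list(zip(kinds, pos)),
            atoms=np.asarray(pos).copy(),
            atom_elements=["C"] * len(pos),
        )
        ligands.append(lig)
        sidecar["ligands"].append(
            {"ligand_id": lig.ligand_id, "source_subset": subset,
             "should_match": False, "decoy_type": decoy_type}
        )
    return ligands, sidecar


_KIND_TO_ELEMENT = {
    "donor": "N", "acceptor": "O", "hydrophobic": "C",
    "aromatic": "C", "positive": "Na", "negative": "Cl",
}


def write_ligand_sdf(ligands: list[LigandFeatureSet], path: str) -> None:
    """Write the library as SDF pseudo-molecules; feature kinds/positions are
    stored losslessly in a JSON molecule property."""
    from rdkit import Chem
    from rdkit.Chem import AllChem  # noqa: F401
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(path)
    writer.SetKekulize(False)
    for lig in ligands:
        mol = Chem.RWMol()
        conf_pos = []
        for kind, pos in lig.features:
            mol.AddAtom(Chem.Atom(_KIND_TO_ELEMENT[kind]))
            conf_pos.append(pos)
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, p in enumerate(conf_pos):
            conf.SetAtomPosition(i, Point3D(*[float(v) for v in p]))
        m = mol.GetMol()
        m.AddConformer(conf)
        m.SetProp("_Name", lig.ligand_id)
        m.SetProp(
            "mdpharm_features",
            json.dumps(
                [[k, [round(float(v), 4) for v in p]] for k, p in lig.features]
            ),
        )
        writer.write(m)
    writer.close()


def read_ligand_sdf(path: str) -> list[LigandFeatureSet]:
    """Read a library SDF; uses the feature property when present, otherwise
    falls back to minimal feature perception."""
    from rdkit import Chem

    from .screening_filter import perceive_features

    out = []
    for i, mol in enumerate(Chem.SDMolSupplier(path, removeHs=False, sanitize=False)):
        if mol is None:
            continue
        lid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"lig_{i}"
        if mol.HasProp("mdpharm_features"):
            feats = [
                (k, np.asarray(p, dtype=float))
                for k, p in json.loads(mol.GetProp("mdpharm_features"))
            ]
        else:
            feats = perceive_features(mol)
        conf = mol.GetConformer()
        coords = np.array(
            [list(conf.GetAtomPosition(j)) for j in range(mol.GetNumAtoms())]
        )
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        out.append(
            LigandFeatureSet(
                ligand_id=lid, features=feats, atoms=coords, atom_elements=elements
            )
        )
    return out


def write_fpocket_outputs(
    spec: FixtureSpec,
    out_dir: str,
    frames: tuple[int, ...] = (0,),
    probe_radius: float = 1.8,
) -> dict:
    """Emulated fpocket output directories for the fixture complex.

    Per frame: ``frame_<f>/pockets/pocket1_vert.pqr`` is a decoy cavity on
    chain A's outer face (contacts one partner only) and ``pocket2_vert.pqr``
    is the true interface cleft.  Returns the ground-truth mapping.
    """
    x_mid = 0.5 * spec.spacing * (spec.residues_per_chain - 1)
    xs = np.arange(0.0, spec.spacing * (spec.residues_per_chain - 1) + 0.1, 1.5)
    interface = np.array([[x, y, 0.0] for x in xs for y in (-1.5, 0.0, 1.5)])
    decoy = np.array(
        [
            [x_mid + dx, spec.half_width + 4.0, dz]
            for dx in np.arange(-4.0, 4.1, 2.0)
            for dz in (-1.0, 1.0)
        ]
    )
    for f in frames:
        pdir = os.path.join(out_dir, f"frame_{f}", "pockets")
        os.makedirs(pdir, exist_ok=True)
        for pid, probes in ((1, decoy), (2, interface)):
            with open(os.path.join(pdir, f"pocket{pid}_vert.pqr"), "w") as fh:
                fh.write("HEADER fixture pocket probes (synthetic)\n")
                for i, (x, y, z) in enumerate(probes, start=1):
                    fh.write(
                        f"ATOM  {i:5d}  C   STP     1    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  0.00 {probe_radius:5.2f}\n"
                    )
    return {"interface_pocket_id": 2, "decoy_pocket_id": 1, "frames": list(frames)}


def make_dual_binding_hits(
    topo: Structure,
    spec: FixtureSpec,
    n_decoys: int = 10,
    seed: int = 0,
) -> tuple[list[HitRecord], dict]:
    """One planted dual-contact ligand pose spanning the cleft plus decoy
    poses touching only chain A's outer face."""
    rng = np.random.default_rng(seed)
    x_mid = 0.5 * spec.spacing * (spec.residues_per_chain - 1)
    xs = x_mid + np.arange(-3.0, 3.1, 1.5)
    planted = np.array(
        [[x, y, 0.0] for x in xs for y in (-2.6, 0.0, 2.6)]
    )
    hits = [
        HitRecord(
            ligand_id="dual_planted",
            model_id="fixture",
            pose=None,
            rmsd_fit=0.0,
            pose_atoms=planted,
        )
    ]
    top_y = spec.half_width + 4.0    # above chain A's backbone row
    for i in range(n_decoys):
        cx = rng.uniform(5.0, spec.spacing * (spec.residues_per_chain - 2))
        blob = np.array(
            [
                [cx + dx, top_y + dy, dz]
                for dx in (-1.5, 0.0, 1.5)
                for dy in (0.0, 1.2)
                for dz in (-1.0, 1.0)
            ]
        )
        hits.append(
            HitRecord(
                ligand_id=f"decoy_{i}",
                model_id="fixture",
                pose=None,
                rmsd_fit=0.0,
                pose_atoms=blob,
            )
        )
    sidecar = {"planted": "dual_planted", "n_decoys": n_decoys, "seed": seed}
    return hits, sidecar
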