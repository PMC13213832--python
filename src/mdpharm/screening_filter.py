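"""Ligand-to-pharmacophore matching, buried-surface-area hit filtering, and
MMGBSA re-ranking.

The built-in reference matcher performs an exact search over injective,
kind-respecting assignments of model features to ligand features, pruned by
pairwise-distance compatibility, followed by Kabsch alignment and exclusion
checks.  It stands in for an external screening engine so the pipeline is
testable end to end; the engine adapter isolates the external call behind
the same interface.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pharmacophore_model import FEATURE_KINDS, PharmacophoreModel
from .structure_io import Structure, kabsch_superpose, vdw_radius
from .surface import buried_surface_areas, harmonic_mean

__all__ = [
    "LigandFeatureSet",
    "Pose",
    "HitRecord",
    "MMGBSARecord",
    "CapabilityError",
    "reference_match",
    "engine_adapter",
    "parse_engine_sdf",
    "bsa_filter",
    "mmgbsa_rank",
    "perceive_features",
]

DEFAULT_POSITION_TOLERANCE = 1.0   # A; matches the default feature radius
CLASH_DISTANCE = 1.0               # A, ligand-protein heavy-atom flag


@dataclass
class LigandFeatureSet:
    """Annotated pharmacophore features of one library ligand."""

    ligand_id: str
    features: list[tuple[str, np.ndarray]]          # (kind, position)
    atoms: np.ndarray | None = None                 # (n, 3) conformer coords
    atom_elements: list[str] | None = None

    def __post_init__(self):
        if len(self.features) == 0:
            raise ValueError(f"ligand {self.ligand_id}: needs >= 1 feature")
        clean = []
        for kind, pos in self.features:
            if kind not in FEATURE_KINDS:
                raise ValueError(f"ligand {self.ligand_id}: unknown kind {kind!r}")
            clean.append((kind, np.asarray(pos, dtype=float)))
        self.features = clean
        if self.atoms is not None:
            self.atoms = np.asarray(self.atoms, dtype=float).reshape(-1, 3)

    def feature_positions(self) -> np.ndarray:
        return np.array([p for _, p in self.features]).reshape(-1, 3)

    def heavy_atom_coords(self) -> np.ndarray:
        """Conformer heavy atoms; falls back to feature positions."""
        if self.atoms is None:
            return self.feature_positions()
        if self.atom_elements is None:
            return self.atoms
        mask = [e.upper() != "H" for e in self.atom_elements]
        return self.atoms[np.asarray(mask, dtype=bool)]


@dataclass
class Pose:
    assignment: tuple[int, ...]      # ligand feature index per model feature
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class HitRecord:
    ligand_id: str
    model_id: str
    pose: Pose | None
    rmsd_fit: float
    pose_atoms: np.ndarray | None = None     # heavy atoms in the complex frame
    bsa_al: float | None = None
    bsa_bl: float | None = None
    hm_score: float | None = None
    clash: bool = False


@dataclass
class MMGBSARecord:
    ligand_id: str
    dG_AL: float
    dG_BL: float
    dG_ABL: float


class CapabilityError(RuntimeError):
    """An optional external capability (screening engine) is unavailable."""


def _assignments(
    model_pos: np.ndarray,
    model_kinds: list[str],
    lig_pos: np.ndarray,
    lig_kinds: list[str],
    tol: float,
):
    """Yield injective kind-respecting assignments, pruned so every pair of
    already-assigned features satisfies |d_model - d_ligand| <= 2 tol."""
    n_m = len(model_kinds)
    dm = np.linalg.norm(model_pos[:, None] - model_pos[None, :], axis=2)
    dl = np.linalg.norm(lig_pos[:, None] - lig_pos[None, :], axis=2)
    candidates = [
        [j for j, lk in enumerate(lig_kinds) if lk == model_kinds[i]]
        for i in range(n_m)
    ]
    assign: list[int] = []
    used: set[int] = set()

    def rec(i: int):
        if i == n_m:
            yield tuple(assign)
            return
        for j in candidates[i]:
            if j in used:
                continue
            ok = True
            for prev_i, prev_j in enumerate(assign):
                if abs(dm[i, prev_i] - dl[j, prev_j]) > 2.0 * tol:
                    ok = False
                    break
            if ok:
                assign.append(j)
                used.add(j)
                yield from rec(i + 1)
                assign.pop()
                used.remove(j)

    yield from rec(0)


def reference_match(
    model,
    ligand: LigandFeatureSet,
    position_tolerance: float = DEFAULT_POSITION_TOLERANCE,
    master: PharmacophoreModel | None = None,
) -> Pose | None:
    """Best pose matching the ligand onto a pharmacophore model, or None.

    ``model`` is either a PharmacophoreModel or a ScoredModel (feature-id
    subset of ``master``).  A match requires every aligned ligand feature
    within ``position_tolerance`` of its model feature and no ligand heavy
    atom penetrating an exclusion sphere.
    """
    if position_tolerance <= 0:
        raise ValueError("position_tolerance must be > 0")
    if isinstance(model, PharmacophoreModel):
        feats = model.features
        exclusion_centers = model.exclusion_centers
        exclusion_radius = model.exclusion_radius
    else:
        if master is None:
            raise ValueError("a feature-id subset model requires master=")
        feats = [master.features[i] for i in model.feature_ids]
        exclusion_centers = master.exclusion_centers
        exclusion_radius = master.exclusion_radius
    if len(feats) < 3:
        raise ValueError("model must have >= 3 features")

    model_pos = np.array([f.position for f in feats])
    model_kinds = [f.kind for f in feats]
    lig_pos = ligand.feature_positions()
    lig_kinds = [k for k, _ in ligand.features]
    lig_atoms = ligand.heavy_atom_coords()

    best: Pose | None = None
    for assign in _assignments(
        model_pos, model_kinds, lig_pos, lig_kinds, position_tolerance
    ):
        pts = lig_pos[list(assign)]
        R, t, rmsd = kabsch_superpose(pts, model_pos)
        aligned = pts @ R.T + t
        if np.any(
            np.linalg.norm(aligned - model_pos, axis=1) > position_tolerance
        ):
            continue
        if len(exclusion_centers) > 0:
            moved = lig_atoms @ R.T + t
            from scipy.spatial import cKDTree

            d, _ = cKDTree(exclusion_centers).query(moved, k=1)
            if np.any(d < exclusion_radius):
                continue
        if best is None or rmsd < best.rmsd:
            best = Pose(assignment=assign, rotation=R, translation=t, rmsd=rmsd)
    return best


def engine_adapter(
    model_json_path: str,
    database_path: str,
    binary: str = "pharmer",
    extra_args: tuple[str, ...] = (),
) -> list[HitRecord]:
    """Invoke an external pharmacophore search engine on one model file and
    parse the returned SDF poses.  Raises CapabilityError when the engine
    binary is not installed; the reference matcher is the drop-in substitute."""
    exe = shutil.which(binary)
    if exe is None:
        raise CapabilityError(
            f"screening engine binary {binary!r} not found on PATH; "
            "use the built-in reference matcher instead"
        )
    out_sdf = model_json_path + ".hits.sdf"
    cmd = [
        exe, "dbsearch", "-dbdir", database_path, "-in", model_json_path,
        "-out", out_sdf, *extra_args,
    ]
    subprocess.run(cmd, check=True, capture_output=True)
    return parse_engine_sdf(out_sdf, model_id=model_json_path)


def parse_engine_sdf(path: str, model_id: str = "") -> list[HitRecord]:
    """Parse engine-output SDF poses into HitRecords (BSA fields unset)."""
    from rdkit import Chem

    hits = []
    supplier = Chem.SDMolSupplier(path, removeHs=False, sanitize=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        conf = mol.GetConformer()
        coords = np.array(
            [list(conf.GetAtomPosition(j)) for j in range(mol.GetNumAtoms())]
        )
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        lid = (
            mol.GetProp("_Name")
            if mol.HasProp("_Name") and mol.GetProp("_Name")
            else f"hit_{i}"
        )
        heavy = np.array([e.upper() != "H" for e in elements])
        hits.append(
            HitRecord(
                ligand_id=lid,
                model_id=model_id,
                pose=None,
                rmsd_fit=float("nan"),
                pose_atoms=coords[heavy],
            )
        )
    return hits


def bsa_filter(
    hits: list[HitRecord],
    complex_struct: Structure,
    top_n: int | None = None,
    n_sphere_points: int | None = None,
    ligand_element: str = "C",
) -> list[HitRecord]:
    """Score hits by the harmonic mean of the buried surface areas with each
    protein partner, sort descending, keep the top ``top_n``.

    Poses with any ligand-protein heavy-atom distance < 1 A are flagged as
    clashing but kept and reported.
    """
    from scipy.spatial import cKDTree

    chains = sorted(set(complex_struct.chain_id[complex_struct.is_protein]))
    if len(chains) < 2:
        raise ValueError("complex must have two protein chains")
    a_idx = np.flatnonzero(
        (complex_struct.chain_id == chains[0])
        & complex_struct.is_protein
        & complex_struct.heavy_mask
    )
    b_idx = np.flatnonzero(
        (complex_struct.chain_id == chains[1])
        & complex_struct.is_protein
        & complex_struct.heavy_mask
    )
    prot = np.concatenate([a_idx, b_idx])
    tree = cKDTree(complex_struct.coords[prot])
    kwargs = {}
    if n_sphere_points is not None:
        kwargs["n_sphere_points"] = n_sphere_points
    for h in hits:
        if h.pose_atoms is None or len(h.pose_atoms) == 0:
            raise ValueError(f"hit {h.ligand_id}: no pose atoms for BSA")
        radii = np.full(len(h.pose_atoms), vdw_radius(ligand_element))
        bsa_al, bsa_bl = buried_surface_areas(
            complex_struct,
            a_idx,
            b_idx,
            None,
            ligand_coords=h.pose_atoms,
            ligand_radii=radii,
            **kwargs,
        )
        h.bsa_al, h.bsa_bl = bsa_al, bsa_bl
        h.hm_score = harmonic_mean(bsa_al, bsa_bl)
        d, _ = tree.query(h.pose_atoms, k=1)
        h.clash = bool(np.any(d < CLASH_DISTANCE))
    ranked = sorted(hits, key=lambda h: (-h.hm_score, h.ligand_id))
    return ranked if top_n is None else ranked[:top_n]


def _balance(dg_al: float, dg_bl: float) -> float:
    hi = max(abs(dg_al), abs(dg_bl))
    if hi == 0:
        return 0.0
    return min(abs(dg_al), abs(dg_bl)) / hi


def mmgbsa_rank(
    table: pd.DataFrame | str,
    balance_threshold: float = 0.5,
    top_n: int = 10,
) -> pd.DataFrame:
    """Rank ligands by total interaction free energy and annotate dual-binding
    balance.

    The table needs columns {ligand_id, dG_AL, dG_BL, dG_ABL}; replicate
    columns like ``dG_AL_1 .. dG_AL_k`` are averaged and their standard error
    reported.  Ranking is ascending in dG_ABL; balance =
    min(|dG_AL|,|dG_BL|)/max(|dG_AL|,|dG_BL|), flagged below the threshold.
    """
    if isinstance(table, str):
        table = pd.read_csv(table, sep=None, engine="python")
    df = table.copy()
    for col in ("dG_AL", "dG_BL", "dG_ABL"):
        if col not in df.columns:
            reps = sorted(
                c for c in df.columns if c.startswith(col + "_")
            )
            if not reps:
                raise ValueError(f"MMGBSA table is missing column {col!r}")
            df[col] = df[reps].mean(axis=1)
            df[col + "_se"] = df[reps].std(axis=1, ddof=1) / np.sqrt(len(reps))
    if "ligand_id" not in df.columns:
        raise ValueError("MMGBSA table is missing column 'ligand_id'")
    df["balance"] = [
        _balance(al, bl) for al, bl in zip(df["dG_AL"], df["dG_BL"])
    ]
    df["balanced"] = df["balance"] >= balance_threshold
    df = df.sort_values(
        ["dG_ABL", "ligand_id"], ascending=[True, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df.attrs["top"] = df.head(top_n)
    return df


# ---------------------------------------------------------------------------
# Minimal feature perception for conformer-only ligand records (convenience;
# engine-grade perception is out of scope).

def perceive_features(mol) -> list[tuple[str, np.ndarray]]:
    """Derive pharmacophore features from an RDKit molecule: charged groups by
    formal charge, aromatic rings by ring perception, donors/acceptors by N/O
    chemistry, hydrophobics from carbon-only ring systems."""
    from rdkit import Chem

    conf = mol.GetConformer()

    def pos(i):
        p = conf.GetAtomPosition(i)
        return np.array([p.x, p.y, p.z])

    feats: list[tuple[str, np.ndarray]] = []
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        center = np.mean([pos(i) for i in ring], axis=0)
        if all(a.GetIsAromatic() for a in atoms):
            feats.append(("aromatic", center))
        elif all(a.GetSymbol() == "C" for a in atoms):
            feats.append(("hydrophobic", center))
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        q = atom.GetFormalCharge()
        if q > 0:
            feats.append(("positive", pos(i)))
        elif q < 0:
            feats.append(("negative", pos(i)))
        elif atom.GetSymbol() in ("N", "O"):
            if atom.GetTotalNumHs() > 0:
                feats.append(("donor", pos(i)))
            else:
                feats.append(("acceptor", pos(i)))
    return feats
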