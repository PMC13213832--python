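"""Molecular structure and trajectory I/O, atom selection, rigid-body geometry.

Coordinates are in Angstrom throughout.  Internal atom and residue indices are
0-based; the 1-based conventions of PDB/GRO apply only at file boundaries.
Parsing and writing of PDB/GRO files is delegated to :mod:`biotite`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "select",
    "kabsch_superpose",
    "WATER_RESNAMES",
    "CATION_RESNAMES",
    "ANION_RESNAMES",
    "vdw_radius",
]

# Solvent / ion residue-name vocabularies (configurable at call sites).
WATER_RESNAMES = frozenset({"HOH", "SOL", "WAT", "TIP3", "OPC"})
CATION_RESNAMES = frozenset({"NA", "NA+", "SOD"})
ANION_RESNAMES = frozenset({"CL", "CL-", "CLA"})

# Bondi-style van der Waals radii (A) keyed by element symbol.
_VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "NA": 2.27, "K": 2.75,
    "MG": 1.73, "CA": 2.31, "ZN": 1.39, "FE": 1.94, "SE": 1.90,
}
_DEFAULT_VDW = 1.70


def vdw_radius(element: str, overrides: dict[str, float] | None = None) -> float:
    """van der Waals radius in A for an element symbol (case-insensitive)."""
    key = element.strip().upper()
    if overrides and key in overrides:
        return overrides[key]
    return _VDW_RADII.get(key, _DEFAULT_VDW)


class ParseError(ValueError):
    """A structure file failed to parse under the named standard."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom with identity metadata (coordinates live in Structure)."""

    atom_index: int
    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    is_hydrogen: bool
    vdw_radius: float

    def __post_init__(self):
        if not self.element:
            raise ValueError(f"atom {self.atom_index}: element must be non-empty")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.atom_index}: vdw_radius must be > 0")
        if self.is_hydrogen != (self.element.upper() == "H"):
            raise ValueError(
                f"atom {self.atom_index}: is_hydrogen inconsistent with element "
                f"{self.element!r}"
            )


@dataclass
class Structure:
    """A molecular structure as parallel per-atom arrays plus coordinates.

    ``residue_index`` is a global 0-based index assigned in file order;
    ``residue_seq`` preserves the author numbering for round-trip output.
    """

    atom_name: np.ndarray          # (N,) str
    element: np.ndarray            # (N,) str, upper-case
    residue_index: np.ndarray      # (N,) int, global 0-based
    residue_name: np.ndarray       # (N,) str
    chain_id: np.ndarray           # (N,) str
    coords: np.ndarray             # (N, 3) float, A
    residue_seq: np.ndarray | None = None   # (N,) int, author numbering
    vdw: np.ndarray = field(default=None)   # (N,) float, A
    hetero: np.ndarray | None = None        # (N,) bool

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atom_name), 3):
            raise ValueError("coords must have shape (n_atoms, 3)")
        if self.vdw is None:
            self.vdw = np.array([vdw_radius(e) for e in self.element])
        if self.residue_seq is None:
            self.residue_seq = self._default_residue_seq()
        if self.hetero is None:
            self.hetero = np.isin(
                self.residue_name,
                sorted(WATER_RESNAMES | CATION_RESNAMES | ANION_RESNAMES),
            )

    def _default_residue_seq(self) -> np.ndarray:
        seq = np.zeros(self.n_atoms, dtype=int)
        for ch in np.unique(self.chain_id):
            mask = self.chain_id == ch
            _, inv = np.unique(self.residue_index[mask], return_inverse=True)
            seq[mask] = inv + 1
        return seq

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def chains(self) -> set[str]:
        return set(np.unique(self.chain_id))

    @property
    def is_hydrogen(self) -> np.ndarray:
        return self.element == "H"

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.element != "H"

    @property
    def is_water(self) -> np.ndarray:
        return np.isin(self.residue_name, sorted(WATER_RESNAMES))

    @property
    def is_ion(self) -> np.ndarray:
        return np.isin(self.residue_name, sorted(CATION_RESNAMES | ANION_RESNAMES))

    @property
    def is_protein(self) -> np.ndarray:
        return ~(self.is_water | self.is_ion)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(
                atom_index=i,
                atom_name=str(self.atom_name[i]),
                element=str(self.element[i]),
                residue_index=int(self.residue_index[i]),
                residue_name=str(self.residue_name[i]),
                chain_id=str(self.chain_id[i]),
                is_hydrogen=self.element[i] == "H",
                vdw_radius=float(self.vdw[i]),
            )
            for i in range(self.n_atoms)
        ]

    def residue_atoms(self, residue_index: int) -> np.ndarray:
        """Atom indices of one global residue, in file order."""
        return np.flatnonzero(self.residue_index == residue_index)

    def subset(self, indices) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            atom_name=self.atom_name[idx],
            element=self.element[idx],
            residue_index=self.residue_index[idx],
            residue_name=self.residue_name[idx],
            chain_id=self.chain_id[idx],
            coords=self.coords[idx],
            residue_seq=self.residue_seq[idx],
            vdw=self.vdw[idx],
            hetero=self.hetero[idx],
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = Structure(
            atom_name=self.atom_name,
            element=self.element,
            residue_index=self.residue_index,
            residue_name=self.residue_name,
            chain_id=self.chain_id,
            coords=np.asarray(coords, dtype=float),
            residue_seq=self.residue_seq,
            vdw=self.vdw,
            hetero=self.hetero,
        )
        return out


@dataclass
class Trajectory:
    """A topology plus per-frame coordinates (A), optional times in ns."""

    topology: Structure
    frames: np.ndarray                 # (F, N, 3)
    frame_times: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"atom count {self.topology.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


def _infer_element(atom_name: str, element: str) -> str:
    """Use the element column when present, else the first alphabetic
    character of the atom name (common PDB dialect fallback)."""
    el = element.strip().upper()
    if el:
        return el
    for ch in atom_name.strip():
        if ch.isalpha():
            return ch.upper()
    raise ParseError(f"cannot infer element for atom name {atom_name!r}")


def _structure_from_atom_array(arr) -> Structure:
    import biotite.structure as bst

    n = arr.array_length()
    elements = np.array(
        [_infer_element(arr.atom_name[i], arr.element[i]) for i in range(n)]
    )
    # Global 0-based residue index in file order.
    starts = bst.get_residue_starts(arr)
    residue_index = np.zeros(n, dtype=int)
    for ri, s in enumerate(starts):
        e = starts[ri + 1] if ri + 1 < len(starts) else n
        residue_index[s:e] = ri
    return Structure(
        atom_name=arr.atom_name.astype(str),
        element=elements,
        residue_index=residue_index,
        residue_name=arr.res_name.astype(str),
        chain_id=arr.chain_id.astype(str),
        coords=np.asarray(arr.coord, dtype=float),
        residue_seq=arr.res_id.astype(int),
        hetero=arr.hetero.astype(bool),
    )


def _check_pdb_model_consistency(path: str) -> None:
    """Pre-scan a multi-model PDB so an atom-count mismatch names the model."""
    counts: list[int] = []
    current = 0
    in_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec.startswith("MODEL"):
                in_model = True
                current = 0
            elif rec.startswith("ENDMDL"):
                counts.append(current)
                in_model = False
            elif rec.startswith(("ATOM  ", "HETATM")):
                current += 1
    if in_model:
        counts.append(current)
    if counts and len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts) if c != counts[0])
        raise ParseError(
            f"MODEL {bad + 1} has {counts[bad]} atoms, expected {counts[0]}"
        )


def _read_atom_array(path: str, fmt: str, model=None):
    from biotite.structure.io.gro import GROFile
    from biotite.structure.io.pdb import PDBFile

    try:
        if fmt == "pdb":
            f = PDBFile.read(path)
            return f.get_structure(model=model)
        elif fmt == "gro":
            f = GROFile.read(path)
            return f.get_structure(model=model)
    except ParseError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ParseError(f"failed to parse {path!r} as {fmt}: {exc}") from exc
    raise ValueError(f"unknown format {fmt!r}; expected 'pdb' or 'gro'")


def read_structure(path: str, format: str = "pdb") -> Structure:
    """Read a single-model structure from a PDB or GRO file.

    For a multi-model file the first model is returned.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    arr = _read_atom_array(path, format, model=1)
    return _structure_from_atom_array(arr)


def read_trajectory(
    topology_path: str,
    coords_path: str | None = None,
    format: str = "multi_model_pdb",
) -> Trajectory:
    """Read a trajectory from a multi-model PDB or a GRO frame series.

    ``coords_path`` defaults to ``topology_path`` (self-contained multi-model
    file).  For ``gro_series`` pass a list of paths or a single multi-frame GRO.
    """
    if coords_path is None:
        coords_path = topology_path
    if format == "multi_model_pdb":
        if not os.path.exists(coords_path):
            raise FileNotFoundError(coords_path)
        _check_pdb_model_consistency(coords_path)
        stack = _read_atom_array(coords_path, "pdb", model=None)
        import biotite.structure as bst

        if isinstance(stack, bst.AtomArray):   # single model
            topo = _structure_from_atom_array(stack)
            frames = topo.coords[None]
        else:
            topo = _structure_from_atom_array(stack[0])
            frames = np.asarray(stack.coord, dtype=float)
        return Trajectory(topology=topo, frames=frames)
    elif format == "gro_series":
        paths = (
            list(coords_path)
            if isinstance(coords_path, (list, tuple))
            else [coords_path]
        )
        topo = read_structure(paths[0], format="gro")
        frames = []
        for p in paths:
            arr = _read_atom_array(p, "gro", model=None)
            import biotite.structure as bst

            stack = arr if not isinstance(arr, bst.AtomArray) else arr[None]
            for f in range(stack.stack_depth()):
                c = np.asarray(stack.coord[f], dtype=float)
                if c.shape[0] != topo.n_atoms:
                    raise ParseError(
                        f"frame in {p!r} has {c.shape[0]} atoms, expected "
                        f"{topo.n_atoms}"
                    )
                frames.append(c)
        return Trajectory(topology=topo, frames=np.array(frames))
    raise ValueError(f"unknown trajectory format {format!r}")


def _atom_array_from_structure(struct: Structure, coords: np.ndarray):
    import biotite.structure as bst

    n = struct.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = struct.chain_id.astype("U4")
    arr.res_id = struct.residue_seq.astype(int)
    arr.res_name = struct.residue_name.astype("U5")
    arr.atom_name = struct.atom_name.astype("U6")
    arr.element = struct.element.astype("U2")
    arr.hetero = struct.hetero.astype(bool)
    return arr


def write_structure(struct: Structure, path: str) -> None:
    """Write a single-model PDB file."""
    from biotite.structure.io.pdb import PDBFile

    f = PDBFile()
    f.set_structure(_atom_array_from_structure(struct, struct.coords))
    f.write(path)


def write_trajectory(traj: Trajectory, path: str) -> None:
    """Write a multi-model PDB file (one MODEL per frame)."""
    import biotite.structure as bst
    from biotite.structure.io.pdb import PDBFile

    template = _atom_array_from_structure(traj.topology, traj.frames[0])
    stack = bst.stack([template] * traj.n_frames)
    stack.coord = traj.frames.astype(np.float32)
    f = PDBFile()
    f.set_structure(stack)
    f.write(path)


_SELECT_KEYS = {
    "chain",
    "residue_name",
    "residue_index",
    "element",
    "heavy_only",
    "within",
}


def select(structure: Structure, **criteria) -> np.ndarray:
    """Select atoms by simple conjunctive criteria; returns sorted indices.

    Supported keys: ``chain``, ``residue_name``, ``residue_index``,
    ``element`` (scalar or iterable each), ``heavy_only`` (bool), and
    ``within=(cutoff_A, atom_indices[, frame_coords])`` meaning minimum
    atom-atom distance to the reference group is <= cutoff.
    """
    unknown = set(criteria) - _SELECT_KEYS
    if unknown:
        raise ValueError(f"unknown selection keys: {sorted(unknown)}")
    mask = np.ones(structure.n_atoms, dtype=bool)

    def as_set(v):
        if isinstance(v, (str, int, np.integer)):
            return {v}
        return set(v)

    if "chain" in criteria:
        mask &= np.isin(structure.chain_id, sorted(as_set(criteria["chain"])))
    if "residue_name" in criteria:
        mask &= np.isin(
            structure.residue_name, sorted(as_set(criteria["residue_name"]))
        )
    if "residue_index" in criteria:
        mask &= np.isin(
            structure.residue_index,
            sorted(int(i) for i in as_set(criteria["residue_index"])),
        )
    if "element" in criteria:
        vals = {str(e).upper() for e in as_set(criteria["element"])}
        mask &= np.isin(structure.element, sorted(vals))
    if criteria.get("heavy_only", False):
        mask &= structure.heavy_mask
    if "within" in criteria:
        spec = criteria["within"]
        cutoff, ref_indices = spec[0], np.asarray(spec[1], dtype=int)
        coords = spec[2] if len(spec) > 2 else structure.coords
        coords = np.asarray(coords, dtype=float)
        tree = cKDTree(coords[ref_indices])
        d, _ = tree.query(coords, k=1)
        mask &= d <= cutoff
    return np.flatnonzero(mask)


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` with
    ``aligned = mobile @ rotation.T + translation``.  The rotation is always
    proper (det +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both have shape (n, 3)")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    R = rot.as_matrix()
    t = rc - R @ mc
    aligned = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - reference) ** 2, axis=1))))
    return R, t, rmsd


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two conformations after optimal superposition."""
    return kabsch_superpose(a, b)[2]
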