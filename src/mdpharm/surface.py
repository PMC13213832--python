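"""Shrake-Rupley solvent-accessible surface areas, per-residue solvation free
energies from atomic solvation parameters, and buried surface areas.

The SASA of atom i is estimated by distributing ``n_sphere_points`` test
points on a sphere of radius ``r_i + probe_radius`` and counting the fraction
not occluded by any neighbour sphere ``r_j + probe_radius``:

    A_i = 4 pi (r_i + w)^2  *  accessible / total

Areas are in A^2, solvation energies in kJ/mol.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Structure, Trajectory

__all__ = [
    "SasaResult",
    "SolvationProfile",
    "AspTable",
    "load_asp_table",
    "sphere_points",
    "shrake_rupley",
    "structure_sasa",
    "residue_solvation_energy",
    "buried_surface_areas",
]

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_SPHERE_POINTS = 960


def sphere_points(n: int) -> np.ndarray:
    """``n`` nearly uniform unit vectors via the golden-section spiral."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


@dataclass
class SasaResult:
    per_atom_area: np.ndarray            # A^2; NaN for atoms outside subset
    probe_radius: float
    n_sphere_points: int
    per_residue_area: dict[int, float] = field(default_factory=dict)

    def total(self) -> float:
        return float(np.nansum(self.per_atom_area))


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
    subset: np.ndarray | None = None,
    residue_index: np.ndarray | None = None,
) -> SasaResult:
    """Shrake-Rupley SASA for ``subset`` atoms (all atoms occlude).

    ``residue_index`` (optional) aggregates per-residue areas over the subset.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("all radii must be > 0")
    if n_sphere_points < 60:
        raise ValueError("n_sphere_points must be >= 60")
    n = coords.shape[0]
    subset = np.arange(n) if subset is None else np.asarray(subset, dtype=int)

    unit = sphere_points(n_sphere_points)
    enlarged = radii + probe_radius
    tree = cKDTree(coords)

    areas = np.full(n, np.nan)
    for i in subset:
        ri = enlarged[i]
        neighbors = tree.query_ball_point(coords[i], ri + enlarged.max())
        neighbors = [
            j
            for j in neighbors
            if j != i
            and np.linalg.norm(coords[j] - coords[i]) < ri + enlarged[j]
        ]
        pts = coords[i] + ri * unit
        if neighbors:
            nb = np.asarray(neighbors, dtype=int)
            d2 = np.sum(
                (pts[:, None, :] - coords[nb][None, :, :]) ** 2, axis=2
            )
            buried = np.any(d2 < enlarged[nb][None, :] ** 2, axis=1)
            accessible = int(np.count_nonzero(~buried))
        else:
            accessible = n_sphere_points
        areas[i] = 4.0 * np.pi * ri * ri * accessible / n_sphere_points

    per_residue: dict[int, float] = {}
    if residue_index is not None:
        residue_index = np.asarray(residue_index, dtype=int)
        for i in subset:
            per_residue[int(residue_index[i])] = (
                per_residue.get(int(residue_index[i]), 0.0) + areas[i]
            )
    return SasaResult(
        per_atom_area=areas,
        probe_radius=probe_radius,
        n_sphere_points=n_sphere_points,
        per_residue_area=per_residue,
    )


def structure_sasa(
    struct: Structure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
    strip_solvent: bool = True,
    heavy_only: bool = True,
) -> SasaResult:
    """SASA of a structure, by default on protein heavy atoms only.

    Solvent (water/ion) stripping reflects that atom exposure is defined
    against the implicit solvent, not the explicit molecules.
    """
    mask = np.ones(struct.n_atoms, dtype=bool)
    if strip_solvent:
        mask &= struct.is_protein
    if heavy_only:
        mask &= struct.heavy_mask
    idx = np.flatnonzero(mask)
    sub = struct.subset(idx)
    res = shrake_rupley(
        sub.coords,
        sub.vdw,
        probe_radius=probe_radius,
        n_sphere_points=n_sphere_points,
        residue_index=sub.residue_index,
    )
    # Re-embed per-atom areas into full-structure indexing.
    full = np.full(struct.n_atoms, np.nan)
    full[idx] = res.per_atom_area
    res.per_atom_area = full
    return res


# ---------------------------------------------------------------------------
# Atomic solvation parameters


@dataclass
class AspTable:
    """Atom-class -> kJ mol^-1 A^-2 solvation coefficients."""

    coefficients: dict[str, float]
    table_id: str

    def coefficient(self, atom_class: str) -> float:
        try:
            return self.coefficients[atom_class]
        except KeyError:
            raise KeyError(f"no solvation coefficient for atom class {atom_class!r}")


_CHARGED_O = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
}
_CHARGED_N = {
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
}


def atom_class(residue_name: str, atom_name: str, element: str) -> str:
    """Assign an ASP atom class: element symbol with charged-group overrides."""
    key = (residue_name.upper(), atom_name.upper())
    if key in _CHARGED_O or atom_name.upper() == "OXT":
        return "O_CHARGED"
    if key in _CHARGED_N:
        return "N_CHARGED"
    return element.upper()


def load_asp_table(path: str | None = None, table_id: str | None = None) -> AspTable:
    """Load a two-column ASP table (class, kJ mol^-1 A^-2).

    With no path, the built-in Eisenberg-McLachlan-style element table is used.
    """
    if path is None:
        ref = importlib.resources.files("mdpharm.data") / "asp_eisenberg.txt"
        text = ref.read_text()
        table_id = table_id or "eisenberg-mclachlan-1986-kj"
    else:
        with open(path) as fh:
            text = fh.read()
        table_id = table_id or path
    coeffs: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed ASP table line: {line!r}")
        coeffs[parts[0].upper()] = float(parts[1])
    return AspTable(coefficients=coeffs, table_id=table_id)


@dataclass
class SolvationProfile:
    """Trajectory-averaged per-residue solvation free energies (kJ/mol)."""

    per_residue_dGsol_mean: dict[int, float]
    per_residue_dGsol_std: dict[int, float]
    asp_table_id: str


def residue_solvation_energy(
    traj: Trajectory,
    residues,
    asp_table: AspTable | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
    stride: int = 1,
) -> SolvationProfile:
    """Per-residue dG_sol = sum_atoms sigma(atom) * SASA(atom), averaged over
    frames with waters and ions stripped.  Mean and standard deviation over
    the (strided) frames are reported.
    """
    if asp_table is None:
        asp_table = load_asp_table()
    residues = [int(r) for r in residues]
    topo = traj.topology
    prot_idx = np.flatnonzero(topo.is_protein & topo.heavy_mask)
    sub = topo.subset(prot_idx)

    # Pre-resolve coefficients; fail loudly for unclassifiable atoms.
    sigma = np.zeros(len(prot_idx))
    for k in range(len(prot_idx)):
        cls = atom_class(sub.residue_name[k], sub.atom_name[k], sub.element[k])
        try:
            sigma[k] = asp_table.coefficient(cls)
        except KeyError:
            raise KeyError(
                f"atom {sub.atom_name[k]} in residue {sub.residue_name[k]} "
                f"(global residue {sub.residue_index[k]}): no ASP class {cls!r}"
            )

    residue_set = set(residues)
    member = {r: np.flatnonzero(np.isin(sub.residue_index, [r])) for r in residue_set}
    per_frame = {r: [] for r in residue_set}
    for f in range(0, traj.n_frames, stride):
        res = shrake_rupley(
            traj.frames[f][prot_idx],
            sub.vdw,
            probe_radius=probe_radius,
            n_sphere_points=n_sphere_points,
        )
        contrib = sigma * res.per_atom_area
        for r in residue_set:
            per_frame[r].append(float(np.sum(contrib[member[r]])))
    mean = {r: float(np.mean(per_frame[r])) for r in residue_set}
    std = {r: float(np.std(per_frame[r])) for r in residue_set}
    return SolvationProfile(
        per_residue_dGsol_mean=mean,
        per_residue_dGsol_std=std,
        asp_table_id=asp_table.table_id,
    )


def _group_sasa_total(coords, radii, probe_radius, n_sphere_points) -> float:
    res = shrake_rupley(
        coords, radii, probe_radius=probe_radius, n_sphere_points=n_sphere_points
    )
    return res.total()


def buried_surface_areas(
    complex_struct: Structure,
    chain_a_indices,
    chain_b_indices,
    ligand_indices,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
    ligand_coords: np.ndarray | None = None,
    ligand_radii: np.ndarray | None = None,
) -> tuple[float, float]:
    """Buried surface area of the ligand with each protein partner.

        BSA_XL = SASA(X) + SASA(L) - SASA(X u L)

    each term computed with only that group present.  The ligand may be given
    either as atom indices into the complex or as explicit coordinates/radii
    (``ligand_indices=None``).  Values are clamped at 0.
    """
    a = np.asarray(chain_a_indices, dtype=int)
    b = np.asarray(chain_b_indices, dtype=int)
    if ligand_indices is not None:
        li = np.asarray(ligand_indices, dtype=int)
        if len(li) == 0:
            raise ValueError("ligand group is empty")
        lig_coords = complex_struct.coords[li]
        lig_radii = complex_struct.vdw[li]
        if len(set(a) & set(li)) or len(set(b) & set(li)) or len(set(a) & set(b)):
            raise ValueError("chain A, chain B and ligand groups must be disjoint")
    else:
        if ligand_coords is None or ligand_radii is None:
            raise ValueError("provide ligand_indices or ligand_coords+ligand_radii")
        lig_coords = np.asarray(ligand_coords, dtype=float)
        lig_radii = np.asarray(ligand_radii, dtype=float)
        if len(lig_coords) == 0:
            raise ValueError("ligand group is empty")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("chain groups must be non-empty")

    out = []
    s_l = _group_sasa_total(lig_coords, lig_radii, probe_radius, n_sphere_points)
    for idx in (a, b):
        cx = complex_struct.coords[idx]
        cr = complex_struct.vdw[idx]
        s_x = _group_sasa_total(cx, cr, probe_radius, n_sphere_points)
        s_xl = _group_sasa_total(
            np.vstack([cx, lig_coords]),
            np.concatenate([cr, lig_radii]),
            probe_radius,
            n_sphere_points,
        )
        out.append(max(0.0, s_x + s_l - s_xl))
    return out[0], out[1]


def harmonic_mean(a: float, b: float) -> float:
    """HM(a, b) = 2ab/(a+b); 0 when either argument is 0."""
    if a <= 0.0 or b <= 0.0:
        return 0.0
    return 2.0 * a * b / (a + b)
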