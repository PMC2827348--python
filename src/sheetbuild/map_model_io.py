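"""Density-map and atomic-model containers with file I/O.

Maps are treated as P1 orthogonal volumes on a regular voxel grid; world
coordinates are always in Angstrom.  Voxel (i, j, k) sits at
``origin + (i, j, k) * spacing`` (0-based).  Models are backbone-only chains
(N, CA, C, O, CB) read from / written to PDB format.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence
import warnings

import numpy as np
from scipy.ndimage import map_coordinates

import gemmi

BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")
MAINCHAIN_ATOMS = ("N", "CA", "C", "O")


class MapFormatError(ValueError):
    """Raised for unreadable or unsupported density-map files."""


class UnsupportedCellError(MapFormatError):
    """Raised when a map's unit cell is not orthogonal (alpha/beta/gamma != 90)."""


@dataclass
class DensityGrid:
    """Orthogonal voxel grid of density values in an Angstrom frame.

    Attributes
    ----------
    origin : (3,) array, Angstrom position of voxel (0, 0, 0).
    spacing : (3,) array, Angstrom per voxel along each axis (all > 0).
    values : 3-D float array of density (sigma units after normalization).
    resolution_hint : nominal resolution in Angstrom, if known.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    resolution_hint: float | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise ValueError("origin and spacing must be 3-vectors")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def upper_corner(self) -> np.ndarray:
        """World coordinate of the last voxel centre."""
        return self.origin + (np.array(self.dims) - 1) * self.spacing

    def voxel_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-coordinate axes (x_i, y_j, z_k) of the voxel centres."""
        return tuple(
            self.origin[a] + np.arange(self.dims[a]) * self.spacing[a]
            for a in range(3)
        )

    def normalized(self) -> "DensityGrid":
        """Return a copy scaled to zero mean and unit standard deviation."""
        v = self.values
        sd = v.std()
        if sd == 0:
            return replace(self, values=v - v.mean())
        return replace(self, values=(v - v.mean()) / sd)

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the bounding box of voxel centres."""
        xyz = np.atleast_2d(xyz)
        lo = self.origin - 1e-9
        hi = self.upper_corner + 1e-9
        return np.all((xyz >= lo) & (xyz <= hi), axis=1)


def interpolate(
    grid: DensityGrid,
    xyz: np.ndarray,
    fill: float | None = None,
) -> np.ndarray | float:
    """Trilinear interpolation of grid values at world coordinates.

    Parameters
    ----------
    xyz : (3,) or (n, 3) array of Angstrom coordinates.
    fill : value returned for out-of-bounds points; ``None`` raises instead.

    Exact at voxel centres; linear along each axis in between.
    """
    pts = np.atleast_2d(np.asarray(xyz, dtype=float))
    frac = (pts - grid.origin) / grid.spacing
    inside = grid.contains(pts)
    if fill is None and not np.all(inside):
        raise ValueError("interpolation point outside grid bounding box")
    out = map_coordinates(
        grid.values, frac.T, order=1, mode="constant",
        cval=0.0 if fill is None else fill,
    )
    if fill is not None:
        out = np.where(inside, out, fill)
    if np.asarray(xyz).ndim == 1:
        return float(out[0])
    return out


def read_map(path: str | Path) -> DensityGrid:
    """Read a CCP4/MRC density map into a :class:`DensityGrid`.

    The map is normalized to zero mean / unit sigma on load so that the
    ratio-based connectivity thresholds operate on a stable scale.
    Non-orthogonal unit cells are rejected.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read CCP4/MRC map {path!s}: {exc}") from exc
    ccp4.setup(float("nan"))
    cell = ccp4.grid.unit_cell
    if not (
        abs(cell.alpha - 90) < 1e-3
        and abs(cell.beta - 90) < 1e-3
        and abs(cell.gamma - 90) < 1e-3
    ):
        raise UnsupportedCellError(
            f"non-orthogonal unit cell (alpha,beta,gamma)="
            f"({cell.alpha},{cell.beta},{cell.gamma}); only P1 orthogonal "
            "volumes are supported"
        )
    values = np.array(ccp4.grid, dtype=float)
    if not np.all(np.isfinite(values)):
        raise MapFormatError(f"map {path!s} does not cover a full unit cell")
    dims = values.shape
    spacing = np.array([cell.a, cell.b, cell.c]) / np.array(dims)
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)], dtype=float)
    reso = ccp4.header_float(55)  # stashed resolution hint (unused MRC word)
    grid = DensityGrid(
        origin=origin,
        spacing=spacing,
        values=values,
        resolution_hint=float(reso) if reso and reso > 0 else None,
    )
    return grid.normalized()


def write_map(grid: DensityGrid, path: str | Path) -> None:
    """Write a :class:`DensityGrid` as a CCP4/MRC map (P1, orthogonal cell)."""
    g = gemmi.FloatGrid(*grid.dims)
    np.asarray(g)[...] = grid.values.astype(np.float32)
    extent = np.array(grid.dims) * grid.spacing
    g.unit_cell = gemmi.UnitCell(*extent, 90.0, 90.0, 90.0)
    g.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = g
    ccp4.update_ccp4_header()
    for w, v in zip((50, 51, 52), grid.origin):
        ccp4.set_header_float(w, float(v))
    if grid.resolution_hint is not None:
        ccp4.set_header_float(55, float(grid.resolution_hint))
    ccp4.write_ccp4_map(str(path))


@dataclass
class AtomRecord:
    chain_id: str
    res_seq: int
    res_name: str
    atom_name: str
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.atom_name not in BACKBONE_ATOMS:
            raise ValueError(f"unsupported atom name {self.atom_name!r}")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("atom coordinates must be finite")


@dataclass
class Residue:
    """One residue: a named set of backbone atom coordinates."""

    chain_id: str
    res_seq: int
    res_name: str = "ALA"
    atoms: dict = field(default_factory=dict)  # name -> (3,) ndarray
    is_strand: bool | None = None

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]

    def atom_records(self) -> list[AtomRecord]:
        return [
            AtomRecord(self.chain_id, self.res_seq, self.res_name, name, xyz)
            for name, xyz in self.atoms.items()
        ]


@dataclass
class ChainModel:
    """Ordered list of residues, possibly spanning several chains.

    Within each chain residue numbers are strictly increasing; every residue
    carries at least N, CA and C (a residue missing CA is kept but flagged
    ``incomplete``).
    """

    residues: list[Residue] = field(default_factory=list)
    score: float | None = None
    # mean map density at the atom positions; used only to break score
    # ties (e.g. between the two direction twins of an ambiguous strand)
    density_fit: float | None = None

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def atoms(self) -> list[AtomRecord]:
        out: list[AtomRecord] = []
        for res in self.residues:
            out.extend(res.atom_records())
        return out

    def ca_coords(self) -> np.ndarray:
        return np.array([r.atoms["CA"] for r in self.residues if "CA" in r.atoms])

    def atom_coords(self, names: Sequence[str] = BACKBONE_ATOMS) -> np.ndarray:
        pts = [r.atoms[n] for r in self.residues for n in names if n in r.atoms]
        return np.array(pts).reshape(-1, 3)

    def chains(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for res in self.residues:
            out.setdefault(res.chain_id, []).append(res)
        return out

    def validate(self) -> None:
        for cid, residues in self.chains().items():
            seqs = [r.res_seq for r in residues]
            if any(b <= a for a, b in zip(seqs, seqs[1:])):
                raise ValueError(f"chain {cid}: residue numbers not increasing")

    def strand_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_strand]


def concat_models(models: Iterable[ChainModel]) -> ChainModel:
    """Concatenate models, renaming chains sequentially A, B, C, ..."""
    merged = ChainModel()
    for idx, model in enumerate(models):
        cid = chain_label(idx)
        for res in model.residues:
            merged.residues.append(
                Residue(cid, res.res_seq, res.res_name, dict(res.atoms), res.is_strand)
            )
    return merged


def chain_label(index: int) -> str:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    label = ""
    index_ = index
    while True:
        label = alphabet[index_ % 26] + label
        index_ = index_ // 26 - 1
        if index_ < 0:
            return label


def read_model(path: str | Path) -> ChainModel:
    """Read a PDB file, keeping the N/CA/C/O/CB backbone atoms."""
    structure = gemmi.read_pdb(str(path))
    model = ChainModel()
    for chain in structure[0]:
        for res in chain:
            atoms = {}
            for atom in res:
                if atom.name in BACKBONE_ATOMS:
                    atoms[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z]
                    )
            if not atoms:
                continue
            if "CA" not in atoms:
                warnings.warn(
                    f"residue {chain.name}/{res.seqid.num} has no CA; retained",
                    stacklevel=2,
                )
            model.residues.append(
                Residue(chain.name, res.seqid.num, res.name, atoms)
            )
    return model


def write_model(model: ChainModel, path: str | Path) -> None:
    """Write a ChainModel as a PDB file.

    Per-fragment scores, when present on the model, are written into the
    B-factor column of every atom of the fragment's chain.
    """
    structure = gemmi.Structure()
    structure.name = "sheetbuild"
    st_model = gemmi.Model("1")
    for cid, residues in model.chains().items():
        chain = gemmi.Chain(cid)
        for res in residues:
            g_res = gemmi.Residue()
            g_res.name = res.res_name
            g_res.seqid = gemmi.SeqId(res.res_seq, " ")
            for name in BACKBONE_ATOMS:
                if name not in res.atoms:
                    continue
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name[0])
                x, y, z = (float(v) for v in res.atoms[name])
                atom.pos = gemmi.Position(x, y, z)
                atom.occ = 1.0
                atom.b_iso = float(model.score) if model.score is not None else 0.0
                g_res.add_atom(atom)
            chain.add_residue(g_res)
        st_model.add_chain(chain)
    structure.add_model(st_model)
    structure.setup_entities()
    structure.write_pdb(str(path))
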