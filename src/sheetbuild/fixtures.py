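"""Idealized β-sheet models and synthetic electron-density maps.

Every downstream stage of the pipeline (tube detection, register assignment,
assembly, evaluation) is exercised against maps generated here: idealized
parallel or antiparallel β-sheets with side chains truncated at Cβ, converted
to model density at a stated resolution (Gaussian atoms low-pass filtered by
Fourier truncation), with optional Gaussian noise.  Ground truth (per-residue
Cα positions and strand direction vectors) is exported alongside every map so
parameter-recovery tests can score the pipeline output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .map_model_io import ChainModel, DensityGrid, Residue

# Backbone internal coordinates (standard single-conformer values, Angstrom
# and degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

# Default strand torsions: centroid of the observed beta-sheet region of the
# Ramachandran plot.  These give a two-residue axial repeat of ~6.7 A, the
# periodicity the register-detection step is built around.
DEFAULT_PHI = -120.0
DEFAULT_PSI = 125.0

# Approximate electron counts used as Gaussian-atom weights.
ATOM_WEIGHTS = {"N": 7.0, "CA": 6.0, "C": 6.0, "O": 8.0, "CB": 6.0}


@dataclass
class SheetSpec:
    """Geometry of an idealized β-sheet fixture.

    ``twist_deg_per_residue`` accumulates over a strand's length into the
    inclination between adjacent strands (e.g. 5°/residue over 6 residues
    gives a 30° inclination, the upper end of what sheets typically show).
    """

    n_strands: int = 4
    residues_per_strand: int = 6
    topology: str = "antiparallel"
    inter_strand_separation: float = 4.5
    twist_deg_per_residue: float = 0.0
    phi: float = DEFAULT_PHI
    psi: float = DEFAULT_PSI

    def __post_init__(self) -> None:
        if self.n_strands < 1:
            raise ValueError("n_strands must be >= 1")
        if self.residues_per_strand < 3:
            raise ValueError("residues_per_strand must be >= 3")
        if self.inter_strand_separation <= 0:
            raise ValueError("inter_strand_separation must be positive")
        if self.topology not in ("antiparallel", "parallel"):
            raise ValueError("topology must be 'antiparallel' or 'parallel'")


@dataclass
class MapSpec:
    """Parameters of synthetic density calculation.

    resolution : Å; Fourier components beyond 1/resolution are zeroed.
    grid_spacing : Å per voxel (default resolution/4, comfortably past Nyquist).
    atom_b_factor : Å², isotropic Gaussian width per atom (σ² = B / 8π²).
    noise_sigma : Gaussian noise level in units of the noise-free map σ.
    """

    resolution: float
    grid_spacing: float | None = None
    atom_b_factor: float = 40.0
    noise_sigma: float = 0.0
    rng_seed: int = 0
    margin: float = 6.0

    def __post_init__(self) -> None:
        if self.grid_spacing is None:
            self.grid_spacing = self.resolution / 4.0
        if self.resolution < 2.0 * self.grid_spacing - 1e-9:
            raise ValueError(
                f"resolution {self.resolution} A below Nyquist limit for "
                f"grid spacing {self.grid_spacing} A"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Position atom d from internal coordinates relative to chain a-b-c.

    Natural-extension reference frame: |cd| = bond, angle(b,c,d) = angle_deg,
    torsion(a,b,c,d) = torsion_deg.
    """
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.cos(tor) * np.sin(ang), np.sin(tor) * np.sin(ang)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Cβ position for an L-amino acid from backbone N, CA, C (ideal frame)."""
    b = ca - n
    c_vec = c - ca
    a = np.cross(b, c_vec)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * c_vec + ca


def build_ideal_strand(
    n_res: int,
    phi: float = DEFAULT_PHI,
    psi: float = DEFAULT_PSI,
    chain_id: str = "A",
    bend_deg_per_residue: float = 0.0,
) -> ChainModel:
    """Extended idealized β-strand with N, CA, C, O, Cβ per residue.

    The strand is returned in a canonical frame: axis along +x (N→C),
    even-residue carbonyl O pointing toward +y (the neighbour-strand
    direction in a sheet), Cβ alternating along ±z; Cα centroid at the
    origin.  ``bend_deg_per_residue`` adds sheet-perpendicular curvature
    (a rotation about +y accumulated along the chain) for curved-strand
    fixtures.
    """
    if n_res < 2:
        raise ValueError("n_res must be >= 2")
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c = ca + BOND_CA_C * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    backbone = [(n, ca, c)]
    for _ in range(1, n_res):
        pn, pca, pc = backbone[-1]
        nn = place_atom(pn, pca, pc, BOND_C_N, ANGLE_CA_C_N, psi)
        nca = place_atom(pca, pc, nn, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        nc = place_atom(pc, nn, nca, BOND_CA_C, ANGLE_N_CA_C, phi)
        backbone.append((nn, nca, nc))

    model = ChainModel()
    for i, (rn, rca, rc) in enumerate(backbone):
        atoms = {
            "N": rn,
            "CA": rca,
            "C": rc,
            "O": place_atom(rn, rca, rc, BOND_C_O, ANGLE_CA_C_O, psi - 180.0),
            "CB": _ideal_cb(rn, rca, rc),
        }
        model.residues.append(Residue(chain_id, i + 1, "ALA", atoms, is_strand=True))
    _to_canonical_frame(model)
    if bend_deg_per_residue != 0.0:
        _apply_bend(model, bend_deg_per_residue)
    return model


def _to_canonical_frame(model: ChainModel) -> None:
    """Rotate/translate in place: axis→+x, even-residue carbonyls→+y."""
    cas = model.ca_coords()
    centroid = cas.mean(axis=0)
    centred = cas - centroid
    _, _, vt = np.linalg.svd(centred)
    axis = vt[0]
    if np.dot(cas[-1] - cas[0], axis) < 0:
        axis = -axis
    co = np.array([r.atoms["O"] - r.atoms["C"] for r in model.residues])
    co_perp = co - np.outer(co @ axis, axis)
    signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(len(co))])
    ydir = (signs[:, None] * co_perp).mean(axis=0)
    ydir -= np.dot(ydir, axis) * axis
    ydir /= np.linalg.norm(ydir)
    zdir = np.cross(axis, ydir)
    rot = np.vstack([axis, ydir, zdir])
    for res in model.residues:
        for name in res.atoms:
            res.atoms[name] = rot @ (res.atoms[name] - centroid)


def _apply_bend(model: ChainModel, bend_deg_per_residue: float) -> None:
    """Curve the canonical strand in the sheet-perpendicular (x-z) plane.

    Bending about +y by ``bend_deg_per_residue`` per unit of axial progress
    of one residue; applied as a rotation of each atom about the y axis
    through an arc, keeping local geometry nearly rigid per residue.
    """
    cas = model.ca_coords()
    rise = (cas[-1, 0] - cas[0, 0]) / max(len(cas) - 1, 1)
    theta_per_x = np.deg2rad(bend_deg_per_residue) / rise
    for res in model.residues:
        pivot_x = res.atoms["CA"][0]
        theta = theta_per_x * pivot_x
        ct, st = np.cos(theta), np.sin(theta)
        rot = np.array([[ct, 0.0, -st], [0.0, 1.0, 0.0], [st, 0.0, ct]])
        for name in res.atoms:
            res.atoms[name] = rot @ res.atoms[name]


def build_sheet(spec: SheetSpec) -> ChainModel:
    """Stack idealized strands into a sheet.

    Strands run along x and are stacked along +y (the carbonyl direction)
    at ``inter_strand_separation`` Å.  Antiparallel topology flips alternate
    strands by a 180° rotation about the stacking axis, so carbonyl O atoms
    of adjacent strands point into the gap between them.  Chains are named
    A, B, C, ... in stacking order.
    """
    strand = build_ideal_strand(spec.residues_per_strand, spec.phi, spec.psi)
    incline = np.deg2rad(spec.twist_deg_per_residue * spec.residues_per_strand)
    sheet = ChainModel()
    flip = np.diag([-1.0, 1.0, -1.0])
    for k in range(spec.n_strands):
        cid = chr(ord("A") + k)
        theta = k * incline
        ct, st = np.cos(theta), np.sin(theta)
        twist_rot = np.array([[ct, 0.0, -st], [0.0, 1.0, 0.0], [st, 0.0, ct]])
        offset = np.array([0.0, k * spec.inter_strand_separation, 0.0])
        for res in strand.residues:
            atoms = {}
            for name, xyz in res.atoms.items():
                p = xyz
                if spec.topology == "antiparallel" and k % 2 == 1:
                    p = flip @ p
                atoms[name] = twist_rot @ p + offset
            sheet.residues.append(
                Residue(cid, res.res_seq, res.res_name, atoms, is_strand=True)
            )
    return sheet


def density_from_model(
    model: ChainModel,
    map_spec: MapSpec,
    normalize: bool = True,
    grid: DensityGrid | None = None,
) -> DensityGrid:
    """Model electron density for a backbone model at a stated resolution.

    Sum of per-atom isotropic Gaussians (width from ``atom_b_factor``,
    weights from approximate electron counts) sampled on the voxel grid,
    then low-pass filtered by zeroing Fourier components beyond
    1/resolution.  Optional Gaussian noise (``noise_sigma`` in units of the
    noise-free map σ, seeded by ``rng_seed``) is added afterwards, and the
    result is normalized to σ units.

    When ``grid`` is given its geometry (origin/spacing/dims) is reused,
    e.g. to synthesize model density on the voxels of an observed map.
    """
    if not model.residues:
        raise ValueError("model is empty")
    spacing = float(map_spec.grid_spacing)  # type: ignore[arg-type]
    if grid is None:
        coords = model.atom_coords()
        lo = coords.min(axis=0) - map_spec.margin
        hi = coords.max(axis=0) + map_spec.margin
        dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 8)
        origin = lo
        spacing_vec = np.full(3, spacing)
    else:
        origin = grid.origin
        spacing_vec = grid.spacing
        dims = np.array(grid.dims)
        if map_spec.resolution < 2.0 * float(spacing_vec.max()) - 1e-9:
            raise ValueError("resolution below Nyquist limit of supplied grid")

    values = np.zeros(tuple(dims))
    sigma = np.sqrt(map_spec.atom_b_factor / (8.0 * np.pi**2))
    reach = 4.0 * sigma
    for atom in model.atoms:
        w = ATOM_WEIGHTS.get(atom.atom_name, 6.0)
        _add_gaussian(values, origin, spacing_vec, atom.xyz, w, sigma, reach)

    values = _fourier_lowpass(values, spacing_vec, map_spec.resolution)
    if map_spec.noise_sigma > 0:
        rng = np.random.default_rng(map_spec.rng_seed)
        values = values + rng.normal(
            scale=map_spec.noise_sigma * values.std(), size=values.shape
        )
    out = DensityGrid(
        origin=np.asarray(origin, dtype=float),
        spacing=np.asarray(spacing_vec, dtype=float),
        values=values,
        resolution_hint=map_spec.resolution,
    )
    return out.normalized() if normalize else out


def _add_gaussian(
    values: np.ndarray,
    origin: np.ndarray,
    spacing: np.ndarray,
    centre: np.ndarray,
    weight: float,
    sigma: float,
    reach: float,
) -> None:
    """Accumulate one Gaussian atom onto the grid (local neighbourhood only)."""
    lo_idx = np.floor((centre - reach - origin) / spacing).astype(int)
    hi_idx = np.ceil((centre + reach - origin) / spacing).astype(int)
    lo_idx = np.maximum(lo_idx, 0)
    hi_idx = np.minimum(hi_idx, np.array(values.shape) - 1)
    if np.any(lo_idx > hi_idx):
        return
    axes = [
        origin[a] + np.arange(lo_idx[a], hi_idx[a] + 1) * spacing[a] - centre[a]
        for a in range(3)
    ]
    g = [np.exp(-(ax**2) / (2.0 * sigma**2)) for ax in axes]
    block = weight * g[0][:, None, None] * g[1][None, :, None] * g[2][None, None, :]
    values[
        lo_idx[0] : hi_idx[0] + 1,
        lo_idx[1] : hi_idx[1] + 1,
        lo_idx[2] : hi_idx[2] + 1,
    ] += block


def _fourier_lowpass(
    values: np.ndarray, spacing: np.ndarray, resolution: float
) -> np.ndarray:
    """Zero all Fourier components with |s| > 1/resolution (s in 1/Å)."""
    freqs = [
        np.fft.fftfreq(n, d=sp) for n, sp in zip(values.shape[:2], spacing[:2])
    ]
    freqs.append(np.fft.rfftfreq(values.shape[2], d=spacing[2]))
    s2 = (
        freqs[0][:, None, None] ** 2
        + freqs[1][None, :, None] ** 2
        + freqs[2][None, None, :] ** 2
    )
    ft = np.fft.rfftn(values)
    ft[s2 > (1.0 / resolution) ** 2] = 0.0
    return np.fft.irfftn(ft, s=values.shape, axes=(0, 1, 2))


def lowpass_to_resolution(grid: DensityGrid, resolution: float) -> DensityGrid:
    """Low-pass an existing map to a coarser resolution and re-normalize."""
    values = _fourier_lowpass(grid.values, grid.spacing, resolution)
    out = DensityGrid(
        origin=grid.origin,
        spacing=grid.spacing,
        values=values,
        resolution_hint=resolution,
    )
    return out.normalized()


def truth_table(model: ChainModel) -> pd.DataFrame:
    """Ground-truth table: chain, residue, Cα position, strand direction.

    The direction vector is the unit N→C axis of the residue's chain
    (principal Cα axis), identical for all residues of one strand.
    """
    rows = []
    for cid, residues in model.chains().items():
        cas = np.array([r.atoms["CA"] for r in residues])
        centred = cas - cas.mean(axis=0)
        _, _, vt = np.linalg.svd(centred)
        axis = vt[0]
        if np.dot(cas[-1] - cas[0], axis) < 0:
            axis = -axis
        for res in residues:
            ca = res.atoms["CA"]
            rows.append(
                {
                    "chain": cid,
                    "res_seq": res.res_seq,
                    "is_strand": bool(res.is_strand),
                    "ca_x": ca[0],
                    "ca_y": ca[1],
                    "ca_z": ca[2],
                    "dir_x": axis[0],
                    "dir_y": axis[1],
                    "dir_z": axis[2],
                }
            )
    return pd.DataFrame(rows)


def write_truth(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
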