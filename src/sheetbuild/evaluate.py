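"""Scoring of built sheet models against references and maps.

Metrics: residues correctly identified as strand (Cα within 3 Å of a
strand-flagged reference Cα, matched one-to-one), main-chain RMSD over the
matched residues (computed in place, no re-superposition — models are
built in the map frame), and the masked map–model correlation (map vs
model-computed density over grid points within 2 Å of a model atom).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assembly import SheetModel
from .config import RunConfig
from .fixtures import MapSpec, density_from_model
from .map_model_io import MAINCHAIN_ATOMS, ChainModel, DensityGrid


@dataclass
class EvalReport:
    n_strand_ref: int
    n_built: int
    n_correct: int
    recall: float
    precision: float
    rmsd_mainchain: float | None
    strand_map_cc: float | None

    def to_dict(self) -> dict:
        return {
            "n_strand_ref": self.n_strand_ref,
            "n_built": self.n_built,
            "n_correct": self.n_correct,
            "recall": self.recall,
            "precision": self.precision,
            "rmsd_mainchain": self.rmsd_mainchain,
            "strand_map_cc": self.strand_map_cc,
        }


def _as_chain_model(built: SheetModel | ChainModel) -> ChainModel:
    if isinstance(built, SheetModel):
        return built.as_chain_model()
    return built


def match_residues(
    built: ChainModel, reference: ChainModel, radius: float = 3.0
) -> list[tuple[int, int]]:
    """One-to-one greedy nearest-first Cα matching within ``radius``.

    Pairs (built residue index, reference strand-residue index); each
    reference residue is matchable once, so duplicated strands cannot
    inflate the correct count.
    """
    ref_strand = [i for i, r in enumerate(reference.residues) if r.is_strand]
    if not ref_strand:
        raise ValueError("reference model carries no strand flags")
    built_cas = built.ca_coords()
    if len(built_cas) == 0:
        return []
    ref_cas = np.array([reference.residues[i].atoms["CA"] for i in ref_strand])
    d = np.linalg.norm(built_cas[:, None, :] - ref_cas[None, :, :], axis=2)
    pairs = [
        (d[i, j], i, j) for i in range(d.shape[0]) for j in range(d.shape[1])
        if d[i, j] <= radius
    ]
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    used_b: set[int] = set()
    used_r: set[int] = set()
    out: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i in used_b or j in used_r:
            continue
        used_b.add(i)
        used_r.add(j)
        out.append((i, ref_strand[j]))
    return out


def count_correct(
    built: SheetModel | ChainModel,
    reference: ChainModel,
    radius: float = 3.0,
) -> EvalReport:
    """Correct / built / recall / precision bookkeeping (RMSD and CC unset)."""
    built_cm = _as_chain_model(built)
    matches = match_residues(built_cm, reference, radius)
    n_ref = len(reference.strand_residues())
    n_built = len(built_cm)
    n_correct = len(matches)
    return EvalReport(
        n_strand_ref=n_ref,
        n_built=n_built,
        n_correct=n_correct,
        recall=n_correct / n_ref if n_ref else 0.0,
        precision=n_correct / n_built if n_built else 0.0,
        rmsd_mainchain=None,
        strand_map_cc=None,
    )


def mainchain_rmsd(
    built: SheetModel | ChainModel,
    reference: ChainModel,
    match_radius: float = 3.0,
) -> float | None:
    """RMSD over N, CA, C, O of the matched residue pairs (in situ).

    Atoms are paired by name within each matched residue pair; ``None``
    when no residues match.
    """
    built_cm = _as_chain_model(built)
    matches = match_residues(built_cm, reference, match_radius)
    if not matches:
        return None
    deltas = []
    for bi, ri in matches:
        b_res = built_cm.residues[bi]
        r_res = reference.residues[ri]
        for name in MAINCHAIN_ATOMS:
            if name in b_res.atoms and name in r_res.atoms:
                deltas.append(b_res.atoms[name] - r_res.atoms[name])
    if not deltas:
        return None
    deltas_arr = np.array(deltas)
    return float(np.sqrt((deltas_arr**2).sum(axis=1).mean()))


def strand_map_cc(
    grid: DensityGrid,
    model: SheetModel | ChainModel,
    mask_radius: float = 2.0,
    b_factor: float = 40.0,
) -> float:
    """Masked correlation between the map and model-computed density.

    The model density is synthesized on the map's own voxels with the same
    Gaussian-atom + Fourier-truncation procedure used for synthetic maps,
    at the map's nominal resolution; the Pearson correlation runs over
    grid points within ``mask_radius`` of any model atom.
    """
    model_cm = _as_chain_model(model)
    if not model_cm.residues:
        raise ValueError("model is empty")
    resolution = grid.resolution_hint or 4.0 * float(grid.spacing.max())
    spec = MapSpec(
        resolution=resolution,
        grid_spacing=float(grid.spacing.max()),
        atom_b_factor=b_factor,
    )
    model_map = density_from_model(model_cm, spec, grid=grid)

    xs, ys, zs = grid.voxel_coords()
    coords = model_cm.atom_coords()
    mask = np.zeros(grid.dims, dtype=bool)
    for p in coords:
        i0 = np.maximum(
            np.floor((p - mask_radius - grid.origin) / grid.spacing).astype(int), 0
        )
        i1 = np.minimum(
            np.ceil((p + mask_radius - grid.origin) / grid.spacing).astype(int),
            np.array(grid.dims) - 1,
        )
        if np.any(i0 > i1):
            continue
        sub = (
            (xs[i0[0] : i1[0] + 1, None, None] - p[0]) ** 2
            + (ys[None, i0[1] : i1[1] + 1, None] - p[1]) ** 2
            + (zs[None, None, i0[2] : i1[2] + 1] - p[2]) ** 2
        ) <= mask_radius**2
        mask[i0[0] : i1[0] + 1, i0[1] : i1[1] + 1, i0[2] : i1[2] + 1] |= sub
    if not mask.any():
        raise ValueError("no grid points within mask radius of the model")
    a = grid.values[mask]
    b = model_map.values[mask]
    if a.std() < 1e-12 or b.std() < 1e-12:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def evaluate(
    grid: DensityGrid,
    built: SheetModel | ChainModel,
    reference: ChainModel,
    match_radius: float = 3.0,
    mask_radius: float = 2.0,
) -> EvalReport:
    """Full report: counts, RMSD and masked map CC in one pass."""
    report = count_correct(built, reference, match_radius)
    report.rmsd_mainchain = mainchain_rmsd(built, reference, match_radius)
    built_cm = _as_chain_model(built)
    if built_cm.residues:
        report.strand_map_cc = strand_map_cc(grid, built_cm, mask_radius)
    return report


def apply_strand_flags(model: ChainModel, flags: pd.DataFrame) -> ChainModel:
    """Set per-residue strand flags from a (chain, res_seq, is_strand) table."""
    lookup = {
        (str(row["chain"]), int(row["res_seq"])): bool(row["is_strand"])
        for _, row in flags.iterrows()
    }
    for res in model.residues:
        res.is_strand = lookup.get((res.chain_id, res.res_seq), False)
    return model


def sweep_cc_strand_min(
    grid: DensityGrid,
    reference: ChainModel,
    values=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7),
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Re-run the full pipeline per tube-correlation threshold.

    Returns a table (cc_strand_min, n_built, n_correct, rmsd) tracing the
    accuracy-vs-completeness compromise: stricter thresholds build fewer
    residues but more accurately.
    """
    from .pipeline import find_strands

    config = config or RunConfig()
    rows = []
    for value in values:
        cfg = RunConfig.from_dict(config.to_dict())
        cfg.tubes.pairing.cc_strand_min = float(value)
        model, _ = find_strands(grid, cfg)
        if model.fragments:
            report = count_correct(model, reference)
            rmsd = mainchain_rmsd(model, reference)
            n_built = report.n_built
        else:
            rmsd = None
            n_built = 0
        rows.append(
            {"cc_strand_min": float(value), "n_built": n_built, "rmsd": rmsd}
        )
    return pd.DataFrame(rows)
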