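"""End-to-end strand building: map in, assembled sheet model out.

Single-resolution flow: ridge points → density-connected links → tube
segments → nearly parallel pairs (fixing each tube's neighbour direction) →
extension and ridge refinement of the axis → tube scoring → repeat-averaged
register and direction → idealized strand placement.  The full run repeats
this at each merge resolution and assembles the pooled candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .assembly import (
    SheetModel,
    greedy_select,
    join_fragments,
    rescore_chains,
    run_multiresolution,
)
from .config import RunConfig
from .map_model_io import DensityGrid, interpolate
from .register import (
    StrandCandidate,
    average_over_repeats,
    determine_direction,
    find_carbonyl_phase,
    place_strand,
    strand_template,
)
from .ridgelines import (
    TubeSegment,
    build_tubes,
    extend_tube,
    find_parallel_pairs,
    find_ridgeline_points,
    refine_axis,
    score_tube,
    smooth_axis,
)

log = logging.getLogger("sheetbuild")


@dataclass
class StageCounts:
    """Per-stage tallies for run reports and debugging."""

    ridge_points: int = 0
    tubes: int = 0
    paired_tubes: int = 0
    scored_tubes: int = 0
    accepted_registers: int = 0
    candidates: int = 0


@dataclass
class RunReport:
    counts_per_resolution: dict = field(default_factory=dict)
    n_candidates: int = 0
    n_fragments: int = 0
    n_residues: int = 0
    total_score: float = 0.0
    config: dict = field(default_factory=dict)


def strand_candidates(
    grid: DensityGrid, config: RunConfig | None = None,
    counts: StageCounts | None = None,
) -> list[StrandCandidate]:
    """Strand candidates from one map at its current resolution."""
    config = config or RunConfig()
    counts = counts if counts is not None else StageCounts()
    conn = config.tubes.connection
    pair = config.tubes.pairing
    reg = config.register

    points = find_ridgeline_points(
        grid, spacing=config.tubes.spacing, density_floor=config.tubes.density_floor
    )
    counts.ridge_points = len(points)
    raw_tubes = build_tubes(points, grid, pair, conn)
    tubes = [
        TubeSegment(axis=smooth_axis(t.axis), source_resolution=grid.resolution_hint)
        for t in raw_tubes
        if t.length >= pair.min_tube_length
    ]
    counts.tubes = len(tubes)
    find_parallel_pairs(tubes, grid, pair, conn)
    paired = [t for t in tubes if t.neighbour_dir is not None]
    counts.paired_tubes = len(paired)

    template = strand_template(probe_radius=reg.probe_radius)
    out: list[StrandCandidate] = []
    for tube in paired:
        # alternate growth into the density and re-centring on the ridge:
        # extension needs accurate end tangents, refinement needs the
        # extended support, so a few rounds converge to the full strand
        axis = tube.axis
        for _ in range(3):
            extended = extend_tube(
                grid,
                TubeSegment(axis=axis, neighbour_dir=tube.neighbour_dir),
                conn=conn,
            )
            axis = refine_axis(grid, extended.axis)
        if float(np.linalg.norm(np.diff(axis, axis=0), axis=1).sum()) < max(
            3.0, pair.min_tube_length
        ):
            continue
        scored = score_tube(
            grid, TubeSegment(axis=axis, neighbour_dir=tube.neighbour_dir), pair
        )
        if scored.rejected:
            continue
        counts.scored_tubes += 1
        if scored.length < reg.period:
            continue
        profile = average_over_repeats(grid, axis, tube.neighbour_dir, reg)
        phase, accepted = find_carbonyl_phase(profile, reg)
        if not accepted:
            continue
        counts.accepted_registers += 1
        direction = determine_direction(profile, phase, reg)
        placed = place_strand(
            axis,
            phase,
            direction,
            scored.score,
            tube.neighbour_dir,
            template=template,
            params=reg,
            source_resolution=grid.resolution_hint,
        )
        for cand in placed:
            atom_dens = interpolate(grid, cand.model.atom_coords(), fill=0.0)
            cand.density_fit = float(np.mean(np.clip(atom_dens, 0.0, None)))
        out.extend(placed)
    counts.candidates = len(out)
    log.info(
        "resolution %s: %d ridge points, %d tubes, %d paired, %d scored, "
        "%d registers, %d candidates",
        grid.resolution_hint,
        counts.ridge_points,
        counts.tubes,
        counts.paired_tubes,
        counts.scored_tubes,
        counts.accepted_registers,
        counts.candidates,
    )
    return out


def find_strands(
    grid: DensityGrid, config: RunConfig | None = None
) -> tuple[SheetModel, RunReport]:
    """Full pipeline: multi-resolution candidates, joining, greedy selection.

    Deterministic for a fixed map and config.  An empty map yields a valid
    empty model.
    """
    config = config or RunConfig()
    report = RunReport(config=config.to_dict())
    candidates = run_multiresolution(grid, config)
    report.n_candidates = len(candidates)
    if not candidates:
        log.warning("no strand candidates found; returning empty model")
        return SheetModel(), report
    chains = join_fragments(candidates, config.assembly)
    chains = rescore_chains(chains, grid)
    model = greedy_select(chains, config.assembly)
    model.check_invariants(config.assembly)
    report.n_fragments = len(model.fragments)
    report.n_residues = model.n_residues
    report.total_score = model.total_score
    return model, report
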