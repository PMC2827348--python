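"""Assembly of strand candidates into a non-overlapping sheet model.

Candidates from analyses at several resolutions are pooled, fragments whose
terminal Cα stretches coincide are spliced into longer chains, and a greedy
pass selects the highest-scoring chain, deletes everything overlapping it,
and repeats until no fragment of at least four residues remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .map_model_io import ChainModel, DensityGrid, Residue
from .register import StrandCandidate


@dataclass
class AssemblyParams:
    overlap_dist: float = 1.0
    min_sequential_overlap: int = 2
    min_fragment: int = 4
    clash_dist: float = 2.0
    merge_resolutions: tuple = (2.5, 3.0, 4.0)

    def __post_init__(self) -> None:
        if self.min_fragment < self.min_sequential_overlap:
            raise ValueError("min_fragment must be >= min_sequential_overlap")
        if self.overlap_dist <= 0:
            raise ValueError("overlap_dist must be positive")
        self.merge_resolutions = tuple(self.merge_resolutions)


@dataclass
class SheetModel:
    """Assembled non-overlapping set of strand fragments."""

    fragments: list = field(default_factory=list)  # list[ChainModel]
    provenance: list = field(default_factory=list)  # per-fragment dicts

    @property
    def n_residues(self) -> int:
        return sum(len(f) for f in self.fragments)

    @property
    def total_score(self) -> float:
        return float(sum(f.score or 0.0 for f in self.fragments))

    def as_chain_model(self) -> ChainModel:
        """Single model with fragments as chains A, B, C... in score order."""
        from .map_model_io import chain_label

        merged = ChainModel()
        order = sorted(
            range(len(self.fragments)),
            key=lambda i: -(self.fragments[i].score or 0.0),
        )
        for new_idx, i in enumerate(order):
            cid = chain_label(new_idx)
            for res in self.fragments[i].residues:
                merged.residues.append(
                    Residue(cid, res.res_seq, res.res_name, dict(res.atoms), res.is_strand)
                )
        return merged

    def check_invariants(self, params: AssemblyParams | None = None) -> None:
        """Exhaustive pairwise verification of the non-overlap guarantee."""
        params = params or AssemblyParams()
        for f in self.fragments:
            if len(f) < params.min_fragment:
                raise AssertionError("fragment shorter than min_fragment")
        for i in range(len(self.fragments)):
            for j in range(i + 1, len(self.fragments)):
                if _n_shared_sequential(
                    self.fragments[i].ca_coords(),
                    self.fragments[j].ca_coords(),
                    params.overlap_dist,
                ) >= params.min_sequential_overlap:
                    raise AssertionError("fragments share an overlapping run")


def run_multiresolution(grid: DensityGrid, config=None) -> list[StrandCandidate]:
    """Run the tube + register pipeline at each merge resolution and pool.

    The input map is low-pass filtered to every resolution in
    ``merge_resolutions`` that is not finer than the map's own resolution;
    candidate pools are concatenated with per-candidate provenance.
    """
    from .config import RunConfig
    from .fixtures import lowpass_to_resolution
    from .pipeline import strand_candidates

    config = config or RunConfig()
    native = grid.resolution_hint
    resolutions = [
        r for r in config.assembly.merge_resolutions
        if native is None or r >= native - 1e-9
    ]
    if not resolutions:
        resolutions = [native]
    pool: list[StrandCandidate] = []
    for res in resolutions:
        work = grid
        if native is None or res > native + 1e-9:
            work = lowpass_to_resolution(grid, res)
        cands = strand_candidates(work, config)
        for c in cands:
            c.source_resolution = res
        pool.extend(cands)
    for i, c in enumerate(pool):
        c.cand_id = i
    return pool


def _ca_matrix(chain: ChainModel) -> np.ndarray:
    return chain.ca_coords()


def _match_run(
    tail: np.ndarray, head: np.ndarray, k: int, overlap_dist: float
) -> bool:
    """Do the last k CAs of `tail` coincide with the first k of `head`?"""
    if k > len(tail) or k > len(head):
        return False
    d = np.linalg.norm(tail[-k:] - head[:k], axis=1)
    return bool(np.all(d <= overlap_dist))


def _n_shared_sequential(
    cas_a: np.ndarray, cas_b: np.ndarray, overlap_dist: float
) -> int:
    """Longest run of consecutive CAs of `a` each within overlap_dist of
    some CA of `b` (direction-agnostic: reversed duplicates count too)."""
    if len(cas_a) == 0 or len(cas_b) == 0:
        return 0
    d = np.linalg.norm(cas_a[:, None, :] - cas_b[None, :, :], axis=2)
    near = d.min(axis=1) <= overlap_dist
    best = run = 0
    for flag in near:
        run = run + 1 if flag else 0
        best = max(best, run)
    return best


def _per_residue_quality(chain: ChainModel) -> float:
    n = max(len(chain), 1)
    return (chain.score or 0.0) / np.sqrt(n)


def _join_two(
    a: ChainModel, b: ChainModel, params: AssemblyParams
) -> ChainModel | None:
    """Splice b onto the tail of a if their terminal CA runs coincide.

    The overlap region keeps the residues of the higher-scoring member;
    the joined score is the length-weighted per-residue quality times
    sqrt(joined length), staying commensurate with the tube score.
    """
    cas_a, cas_b = _ca_matrix(a), _ca_matrix(b)
    max_k = min(len(cas_a), len(cas_b))
    for k in range(max_k, params.min_sequential_overlap - 1, -1):
        if not _match_run(cas_a, cas_b, k, params.overlap_dist):
            continue
        if (a.score or 0.0) >= (b.score or 0.0):
            residues = a.residues + b.residues[k:]
        else:
            residues = a.residues[:-k] + b.residues
        joined = ChainModel([
            Residue("A", i + 1, r.res_name, dict(r.atoms), r.is_strand)
            for i, r in enumerate(residues)
        ])
        qa, qb = _per_residue_quality(a), _per_residue_quality(b)
        q = (qa * len(a) + qb * len(b)) / (len(a) + len(b))
        joined.score = q * np.sqrt(len(joined))
        fa, fb = a.density_fit or 0.0, b.density_fit or 0.0
        joined.density_fit = (fa * len(a) + fb * len(b)) / (len(a) + len(b))
        return joined
    return None


def join_fragments(
    candidates: list[StrandCandidate] | list[ChainModel],
    params: AssemblyParams | None = None,
) -> list[ChainModel]:
    """Connect fragments sharing >= 2 sequential overlapping CAs (~1 Å).

    Only same-direction overlaps join (an antiparallel coincidence fails
    the ordered terminal match and is left for greedy selection to
    resolve).  Joining repeats until no further splice is possible; a
    fragment spliced with its own copy reproduces the original.
    """
    params = params or AssemblyParams()
    chains: list[ChainModel] = []
    for c in candidates:
        if isinstance(c, StrandCandidate):
            m = c.model
            m.score = c.score
            m.density_fit = c.density_fit
            chains.append(m)
        else:
            chains.append(c)

    changed = True
    while changed:
        changed = False
        out: list[ChainModel] = []
        used = [False] * len(chains)
        order = sorted(
            range(len(chains)), key=lambda i: -(chains[i].score or 0.0)
        )
        for i in order:
            if used[i]:
                continue
            cur = chains[i]
            used[i] = True
            progress = True
            while progress:
                progress = False
                for j in order:
                    if used[j]:
                        continue
                    for x, y in ((cur, chains[j]), (chains[j], cur)):
                        joined = _join_two(x, y, params)
                        if joined is not None and len(joined) > max(len(cur), len(chains[j])) - 1:
                            cur = joined
                            used[j] = True
                            progress = True
                            changed = True
                            break
                    if progress:
                        break
            out.append(cur)
        chains = out
    return chains


def rescore_chains(
    chains: list[ChainModel], grid: DensityGrid
) -> list[ChainModel]:
    """Re-rank chains by their match to the map's density.

    Score = mean (clamped) density over the chain's atoms × sqrt(Cα-path
    length in Å) — the tube scoring rule applied to the placed model —
    evaluated on the native map so chains pooled from several resolutions
    rank on one scale.  Scoring the atoms rather than the bare axis makes
    the score sensitive to the register: the two direction twins of an
    ambiguous strand share an axis but put O and Cβ in different places.
    """
    from .map_model_io import interpolate

    for chain in chains:
        cas = chain.ca_coords()
        if len(cas) < 2:
            chain.score = 0.0
            continue
        length = float(np.linalg.norm(np.diff(cas, axis=0), axis=1).sum())
        atoms = chain.atom_coords()
        afit = np.clip(np.asarray(interpolate(grid, atoms, fill=0.0)), 0.0, None)
        chain.density_fit = float(afit.mean())
        chain.score = float(afit.mean() * np.sqrt(length))
    return chains


def greedy_select(
    chains: list[ChainModel],
    params: AssemblyParams | None = None,
) -> SheetModel:
    """Iteratively pick the best chain and delete everything overlapping it.

    The highest-scoring chain enters the model; remaining chains with an
    overlapping run (>= ``min_sequential_overlap`` consecutive CAs within
    ``overlap_dist`` of the model, in either direction) are deleted;
    survivors are trimmed of residues clashing with the model
    (< ``clash_dist`` CA–CA) and dropped if shorter than
    ``min_fragment``.  Ties break toward the longer fragment, then input
    order (deterministic).
    """
    params = params or AssemblyParams()
    pool = [
        (c, idx) for idx, c in enumerate(chains) if len(c) >= params.min_fragment
    ]
    model = SheetModel()
    while pool:
        pool.sort(
            key=lambda t: (
                -(t[0].score or 0.0),
                -(t[0].density_fit or 0.0),
                -len(t[0]),
                t[1],
            )
        )
        best, best_idx = pool.pop(0)
        model.fragments.append(best)
        model.provenance.append({"input_index": best_idx, "score": best.score})
        model_cas = np.vstack([f.ca_coords() for f in model.fragments])
        survivors: list[tuple[ChainModel, int]] = []
        for chain, idx in pool:
            if (
                _n_shared_sequential(chain.ca_coords(), model_cas, params.overlap_dist)
                >= params.min_sequential_overlap
            ):
                continue
            trimmed = _trim_clashes(chain, model_cas, params)
            if trimmed is not None and len(trimmed) >= params.min_fragment:
                survivors.append((trimmed, idx))
        pool = survivors
    return model


def _trim_clashes(
    chain: ChainModel, model_cas: np.ndarray, params: AssemblyParams
) -> ChainModel | None:
    """Drop residues whose CA clashes with the selected model; keep the
    longest clean run so chains never thread through placed fragments."""
    cas = chain.ca_coords()
    d = np.linalg.norm(cas[:, None, :] - model_cas[None, :, :], axis=2).min(axis=1)
    clean = d >= params.clash_dist
    if clean.all():
        return chain
    best_start = best_len = 0
    run_start = run_len = 0
    for i, ok in enumerate(clean):
        if ok:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_start, best_len = run_start, run_len
        else:
            run_len = 0
    if best_len == 0:
        return None
    residues = chain.residues[best_start : best_start + best_len]
    out = ChainModel(
        [
            Residue(r.chain_id, i + 1, r.res_name, dict(r.atoms), r.is_strand)
            for i, r in enumerate(residues)
        ]
    )
    n_old = max(len(chain), 1)
    out.score = (chain.score or 0.0) * np.sqrt(len(out) / n_old)
    out.density_fit = chain.density_fit
    return out
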