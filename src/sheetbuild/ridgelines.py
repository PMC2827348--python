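"""Detection of β-strand-like tubes of density.

At moderate resolution (2.5–4 Å) a β-strand appears as a gently curved tube
of density; strands of one sheet run nearly parallel, ~4.5 Å apart.  This
module finds points on ridgelines of high density, links points that are
connected by continuously high density into tube segments, keeps tubes that
have a nearly parallel partner at sheet-like separation with *no* density
bridge in between, extends each tube along the density (curvature allowed
only perpendicular to the sheet plane), and scores it against an ideal tube
profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .map_model_io import DensityGrid, interpolate


@dataclass
class ConnectionParams:
    """Thresholds for the two-point density-connectivity test.

    A pair of points is connected when, along the straight line between
    them, min density >= rho_max*cut_1 and mean density >= rho_max*cut_2,
    with rho_max the higher of the two end-point densities.
    """

    cut_1: float = 0.5
    cut_2: float = 0.75
    line_step: float = 0.25

    def __post_init__(self) -> None:
        if not (0 < self.cut_1 <= self.cut_2 <= 1):
            raise ValueError("require 0 < cut_1 <= cut_2 <= 1")


@dataclass
class PairParams:
    """Geometry thresholds for tube pairing, extension and scoring."""

    min_cos: float = 0.5
    target_sep: float = 4.5
    sep_tol: float = 2.0
    cc_strand_min: float = 0.5
    tube_radius: float = 1.5
    min_tube_length: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.min_cos < 1):
            raise ValueError("require 0 < min_cos < 1")
        if not (0 < self.sep_tol < self.target_sep):
            raise ValueError("require 0 < sep_tol < target_sep")


@dataclass
class RidgePoint:
    xyz: np.ndarray
    density: float


@dataclass
class TubeSegment:
    """A polyline axis of high density with score and pairing metadata."""

    axis: np.ndarray  # (n, 3) ordered polyline, consecutive points 0.5-2.5 A
    mean_axis_density: float = 0.0
    tube_cc: float = 0.0
    score: float = 0.0
    neighbour_dir: np.ndarray | None = None
    rejected: bool = False
    source_resolution: float | None = None

    @property
    def direction(self) -> np.ndarray:
        """Unit end-to-end axis direction."""
        v = self.axis[-1] - self.axis[0]
        return v / np.linalg.norm(v)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.axis, axis=0), axis=1).sum())


def find_ridgeline_points(
    grid: DensityGrid,
    spacing: float = 2.0,
    density_floor: float = 1.0,
    min_spacing: float = 1.4,
) -> list[RidgePoint]:
    """Points on ridgelines of high density, ~``spacing`` Å apart.

    A voxel is a ridge candidate when its density is above ``density_floor``
    (σ units) and it is a local maximum in the plane perpendicular to the
    local ridge direction — the eigenvector of the density Hessian with the
    least negative curvature.  Candidates are thinned greedily by descending
    density so surviving points are at least ``min_spacing`` Å apart
    (``spacing`` is the target separation; thinning uses the enforced
    minimum so gently curved ridges are not over-pruned).
    """
    v = grid.values
    mask = v >= density_floor
    # exclude the one-voxel border: central differences need all neighbours
    mask[[0, -1], :, :] = False
    mask[:, [0, -1], :] = False
    mask[:, :, [0, -1]] = False
    idx = np.argwhere(mask)
    if idx.size == 0:
        return []

    hess = _hessian_at(v, grid.spacing, idx)
    evals, evecs = np.linalg.eigh(hess)  # ascending eigenvalues
    # ridge direction: the flattest curvature (smallest |eigenvalue|); the
    # two cross-ridge curvatures must both be negative, which excludes the
    # flanks of a tube where the radial curvature turns positive
    flat = np.argmin(np.abs(evals), axis=1)
    rows = np.arange(len(idx))
    perp_idx = np.array([[j for j in range(3) if j != f] for f in flat])
    perp1 = evecs[rows, :, perp_idx[:, 0]]
    perp2 = evecs[rows, :, perp_idx[:, 1]]

    world = grid.origin + idx * grid.spacing
    dens = v[idx[:, 0], idx[:, 1], idx[:, 2]]
    h = float(grid.spacing.min())
    keep = (evals[rows, perp_idx[:, 0]] < 0) & (evals[rows, perp_idx[:, 1]] < 0)
    # local maximum in the cross-ridge plane (probe the eigen-directions
    # and their diagonals so a rotated eigenbasis cannot hide a climb)
    diag1 = (perp1 + perp2) / np.sqrt(2.0)
    diag2 = (perp1 - perp2) / np.sqrt(2.0)
    for perp in (perp1, perp2, diag1, diag2):
        step = perp * h
        for sgn in (1.0, -1.0):
            probe = interpolate(grid, world + sgn * step, fill=0.0)
            keep &= dens >= probe - 1e-12

    world, dens = world[keep], dens[keep]
    order = np.argsort(dens)[::-1]
    chosen: list[int] = []
    chosen_xyz = np.empty((0, 3))
    for i in order:
        if chosen and np.min(np.linalg.norm(chosen_xyz - world[i], axis=1)) < min_spacing:
            continue
        chosen.append(i)
        chosen_xyz = np.vstack([chosen_xyz, world[i]])
    return [RidgePoint(world[i].copy(), float(dens[i])) for i in chosen]


def _hessian_at(
    values: np.ndarray, spacing: np.ndarray, idx: np.ndarray
) -> np.ndarray:
    """Central-difference Hessians of the density at the given voxels."""
    i, j, k = idx[:, 0], idx[:, 1], idx[:, 2]
    sx, sy, sz = spacing
    v = values
    c = v[i, j, k]
    h = np.empty((len(idx), 3, 3))
    h[:, 0, 0] = (v[i + 1, j, k] - 2 * c + v[i - 1, j, k]) / sx**2
    h[:, 1, 1] = (v[i, j + 1, k] - 2 * c + v[i, j - 1, k]) / sy**2
    h[:, 2, 2] = (v[i, j, k + 1] - 2 * c + v[i, j, k - 1]) / sz**2
    h[:, 0, 1] = h[:, 1, 0] = (
        v[i + 1, j + 1, k] - v[i + 1, j - 1, k] - v[i - 1, j + 1, k] + v[i - 1, j - 1, k]
    ) / (4 * sx * sy)
    h[:, 0, 2] = h[:, 2, 0] = (
        v[i + 1, j, k + 1] - v[i + 1, j, k - 1] - v[i - 1, j, k + 1] + v[i - 1, j, k - 1]
    ) / (4 * sx * sz)
    h[:, 1, 2] = h[:, 2, 1] = (
        v[i, j + 1, k + 1] - v[i, j + 1, k - 1] - v[i, j - 1, k + 1] + v[i, j - 1, k - 1]
    ) / (4 * sy * sz)
    return h


def _line_samples(p1: np.ndarray, p2: np.ndarray, step: float) -> np.ndarray:
    dist = float(np.linalg.norm(p2 - p1))
    n = max(int(np.ceil(dist / step)) + 1, 2)
    t = np.linspace(0.0, 1.0, n)[:, None]
    return p1 + t * (p2 - p1)


def points_connected(
    grid: DensityGrid,
    p1: np.ndarray,
    p2: np.ndarray,
    params: ConnectionParams | None = None,
) -> bool:
    """Density-connectivity test between two points (symmetric).

    Densities sampled along the line are clamped at 0 before the ratio
    tests so negative Fourier-truncation ripples cannot flip the sign of
    the thresholds.  Coincident points are connected by convention.
    """
    params = params or ConnectionParams()
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.allclose(p1, p2):
        return True
    dens = np.clip(
        np.asarray(interpolate(grid, _line_samples(p1, p2, params.line_step), fill=0.0)),
        0.0,
        None,
    )
    rho_max = max(dens[0], dens[-1])
    if rho_max <= 0:
        return False
    return bool(
        dens.min() >= rho_max * params.cut_1
        and dens.mean() >= rho_max * params.cut_2
    )


def build_tubes(
    points: list[RidgePoint],
    grid: DensityGrid,
    params: PairParams | None = None,
    conn: ConnectionParams | None = None,
    max_link: float = 2.5,
) -> list[TubeSegment]:
    """Link connected ridge points into polyline tube segments.

    All point pairs within ``max_link`` Å are tested with
    :func:`points_connected`; accepted links are merged into open paths,
    processed by descending mean end-point density (deterministic), a link
    being attached to a path end only when its direction stays within
    ``min_cos`` of the adjacent link (so crossing ridges stay separate
    tubes).  Every returned segment has at least two points.
    """
    params = params or PairParams()
    conn = conn or ConnectionParams()
    n = len(points)
    if n < 2:
        return []
    xyz = np.array([p.xyz for p in points])
    dens = np.array([p.density for p in points])

    links: list[tuple[float, int, int]] = []
    for i in range(n):
        d2 = np.linalg.norm(xyz[i + 1 :] - xyz[i], axis=1)
        for off in np.nonzero(d2 <= max_link)[0]:
            j = i + 1 + off
            if points_connected(grid, xyz[i], xyz[j], conn):
                links.append((float(dens[i] + dens[j]) / 2.0, i, j))
    links.sort(key=lambda t: (-t[0], t[1], t[2]))

    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for _, i, j in links:
        if len(adj[i]) >= 2 or len(adj[j]) >= 2:
            continue
        if find(i) == find(j):
            continue  # would close a cycle
        v = xyz[j] - xyz[i]
        v = v / np.linalg.norm(v)
        ok = True
        for a, b in ((i, j), (j, i)):
            for other in adj[a]:
                w = xyz[a] - xyz[other]
                w = w / np.linalg.norm(w)
                sgn = 1.0 if a == i else -1.0
                if np.dot(sgn * v, w) < params.min_cos:
                    ok = False
        if not ok:
            continue
        adj[i].append(j)
        adj[j].append(i)
        parent[find(i)] = find(j)

    tubes: list[TubeSegment] = []
    seen: set[int] = set()
    for start in range(n):
        if start in seen or len(adj[start]) != 1:
            continue
        path = [start]
        seen.add(start)
        cur = start
        while True:
            nxt = [k for k in adj[cur] if k not in seen]
            if not nxt:
                break
            cur = nxt[0]
            path.append(cur)
            seen.add(cur)
        if len(path) >= 2:
            tubes.append(TubeSegment(axis=xyz[path].copy()))
    return tubes


def closest_approach(
    a: TubeSegment, b: TubeSegment
) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimum distance between two polylines and the realizing points.

    Brute force over all segment pairs (tubes are short)."""
    best = (np.inf, a.axis[0], b.axis[0])
    for i in range(len(a.axis) - 1):
        for j in range(len(b.axis) - 1):
            d, p, q = _segment_distance(
                a.axis[i], a.axis[i + 1], b.axis[j], b.axis[j + 1]
            )
            if d < best[0]:
                best = (d, p, q)
    return best


def _segment_distance(
    p1: np.ndarray, p2: np.ndarray, q1: np.ndarray, q2: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Closest points between two 3-D segments (standard clamped solution)."""
    u = p2 - p1
    v = q2 - q1
    w = p1 - q1
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    s = np.clip((b * t - d) / a, 0.0, 1.0) if a > 1e-12 else 0.0
    p = p1 + s * u
    q = q1 + t * v
    return float(np.linalg.norm(p - q)), p, q


def find_parallel_pairs(
    tubes: list[TubeSegment],
    grid: DensityGrid,
    params: PairParams | None = None,
    conn: ConnectionParams | None = None,
) -> list[tuple[TubeSegment, TubeSegment]]:
    """Keep tubes that have a nearly parallel sheet-like partner.

    A pair qualifies when |cos| of the axis angle >= ``min_cos`` (either
    strand sense is allowed), the closest approach lies within
    ``target_sep`` ± ``sep_tol``, and the closest cross-tube point pair is
    *not* density-connected (a continuous bridge means one fused feature,
    not two strands).  Each tube in a retained pair records
    ``neighbour_dir``, the unit direction toward its partner at closest
    approach — the expected carbonyl direction for the register analysis.
    When a tube has several partners the one with the smallest deviation
    from ``target_sep`` sets its ``neighbour_dir``.
    """
    params = params or PairParams()
    conn = conn or ConnectionParams()
    usable = [t for t in tubes if t.length >= params.min_tube_length]
    pairs: list[tuple[TubeSegment, TubeSegment]] = []
    best_sep: dict[int, float] = {}
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            a, b = usable[i], usable[j]
            if abs(np.dot(a.direction, b.direction)) < params.min_cos:
                continue
            sep, p, q = closest_approach(a, b)
            if abs(sep - params.target_sep) > params.sep_tol:
                continue
            if sep < 1e-6:
                continue
            # partner must lie to the side, not end-to-end along the axis
            d = (q - p) / sep
            if max(abs(np.dot(d, a.direction)), abs(np.dot(d, b.direction))) > 0.7:
                continue
            if _tubes_bridged(grid, a, b, sep, conn):
                continue
            pairs.append((a, b))
            for tube, here, there in ((a, p, q), (b, q, p)):
                key = id(tube)
                dev = abs(sep - params.target_sep)
                if dev < best_sep.get(key, np.inf):
                    best_sep[key] = dev
                    d = there - here
                    tube.neighbour_dir = d / np.linalg.norm(d)
    return pairs


def _tubes_bridged(
    grid: DensityGrid,
    a: TubeSegment,
    b: TubeSegment,
    sep: float,
    conn: ConnectionParams,
    slack: float = 1.0,
) -> bool:
    """Any high-density connection between the tubes near closest approach?

    For nearly parallel tubes the closest approach is realized along the
    whole overlapping span, so a single cross line could miss a bridge;
    every axis point of the shorter tube whose distance to the other tube
    is within ``slack`` Å of the closest approach contributes a test line.
    A line counts as a bridge when the density along it never falls below
    rho_max * cut_1 (the min-density criterion; the mean criterion plays
    no role in the bridge veto).
    """
    short, long_ = (a, b) if len(a.axis) <= len(b.axis) else (b, a)
    for p in short.axis:
        q, d = _closest_on_polyline(long_.axis, p)
        if d > sep + slack:
            continue
        dens = np.clip(
            np.asarray(interpolate(grid, _line_samples(p, q, conn.line_step), fill=0.0)),
            0.0,
            None,
        )
        rho_max = max(dens[0], dens[-1])
        if rho_max > 0 and dens.min() >= rho_max * conn.cut_1:
            return True
    return False


def _closest_on_polyline(axis: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, float]:
    best_q, best_d = axis[0], float(np.linalg.norm(axis[0] - p))
    for s, e in zip(axis, axis[1:]):
        v = e - s
        L2 = float(v @ v)
        t = 0.0 if L2 <= 1e-12 else float(np.clip((p - s) @ v / L2, 0.0, 1.0))
        q = s + t * v
        d = float(np.linalg.norm(q - p))
        if d < best_d:
            best_q, best_d = q, d
    return best_q, best_d


def extend_tube(
    grid: DensityGrid,
    tube: TubeSegment,
    neighbour_dir: np.ndarray | None = None,
    step: float = 1.0,
    max_bend_deg: float = 15.0,
    bend_step_deg: float = 5.0,
    conn: ConnectionParams | None = None,
) -> TubeSegment:
    """Grow a tube axis into the available density from both ends.

    New points are taken at ``step`` Å, choosing among candidate bends of up
    to ``max_bend_deg`` confined to the plane spanned by the local axis
    direction and the sheet perpendicular (axis × neighbour direction) —
    strand curvature in sheets is roughly perpendicular to the sheet plane.
    Growth stops when the best candidate density falls below
    ``cut_1`` × the seed tube's mean axis density, or at the map boundary.
    """
    conn = conn or ConnectionParams()
    ndir = tube.neighbour_dir if neighbour_dir is None else np.asarray(neighbour_dir)
    if ndir is None:
        raise ValueError("tube has no paired neighbour direction")
    axis = [p.copy() for p in tube.axis]
    mean_dens = float(np.mean(np.clip(interpolate(grid, np.array(axis), fill=0.0), 0, None)))
    floor = conn.cut_1 * mean_dens
    angles = np.deg2rad(
        np.arange(-max_bend_deg, max_bend_deg + 1e-9, bend_step_deg)
    )
    for end in (1, 0):
        for _ in range(200):  # hard cap; density floor is the real stop
            if end == 1:
                tip, prev = axis[-1], axis[-2]
            else:
                tip, prev = axis[0], axis[1]
            t = tip - prev
            t = t / np.linalg.norm(t)
            perp = np.cross(t, ndir)
            nrm = np.linalg.norm(perp)
            if nrm < 1e-9:
                break
            perp /= nrm
            cands = np.array(
                [tip + step * (np.cos(a) * t + np.sin(a) * perp) for a in angles]
            )
            inb = grid.contains(cands)
            if not inb.any():
                break
            dens = np.where(
                inb, np.clip(interpolate(grid, cands, fill=0.0), 0, None), -np.inf
            )
            k = int(np.argmax(dens))
            if dens[k] < floor or dens[k] <= 0.0:
                break
            if end == 1:
                axis.append(cands[k])
            else:
                axis.insert(0, cands[k])
    return TubeSegment(
        axis=np.array(axis),
        neighbour_dir=None if tube.neighbour_dir is None else tube.neighbour_dir.copy(),
        source_resolution=tube.source_resolution,
    )


def score_tube(
    grid: DensityGrid,
    tube: TubeSegment,
    params: PairParams | None = None,
    axial_step: float = 0.5,
    max_radius: float = 2.5,
    n_azimuth: int = 8,
) -> TubeSegment:
    """Fill ``tube_cc`` and ``score``; mark the tube rejected if it fails.

    ``tube_cc`` is the Pearson correlation between the map and an ideal
    tube profile (1 on the axis, falling linearly to 0 at ``tube_radius``)
    evaluated on a cylindrical lattice around the axis (radii up to
    ``max_radius``, ``n_azimuth`` azimuths, axial step ``axial_step``).
    Tubes with ``tube_cc`` below ``cc_strand_min`` are rejected.  The score
    is the mean interpolated axis density times sqrt(axis length in Å).
    """
    params = params or PairParams()
    if tube.length < 3.0:
        raise ValueError("axis too short to score (need >= 3 A)")

    seg = np.diff(tube.axis, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    s_samples = np.arange(0.0, arc[-1] + 1e-9, axial_step)
    centres = np.array([_axis_point(tube.axis, arc, s) for s in s_samples])
    tangents = np.array([_axis_tangent(tube.axis, arc, s) for s in s_samples])

    radii = np.arange(0.0, max_radius + 1e-9, 0.5)
    phis = np.linspace(0.0, 2 * np.pi, n_azimuth, endpoint=False)
    ref = np.array([1.0, 0.0, 0.0])
    map_vals: list[float] = []
    tmpl_vals: list[float] = []
    for centre, tang in zip(centres, tangents):
        u = ref - np.dot(ref, tang) * tang
        if np.linalg.norm(u) < 1e-6:
            u = np.array([0.0, 1.0, 0.0]) - tang[1] * tang
        u /= np.linalg.norm(u)
        w = np.cross(tang, u)
        for r in radii:
            if r == 0.0:
                pts = centre[None, :]
            else:
                pts = centre + r * (
                    np.cos(phis)[:, None] * u + np.sin(phis)[:, None] * w
                )
            vals = np.asarray(interpolate(grid, pts, fill=0.0)).ravel()
            t = max(0.0, 1.0 - r / params.tube_radius)
            map_vals.extend(vals.tolist())
            tmpl_vals.extend([t] * len(vals))

    mv = np.array(map_vals)
    tv = np.array(tmpl_vals)
    if mv.std() < 1e-12 or tv.std() < 1e-12:
        cc = 0.0
    else:
        cc = float(np.corrcoef(mv, tv)[0, 1])
    axis_dens = np.asarray(interpolate(grid, centres, fill=0.0))
    mean_axis = float(axis_dens.mean())
    out = TubeSegment(
        axis=tube.axis.copy(),
        mean_axis_density=mean_axis,
        tube_cc=cc,
        score=mean_axis * np.sqrt(tube.length),
        neighbour_dir=None if tube.neighbour_dir is None else tube.neighbour_dir.copy(),
        rejected=cc < params.cc_strand_min,
        source_resolution=tube.source_resolution,
    )
    return out


def smooth_axis(axis: np.ndarray, order: int = 2, step: float = 1.0) -> np.ndarray:
    """Replace a wiggly polyline by a low-order curve through it.

    β-strands are nearly straight, with gentle curvature essentially
    perpendicular to the sheet; the pleat of the backbone (±1 Å) and the
    pull of carbonyl/Cβ bumps make raw ridge axes wiggle at the repeat
    scale.  Fitting the perpendicular offsets along the principal axis
    with a polynomial of ``order`` keeps the curvature and removes the
    wiggle.  The result is resampled every ``step`` Å.
    """
    axis = np.asarray(axis, dtype=float)
    centroid = axis.mean(axis=0)
    centred = axis - centroid
    _, _, vt = np.linalg.svd(centred)
    t = vt[0]
    s = centred @ t
    idx = np.argsort(s)
    s = s[idx]
    centred = centred[idx]
    deg = int(min(order, len(axis) - 1))
    out_s = np.arange(s[0], s[-1] + 1e-9, step)
    if len(out_s) < 2:
        out_s = np.array([s[0], s[-1]])
    pts = np.outer(out_s, t) + centroid
    perp = centred - np.outer(s, t)
    for a in range(3):
        coef = np.polyfit(s, perp[:, a], deg)
        pts[:, a] += np.polyval(coef, out_s)
    return pts


def refine_axis(
    grid: DensityGrid,
    axis: np.ndarray,
    n_iter: int = 3,
    max_shift: float = 1.0,
    shift_step: float = 0.25,
    order: int = 2,
) -> np.ndarray:
    """Pull an axis onto the density ridge it follows.

    Alternates two moves: each sample point climbs to the density maximum
    within ``max_shift`` Å in its perpendicular plane (grid search at
    ``shift_step``), then the polyline is re-smoothed with
    :func:`smooth_axis` so the axis stays a low-curvature strand-like
    curve rather than tracking individual atom bumps.
    """
    cur = smooth_axis(axis, order=order, step=1.0)
    offsets = np.arange(-max_shift, max_shift + 1e-9, shift_step)
    for _ in range(n_iter):
        tangents = np.gradient(cur, axis=0)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        new_pts = cur.copy()
        for i, (p, t) in enumerate(zip(cur, tangents)):
            u = np.array([1.0, 0.0, 0.0])
            u = u - np.dot(u, t) * t
            if np.linalg.norm(u) < 1e-6:
                u = np.array([0.0, 1.0, 0.0]) - t[1] * t
            u /= np.linalg.norm(u)
            w = np.cross(t, u)
            cand = (
                p
                + offsets[:, None, None] * u
                + offsets[None, :, None] * w
            ).reshape(-1, 3)
            dens = np.asarray(interpolate(grid, cand, fill=-np.inf))
            new_pts[i] = cand[int(np.argmax(dens))]
        cur = smooth_axis(new_pts, order=order, step=1.0)
    return cur


def _axis_point(axis: np.ndarray, arc: np.ndarray, s: float) -> np.ndarray:
    """Point at arclength s along a polyline (arc = cumulative lengths)."""
    s = min(max(s, 0.0), arc[-1])
    i = int(np.searchsorted(arc, s, side="right") - 1)
    i = min(i, len(axis) - 2)
    span = arc[i + 1] - arc[i]
    t = 0.0 if span <= 0 else (s - arc[i]) / span
    return axis[i] + t * (axis[i + 1] - axis[i])


def _axis_tangent(axis: np.ndarray, arc: np.ndarray, s: float) -> np.ndarray:
    s = min(max(s, 0.0), arc[-1])
    i = int(np.searchsorted(arc, s, side="right") - 1)
    i = min(i, len(axis) - 2)
    v = axis[i + 1] - axis[i]
    return v / np.linalg.norm(v)
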