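# Methods

This note documents the models, parameters and numerical choices behind
`sheetbuild`, and what the synthetic benchmarks do and do not demonstrate.

## The physical model

A β-strand's backbone repeats every two residues with an axial period
P ≈ 6.7 Å. In a map at 2.5–4 Å resolution the backbone blurs into a tube
of density; individual atoms are not resolved, but the two-residue
periodicity survives as azimuthal structure around the tube axis:

- carbonyl O atoms point alternately toward the two neighbouring strands
  of the sheet, giving density peaks ~1.5 Å off-axis toward each
  neighbour, half a period apart;
- Cβ atoms point alternately along the two sheet perpendiculars, offset
  by P/3 from the carbonyls.

Walking along one six-atom (two-residue) repeat starting at a carbonyl C,
high off-axis density appears: toward the neighbour at atom 1,
sheet-perpendicular at atom 3, away from the neighbour at atom 4, and on
the other perpendicular at atom 6. Reversing the chain direction mirrors
the pattern, so matching all peaks against the two hypotheses fixes both
the register (translational phase) and the direction of the strand. With
a tolerance of 1/12 period per peak, three free peaks and two directions,
random phases pass with probability 2·(1/6)³ ≈ 0.93% — the direction
call is wrong by chance about once per hundred candidates.

## Pipeline stages and parameters

All parameters live in `RunConfig` (YAML-serializable; every value can be
overridden from the CLI). Defaults are the method's typical operating
values.

### Ridge points and connectivity (`[tubes]`)

- `density_floor` = 1.0 σ: minimum density for a ridge point. Maps are
  normalized to zero mean / unit σ on load, so this is a contour level.
- Ridge definition: a voxel is on a ridge when the density Hessian
  (central differences) has two negative curvatures across the ridge and
  the voxel is a local maximum in that cross-plane (probed along the two
  cross eigenvectors and their diagonals). The ridge direction is the
  smallest-|λ| eigenvector; taking the *largest* eigenvalue instead
  mislabels tube flanks, where the radial curvature turns positive.
- Greedy thinning by descending density to ≥1.4 Å spacing (2 Å target).
- `cut_1` = 0.5, `cut_2` = 0.75: two points are connected when, along the
  straight line between them, min ρ ≥ ρ_max·cut₁ **and** mean
  ρ ≥ ρ_max·cut₂ (ρ_max = higher end-point density). Sampled at
  `line_step` = 0.25 Å; densities clamped at 0 first so Fourier-ripple
  troughs cannot produce negative thresholds. The test is symmetric and
  monotone in both cuts. Near-threshold lines (margin ≲ 0.5% of ρ_max)
  are genuine knife-edges where the sampling step can tip the decision;
  the oracle tests treat those as ties.
- Tube building: accepted links are merged into open paths, processed by
  descending mean end-point density, a link attaching only if it stays
  within `min_cos` = 0.5 of the adjacent link. This keeps crossing ridges
  separate and is deterministic given the map.

### Pairing, extension, scoring

- Pair criteria: |cos(axis angle)| ≥ 0.5 (either strand sense),
  closest approach within `target_sep` ± `sep_tol` = 4.5 ± 2.0 Å, the
  partner lying to the side (|separation·axis| ≤ 0.7 — rules out
  end-to-end collinear "pairs"), and no density bridge: a cross line
  counts as a bridge when its density never falls below ρ_max·cut₁ (the
  min criterion only). Because the closest approach between nearly
  parallel tubes is degenerate, bridges are tested on every near-closest
  cross line, not a single one.
- Closest approach between tube polylines is computed by brute force over
  segment pairs (tubes are short; O(n²) is negligible).
- `neighbour_dir`, the direction toward the partner at closest approach,
  is stored per tube: it is the expected carbonyl direction. With several
  partners, the one closest to 4.5 Å wins.
- Extension: 1.0 Å steps from both ends, candidate bends ±15° in 5°
  increments confined to the plane of the axis and the sheet
  perpendicular (strand curvature in sheets is roughly sheet-
  perpendicular); growth stops when the best candidate density falls
  below cut₁ × the seed tube's mean axis density, or leaves the map.
- Axis refinement: raw ridge axes wiggle at the repeat scale (backbone
  pleat ±1 Å, carbonyl/Cβ bumps). The axis is alternately (i) pulled to
  the density maximum in each point's perpendicular plane (±1 Å grid
  search at 0.25 Å) and (ii) re-fit with a quadratic along its principal
  direction. Three rounds of extend→refine converge to the full strand on
  clean maps. The quadratic keeps genuine sheet-perpendicular curvature
  while suppressing the pleat.
- Scoring: Pearson correlation between the map and an ideal tube profile
  (1 on the axis, linear falloff to 0 at `tube_radius` = 1.5 Å) sampled
  on a cylindrical lattice (radii to 2.5 Å in 0.5 Å steps, 8 azimuths,
  0.5 Å axial step). Tubes with correlation < `cc_strand_min` (default
  0.5) are rejected; zero-variance samples give correlation 0 (rejected).
  Tube score = mean axis density × √(length in Å).

### Register and direction (`[register]`)

- `period` = 6.7 Å, `probe_radius` = 1.5 Å, `phase_tol` = 1/12 of the
  period, `n_phase_bins` = 36 (0.19 Å per bin, >2× finer than the
  tolerance), 3-bin circular boxcar smoothing before peak picking (the
  profiles carry interpolation jitter at the bin scale).
- The probe frame (tangent / neighbour / perpendicular) is re-
  orthogonalized at every axis sample; the neighbour direction is carried
  along the axis by discrete parallel transport rather than used as one
  global vector, so curved tubes keep a consistent azimuthal frame.
- Carbonyl phase = circular argmax of the toward-neighbour profile;
  accepted only if the away-from-neighbour profile peaks within
  `phase_tol`·P of phase + P/2. Direction: the three remaining peaks are
  tested per-peak against exact sixths of the period under both direction
  hypotheses (targets 3/6, 2/6, 5/6 forward; 3/6, 1/6, 4/6 reverse);
  both-or-neither passing → ambiguous, and two candidates are created.
  Per-peak testing matches the ~1%-by-chance arithmetic.
- Placement: the ideal-strand template's two-residue repeat is laid into
  the local axis frame once per period, anchored at the phase where the
  template's own off-axis density peaks (calibrated analytically from the
  Gaussian-atom model — the measured profile peak is displaced ~0.13 Å
  from the carbonyl C along the axis, and the anchor accounts for that).
  Atoms are placed with per-atom local frames, so a curved axis distorts
  the strand smoothly instead of breaking it. Because terminal residues
  have weak density, the traced tube ends short of the true strand;
  repeats may overhang the axis by up to 1.5 Å per end (frames
  extrapolated linearly). Axes shorter than two periods yield nothing.

### Assembly (`[assembly]`)

- Pool: the tube+register stages run on the map low-passed (Fourier
  truncation, then re-normalization) to each of `merge_resolutions` =
  (2.5, 3.0, 4.0) Å, skipping resolutions finer than the map's own.
- Joining: fragments whose terminal Cα runs coincide (≥
  `min_sequential_overlap` = 2 sequential Cα within `overlap_dist` = 1 Å,
  same direction) are spliced, the higher-scoring member keeping the
  overlap region. Antiparallel coincident fragments never splice (the
  ordered terminal match fails) and are left to selection.
- Ranking: joined chains are re-scored against the native map as mean
  (clamped) density over the chain's atoms × √(Cα-path length). This is
  the tube scoring rule applied to the placed model; scoring the atoms
  rather than the bare axis makes the score register-sensitive, which is
  what lets selection separate the two direction twins of an ambiguous
  strand (their Cα paths coincide; their O/Cβ positions do not). Exact
  ties fall back to mean all-atom density, then length, then input order.
- Greedy selection: take the best chain, delete every remaining chain
  with an overlapping run (either direction), trim survivors of residues
  whose Cα comes within `clash_dist` = 2 Å of the model (keeping their
  longest clean stretch), drop fragments under `min_fragment` = 4
  residues, repeat. The output provably contains no overlapping pair; an
  exhaustive pairwise check runs after every pipeline run.

### Evaluation

- Correctness: a built residue is correct when its Cα lies within 3 Å of
  a strand-flagged reference Cα; matching is greedy nearest-first and
  one-to-one, so duplicated strands cannot double-count. Recall =
  matched / reference strand residues; precision = matched / built.
- Main-chain RMSD over N, CA, C, O of matched pairs, computed in place
  (both models live in the map frame; no re-superposition).
- Strand–map CC: Pearson correlation between the map and model-computed
  density (same Gaussian-atom + truncation synthesis, on the map's own
  voxels, at its nominal resolution) over grid points within 2 Å of a
  model atom.

## The synthetic generator

`fixtures` builds idealized sheets: an extended strand from standard bond
lengths/angles via natural-extension (NeRF) chain construction, torsions
φ = −120°, ψ = +125° — the centroid of the observed β-sheet region of the
Ramachandran plot, chosen because it reproduces the 6.7 Å two-residue
repeat that the register analysis is built around (the textbook
fully-extended values near (−139, +135) give 6.93 Å with standard bond
geometry). Strands are stacked 4.5 Å apart along the carbonyl direction;
antiparallel topology rotates alternate strands 180° about the stacking
axis so carbonyls face each other; an optional per-residue twist
accumulates into an inclination between adjacent strands (5°/residue over
6 residues ≈ the ~30° upper end seen in natural sheets).

Density = sum of per-atom isotropic Gaussians (electron-count weights;
width from `atom_b_factor` = 40 Å², a typical value for structures
determined at these resolutions), low-pass filtered by zeroing Fourier
components beyond 1/resolution, plus optional seeded Gaussian noise in
units of the map σ, then normalized. Grid spacing defaults to
resolution/4.

What the generator does **not** emulate: real side chains beyond Cβ,
solvent, density-modification artefacts, phase error correlated over
resolution shells, crystallographic symmetry, or sheets embedded in a
full protein with helices and loops competing for density. Passing the
synthetic benchmarks therefore shows that the geometry/periodicity logic
is implemented correctly and is robust to additive noise and blur — not
that the precision/recall figures transfer to experimental maps, where
neighbouring non-strand density is the dominant source of false
positives.

## Benchmark conditions and their rationale

- Parameter recovery: 4 antiparallel strands × 6 residues at 2.5 Å,
  noise-free. The pipeline rebuilds ≥80% of strand residues (termini have
  weak density and are the usual misses) at well under 1.5 Å main-chain
  RMSD, with every unambiguous direction call correct.
- Threshold sweep: the `cc_strand_min` trade-off (fewer but more accurate
  residues as the threshold rises) only has physics to show when marginal
  tubes exist; on clean 2.5 Å fixtures the earlier filters already reject
  everything questionable and the sweep is flat. The benchmark therefore
  uses deliberately marginal maps — 3.5 Å resolution with 0.8 σ noise,
  ten seeds — comparable to the lowest-quality inputs the method is
  expected to meet, where the sweep reproduces the expected shape
  (residues built non-increasing, mean RMSD non-increasing).
- Chance rate: 100,000 Monte-Carlo trials give a binomial standard error
  of ~0.03 percentage points around the analytic 0.93%.

## Numerical choices, degenerate inputs, determinism

- Trilinear interpolation everywhere (`scipy.ndimage.map_coordinates`,
  order 1); exact at voxel centres; out-of-bounds reads either raise or
  use a configured fill of 0 (pipeline stages use the fill — beyond-edge
  density is treated as empty).
- Maps are treated as P1 orthogonal volumes; non-orthogonal cells are
  rejected on read. World coordinates are Å throughout; voxel indices are
  0-based and never leave the I/O layer.
- Empty maps, maps with no points above the floor, and candidate pools
  that assemble to nothing all return empty results, not errors.
- The core pipeline is deterministic for a fixed map and config (ties in
  link processing, selection order and matching are all broken by
  explicit deterministic keys); the only randomness (noise synthesis,
  Monte-Carlo null) flows from explicit integer seeds.
- Scores are never compared across differently-normalized maps except
  through the final re-scoring pass, which evaluates every pooled chain
  against the same native map.

## Known limitations

- Strands shorter than two periods (~4 residues) cannot be placed; very
  short real strands are invisible to the method by construction.
- Register/direction calls need ≳2 repeats of tube length; on heavily
  fragmented tubes the direction is often ambiguous, and both twins are
  then carried to assembly, where the register-sensitive chain score
  usually — not provably — selects the correct one.
- Edge strands have a neighbour on one side only; their profiles are
  noisier and they dominate the ambiguous/rejected calls.
- Hydrogen-bond-based register refinement and β-bulge/irregularity
  detection are not implemented; the placed strands are ideal-geometry
  approximations.
- The bridge veto tests straight cross lines; a strongly curved density
  bridge slipping between test lines is conceivable on pathological
  inputs.
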