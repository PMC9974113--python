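# Methods

This note records the model, the numerical choices, and the reasoning
behind every parameter default, in enough detail to re-derive or challenge
them.

## Input contract and conventions

The pipeline operates on 2-D binary masks (`uint8`, values {0, 1},
foreground = lung parenchyma) as produced by an upstream Hounsfield-unit
threshold segmenter. Coordinates are 0-based `(row, col)` with the row axis
pointing down; on disk, masks are 8-bit single-channel PNG/TIFF with
foreground 255. HU thresholding, DICOM handling and 3-D reconstruction are
out of scope. The whole correction is deterministic: randomness exists only
in the fixture generator, which takes an explicit seed.

## Keypoint detector

A DoG detector flags abrupt boundary-curvature changes. Per octave,
Gaussian levels are smoothed at `σ0·k^i` (k = 2^(1/scales_per_octave),
`scales_per_octave + 3` levels) from the octave base, which is the 2×
downsample of the level with twice the base blur; DoG level i is the
difference of adjacent Gaussians. Candidates are strict extrema over the 26
scale-space neighbors; they pass a contrast gate (|D| ≥ 0.01 on masks in
[0, 1]) and a principal-curvature gate (tr²H/det H of the 2×2 spatial
Hessian ≤ (r+1)²/r), then receive up to five steps of 3-D quadratic
(Taylor) refinement, discarding candidates whose offset never settles below
half a pixel. Orientation assignment builds the classical 36-bin gradient
histogram (10° per bin) with weight `m` and a Gaussian spatial weight of
scale 1.5σ, returning one keypoint per peak at ≥ 80% of the maximum.

Two gradient conventions coexist: the magnitude `m` is by default the *sum
of squared* central differences (`m1 + m2`, each term already squared), a
`squared=False` flag gives the conventional square root. Only relative
weighting matters downstream, so the choice is inert; the squared form is
the primary one because it is the cheaper and the one the orientation
histogram was validated with.

Defaults and why:

* `sigma0 = 1.6` (base smoothing, px). A binary mask's boundary is a
  staircase: at 45° tangents, single-pixel steps act as genuine corners at
  scale ~1 px and generate spurious keypoints on perfectly smooth arcs. At
  σ0 = 1.6 those steps are blurred below the contrast gate while defect
  corners (arms ≥ 8 px) survive; at σ0 = 1.2 occasional staircase keypoints
  appear on smooth phantoms. (The snake's edge-map scale stays at the
  published σ = 1.2 — the two scales are independent settings.)
* `edge_ratio = 5` (curvature-ratio gate r). Measured on development
  phantoms (seeds disjoint from any test), smooth-arc survivors score
  tr²/det ≥ 8 (near the ridge-like limit) while notch-corner keypoints
  score ≈ 4–8. The gate (r+1)²/r = 7.2 separates the two populations with
  a structural margin: the ratio reflects the local curvature radius
  (~40 px for lobe arcs vs ≤ 15 px for defects), not a tuned accident.
  The classical r = 10 admits the smooth-arc responses.
* `scales_per_octave = 3`, `n_octaves = 4`, `contrast_thresh = 0.01`:
  standard detector values; masks have unit contrast so the contrast gate
  is undemanding.

## Supportive boundary lines

The mask boundary is the set of foreground pixels with a background
4-neighbor (image border counts as background); line connectivity is
8-connected so diagonal runs stay whole. Keypoints are snapped to their
Euclidean-nearest boundary pixel (k-d tree; exhaustively verified in
tests); boundary pixels within radius `R` (inclusive) of an anchor form the
supportive subset; components shorter than `min_len = 5` px are discarded
as debris.

`R = 20` px. R controls how much boundary a single anchor recruits. A
defect of radius ρ has a concave arc of length ≈ πρ flanked by two mouth
corners; with R smaller than ρ the corner anchors recruit two disconnected
half-arcs, the defect splinters into two lines, and each line's rectangle
covers only part of the defect — measured on development phantoms, R = 10
leaves ~30% of carved pixels outside every flagged rectangle, R = 20
(≈ the largest defect radius the generator produces, 15 px, plus anchor
slack) leaves ~1%. Tools applying the package to defects of a different
scale should set R accordingly.

## Recognition

Per line: the minimum enclosing axis-aligned rectangle (OR) grows by
`margin` on each side (clipped) into the ER; the ER crop of the mask is the
block. The largest 8-connected component's closed boundary is traced
Moore-neighbor-wise, clockwise from the uppermost-leftmost pixel, stopping
when the (pixel, backtrack) walk state repeats — a termination rule that is
robust to one-pixel spurs (where pixels may legitimately repeat).

The contour is encoded as `z(n) = col(n) + j·row(n)`; `Z = fft(z)` (plain
forward sum), `Z(0) := 0` removes translation; `Z′ = Z/Z(1)` (with
`Z′(1) := 1` exactly) removes rotation, scale and start point from the
magnitudes. The flagging statistic is `band_max = max |Z′(k)|` over
harmonics with `min(k, N−k) ≥ k_min` (conjugate-symmetric band, default
`k_min = 10`); a block is repaired iff `band_max > threshold` (strict).

* **Normalized vs raw.** The classical formulation reports a fixed level
  of 10⁴ on descriptor values, which only makes sense for unnormalized
  |Z(k)| at full-slice coordinate magnitudes. This package traces contours
  in block-local coordinates (blocks are ~50–120 px), where raw |Z(k)| is
  O(10²–10³) and scales with block size and contour length — a fixed raw
  threshold cannot transfer between blocks. The normalized |Z′(k)| is a
  pure shape statistic, so the default is `use_normalized = True`; the raw
  convention remains available (`use_normalized=False`, threshold in
  absolute units) for full-slice-scale workflows.
* **`threshold = 0.004`.** Chosen once against development phantoms:
  blocks whose ER intersects a carved defect score band_max ≥ 0.005
  (median ≈ 0.010), while the detector's curvature gate already keeps
  smooth-boundary blocks from being built at all, so the descriptor
  threshold serves as a backstop that any essentially-smooth contour
  (band_max ≲ 0.004) cannot pass. It is deliberately permissive: a missed
  defect costs recall, a flagged smooth block costs only a snake run whose
  restore rule makes it near-idempotent.
* `margin = 15` px. The ER must hold the outside-initialized snake
  rectangle plus the whole defect; with margin 10 the snake's contour
  sampling is too fine relative to the defect mouth (see below) and
  bridging degrades measurably.

## GVF snake

Edge map: `f = |∇(G_σ ∗ I)|²`, max-normalized (σ = 1.2, the published
value). The GVF field diffuses `∇f`: explicit iteration
`u ← u + dt(μ∇²u − |∇f|²(u − f_x))` (same for v), Neumann borders,
initialized at ∇f; stability needs `dt ≤ 1/(4μ)`.

* `μ = 0.2, dt = 1`: the classical regularization weight at its stable
  step.
* `n_iter = 2000`: the explicit scheme's influence radius grows like
  √(μ·dt·n); the snake starts 10–40 px from the boundary, so the field
  must be meaningful (direction-wise) across the whole block. 80
  iterations — a common demo value — give a ~5 px capture range and the
  outside-initialized contour stalls; 2000 iterations approach the steady
  state on these block sizes at negligible cost (~0.1 s per block).

Before the correction runs, the block is zero-padded by 3 px. Where the
lung runs off the ER crop the object would otherwise have no enclosing
edge; the pad line turns the crop frame into an edge, giving the snake a
closed boundary to settle on all the way around — the very purpose of the
ER's background outskirt, enforced unconditionally.

Evolution: semi-implicit per-axis solves
`x_{t+1} = (γI − A)⁻¹(γx_t + κ₁·V̂_x − κ₂·N_x)` with A the cyclic
penta-diagonal operator `λ₁D₂ − λ₂D₄` (unit parameter spacing; its rows
sum to zero and its eigenvalues on circulant cosines are
`λ₁(2cosθ−2) − λ₂(2cosθ−2)²`). Since A is negative-semidefinite, the
well-posed implicit matrix is `γI − A` (equivalently `Â + γI` for the
positive form `Â = −A` used by standard snake implementations); published
sign conventions for these terms are not mutually consistent, so the signs
here are fixed by the physical requirements — GVF attracts to edges,
balloon deflates — and pinned by the disk-convergence test. V̂ is the GVF
field sampled bilinearly at the contour points and normalized to unit
magnitude (`normalize_gvf = True`), the standard practice that makes
κ₁ = 0.5 an advance speed of 0.5 px/step: with the raw field (which decays
away from edges) the published κ values cannot move the contour tens of
pixels in any practical iteration count. N is the outward unit normal from
central-difference tangents, oriented by the signed polygon area — so it
points outward for either traversal direction. Points are clipped to the
block; iteration stops when the mean per-point displacement falls below
`tol = 0.05` px or at `max_iter = 400`.

* `n_points = 40`. With unit parameter spacing, the operator's stiffness
  lives in *index* space: a feature spanning w contour points feels a
  restoring weight ≈ λ₂(2cos(2π/2w)−2)². The defect mouth (16–30 px) must
  span few points (w ≈ 3–5) for λ₂ = 3 to bridge it, while the global
  mode (w ≈ n/2) must stay soft enough that the field can hold the contour
  against the overall inward pull. n = 40 on these block perimeters
  (~150–400 px) satisfies both; n ≈ 100 makes the snake follow the defect
  into the cavity (spacing ~1–2 px), n ≤ 16 lets pure smoothing collapse
  the contour through the boundary. The initial rectangle sits `inset = 2`
  px inside the (padded) block border.
* Interior rasterization: scanline polygon fill (even-odd) plus the
  rounded contour polyline.
* Restore rule: the corrected crop is `interior ∪ original`; only the OR
  portion (ORCR) is pasted back, by union. Hence the global invariant
  `output ⊇ input`, held by construction and asserted in every end-to-end
  test. A snake that degenerates (zero-area contour) leaves its block
  unchanged, with a logged warning.

## Evaluation and baseline

`ACC = 100·|S_manu ∩ S_auto|/|S_manu|`; `R_u` is computed as `100 − ACC`
(the two are the same integer-count ratio by definition, and this form
keeps the identity exact in floating point); `R_o = 100·(|S_auto| −
|S_manu ∩ S_auto|)/|S_manu|`. The rolling-ball baseline is morphological
closing with a discrete disk; closing is extensive and idempotent, and
fills only concavities narrower than the ball — which is why it barely
touches defects of radius ≥ its own.

## Synthetic phantoms

`make_lung_truth` draws two filled ellipse lobes (semi-axes 0.30·height by
0.15·width, centers at 28% and 72% of the width, 52% of the height) whose
boundary radius is perturbed by a 3-term low-frequency cosine series of
total amplitude ≤ 2.5 px — enough texture that the boundary is not
analytically circular, little enough that it stays smooth at detector
scale. `carve_notches` subtracts disks of radius 8–15 px centered at
uniformly sampled boundary points, kept ≥ 3× the maximum radius apart
(rejection sampling, 1000-draw budget). All fixtures are pure functions of
(dimensions, parameters, seed).

What the phantoms do *not* emulate: CT texture, vessels and airways,
attached structures other than disk bites, multi-slice coherence, and the
mediastinal boundary's fine anatomy. Passing the synthetic suites shows
the geometry of the method works — detection of curvature anomalies,
shape-based recognition, smooth refilling, monotone safety — not that the
specific thresholds transfer untouched to clinical masks, where the defect
scale and boundary roughness differ.

## Study sizes

The packaged studies use 512×512 masks: 10 un-notched phantoms for the
no-op suite and 20 phantoms with 1–3 notches (radius 8–15 px) for the
recovery suite; together they complete in well under a minute on one CPU,
which keeps the whole verification loop interactive. On these conditions
the pipeline typically reports mean ACC ≈ 99.8% (from ≈ 99.4% uncorrected),
mean R_u ≈ 0.2%, improvement on every case, and strictly better mean ACC
than 5-px rolling-ball closing.

## Known limitations

* A defect wider than the supportive radius regime (mouth ≫ 2R) fragments
  into several lines; the union of their rectangles usually still covers
  it, but single-block coverage is not guaranteed.
* Bridging quality falls with defect size: the snake dips ~1–3 px into
  wide mouths, so very large defects are only partially refilled (the
  monotone guarantee still holds).
* The snake does not resample its contour; extreme aspect-ratio blocks can
  cluster points and waste resolution on one side.
* The descriptor threshold backstop was calibrated for block-local
  coordinates and the fixture defect scale; full-slice workflows using the
  raw convention must supply their own absolute threshold.
* The detector's exact keypoint reproducibility under rotation holds on
  the base octave; coarser octaves live on decimated lattices that do not
  map onto themselves under arbitrary rotations or sub-lattice shifts.
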