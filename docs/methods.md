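# Methods

`lascar` quantifies left-atrial ablation scar on late-gadolinium-
enhancement (LGE) cardiac MR the way post-PVI imaging studies do:
project wall intensity onto an endocardial shell, threshold it against
blood-pool statistics, and assess the lesion ring around each pulmonary
vein pair for width and continuity. Because no imaging data ship with
the package, every stage is validated on synthetic phantoms with known
ground truth. This note records the model, the parameters that matter,
and the numerical choices where the design was genuinely open.

## Measurement model

**Shell and projection.** The blood pool is segmented from a
bright-blood (MRA-like) volume by Otsu thresholding plus seeded
connected-component selection and slice-wise hole filling — a
deterministic stand-in for interactive segmentation. The endocardial
surface is the marching-cubes iso-surface at level 0.5 of the
Gaussian-smoothed mask (σ = 1 voxel): the iso-surface of the raw binary
field is a staircase whose area overestimates a smooth boundary by
~10%, while the smoothed surface reproduces a sphere's area to ~1%
(masks too small to survive smoothing, e.g. a single voxel, fall back
to the raw field). Meshes live in mm world coordinates
(`origin + index·spacing`); normals are oriented outward by a
signed-volume check. Each vertex then receives the **maximum** LGE
intensity interpolated trilinearly along its outward normal from 0 to
`depth` (default 3 mm, step = half the smallest voxel spacing).
Sampling is wall-ward only: sampling into the blood pool would bias the
maximum toward bright blood. Increasing `depth` can only increase a
vertex's value.

**Threshold and burden.** The scar threshold is
`bp_mean + k·bp_sd` with `k = 3.3`, the blood-pool statistics taken
over the LGE values of the segmented pool after 3 mm morphological
erosion (partial-volume voxels at the rim inflate the SD; population SD,
ddof = 0). Classification is strict (`SI > threshold`, ties below).
Burden is the percentage of included shell area above threshold, with
barycentric vertex areas (one third of each incident face) accumulated
over faces whose three vertices survive vein/appendage clipping; the
included area is the denominator. Scaling all intensities by a common
factor leaves the classification unchanged; raising the threshold can
only lower the burden.

**Encirclement loops.** Each vein-pair encirclement is a closed chain of
shortest paths (Dijkstra, Euclidean edge weights) between consecutive
seed vertices — an explicit, reproducible replacement for manual
clicking. The loop must be simple; seeds must be included vertices.
Dense seeds (the phantom generator suggests one every ~2 edge lengths
along the band centreline) keep the chained path pinned to the curve:
with only a couple of edges between seeds, near-tie staircase detours
have no room to bow the path laterally.

**Corridor parameterisation.** Corridor membership is geodesic: a
multi-source Dijkstra from all path nodes on a chord-augmented graph
(mesh edges plus straight chords to the 2/3-ring neighbourhood; plain
edge-graph distances overestimate geodesics by up to ~15% from lattice
anisotropy, the augmented graph by ~1–2%), restricted to included
vertices so the corridor cannot jump across clipped holes. Each member
within `half_width` (default 5 mm) is then assigned `(s, d)` by
projecting onto a **smoothed** polyline through the path nodes
(±6-node moving average): `s` is the arc length of the projection foot,
`d` the projection distance signed by loop side (tangent × surface
normal). Two numerical facts force the smoothing and projection:
a raw mesh-edge chain zigzags laterally by up to an edge length, which
both inflates its length (~12% on an icosphere equator) and perturbs
nearest-node distances; and raw nearest-node (Voronoi) assignment lets
laterally bulging nodes capture all far members of a neighbourhood,
starving a quarter of the sectors of their band-edge members. The
smoothed curve departs from the surface only by the sagitta over the
window span (~0.2 mm at chamber curvature), and path arc length is
defined along the same smoothed chain. Path vertices are members with
`d = 0`; `|d|` is capped at `half_width`.

**Sector statistics.** The loop is cut into equal arc-length sectors
(half-open intervals anchored at the first seed; boundary ties to the
lower sector). *Width* (100 sectors): the offset extent
`max(d) − min(d)` of the above-threshold region in the sector, zero
when no member is above; the loop mean averages all 100 sectors
including zeros. By default the region edge is localised at sub-vertex
precision: along every corridor mesh edge crossing the threshold, the
linear-interpolation crossing point contributes its offset to the above
endpoint's sector — vertex-only sampling shrinks the extent by about
half the vertex spacing per side, and the interpolated crossing is the
unbiased edge estimate, exactly as an iso-contour extraction would place
it. Fully-above edges contribute both endpoints to both endpoint
sectors, which keeps every sector width non-increasing as the threshold
rises (each edge's above portion only shrinks). With
`boundary_refinement=False` the estimator is the bare vertex extent (a
single above-threshold vertex then has width 0). *Continuity* (16
sectors): a sector passes when the mean SI of all its corridor members
exceeds the threshold; the encirclement is complete when all 16 pass,
and bilateral completeness is the conjunction over both loops. An empty
continuity sector is a hard error (under-resolved mesh); a corridor
with fewer members than width sectors only warns, since a zero-width
corridor is legitimately just the path.

A consequence worth knowing: with a 5 mm half-width corridor, a
gap-free ring only classifies complete when its band fills at least
(threshold − wall)/(scar − wall) of the corridor — ≈ 52% under the
default phantom intensities, i.e. bands ≥ ~5.5 mm. Completeness is
therefore width-dependent as well as gap-dependent, and measurable
width is capped at `2·half_width`; recovery experiments on bands wider
than ~7 mm enlarge the corridor to `max(5, w/2 + 1.5)` mm so both band
edges stay inside it. This is a measurement-range requirement fixed by
geometry, not a tuning knob.

**Cohort statistics.** Continuous metrics: independent-samples t-test
(pooled by default; Welch via `variant="welch"`; summary form
`(mean, sd, n)` algebraically identical to the raw form) or
Mann-Whitney U (exact null for tie-free combined n ≤ 20, tie-corrected
normal approximation otherwise). Binary completeness: Pearson
chi-square on the 2×2 table without continuity correction (Fisher's
exact as fallback when a marginal is zero, or on request). The default
metric→test map (burden → Mann-Whitney, widths → t-test,
completeness → chi-square) is configurable. Conventions: two identical
zero-variance samples give p = 1; all-tied Mann-Whitney gives
U = n₁n₂/2, p = 1. All tests are two-sided, significance at 0.05.
scipy.stats provides the engines; the tests cross-check them against
exhaustive permutation enumeration and the 2×2 closed form.

## Synthetic phantoms

The generator emulates the imaging substrate, not MRI physics: no
inversion-recovery signal model, no Rician noise, no motion artefacts.
The chamber is an ellipsoid (default semi-axes 30 × 27 × 24 mm) with
four cylindrical vein stubs (two per side, radius 5 mm, split ±18° about
each pair axis) and an appendage stub. Compartment intensities are
Gaussian — blood pool (100, 10), wall (60, 5), scar (200, 10), plus
additive Gaussian noise — because the SD-referenced threshold contract
is exact under Gaussianity; the default threshold is therefore 133 and
scar sits ~6.7 noise SDs above it at the 10% contrast noise level used
in experiments (noise SD 10 = 10% of the scar−blood contrast).
Voxel spacing defaults to 1.25 × 1.25 × 2 mm, wall thickness 3 mm.

Scar bands are defined geodesically: per vein pair, the band centreline
is the locus at `offset` (default 8 mm) surface distance from the
ostium cluster, and the band spans `offset ± width/2` in that distance
field — the same definition the width estimator uses, which makes
parameter recovery well-posed. Gaps remove an azimuthal interval of the
band. Ground-truth completeness flags follow the gap spec: a loop is
complete unless a gap exceeds one continuity sector (22.5°); gaps
between 22.5° and 45° are alignment-dependent for the classifier, so
the guaranteed-detection experiments use ≥ 45°. In shell mode the
ostium discs are excluded from analysis (emulating clipped veins), a
requested total burden is realised exactly (to one vertex area) by
growing a compact patch on the free posterior wall, and centreline seed
vertices are exported for the loop reconstruction. In volume mode the
bands are painted into the wall by arc length beyond each pair's ostium
cone, and burden ground truth is a voxel-count approximation.

Two-group cohorts draw per-subject burden fraction, band width and
gap-free status from configurable group distributions (defaults: the
two study arms, n = 26/20, burden 6.6 ± 6.8% vs 9.6 ± 5.0%, width
7.9 ± 3.6 vs 10.7 ± 2.3 mm, gap-free probability 5/26 vs 0). Draws are
Gaussian truncated at zero — group summaries alone do not identify the
per-subject law, and the reported SDs exceeding means imply a skew the
generator does not attempt to reproduce. Two couplings are inherent:
with full annuli the band area floors the burden (~19–26% at the
default chamber for 8–11 mm bands), so drawn burdens below the floor
are clamped up to it and cohort burden is width-driven; and, as above,
narrow-band subjects classify incomplete even without a gap, so the
classified bilateral-completeness rate sits below the configured
gap-free probability. The dedicated burden-recovery phantoms avoid the
first coupling by using narrow 2 mm bands plus the area-controlled
patch. Passing tests on these phantoms show the estimators recover
known geometry under Gaussian noise; they do not certify performance on
real LGE data, where wall enhancement is heterogeneous, the blood-pool
distribution is non-Gaussian, and segmentation error dominates.

All randomness flows from a single integer seed per phantom or cohort
(`numpy.random.default_rng`); identical spec + seed is bit-identical,
and the pipeline's provenance manifest (config, seed, version, file
checksums) reproduces a run byte-for-byte.

## Problem sizes used in validation

Width recovery runs on full-size phantoms (mesh edge ≤ 0.8 mm, ~41k
vertices, 10 noise realisations per width; geometry, path and corridor
are noise-independent and reused across realisations). Recovery error
across band widths 2–12.3 mm is within ±0.3 mm noise-free and ±0.5 mm
under 10% contrast noise. Burden recovery uses 5 noisy realisations per
target. Gap classification uses 100 randomised phantoms per condition
(side, start, extent ∈ [45°, 120°], fresh noise). The cohort experiment
runs the full 26 + 20 pipeline. Unit tests use a scaled-down chamber
(20 × 18 × 16 mm, ~10k vertices) with proportionally smaller band
offsets.

## Known limitations

- Widths beyond `2·half_width` are unmeasurable by construction; the
  corridor must be widened for bands over ~7 mm.
- The width estimator is validated on annular bands of locally uniform
  width; strongly tapering lesions inherit the sector-max behaviour of
  the definition (the extent of the extremes, not an average profile).
- Volume-mode ground truth (burden, band extent) is voxel-approximate;
  exact-recovery claims apply to shell mode.
- The MRA→LGE registration step of real workflows is out of scope;
  volumes are assumed co-registered.
- Per-row test choice in the group report (t vs Mann-Whitney, pooled vs
  Welch) is a configuration, not an inference from the data; no
  multiple-testing correction is applied.
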