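"""Seeded synthetic atrial phantoms with known ground-truth scar geometry.

No imaging data accompany the analysis this package implements, so every
downstream stage is validated on phantoms: an ellipsoidal left-atrial
blood pool with four tubular pulmonary-vein ostia and an appendage stub,
a thin wall, and annular high-intensity scar bands of configurable true
width encircling each vein pair, optionally interrupted by gaps of
configurable angular extent.

Two phantom modes exist:

* volume mode — paints a bright-blood (MRA-like) and an LGE-like voxel
  volume, exercising segmentation, shell extraction, clipping and
  projection;
* shell mode — paints per-vertex signal intensity directly onto a
  triangle shell, bypassing segmentation for fast, exactly controlled
  encirclement and burden experiments.

Scar bands are defined geodesically: the band centreline is the locus at
a fixed on-surface offset from the vein-pair ostium cluster, and the true
width is the geodesic extent across the band — the same definition the
width estimator uses, which makes parameter recovery well-posed.
Intensities are Gaussian per compartment with additive Gaussian noise
(an SD-referenced threshold stays exact under Gaussianity; no Rician
model).  All randomness is driven by a single integer seed; identical
spec + seed gives bit-identical output.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from . import _surface
from .shellmap import AtrialShell, BloodPoolMask, IntensityVolume

N_CONTINUITY_SECTORS = 16  # sector count defining the completeness flags
_AIR_LGE = (10.0, 3.0)     # background intensity (mean, SD) in LGE volumes
_MRA_BLOOD = (150.0, 5.0)  # bright-blood contrast in MRA volumes
_MRA_BACKGROUND = (30.0, 5.0)
_PATCH_DIRECTION = (0.0, -0.872, -0.489)  # free posterior-inferior wall


class GeometryError(ValueError):
    """Raised when requested scar geometry cannot be realised."""


def _unit(v) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=float)
    n = np.linalg.norm(a)
    if n == 0:
        raise ValueError("zero direction vector")
    return tuple(a / n)


@dataclass(frozen=True)
class Ostium:
    """A vein or appendage ostium: outward unit direction, radius, tube length."""

    direction: tuple[float, float, float]
    radius_mm: float
    length_mm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", _unit(self.direction))
        if self.radius_mm <= 0 or self.length_mm <= 0:
            raise ValueError("ostium radius and length must be positive")


@dataclass(frozen=True)
class ScarBand:
    """Annular band around one vein pair: true full width and the geodesic
    offset of its centreline from the ostium cluster (both mm)."""

    width_mm: float
    offset_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.width_mm < 0:
            raise ValueError("band width must be non-negative")
        if self.offset_mm <= self.width_mm / 2:
            raise GeometryError(
                f"band of width {self.width_mm} mm at offset {self.offset_mm} mm "
                "would reach inside the ostium cluster (need offset > width/2)")


@dataclass(frozen=True)
class Gap:
    """Azimuthal interruption of one loop's scar band, in degrees."""

    side: str
    start_deg: float
    extent_deg: float

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("gap side must be 'left' or 'right'")
        if not (0.0 <= self.extent_deg < 360.0):
            raise ValueError("gap extent must lie in [0, 360) degrees")


def _rotate(v, axis, angle_rad):
    v = np.asarray(v, float)
    k = np.asarray(axis, float)
    k = k / np.linalg.norm(k)
    return (v * np.cos(angle_rad) + np.cross(k, v) * np.sin(angle_rad)
            + k * np.dot(k, v) * (1 - np.cos(angle_rad)))


def default_vein_ostia(radius_mm: float = 5.0, length_mm: float = 12.0,
                       split_deg: float = 18.0) -> tuple[Ostium, ...]:
    """Four pulmonary-vein ostia: a left and a right pair, each pair split
    superior/inferior about its axis."""
    ostia = []
    for axis in ((-0.97, 0.24, 0.10), (0.97, 0.24, 0.10)):
        a = np.asarray(_unit(axis))
        rot_axis = np.cross(a, (0.0, 0.0, 1.0))
        for sgn in (+1.0, -1.0):
            d = _rotate(a, rot_axis, sgn * np.deg2rad(split_deg))
            ostia.append(Ostium(tuple(d), radius_mm, length_mm))
    return tuple(ostia)


def default_appendage() -> Ostium:
    return Ostium((0.0, 0.898, 0.438), 4.0, 10.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic atrial phantom.

    Intensities are (mean, SD) pairs in arbitrary SI units.  The first
    two entries of ``vein_ostia`` form the left pair, the last two the
    right pair.  ``mesh_edge_mm`` controls shell-mode resolution (the
    icosphere subdivision level is chosen so the longest edge stays at or
    below it).
    """

    chamber_semi_axes: tuple[float, float, float] = (30.0, 27.0, 24.0)
    wall_thickness: float = 3.0
    vein_ostia: tuple[Ostium, ...] = field(default_factory=default_vein_ostia)
    appendage_ostium: Ostium = field(default_factory=default_appendage)
    blood_pool_intensity: tuple[float, float] = (100.0, 10.0)
    wall_intensity: tuple[float, float] = (60.0, 5.0)
    scar_intensity: tuple[float, float] = (200.0, 10.0)
    scar_band_left: ScarBand | None = field(default_factory=lambda: ScarBand(4.0))
    scar_band_right: ScarBand | None = field(default_factory=lambda: ScarBand(4.0))
    gaps: tuple[Gap, ...] = ()
    noise_sd: float = 0.0
    voxel_spacing: tuple[float, float, float] = (1.25, 1.25, 2.0)
    seed: int = 0
    mesh_edge_mm: float = 0.8

    def band(self, side: str) -> ScarBand | None:
        return self.scar_band_left if side == "left" else self.scar_band_right

    def validate(self, allow_subthreshold_scar: bool = False) -> None:
        if any(a <= 0 for a in self.chamber_semi_axes):
            raise ValueError("chamber semi-axes must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if self.wall_thickness < max(self.voxel_spacing):
            raise ValueError(
                "wall thickness must be at least one voxel in every axis")
        if len(self.vein_ostia) != 4:
            raise ValueError("exactly four vein ostia are required")
        if self.noise_sd < 0 or self.mesh_edge_mm <= 0:
            raise ValueError("noise SD must be >= 0 and mesh edge > 0")
        for pair in (self.blood_pool_intensity, self.wall_intensity,
                     self.scar_intensity):
            if pair[1] < 0:
                raise ValueError("intensity SDs must be non-negative")
        bp_mean, bp_sd = self.blood_pool_intensity
        if not allow_subthreshold_scar and (
                self.scar_band_left or self.scar_band_right):
            if self.scar_intensity[0] <= bp_mean + 3.3 * bp_sd:
                raise ValueError(
                    "scar mean intensity must exceed blood-pool mean + 3.3 SD "
                    "(pass allow_subthreshold_scar=True for negative tests)")
        for side in ("left", "right"):
            gaps = sorted((g for g in self.gaps if g.side == side),
                          key=lambda g: g.start_deg)
            ivals = [(g.start_deg % 360.0, g.start_deg % 360.0 + g.extent_deg)
                     for g in gaps]
            for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
                if b0 < a1 and a0 < b1:
                    raise ValueError(f"overlapping gaps on the {side} loop")


@dataclass
class GroundTruth:
    """Known truth of a phantom: what the pipeline should recover.

    ``scar_mask`` is per-voxel (volume mode) or per-vertex (shell mode).
    A loop is flagged complete when no gap wider than one continuity
    sector (360/16 = 22.5 degrees) interrupts it.  ``seed_vertices``
    (shell mode) lists vertices on each band centreline, equally spaced
    in azimuth, for use as encirclement path seeds.
    """

    scar_mask: np.ndarray
    true_burden_fraction: float
    true_width_per_loop: dict
    gap_spec: tuple[Gap, ...]
    complete_left: bool
    complete_right: bool
    complete_bilateral: bool
    mode: str = "shell"
    blood_pool_mask: np.ndarray | None = None
    seed_vertices: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_burden_fraction <= 1.0):
            raise ValueError("true burden fraction must lie in [0, 1]")
        if self.complete_bilateral != (self.complete_left and self.complete_right):
            raise ValueError("bilateral completeness must equal left AND right")


def _complete_flags(gaps) -> tuple[bool, bool, bool]:
    sector_deg = 360.0 / N_CONTINUITY_SECTORS
    left = not any(g.side == "left" and g.extent_deg > sector_deg for g in gaps)
    right = not any(g.side == "right" and g.extent_deg > sector_deg for g in gaps)
    return left, right, left and right


# ---------------------------------------------------------------------------
# shared phantom geometry (shell mode), cached across identical specs
# ---------------------------------------------------------------------------

def _surface_point(direction, semi_axes) -> np.ndarray:
    d = np.asarray(direction, float)
    a = np.asarray(semi_axes, float)
    t = 1.0 / np.sqrt(np.sum((d / a) ** 2))
    return t * d


def _pair_frame(axis) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c = np.asarray(_unit(axis))
    up = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(c, up)) > 0.95:
        up = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(c, up)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(c, e1)
    return c, e1, e2


class _ShellGeometry:
    """Mesh, ostium exclusions, per-pair geodesic and azimuth fields."""

    def __init__(self, semi_axes, vein_ostia, appendage, mesh_edge_mm):
        self.semi_axes = np.asarray(semi_axes, float)
        # smallest icosphere level whose longest edge fits under mesh_edge_mm
        # (level-4 unit icosphere max edge ~0.0826; halves per level)
        unit_edge4 = 0.0826
        need = unit_edge4 * max(semi_axes) / mesh_edge_mm
        sub = 4 + max(0, int(np.ceil(np.log2(need)))) if need > 1 else 4
        sub = min(sub, 7)
        ico = trimesh.creation.icosphere(subdivisions=sub, radius=1.0)
        self.unit_dirs = np.asarray(ico.vertices)
        self.vertices = self.unit_dirs * self.semi_axes
        self.faces = np.asarray(ico.faces)
        n = len(self.vertices)

        self.ostium_discs = []
        include = np.ones(n, dtype=bool)
        for ost in list(vein_ostia) + [appendage]:
            p = _surface_point(ost.direction, semi_axes)
            disc = np.linalg.norm(self.vertices - p, axis=1) <= ost.radius_mm
            self.ostium_discs.append(disc)
            include &= ~disc
        self.include = include

        graph = _surface.chord_graph(self.vertices, self.faces, rings=3)
        self.dist = {}
        self.azimuth = {}
        pair_axes = {}
        for side, (i, j) in (("left", (0, 1)), ("right", (2, 3))):
            cluster = self.ostium_discs[i] | self.ostium_discs[j]
            if not cluster.any():
                raise GeometryError(f"{side} ostium cluster contains no vertices")
            d, _ = _surface.surface_distance(graph, np.flatnonzero(cluster))
            self.dist[side] = d
            axis = np.asarray(vein_ostia[i].direction) + np.asarray(
                vein_ostia[j].direction)
            c, e1, e2 = _pair_frame(axis)
            pair_axes[side] = c
            w = self.unit_dirs - np.outer(self.unit_dirs @ c, c)
            self.azimuth[side] = np.degrees(
                np.arctan2(w @ e2, w @ e1)) % 360.0
        self.pair_axes = pair_axes
        self.assign = np.where(self.dist["left"] <= self.dist["right"],
                               "left", "right")
        patch_point = _surface_point(_PATCH_DIRECTION, semi_axes)
        self.patch_rank = np.linalg.norm(self.vertices - patch_point, axis=1)
        e = _surface.unique_edges(self.faces)
        self.edge_length = float(np.median(np.linalg.norm(
            self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)))


@functools.lru_cache(maxsize=8)
def _shell_geometry(semi_axes, vein_ostia, appendage, mesh_edge_mm):
    return _ShellGeometry(semi_axes, vein_ostia, appendage, mesh_edge_mm)


def _az_in_gap(az: np.ndarray, gap: Gap) -> np.ndarray:
    rel = (az - gap.start_deg) % 360.0
    return rel < gap.extent_deg


# ---------------------------------------------------------------------------
# shell-mode phantom
# ---------------------------------------------------------------------------

def generate_shell_phantom(spec: PhantomSpec, target_burden: float | None = None,
                           clamp_target_burden: bool = False,
                           allow_subthreshold_scar: bool = False
                           ) -> tuple[AtrialShell, GroundTruth]:
    """Paint per-vertex SI directly onto a triangle shell.

    Scar bands of the requested geodesic width are painted around each
    vein pair; when ``target_burden`` is given, extra scar is grown as a
    compact patch on the free posterior wall until the above-threshold
    area fraction matches it to within one vertex area.  If the bands
    alone already exceed ``target_burden`` a :class:`GeometryError` names
    the conflict (or, with ``clamp_target_burden``, the band coverage is
    accepted as-is).
    """
    spec.validate(allow_subthreshold_scar)
    geo = _shell_geometry(tuple(spec.chamber_semi_axes), tuple(spec.vein_ostia),
                          spec.appendage_ostium, spec.mesh_edge_mm)
    n = len(geo.vertices)
    include = geo.include

    scar = np.zeros(n, dtype=bool)
    widths = {}
    for side in ("left", "right"):
        band = spec.band(side)
        widths[side] = 0.0 if band is None else band.width_mm
        if band is None or band.width_mm <= 0:
            continue
        sel = (geo.assign == side) & (
            np.abs(geo.dist[side] - band.offset_mm) <= band.width_mm / 2.0)
        for gap in spec.gaps:
            if gap.side == side:
                sel &= ~_az_in_gap(geo.azimuth[side], gap)
        scar |= sel
    scar &= include

    areas = _surface.vertex_areas(
        geo.vertices, geo.faces, include[geo.faces].all(axis=1))
    total = areas[include].sum()
    if target_burden is not None:
        if not (0.0 <= target_burden <= 1.0):
            raise ValueError("target burden must lie in [0, 1]")
        band_frac = areas[scar].sum() / total
        one_tri = _surface.face_areas(geo.vertices, geo.faces).max() / total
        if band_frac > target_burden + one_tri:
            if not clamp_target_burden:
                raise GeometryError(
                    f"painted bands already cover {100 * band_frac:.2f}% of the "
                    f"shell, above the requested burden "
                    f"{100 * target_burden:.2f}%; widen the target or narrow "
                    "the bands")
        else:
            cand = np.flatnonzero(include & ~scar)
            cand = cand[np.argsort(geo.patch_rank[cand], kind="stable")]
            need = target_burden * total - areas[scar].sum()
            if need > 0:
                cum = np.cumsum(areas[cand])
                k = int(np.searchsorted(cum, need))
                # stop at whichever cut lands nearer the target area
                if k > 0 and need - cum[k - 1] < cum[min(k, len(cum) - 1)] - need:
                    k -= 1
                scar[cand[:k + 1]] = True

    rng = np.random.default_rng(spec.seed)
    si = rng.normal(spec.wall_intensity[0], spec.wall_intensity[1], n)
    scar_draw = rng.normal(spec.scar_intensity[0], spec.scar_intensity[1], n)
    si[scar] = scar_draw[scar]
    if spec.noise_sd > 0:
        si += rng.normal(0.0, spec.noise_sd, n)

    shell = AtrialShell(geo.vertices.copy(), geo.faces.copy(), si, include.copy())
    cl, cr, cb = _complete_flags(spec.gaps)
    gt = GroundTruth(
        scar_mask=scar,
        true_burden_fraction=float(areas[scar].sum() / total),
        true_width_per_loop=widths,
        gap_spec=tuple(spec.gaps),
        complete_left=cl, complete_right=cr, complete_bilateral=cb,
        mode="shell",
        seed_vertices=_centerline_seeds(geo, spec),
    )
    return shell, gt


def _centerline_seeds(geo: _ShellGeometry, spec: PhantomSpec,
                      seed_spacing_edges: float = 2.0) -> dict:
    """Vertices tracing each band centreline, ~2 edge lengths apart.

    Dense seeds keep the chained shortest-path loop pinned to the
    centreline: with only a couple of mesh edges between consecutive
    seeds, near-tie staircase detours (which bow an edge path laterally
    off a smooth curve) have no room to develop.
    """
    seeds = {}
    spacing = seed_spacing_edges * geo.edge_length
    n_bins = max(8, int(round(360.0 / np.degrees(
        spacing / (0.7 * float(np.mean(geo.semi_axes)))))))
    for side in ("left", "right"):
        band = spec.band(side)
        offset = band.offset_mm if band is not None else 8.0
        sel_side = (geo.assign == side) & geo.include
        picks = []
        half = 180.0 / n_bins
        for k in range(n_bins):
            az_c = k * 360.0 / n_bins
            rel = np.abs((geo.azimuth[side] - az_c + 180.0) % 360.0 - 180.0)
            window = sel_side & (rel <= half)
            if not window.any():
                continue
            idx = np.flatnonzero(window)
            picks.append(int(idx[np.argmin(
                np.abs(geo.dist[side][idx] - offset))]))
        # drop consecutive duplicates while keeping azimuthal order
        out = [p for i, p in enumerate(picks) if p != picks[i - 1]]
        seeds[side] = np.asarray(out, dtype=np.int64)
    return seeds


# ---------------------------------------------------------------------------
# volume-mode phantom
# ---------------------------------------------------------------------------

def generate_volume_phantom(spec: PhantomSpec
                            ) -> tuple[IntensityVolume, IntensityVolume, GroundTruth]:
    """Paint MRA-like and LGE-like voxel volumes plus ground truth.

    The blood pool is the ellipsoid united with five cylinders (four
    veins, one appendage stub); the wall is the shell of voxels within
    ``wall_thickness`` outside the pool; scar bands are painted into the
    wall at an arc-length offset from each vein-pair's ostium cone.  Both
    volumes share grid and spacing.
    """
    spec.validate()
    a = np.asarray(spec.chamber_semi_axes, float)
    ostia = list(spec.vein_ostia) + [spec.appendage_ostium]
    surface_pts = [_surface_point(o.direction, a) for o in ostia]
    tips = [p + o.length_mm * np.asarray(o.direction)
            for p, o in zip(surface_pts, ostia)]
    pad = 5.0 + spec.wall_thickness
    bound = np.maximum(a, np.max(np.abs(tips), axis=0)
                       + max(o.radius_mm for o in ostia)) + pad
    spacing = np.asarray(spec.voxel_spacing, float)
    shape = (np.ceil(2 * bound / spacing).astype(int) + 1)
    origin = -(shape - 1) / 2.0 * spacing
    grids = [origin[i] + spacing[i] * np.arange(shape[i]) for i in range(3)]
    x, y, z = np.meshgrid(*grids, indexing="ij")
    pts = np.stack([x, y, z], axis=-1)

    blood = ((x / a[0]) ** 2 + (y / a[1]) ** 2 + (z / a[2]) ** 2) <= 1.0
    for p0, o in zip(surface_pts, ostia):
        d = np.asarray(o.direction)
        base = p0 - 2.0 * d  # start inside the chamber so the tube connects
        rel = pts - base
        t = rel @ d
        radial = np.linalg.norm(rel - t[..., None] * d, axis=-1)
        blood |= (t >= 0) & (t <= o.length_mm + 2.0) & (radial <= o.radius_mm)

    from scipy import ndimage
    edt_out = ndimage.distance_transform_edt(~blood, sampling=spacing)
    wall = (~blood) & (edt_out <= spec.wall_thickness)

    # scar bands in the wall, by arc-length from each pair's ostium cone
    r = np.linalg.norm(pts, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = pts / np.where(r[..., None] > 0, r[..., None], 1.0)
    scar = np.zeros(shape, dtype=bool)
    pair_axes = {}
    phi = {}
    cone = {}
    for side, (i, j) in (("left", (0, 1)), ("right", (2, 3))):
        axis = np.asarray(ostia[i].direction) + np.asarray(ostia[j].direction)
        c, e1, e2 = _pair_frame(axis)
        pair_axes[side] = (c, e1, e2)
        phi[side] = np.arccos(np.clip(u @ c, -1.0, 1.0))
        cone[side] = max(
            float(np.arccos(np.clip(np.dot(c, ostia[k].direction), -1, 1)))
            + np.arcsin(min(1.0, ostia[k].radius_mm
                            / np.linalg.norm(surface_pts[k])))
            for k in (i, j))
    axis_gap = float(np.arccos(np.clip(
        np.dot(pair_axes["left"][0], pair_axes["right"][0]), -1, 1)))
    for side in ("left", "right"):
        band = spec.band(side)
        if band is None or band.width_mm <= 0:
            continue
        outer_angle = cone[side] + (band.offset_mm + band.width_mm / 2) / a.min()
        if outer_angle >= axis_gap / 2:
            raise GeometryError(
                f"{side} scar band (outer reach {np.degrees(outer_angle):.0f} deg) "
                "is wider than geometrically representable on this chamber")
        rho = r * (phi[side] - cone[side])  # arc length beyond the cone, mm
        sel = wall & (phi[side] <= phi["left" if side == "right" else "right"]) \
            & (np.abs(rho - band.offset_mm) <= band.width_mm / 2.0)
        if spec.gaps:
            c, e1, e2 = pair_axes[side]
            w = u - (u @ c)[..., None] * c
            az = np.degrees(np.arctan2(w @ e2, w @ e1)) % 360.0
            for gap in spec.gaps:
                if gap.side == side:
                    sel &= ~_az_in_gap(az, gap)
        scar |= sel

    rng = np.random.default_rng(spec.seed)

    def paint(regions):
        out = rng.normal(*regions[0][1], size=tuple(shape))
        for mask_r, (mu, sd) in regions[1:]:
            out[mask_r] = rng.normal(mu, sd, size=tuple(shape))[mask_r]
        return out

    lge = paint([(None, _AIR_LGE), (blood, spec.blood_pool_intensity),
                 (wall, spec.wall_intensity), (scar, spec.scar_intensity)])
    mra = paint([(None, _MRA_BACKGROUND), (blood, _MRA_BLOOD)])
    if spec.noise_sd > 0:
        lge += rng.normal(0.0, spec.noise_sd, tuple(shape))
        mra += rng.normal(0.0, spec.noise_sd, tuple(shape))

    spacing_t = tuple(float(s) for s in spacing)
    origin_t = tuple(float(o) for o in origin)
    mra_vol = IntensityVolume(mra, spacing_t, origin_t)
    lge_vol = IntensityVolume(lge, spacing_t, origin_t)
    cl, cr, cb = _complete_flags(spec.gaps)
    n_wall = int(wall.sum())
    gt = GroundTruth(
        scar_mask=scar,
        true_burden_fraction=float(scar.sum() / n_wall) if n_wall else 0.0,
        true_width_per_loop={s: (spec.band(s).width_mm if spec.band(s) else 0.0)
                             for s in ("left", "right")},
        gap_spec=tuple(spec.gaps),
        complete_left=cl, complete_right=cr, complete_bilateral=cb,
        mode="volume",
        blood_pool_mask=blood,
    )
    return mra_vol, lge_vol, gt


# ---------------------------------------------------------------------------
# two-group cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Two synthetic study arms with configurable scar-parameter distributions.

    Per-subject true burden fraction and band width are drawn from group
    Gaussians and truncated at zero; with probability
    ``completeness_probability`` a subject's rings are gap-free, otherwise
    one randomly placed gap of at least 45 degrees interrupts one loop.
    """

    n_per_group: tuple[int, int] = (26, 20)
    group_names: tuple[str, str] = ("point_by_point", "control")
    burden_distribution: tuple[tuple[float, float], tuple[float, float]] = (
        (0.066, 0.068), (0.096, 0.050))
    width_distribution: tuple[tuple[float, float], tuple[float, float]] = (
        (7.9, 3.6), (10.7, 2.3))
    completeness_probability: tuple[float, float] = (5.0 / 26.0, 0.0)
    seed: int = 0
    noise_sd: float = 10.0
    mesh_edge_mm: float = 0.8
    chamber_semi_axes: tuple[float, float, float] = (30.0, 27.0, 24.0)

    def validate(self) -> None:
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("each group needs at least one subject")
        if any(not (0.0 <= p <= 1.0) for p in self.completeness_probability):
            raise ValueError("completeness probabilities must lie in [0, 1]")
        for dist in (*self.burden_distribution, *self.width_distribution):
            if dist[1] < 0:
                raise ValueError("distribution SDs must be non-negative")


@dataclass
class CohortSubject:
    subject_id: str
    group: str
    shell: AtrialShell
    ground_truth: GroundTruth
    params: dict


def draw_cohort_parameters(spec: CohortSpec) -> list[dict]:
    """Per-subject ground-truth parameter draws (no meshes built).

    Separated from :func:`generate_cohort` so distributional properties
    of the draws can be checked cheaply at large n.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for g, (name, n) in enumerate(zip(spec.group_names, spec.n_per_group)):
        bmu, bsd = spec.burden_distribution[g]
        wmu, wsd = spec.width_distribution[g]
        pc = spec.completeness_probability[g]
        for i in range(n):
            burden = max(0.0, float(rng.normal(bmu, bsd)))
            width = max(0.0, float(rng.normal(wmu, wsd)))
            complete = bool(rng.random() < pc)
            gap = None
            if not complete:
                gap = Gap(side=("left", "right")[int(rng.integers(2))],
                          start_deg=float(rng.uniform(0.0, 360.0)),
                          extent_deg=float(rng.uniform(45.0, 120.0)))
            rows.append({
                "subject_id": f"{name}_{i:03d}",
                "group": name,
                "true_burden": min(1.0, burden),
                "true_width": width,
                "gap": gap,
                "subject_seed": int(rng.integers(2 ** 31)),
            })
    return rows


def generate_cohort(spec: CohortSpec) -> list[CohortSubject]:
    """Seeded two-group cohort of shell phantoms with known ground truth.

    With full annular bands the band area alone sets a floor on burden,
    so each subject's target burden is clamped up to its band coverage
    when the draw falls below it (burden then width-driven).
    """
    subjects = []
    for row in draw_cohort_parameters(spec):
        w = row["true_width"]
        band = ScarBand(w) if w > 0 else None
        ps = PhantomSpec(
            chamber_semi_axes=spec.chamber_semi_axes,
            scar_band_left=band, scar_band_right=band,
            gaps=(row["gap"],) if row["gap"] is not None else (),
            noise_sd=spec.noise_sd,
            seed=row["subject_seed"],
            mesh_edge_mm=spec.mesh_edge_mm,
        )
        shell, gt = generate_shell_phantom(
            ps, target_burden=row["true_burden"], clamp_target_burden=True)
        subjects.append(CohortSubject(row["subject_id"], row["group"],
                                      shell, gt, row))
    return subjects
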