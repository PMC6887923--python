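"""Parameter-recovery experiments on phantoms with known ground truth.

The study's imaging data are not public, so validation is synthetic:
phantoms are built whose true scar width, burden and gap structure are
set to the quantities of interest, the full measurement pipeline is run,
and the recovered values are compared with the truth.  These experiments
back both the acceptance test suite and ``scripts/acceptance.py``.

Phantom geometry, the encirclement path and the corridor depend only on
the chamber and band layout — not on the intensity noise — so each
experiment builds them once and re-paints intensities per noise seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .encircle import build_corridor, sector_continuity, sector_widths, \
    shortest_path_loop
from .scarquant import ScarThreshold, scar_burden
from .synthgen import CohortSpec, Gap, PhantomSpec, ScarBand, \
    generate_cohort, generate_shell_phantom

#: noise SD used across experiments: 10% of the scar/blood-pool contrast
#: of the default phantom intensities (200 vs 100).
DEFAULT_NOISE_SD = 10.0


def _default_threshold(k: float = 3.3) -> ScarThreshold:
    bp_mean, bp_sd = PhantomSpec().blood_pool_intensity
    return ScarThreshold.from_stats(bp_mean, bp_sd, k)


def recovery_half_width(width_mm: float) -> float:
    """Corridor half-width able to contain a band of the given width.

    The analysis default is 5 mm, which caps measurable width at 10 mm;
    wider bands need a corridor that still covers both band edges after
    allowing ~1.5 mm for path and mesh tolerance.
    """
    return max(5.0, width_mm / 2.0 + 1.5)


def width_recovery(width_left: float, width_right: float | None = None,
                   n_noise_seeds: int = 10, seed: int = 0,
                   noise_sd: float = DEFAULT_NOISE_SD,
                   mesh_edge_mm: float = 0.8) -> dict:
    """Estimate loop widths on phantoms painted at known true widths.

    Returns mean estimates over ``n_noise_seeds`` independent noise
    realisations (geometry fixed, intensities re-drawn).
    """
    if width_right is None:
        width_right = width_left
    thr = _default_threshold()
    base = PhantomSpec(scar_band_left=ScarBand(width_left),
                       scar_band_right=ScarBand(width_right),
                       noise_sd=noise_sd, seed=seed,
                       mesh_edge_mm=mesh_edge_mm)
    shell0, gt0 = generate_shell_phantom(base)
    corridors = {}
    for side, w in (("left", width_left), ("right", width_right)):
        path = shortest_path_loop(shell0, gt0.seed_vertices[side], side)
        corridors[side] = build_corridor(shell0, path,
                                         half_width=recovery_half_width(w))
    est = {"left": [], "right": []}
    for i in range(n_noise_seeds):
        shell, _ = generate_shell_phantom(replace(base, seed=seed + 1 + i))
        for side in ("left", "right"):
            corr = corridors[side]
            corr_i = replace(corr, si=shell.vertex_si[corr.vertex_indices])
            est[side].append(sector_widths(corr_i, thr, 100).mean_width)
    left = float(np.mean(est["left"]))
    right = float(np.mean(est["right"]))
    return {
        "true_left": width_left, "true_right": width_right,
        "estimated_left": left, "estimated_right": right,
        "estimated_total": (left + right) / 2.0,
        "n_noise_seeds": n_noise_seeds,
    }


def burden_recovery(target_burden_percent: float, noise_sd: float = 0.0,
                    n_noise_seeds: int = 5, seed: int = 0,
                    mesh_edge_mm: float = 0.8) -> dict:
    """Measure burden on phantoms painted at a known area fraction.

    Narrow 2 mm bands plus an area-controlled patch realise the exact
    target fraction; the measured burden should recover it.
    """
    thr = _default_threshold()
    vals = []
    for i in range(n_noise_seeds):
        spec = PhantomSpec(scar_band_left=ScarBand(2.0),
                           scar_band_right=ScarBand(2.0),
                           noise_sd=noise_sd, seed=seed + i,
                           mesh_edge_mm=mesh_edge_mm)
        shell, gt = generate_shell_phantom(
            spec, target_burden=target_burden_percent / 100.0)
        vals.append(scar_burden(shell, thr).burden_percent)
    return {
        "true_percent": target_burden_percent,
        "estimated_percent": float(np.mean(vals)),
        "n_noise_seeds": n_noise_seeds,
    }


def gap_classification(n_phantoms: int = 100, seed: int = 0,
                       with_gap: bool = True, band_width: float = 7.9,
                       noise_sd: float = DEFAULT_NOISE_SD,
                       mesh_edge_mm: float = 0.8) -> dict:
    """Classification rate for gapped (>= 45 deg) vs gap-free rings.

    Each phantom redraws noise and (when gapped) the gap's side, start
    and extent; the continuity verdict must match the construction.
    """
    thr = _default_threshold()
    rng = np.random.default_rng(seed)
    base = PhantomSpec(scar_band_left=ScarBand(band_width),
                       scar_band_right=ScarBand(band_width),
                       noise_sd=noise_sd, seed=seed, mesh_edge_mm=mesh_edge_mm)
    shell0, gt0 = generate_shell_phantom(base)
    corridors = {}
    for side in ("left", "right"):
        path = shortest_path_loop(shell0, gt0.seed_vertices[side], side)
        corridors[side] = build_corridor(shell0, path, half_width=5.0)
    correct = 0
    for _ in range(n_phantoms):
        gaps = ()
        gap_side = None
        if with_gap:
            gap_side = ("left", "right")[int(rng.integers(2))]
            gaps = (Gap(gap_side, float(rng.uniform(0, 360)),
                        float(rng.uniform(45.0, 120.0))),)
        spec = replace(base, gaps=gaps, seed=int(rng.integers(2 ** 31)))
        shell, _ = generate_shell_phantom(spec)
        verdicts = {}
        for side in ("left", "right"):
            corr = corridors[side]
            corr_i = replace(corr, si=shell.vertex_si[corr.vertex_indices])
            verdicts[side] = sector_continuity(corr_i, thr, 16).complete
        if with_gap:
            correct += (not verdicts[gap_side]) and \
                verdicts["left" if gap_side == "right" else "right"]
        else:
            correct += verdicts["left"] and verdicts["right"]
    return {"n_phantoms": n_phantoms, "correct": correct,
            "rate": correct / n_phantoms}


def cohort_completeness(seed: int = 0, n_per_group: tuple[int, int] = (26, 20),
                        half_width: float = 5.0) -> dict:
    """Run the cohort pipeline and report classified completeness rates."""
    from .encircle import analyze_subject
    thr = _default_threshold()
    subjects = generate_cohort(CohortSpec(n_per_group=n_per_group, seed=seed))
    counts: dict[str, list[bool]] = {}
    for subj in subjects:
        seeds = subj.ground_truth.seed_vertices
        res = analyze_subject(subj.shell, thr, seeds["left"], seeds["right"],
                              half_width=half_width)
        counts.setdefault(subj.group, []).append(res.complete_bilateral)
    return {g: {"n": len(v), "complete": int(sum(v)),
                "percent": 100.0 * sum(v) / len(v)}
            for g, v in counts.items()}
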