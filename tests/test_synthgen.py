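"""Phantom generator: determinism, ground-truth consistency, validation."""

import numpy as np
import pytest

import lascar as L
from lascar.synthgen import Gap, ScarBand


class TestSpecValidation:
    def test_rejects_nonpositive_geometry(self, small_kwargs):
        kw = dict(small_kwargs)
        kw["chamber_semi_axes"] = (20.0, -1.0, 16.0)
        with pytest.raises(ValueError, match="semi-axes"):
            L.PhantomSpec(**kw).validate()

    def test_wall_must_cover_a_voxel(self, small_kwargs):
        spec = L.PhantomSpec(wall_thickness=1.0, voxel_spacing=(1.25, 1.25, 2.0),
                             **small_kwargs)
        with pytest.raises(ValueError, match="voxel"):
            spec.validate()

    def test_subthreshold_scar_needs_explicit_opt_in(self, small_kwargs):
        spec = L.PhantomSpec(scar_intensity=(120.0, 5.0), **small_kwargs)
        with pytest.raises(ValueError, match="3.3"):
            spec.validate()
        spec.validate(allow_subthreshold_scar=True)

    def test_overlapping_gaps_rejected(self, small_kwargs):
        spec = L.PhantomSpec(gaps=(Gap("left", 10.0, 50.0),
                                   Gap("left", 40.0, 20.0)), **small_kwargs)
        with pytest.raises(ValueError, match="overlap"):
            spec.validate()
        # same azimuths on different loops are fine
        L.PhantomSpec(gaps=(Gap("left", 10.0, 50.0),
                            Gap("right", 40.0, 20.0)), **small_kwargs).validate()

    def test_gap_extent_range(self):
        with pytest.raises(ValueError):
            Gap("left", 0.0, 360.0)

    def test_band_must_clear_ostium_cluster(self):
        with pytest.raises(L.GeometryError):
            ScarBand(width_mm=10.0, offset_mm=4.0)


class TestShellPhantom:
    def test_seeded_determinism(self, small_kwargs):
        spec = L.PhantomSpec(noise_sd=8.0, seed=42, **small_kwargs)
        s1, g1 = L.generate_shell_phantom(spec)
        s2, g2 = L.generate_shell_phantom(spec)
        assert np.array_equal(s1.vertex_si, s2.vertex_si)
        assert np.array_equal(g1.scar_mask, g2.scar_mask)

    def test_threshold_recovers_painted_scar_exactly(self, thr_default,
                                                     small_kwargs):
        """Noise-free, zero-SD compartments: the 3.3 SD rule classifies
        exactly the painted vertex set."""
        spec = L.PhantomSpec(scar_band_left=ScarBand(6.0, 6.0),
                             scar_band_right=ScarBand(6.0, 6.0),
                             wall_intensity=(60.0, 0.0),
                             scar_intensity=(200.0, 0.0),
                             noise_sd=0.0, seed=1, **small_kwargs)
        shell, gt = L.generate_shell_phantom(spec)
        flags = shell.include_mask & (shell.vertex_si > thr_default.threshold)
        assert np.array_equal(flags, gt.scar_mask & shell.include_mask)

    def test_target_burden_hit_within_one_triangle(self, small_kwargs):
        spec = L.PhantomSpec(scar_band_left=ScarBand(2.0, 6.0),
                             scar_band_right=ScarBand(2.0, 6.0),
                             noise_sd=0.0, seed=3, **small_kwargs)
        shell, gt = L.generate_shell_phantom(spec, target_burden=0.096)
        from lascar._surface import face_areas
        tol = face_areas(shell.vertices, shell.faces).max() / \
            shell.total_included_area
        assert abs(gt.true_burden_fraction - 0.096) <= tol

    def test_target_burden_conflict_raises(self, small_kwargs):
        spec = L.PhantomSpec(scar_band_left=ScarBand(7.0, 6.0),
                             scar_band_right=ScarBand(7.0, 6.0),
                             noise_sd=0.0, seed=3, **small_kwargs)
        with pytest.raises(L.GeometryError, match="burden"):
            L.generate_shell_phantom(spec, target_burden=0.01)
        # clamping accepts the band coverage instead
        _, gt = L.generate_shell_phantom(spec, target_burden=0.01,
                                         clamp_target_burden=True)
        assert gt.true_burden_fraction > 0.01

    def test_completeness_flags_follow_gap_spec(self, small_kwargs):
        base = dict(scar_band_left=ScarBand(6.0, 6.0),
                    scar_band_right=ScarBand(6.0, 6.0),
                    noise_sd=0.0, seed=1, **small_kwargs)
        _, gt = L.generate_shell_phantom(L.PhantomSpec(**base))
        assert gt.complete_left and gt.complete_right and gt.complete_bilateral
        _, gt = L.generate_shell_phantom(
            L.PhantomSpec(gaps=(Gap("left", 100.0, 45.0),), **base))
        assert not gt.complete_left and gt.complete_right
        assert not gt.complete_bilateral
        # a gap narrower than one 16-sector (22.5 deg) keeps the flag
        _, gt = L.generate_shell_phantom(
            L.PhantomSpec(gaps=(Gap("right", 10.0, 20.0),), **base))
        assert gt.complete_right


class TestVolumePhantom:
    def test_seeded_determinism(self, small_volume_phantom):
        spec, mra, lge, gt = small_volume_phantom
        mra2, lge2, gt2 = L.generate_volume_phantom(spec)
        assert np.array_equal(lge.data, lge2.data)
        assert np.array_equal(mra.data, mra2.data)
        assert np.array_equal(gt.scar_mask, gt2.scar_mask)

    def test_no_scar_painted_without_bands(self):
        spec = L.PhantomSpec(chamber_semi_axes=(20.0, 20.0, 20.0),
                             scar_band_left=None, scar_band_right=None,
                             blood_pool_intensity=(100.0, 0.0),
                             wall_intensity=(60.0, 0.0), noise_sd=0.0, seed=0)
        _, lge, gt = L.generate_volume_phantom(spec)
        assert gt.scar_mask.sum() == 0
        # degenerate threshold mean_bp + 3.3*0: nothing in the volume above
        # it except nothing — wall and air sit below the blood mean
        assert not np.any(lge.data > 100.0 + 3.3 * 0.0 + 1e-9)

    def test_painted_band_extent_matches_width(self, small_volume_phantom):
        """Brute-force voxel scan: arc extent of the painted band across
        its centreline equals the requested 4 mm within a voxel diagonal."""
        spec, _, _, gt = small_volume_phantom
        a = 20.0
        scar_idx = np.argwhere(gt.scar_mask)
        spacing = np.asarray(spec.voxel_spacing)
        origin = -(np.asarray(gt.scar_mask.shape) - 1) / 2.0 * spacing
        pts = origin + scar_idx * spacing
        r = np.linalg.norm(pts, axis=1)
        diag = float(np.linalg.norm(spacing))
        # left pair: arc-length coordinate of each scar voxel beyond the cone
        ostia = spec.vein_ostia
        axis = np.asarray(ostia[0].direction) + np.asarray(ostia[1].direction)
        axis /= np.linalg.norm(axis)
        phi = np.arccos(np.clip(pts @ axis / r, -1, 1))
        cone = max(np.arccos(np.clip(np.dot(axis, o.direction), -1, 1))
                   + np.arcsin(o.radius_mm / a) for o in ostia[:2])
        rho = r * (phi - cone)
        left = phi < np.pi / 2
        extent = rho[left].max() - rho[left].min()
        assert extent == pytest.approx(4.0, abs=diag)

    def test_band_too_wide_raises(self):
        spec = L.PhantomSpec(chamber_semi_axes=(20.0, 20.0, 20.0),
                             scar_band_left=ScarBand(30.0, 16.0), noise_sd=0.0)
        with pytest.raises(L.GeometryError, match="wider"):
            L.generate_volume_phantom(spec)

    def test_volumes_share_grid(self, small_volume_phantom):
        _, mra, lge, _ = small_volume_phantom
        assert mra.shape == lge.shape
        assert mra.spacing == lge.spacing
        assert mra.origin == lge.origin


class TestCohort:
    def test_group_sizes_and_labels(self):
        rows = L.draw_cohort_parameters(L.CohortSpec(n_per_group=(26, 20),
                                                     seed=5))
        assert len(rows) == 46
        assert sum(r["group"] == "point_by_point" for r in rows) == 26
        assert sum(r["group"] == "control" for r in rows) == 20

    def test_zero_sd_gives_identical_truth_within_group(self, small_kwargs):
        spec = L.CohortSpec(n_per_group=(3, 2),
                            burden_distribution=((0.15, 0.0), (0.2, 0.0)),
                            width_distribution=((6.0, 0.0), (7.0, 0.0)),
                            completeness_probability=(1.0, 1.0), seed=9,
                            mesh_edge_mm=small_kwargs["mesh_edge_mm"],
                            chamber_semi_axes=small_kwargs["chamber_semi_axes"])
        subs = L.generate_cohort(spec)
        g1 = [s for s in subs if s.group == "point_by_point"]
        assert all(s.ground_truth.true_width_per_loop ==
                   g1[0].ground_truth.true_width_per_loop for s in g1)
        assert all(abs(s.ground_truth.true_burden_fraction -
                       g1[0].ground_truth.true_burden_fraction) < 1e-12
                   for s in g1)

    def test_drawn_width_mean_obeys_law_of_large_numbers(self):
        """Sample mean of 200 width draws at (10.7, 2.3) within 3 SEM."""
        spec = L.CohortSpec(n_per_group=(200, 1),
                            width_distribution=((10.7, 2.3), (10.7, 2.3)),
                            seed=17)
        rows = L.draw_cohort_parameters(spec)
        w = np.array([r["true_width"] for r in rows if r["group"] ==
                      "point_by_point"])
        sem = 2.3 / np.sqrt(200)
        assert abs(w.mean() - 10.7) <= 3 * sem

    def test_cohort_determinism(self):
        spec = L.CohortSpec(n_per_group=(4, 4), seed=3)
        a = L.draw_cohort_parameters(spec)
        b = L.draw_cohort_parameters(spec)
        assert a == b
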