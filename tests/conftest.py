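"""Shared fixtures: scaled-down phantoms and simple analytic meshes.

Unit tests run on a small chamber (20 x 18 x 16 mm semi-axes, ~10k
vertices) so the whole suite stays fast; the acceptance tests use the
full-size defaults.
"""

import numpy as np
import pytest
import trimesh

import lascar as L


SMALL_KWARGS = dict(
    chamber_semi_axes=(20.0, 18.0, 16.0),
    mesh_edge_mm=0.9,
    appendage_ostium=L.Ostium((0.0, 0.7, -0.714), 3.5, 8.0),
)


@pytest.fixture(scope="session")
def small_kwargs():
    return dict(SMALL_KWARGS)


@pytest.fixture(scope="session")
def thr_default():
    """Phantom blood pool is N(100, 10); threshold 100 + 3.3*10 = 133."""
    return L.ScarThreshold.from_stats(100.0, 10.0, 3.3)


@pytest.fixture(scope="session")
def small_ring_phantom():
    """Noise-free small phantom with 6.5 mm bands at 6 mm offset."""
    spec = L.PhantomSpec(scar_band_left=L.ScarBand(6.5, 6.0),
                         scar_band_right=L.ScarBand(6.5, 6.0),
                         noise_sd=0.0, seed=1, **SMALL_KWARGS)
    shell, gt = L.generate_shell_phantom(spec)
    return spec, shell, gt


@pytest.fixture(scope="session")
def small_volume_phantom():
    """Noise-free small volume phantom (spherical chamber for analytics)."""
    spec = L.PhantomSpec(chamber_semi_axes=(20.0, 20.0, 20.0),
                         scar_band_left=L.ScarBand(4.0, 8.0),
                         scar_band_right=L.ScarBand(4.0, 8.0),
                         noise_sd=0.0, seed=2)
    mra, lge, gt = L.generate_volume_phantom(spec)
    return spec, mra, lge, gt


def sphere_shell(radius=20.0, subdivisions=4, si=None):
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return L.AtrialShell(np.asarray(m.vertices), np.asarray(m.faces),
                         vertex_si=si)


@pytest.fixture
def sphere20():
    return sphere_shell(20.0, 4)


def flat_strip(nx=41, ny=25, spacing=1.0):
    """Planar z=0 grid mesh for exact-geometry oracles."""
    xs, ys = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing,
                         indexing="ij")
    verts = np.stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)], axis=1)
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return verts, np.asarray(faces, dtype=np.int64)
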