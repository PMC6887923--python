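"""Geodesic distance and area primitives on triangle surface meshes.

All public pipeline stages that need on-surface distances (scar band
painting, encirclement corridors) go through :func:`surface_distance`,
which runs a multi-source Dijkstra on a chord-augmented edge graph.
Plain edge-graph Dijkstra systematically overestimates geodesic length
on a roughly hexagonal vertex lattice (worst case ~15% when the true
geodesic runs between lattice directions); adding straight-line chords
to the 2- and 3-ring neighbourhoods brings the anisotropy error down to
~1-2%, which is what the sub-millimetre width tolerances downstream
require.  Chords are straight 3D segments; at the few-millimetre scale
of a ring neighbourhood their shortfall versus the true surface arc is
negligible for chamber-scale curvature radii.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra


def unique_edges(faces: np.ndarray) -> np.ndarray:
    """Undirected unique vertex-index pairs (E, 2) of a triangulation."""
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


def edge_graph(vertices: np.ndarray, faces: np.ndarray,
               include: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse symmetric graph of mesh edges weighted by Euclidean length.

    When ``include`` is given, edges with an excluded endpoint are dropped,
    so shortest paths cannot cross clipped regions.
    """
    n = len(vertices)
    e = unique_edges(faces)
    if include is not None:
        keep = include[e[:, 0]] & include[e[:, 1]]
        e = e[keep]
    w = np.linalg.norm(vertices[e[:, 0]] - vertices[e[:, 1]], axis=1)
    g = sp.csr_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n))
    return g + g.T


def chord_graph(vertices: np.ndarray, faces: np.ndarray, rings: int = 3,
                include: np.ndarray | None = None) -> sp.csr_matrix:
    """Edge graph augmented with straight chords to the k-ring neighbourhood."""
    n = len(vertices)
    e = unique_edges(faces)
    if include is not None:
        keep = include[e[:, 0]] & include[e[:, 1]]
        e = e[keep]
    ones = np.ones(len(e))
    a = sp.csr_matrix((ones, (e[:, 0], e[:, 1])), shape=(n, n))
    a = a + a.T
    a.data[:] = 1.0
    reach = a.copy()
    power = a.copy()
    for _ in range(rings - 1):
        power = (power @ a).tocsr()
        power.data[:] = 1.0
        reach = reach + power
    reach = sp.triu(reach.tocoo(), k=1).tocoo()
    i, j = reach.row, reach.col
    w = np.linalg.norm(vertices[i] - vertices[j], axis=1)
    g = sp.csr_matrix((w, (i, j)), shape=(n, n))
    return g + g.T


def surface_distance(graph: sp.csr_matrix, sources: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Multi-source shortest-path distance to every vertex.

    Returns ``(dist, nearest_source)`` where ``nearest_source[v]`` is the
    source vertex index realising ``dist[v]`` (-9999 where unreachable).
    """
    sources = np.asarray(sources, dtype=np.intp)
    dist, _, src = dijkstra(graph, directed=False, indices=sources,
                            min_only=True, return_predecessors=True)
    return dist, src


def face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a = vertices[faces[:, 1]] - vertices[faces[:, 0]]
    b = vertices[faces[:, 2]] - vertices[faces[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def vertex_areas(vertices: np.ndarray, faces: np.ndarray,
                 face_mask: np.ndarray | None = None) -> np.ndarray:
    """Barycentric vertex areas: one third of each incident face's area.

    ``face_mask`` restricts the accumulation to a subset of faces (used
    after clipping so burden denominators only count retained surface).
    Sums to the (masked) total surface area exactly.
    """
    fa = face_areas(vertices, faces)
    if face_mask is not None:
        fa = np.where(face_mask, fa, 0.0)
    va = np.zeros(len(vertices))
    for k in range(3):
        np.add.at(va, faces[:, k], fa / 3.0)
    return va
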