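"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import Voronoi

from flysocial.core import ArenaSpec, Configuration, FlyRecord


@pytest.fixture(scope="session")
def arena() -> ArenaSpec:
    return ArenaSpec()


@pytest.fixture
def point_config(arena):
    """Factory: a configuration of point-like flies at given positions."""

    def make(points, body=0.4, arena_=None) -> Configuration:
        a = arena_ or arena
        return Configuration(
            a,
            [
                FlyRecord(i, float(x), float(y), body, body, 0.0)
                for i, (x, y) in enumerate(points)
            ],
        )

    return make


def _segment_distance_to_point(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    ab = b - a
    t = np.clip(-((a - c) @ ab) / (ab @ ab), 0.0, 1.0)
    return float(np.hypot(*(a + t * ab - c)))


def arena_delaunay_edges(points: np.ndarray, arena: ArenaSpec) -> set[tuple[int, int]]:
    """Independent contiguity oracle: Delaunay neighbours whose shared
    Voronoi ridge intersects the arena disc (brute-force geometry on the
    scipy Voronoi diagram)."""
    pts = np.asarray(points, dtype=float)
    vor = Voronoi(pts)
    centre = np.asarray(arena.centre, dtype=float)
    edges: set[tuple[int, int]] = set()
    for (i, j), rv in zip(vor.ridge_points, vor.ridge_vertices):
        rv = list(rv)
        if -1 in rv:
            v = vor.vertices[rv[1 - rv.index(-1)]]
            t = pts[j] - pts[i]
            t = t / np.hypot(*t)
            n = np.array([-t[1], t[0]])
            mid = (pts[i] + pts[j]) / 2.0
            if (mid - pts.mean(axis=0)) @ n < 0:
                n = -n
            a, b = v, v + n * 1e4
        else:
            a, b = vor.vertices[rv[0]], vor.vertices[rv[1]]
        if _segment_distance_to_point(np.asarray(a), np.asarray(b), centre) <= arena.radius:
            edges.add((int(min(i, j)), int(max(i, j))))
    return edges


def contiguity_agreement(tess, points: np.ndarray, arena: ArenaSpec) -> float:
    """Fraction of agreeing edges between a tessellation's contiguity graph
    and the arena-restricted Delaunay oracle."""
    got = {tuple(sorted(e)) for e in tess.contiguity.edges}
    want = arena_delaunay_edges(points, arena)
    return len(got & want) / max(len(got), len(want))
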