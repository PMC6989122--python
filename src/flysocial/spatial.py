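"""Point statistics of aggregation.

Distances are centre-to-centre throughout.  The social space index (SSI)
summarises a group's nearest-neighbour distance (NND) histogram built in
5 mm bins: SSI = (% of flies with NND in [0, 5)) − (% in [5, 10)).

Surrounding-fly profiles superimpose every fly in turn as the reference at
the origin (translation only) and pool the others across flies and arenas.
Because a reference near the dish wall sees part of each annulus outside
the arena, counts are adjusted by the ratio of the full annulus area to
the in-arena annulus area; the in-arena area comes from the closed-form
circle–circle intersection ("lens") between the arena disc and the
measuring circle centred on the reference fly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ArenaSpec, Configuration, InputError, pairwise_distances

__all__ = [
    "DistanceMatrix",
    "NeighborSummary",
    "SSIResult",
    "RadialProfile",
    "distance_matrix",
    "neighbor_summary",
    "social_space_index",
    "lens_area",
    "surround_profiles",
]

SSI_BIN_EDGES = (0.0, 5.0, 10.0, 15.0)  # mm, half-open bins


@dataclass
class DistanceMatrix:
    ids: list[int]
    d: np.ndarray  # (n, n), mm


@dataclass
class NeighborSummary:
    nnd: dict[int, float]
    nearest_id: dict[int, int]
    sorted_nnds: np.ndarray
    mean_nnd: float
    multi_neighbor_mean: dict[int, float]  # k -> mean distance to k nearest


@dataclass
class SSIResult:
    bin_percents: tuple[float, float, float]  # [0,5), [5,10), [10,15) mm
    ssi: float


@dataclass
class RadialProfile:
    bin_edges: np.ndarray
    raw_count: np.ndarray
    adjusted_count: np.ndarray
    density: np.ndarray  # cumulative count / cumulative in-arena area
    n_reference: int


def distance_matrix(config: Configuration) -> DistanceMatrix:
    """All centre-to-centre distances in one arena."""
    if len(config) < 2:
        raise InputError("distance matrix needs at least 2 flies")
    ids = config.ids()
    if len(set(ids)) != len(ids):
        raise InputError("duplicate fly ids")
    return DistanceMatrix(ids=ids, d=pairwise_distances(config.positions()))


def neighbor_summary(dm: DistanceMatrix, k_max: int = 8) -> NeighborSummary:
    """Per-fly NND and nearest neighbour (ties to the lower id), plus mean
    multi-neighbour distances: for each k, the mean distance to the k
    nearest neighbours, averaged over flies."""
    n = len(dm.ids)
    if k_max >= n:
        raise InputError(f"k_max={k_max} must be below the number of flies ({n})")
    d = dm.d.copy()
    np.fill_diagonal(d, np.inf)
    # argmin breaks ties by first (lowest) index; ids are in ascending order
    # only if the caller ordered them so — resolve ties on the id value
    nnd, nearest = {}, {}
    for i, fid in enumerate(dm.ids):
        row = d[i]
        m = row.min()
        cand = [dm.ids[j] for j in np.nonzero(row == m)[0]]
        nnd[fid] = float(m)
        nearest[fid] = min(cand)
    srt = np.sort(d, axis=1)  # row-wise ascending neighbour distances
    multi = {
        k: float(np.mean(srt[:, :k].mean(axis=1))) for k in range(1, k_max + 1)
    }
    nnds = np.sort(np.array(list(nnd.values())))
    return NeighborSummary(
        nnd=nnd,
        nearest_id=nearest,
        sorted_nnds=nnds,
        mean_nnd=float(nnds.mean()),
        multi_neighbor_mean=multi,
    )


def social_space_index(ns: NeighborSummary) -> SSIResult:
    """SSI = %NND in [0,5) − %NND in [5,10)."""
    vals = np.array(list(ns.nnd.values()))
    n = vals.size
    percents = tuple(
        float(
            100.0
            * np.count_nonzero((vals >= SSI_BIN_EDGES[k]) & (vals < SSI_BIN_EDGES[k + 1]))
            / n
        )
        for k in range(3)
    )
    return SSIResult(bin_percents=percents, ssi=percents[0] - percents[1])


def lens_area(dist_to_centre: float, rho: float, arena: ArenaSpec = ArenaSpec()) -> float:
    """Area of the intersection between the arena disc (radius R) and a
    circle of radius ``rho`` centred ``dist_to_centre`` from the arena
    centre (the reference fly's position).  Closed form.
    """
    R = arena.radius
    d = float(dist_to_centre)
    r = float(rho)
    if d < 0 or d > R:
        raise InputError("reference fly must lie inside the arena")
    if r < 0:
        raise InputError("rho must be >= 0")
    if r == 0:
        return 0.0
    if d + r <= R:  # measuring circle fully inside the arena
        return float(np.pi * r * r)
    if d + R <= r:  # arena fully covered
        return float(np.pi * R * R)
    # standard two-circle lens
    alpha = np.arccos(np.clip((d * d + r * r - R * R) / (2 * d * r), -1.0, 1.0))
    beta = np.arccos(np.clip((d * d + R * R - r * r) / (2 * d * R), -1.0, 1.0))
    return float(
        r * r * (alpha - np.sin(2 * alpha) / 2) + R * R * (beta - np.sin(2 * beta) / 2)
    )


def surround_profiles(
    configs: list[Configuration],
    bin_width: float = 1.0,
    max_distance: float | None = None,
) -> RadialProfile:
    """Merged surrounding-fly distribution over all reference flies.

    Every fly of every arena serves once as the reference; all other flies
    are translated so the reference sits at the origin (no rotation) and
    pooled.  ``raw_count`` is the pooled per-annulus count;
    ``adjusted_count`` multiplies each reference's contribution by full /
    in-arena annulus area; ``density`` is the across-reference mean of
    cumulative count over cumulative in-arena area at each outer edge.
    """
    if bin_width <= 0:
        raise InputError("bin_width must be positive")
    if not configs:
        raise InputError("need at least one configuration")
    for cfg in configs:
        if len(cfg) < 2:
            raise InputError("every configuration needs at least 2 flies")
    if max_distance is None:
        max_distance = 2 * max(cfg.arena.radius for cfg in configs)
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    n_bins = len(edges) - 1
    raw = np.zeros(n_bins)
    adjusted = np.zeros(n_bins)
    cum_density = np.zeros(n_bins)
    n_ref = 0
    for cfg in configs:
        pos = cfg.positions()
        dmat = pairwise_distances(pos)
        centre = np.asarray(cfg.arena.centre)
        d_centre = np.hypot(*(pos - centre).T)
        for i in range(len(cfg)):
            others = np.delete(dmat[i], i)
            counts, _ = np.histogram(others, bins=edges)
            raw += counts
            lens = np.array(
                [lens_area(d_centre[i], e, cfg.arena) for e in edges]
            )
            in_area = np.diff(lens)
            full_area = np.pi * np.diff(edges**2)
            with np.errstate(divide="ignore", invalid="ignore"):
                w = np.where(in_area > 0, full_area / in_area, 0.0)
            adjusted += counts * w
            cum = np.cumsum(counts)
            with np.errstate(divide="ignore", invalid="ignore"):
                dens_i = np.where(lens[1:] > 0, cum / lens[1:], 0.0)
            cum_density += dens_i
            n_ref += 1
    return RadialProfile(
        bin_edges=edges,
        raw_count=raw,
        adjusted_count=adjusted,
        density=cum_density / n_ref,
        n_reference=n_ref,
    )
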