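"""Residing-area tessellation and graded cluster reconstruction.

The arena interior is partitioned into one "residing area" per fly: each
interior pixel is assigned to the fly whose body silhouette is nearest
(the generalised Voronoi diagram of the silhouettes, computed with a
distance transform).  Two flies are contiguous neighbours when their
residing areas share a border.  Clusters are then reconstructed under one
of five criterial sets (CSC 1–5), each derived from a Stringent Factor SF:

    unit_area          = pi * R^2 / N
    unit_distance      = 2 * R / sqrt(N)
    area_threshold     = unit_area * SF
    distance_threshold = unit_distance * sqrt(0.5 * SF)

A basic cluster is a contiguity-connected component of flies whose
residing areas fall below the area threshold; nearby flies are then folded
in, to a fixpoint, whenever their centre-to-centre distance to any current
member is below the distance threshold.  Members are insiders when every
contiguous neighbour belongs to the same cluster and their residing area
does not touch the arena edge, otherwise outsiders.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage

from .core import (
    AmbiguousSilhouetteError,
    ArenaSpec,
    Configuration,
    InputError,
    pairwise_distances,
)

__all__ = [
    "STRINGENT_FACTORS",
    "Tessellation",
    "ClusterCriteria",
    "ClusterResult",
    "ClusterMetrics",
    "compute_residing_areas",
    "csc_criteria",
    "reconstruct_clusters",
    "cluster_metrics",
    "dcn_below_median",
]

#: the five Stringent Factors, most stringent (CSC 1) to most relaxed (CSC 5)
STRINGENT_FACTORS = (0.25, 0.302, 0.423, 0.49, 0.723)


@dataclass
class Tessellation:
    residing_area: dict[int, float]  # fly_id -> mm^2
    label_image: np.ndarray  # 0 outside the arena, else fly label index + 1
    ids: list[int]  # label index -> fly_id
    contiguity: nx.Graph  # nodes are fly_ids, edges = shared borders
    touches_edge: dict[int, bool]
    px_per_mm: float
    masked_area: float  # mm^2


def _rasterise_silhouettes(
    config: Configuration, px_per_mm: float
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Paint each fly's body ellipse into an int32 label image (fly order);
    returns (labels, arena mask, origin in mm)."""
    arena = config.arena
    size = int(np.ceil(2 * arena.radius * px_per_mm))
    ox = arena.centre[0] - arena.radius
    oy = arena.centre[1] - arena.radius
    labels = np.zeros((size, size), dtype=np.int32)
    cols = (np.arange(size) + 0.5) / px_per_mm + ox
    rows = (np.arange(size) + 0.5) / px_per_mm + oy
    gx, gy = np.meshgrid(cols, rows)
    mask = np.hypot(gx - arena.centre[0], gy - arena.centre[1]) <= arena.radius
    overlap_ids: set[int] = set()
    for k, fly in enumerate(config.flies, start=1):
        a, b = fly.length / 2.0, fly.width / 2.0
        pad = a + 2.0 / px_per_mm
        c0 = max(0, int((fly.x - ox - pad) * px_per_mm))
        c1 = min(size, int(np.ceil((fly.x - ox + pad) * px_per_mm)) + 1)
        r0 = max(0, int((fly.y - oy - pad) * px_per_mm))
        r1 = min(size, int(np.ceil((fly.y - oy + pad) * px_per_mm)) + 1)
        xs = cols[c0:c1] - fly.x
        ys = rows[r0:r1] - fly.y
        sx, sy = np.meshgrid(xs, ys)
        th = np.deg2rad(fly.orientation)
        u = sx * np.cos(th) + sy * np.sin(th)
        v = -sx * np.sin(th) + sy * np.cos(th)
        inside = ((u / a) ** 2 + (v / b) ** 2 <= 1.0) & mask[r0:r1, c0:c1]
        if not inside.any():
            # sub-pixel fly: paint the pixel nearest its centre
            rr = min(size - 1, max(0, int((fly.y - oy) * px_per_mm)))
            cc = min(size - 1, max(0, int((fly.x - ox) * px_per_mm)))
            inside = np.zeros_like(inside)
            patch = labels[r0:r1, c0:c1]
            if not (r0 <= rr < r1 and c0 <= cc < c1):
                r0, r1, c0, c1 = rr, rr + 1, cc, cc + 1
                inside = np.ones((1, 1), dtype=bool)
            else:
                inside[rr - r0, cc - c0] = True
        patch = labels[r0:r1, c0:c1]
        clash = inside & (patch > 0)
        if clash.any():
            prev = np.unique(patch[clash])
            overlap_ids.update(config.flies[p - 1].fly_id for p in prev)
            overlap_ids.add(fly.fly_id)
        patch[inside] = k
    if overlap_ids:
        raise AmbiguousSilhouetteError(
            f"fly silhouettes overlap at {px_per_mm} px/mm", sorted(overlap_ids)
        )
    return labels, mask, (ox, oy)


def compute_residing_areas(
    config: Configuration,
    px_per_mm: float = 10.0,
    mask: np.ndarray | None = None,
) -> Tessellation:
    """Partition the arena interior into per-fly residing areas.

    Every interior pixel joins the fly whose silhouette is nearest
    (distance-transform label propagation); contiguity links flies whose
    regions share a border (8-neighbour); ``touches_edge`` marks regions
    reaching the arena rim.  An optional boolean ``mask`` overrides the
    default full-disc arena mask.
    """
    if len(config) < 2:
        raise InputError("tessellation needs at least 2 flies")
    labels, arena_mask, _ = _rasterise_silhouettes(config, px_per_mm)
    if mask is not None:
        if mask.shape != arena_mask.shape:
            raise InputError("mask shape does not match the rasterised arena")
        arena_mask = arena_mask & mask.astype(bool)
    # nearest-silhouette assignment
    _, (ir, ic) = ndimage.distance_transform_edt(labels == 0, return_indices=True)
    assigned = labels[ir, ic]
    assigned[~arena_mask] = 0

    ids = [f.fly_id for f in config.flies]
    counts = np.bincount(assigned.ravel(), minlength=len(ids) + 1)
    area = {ids[k - 1]: counts[k] / px_per_mm**2 for k in range(1, len(ids) + 1)}

    contiguity = nx.Graph()
    contiguity.add_nodes_from(ids)
    H, W = assigned.shape
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):  # 8-neighbour adjacency
        r0, r1 = max(0, -dr), H - max(0, dr)
        c0, c1 = max(0, -dc), W - max(0, dc)
        a = assigned[r0:r1, c0:c1]
        b = assigned[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        both = (a > 0) & (b > 0) & (a != b)
        pairs = np.unique(
            np.sort(np.stack([a[both], b[both]]), axis=0), axis=1
        )
        for p, q in pairs.T:
            contiguity.add_edge(ids[p - 1], ids[q - 1])

    eroded = ndimage.binary_erosion(arena_mask)
    ring = arena_mask & ~eroded
    edge_labels = set(np.unique(assigned[ring])) - {0}
    touches = {ids[k - 1]: (k in edge_labels) for k in range(1, len(ids) + 1)}

    return Tessellation(
        residing_area=area,
        label_image=assigned,
        ids=ids,
        contiguity=contiguity,
        touches_edge=touches,
        px_per_mm=px_per_mm,
        masked_area=float(arena_mask.sum()) / px_per_mm**2,
    )


@dataclass(frozen=True)
class ClusterCriteria:
    stringent_factor: float
    unit_area: float
    unit_distance: float
    area_threshold: float
    distance_threshold: float
    csc_index: int


def csc_criteria(n_flies: int, arena: ArenaSpec, csc_index: int) -> ClusterCriteria:
    """Thresholds of criterial set ``csc_index`` (1 = most stringent,
    5 = most relaxed) for ``n_flies`` flies in the given arena."""
    if n_flies < 1:
        raise InputError("n_flies must be >= 1")
    if not 1 <= csc_index <= 5:
        raise InputError("csc_index must be in 1..5")
    sf = STRINGENT_FACTORS[csc_index - 1]
    unit_area = arena.area / n_flies
    unit_distance = 2.0 * arena.radius / np.sqrt(n_flies)
    return ClusterCriteria(
        stringent_factor=sf,
        unit_area=unit_area,
        unit_distance=unit_distance,
        area_threshold=unit_area * sf,
        distance_threshold=unit_distance * np.sqrt(0.5 * sf),
        csc_index=csc_index,
    )


@dataclass
class ClusterResult:
    clusters: list[set[int]]
    role: dict[int, str]  # insider | outsider | unclustered
    links: list[tuple[int, int, float]]  # contiguous same-cluster edges, mm
    criteria: ClusterCriteria | None = None


def reconstruct_clusters(
    tess: Tessellation,
    config: Configuration,
    criteria: ClusterCriteria,
    min_cluster_size: int = 5,
) -> ClusterResult:
    """Reconstruct clusters under one criterial set.

    Basic clusters are contiguity-connected components of flies whose
    residing area is below the area threshold; the expansion loop then
    repeatedly adds any fly whose centre-to-centre distance to a current
    member is below the distance threshold (a fly reachable from several
    clusters joins the one with the nearest member, ties to the lower
    cluster label).  Clusters smaller than ``min_cluster_size`` are
    discarded at the end.
    """
    ids = config.ids()
    if set(ids) != set(tess.ids):
        raise InputError("tessellation and configuration have different flies")
    pos = {f.fly_id: (f.x, f.y) for f in config.flies}
    dmat = pairwise_distances(config.positions())
    idx = {fid: k for k, fid in enumerate(ids)}

    basic = [fid for fid in ids if tess.residing_area[fid] < criteria.area_threshold]
    sub = tess.contiguity.subgraph(basic)
    components = sorted(
        (sorted(c) for c in nx.connected_components(sub)), key=lambda c: c[0]
    )
    clusters: list[set[int]] = [set(c) for c in components]

    # expansion to fixpoint
    while True:
        assigned = set().union(*clusters) if clusters else set()
        additions: list[tuple[int, int]] = []  # (fly, cluster label)
        for fid in ids:
            if fid in assigned:
                continue
            best = None
            for lab, members in enumerate(clusters):
                dmin = min(dmat[idx[fid], idx[m]] for m in members)
                if dmin < criteria.distance_threshold:
                    if best is None or dmin < best[0] - 1e-12:
                        best = (dmin, lab)
            if best is not None:
                additions.append((fid, best[1]))
        if not additions:
            break
        for fid, lab in additions:
            clusters[lab].add(fid)

    clusters = [c for c in clusters if len(c) >= min_cluster_size]
    clusters.sort(key=lambda c: min(c))

    member_of: dict[int, int] = {}
    for lab, c in enumerate(clusters):
        for fid in c:
            member_of[fid] = lab
    role: dict[int, str] = {}
    links: list[tuple[int, int, float]] = []
    for fid in ids:
        if fid not in member_of:
            role[fid] = "unclustered"
            continue
        cl = clusters[member_of[fid]]
        nbrs = list(tess.contiguity.neighbors(fid))
        inside = (not tess.touches_edge[fid]) and all(nb in cl for nb in nbrs)
        role[fid] = "insider" if inside else "outsider"
    seen = set()
    for lab, c in enumerate(clusters):
        for fid in sorted(c):
            for nb in tess.contiguity.neighbors(fid):
                if nb in c and (min(fid, nb), max(fid, nb)) not in seen:
                    seen.add((min(fid, nb), max(fid, nb)))
                    links.append(
                        (fid, nb, float(dmat[idx[fid], idx[nb]]))
                    )
    return ClusterResult(clusters=clusters, role=role, links=links, criteria=criteria)


@dataclass
class ClusterMetrics:
    ct_percent: float
    it_percent: float
    arena_has_cluster: bool
    insider_connectivity: float | None  # mean contiguous links per insider
    insider_link_length: float | None  # mean link length over insiders, mm
    dcn_sd_per_inner_fly: dict[int, float] = field(default_factory=dict)


def cluster_metrics(
    result: ClusterResult, tess: Tessellation, config: Configuration
) -> ClusterMetrics:
    """Arena-level summary of one reconstruction.

    CT/IT are the percentages of clustered flies and insiders out of all
    flies; connectivity and link length are averaged over insiders only
    (outsiders vary too much to be comparable); the DCN spread (standard
    deviation of a fly's distances to its contiguous neighbours) is
    reported per inner fly, i.e. every fly whose residing area does not
    touch the arena edge.
    """
    n = len(config)
    ids = config.ids()
    dmat = pairwise_distances(config.positions())
    idx = {fid: k for k, fid in enumerate(ids)}
    clustered = [fid for fid in ids if result.role[fid] != "unclustered"]
    insiders = [fid for fid in ids if result.role[fid] == "insider"]
    if insiders:
        degs = [tess.contiguity.degree(fid) for fid in insiders]
        lengths = [
            dmat[idx[fid], idx[nb]]
            for fid in insiders
            for nb in tess.contiguity.neighbors(fid)
        ]
        connectivity = float(np.mean(degs))
        link_length = float(np.mean(lengths))
    else:
        connectivity = None
        link_length = None
    dcn = {}
    for fid in ids:
        if tess.touches_edge[fid]:
            continue
        nbrs = list(tess.contiguity.neighbors(fid))
        if len(nbrs) >= 2:
            dists = [dmat[idx[fid], idx[nb]] for nb in nbrs]
            dcn[fid] = float(np.std(dists))
    return ClusterMetrics(
        ct_percent=100.0 * len(clustered) / n,
        it_percent=100.0 * len(insiders) / n,
        arena_has_cluster=bool(result.clusters),
        insider_connectivity=connectivity,
        insider_link_length=link_length,
        dcn_sd_per_inner_fly=dcn,
    )


def dcn_below_median(dcn_map: dict[int, float]) -> dict[int, float]:
    """Secondary filter for arena-level spacing-regularity summaries: keep
    the inner flies whose DCN spread lies below the arena median (these are
    the flies most likely to sit inside the cluster proper)."""
    if not dcn_map:
        return {}
    med = float(np.median(list(dcn_map.values())))
    return {fid: v for fid, v in dcn_map.items() if v < med}
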