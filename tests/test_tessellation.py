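"""Residing areas, criterial sets, cluster reconstruction and metrics."""
import networkx as nx
import numpy as np
import pytest

from flysocial.core import AmbiguousSilhouetteError, ArenaSpec, Configuration, FlyRecord, InputError
from flysocial.synthetic import SceneParams, gen_clustered_config, gen_dispersed_config
from flysocial.tessellation import (
    STRINGENT_FACTORS,
    ClusterCriteria,
    Tessellation,
    cluster_metrics,
    compute_residing_areas,
    csc_criteria,
    dcn_below_median,
    reconstruct_clusters,
)

from conftest import contiguity_agreement


@pytest.fixture(scope="module")
def hexagon():
    cfg, _ = gen_clustered_config(
        SceneParams(n_flies=7, spacing=5.0, jitter_sd=0.0, hardcore=2.5),
        cluster_centre=(0.0, 0.0),
    )
    tess = compute_residing_areas(cfg, px_per_mm=10.0)
    return cfg, tess


class TestResidingAreas:
    def test_two_flies_split_arena_evenly(self, point_config):
        cfg = point_config([(-6.0, 0.0), (6.0, 0.0)])
        tess = compute_residing_areas(cfg, px_per_mm=5.0)
        a0, a1 = tess.residing_area[0], tess.residing_area[1]
        assert abs(a0 - a1) / (a0 + a1) < 0.01
        assert tess.contiguity.has_edge(0, 1)

    def test_hexagon_contiguity(self, hexagon):
        """Central fly is contiguous with all six ring flies; each ring fly
        with the centre and its two ring neighbours (Delaunay geometry)."""
        _, tess = hexagon
        assert sorted(tess.contiguity.neighbors(0)) == [1, 2, 3, 4, 5, 6]
        for fid in range(1, 7):
            nbrs = set(tess.contiguity.neighbors(fid))
            assert 0 in nbrs and len(nbrs) == 3
        assert not tess.touches_edge[0]
        assert all(tess.touches_edge[f] for f in range(1, 7))

    def test_pixel_conservation(self, arena):
        """Residing areas partition the masked arena exactly."""
        for seed in (0, 1):
            cfg = gen_dispersed_config(30, arena, hardcore=5.0, seed=seed)
            tess = compute_residing_areas(cfg, px_per_mm=5.0)
            total = sum(tess.residing_area.values())
            assert abs(total - tess.masked_area) / tess.masked_area < 0.005

    def test_single_fly_rejected(self, point_config):
        with pytest.raises(InputError):
            compute_residing_areas(point_config([(0.0, 0.0)]))

    def test_overlapping_silhouettes_rejected(self, arena):
        cfg = Configuration(
            arena,
            [
                FlyRecord(0, 0.0, 0.0, 3.0, 1.0, 0.0),
                FlyRecord(1, 0.5, 0.0, 3.0, 1.0, 0.0),
                FlyRecord(2, 20.0, 0.0, 3.0, 1.0, 0.0),
            ],
        )
        with pytest.raises(AmbiguousSilhouetteError) as exc:
            compute_residing_areas(cfg, px_per_mm=5.0)
        assert exc.value.ids == [0, 1]

    def test_contiguity_matches_delaunay_oracle(self, arena, point_config):
        """On random point patterns the contiguity graph agrees with the
        arena-restricted Delaunay neighbour graph on ≥95% of edges."""
        for seed in range(5):
            base = gen_dispersed_config(20, arena, hardcore=8.0, seed=seed)
            cfg = point_config(base.positions())
            tess = compute_residing_areas(cfg, px_per_mm=5.0)
            assert contiguity_agreement(tess, base.positions(), arena) >= 0.95


class TestCriteria:
    def test_unit_values_n50(self, arena):
        c = csc_criteria(50, arena, 1)
        assert c.unit_area == pytest.approx(np.pi * 45**2 / 50, rel=1e-9)
        assert c.unit_distance == pytest.approx(90 / np.sqrt(50), rel=1e-9)

    def test_csc2_thresholds(self, arena):
        c = csc_criteria(50, arena, 2)
        assert c.area_threshold == pytest.approx(38.42, abs=0.01)
        assert c.distance_threshold == pytest.approx(4.946, abs=0.001)

    def test_sqrt_stringent_factors(self):
        roots = [round(np.sqrt(sf), 2) for sf in STRINGENT_FACTORS]
        assert roots == [0.5, 0.55, 0.65, 0.70, 0.85]

    def test_bad_index(self, arena):
        with pytest.raises(InputError):
            csc_criteria(50, arena, 0)
        with pytest.raises(InputError):
            csc_criteria(50, arena, 6)


def _toy_tessellation(areas, edges, touches=None):
    g = nx.Graph()
    g.add_nodes_from(areas)
    g.add_edges_from(edges)
    return Tessellation(
        residing_area=dict(areas),
        label_image=np.zeros((1, 1), dtype=np.int32),
        ids=sorted(areas),
        contiguity=g,
        touches_edge=touches or {k: False for k in areas},
        px_per_mm=1.0,
        masked_area=sum(areas.values()),
    )


class TestReconstruction:
    def test_basic_plus_distance_expansion(self, point_config):
        """Two small-area contiguous flies seed the cluster; a third with a
        large residing area joins through the distance criterion."""
        cfg = point_config([(0.0, 0.0), (4.0, 0.0), (8.5, 0.0)])
        tess = _toy_tessellation(
            {0: 30.0, 1: 35.0, 2: 200.0}, [(0, 1), (1, 2)]
        )
        crit = ClusterCriteria(
            stringent_factor=0.302,
            unit_area=127.23,
            unit_distance=12.73,
            area_threshold=38.42,
            distance_threshold=4.946,
            csc_index=2,
        )
        res = reconstruct_clusters(tess, cfg, crit, min_cluster_size=3)
        assert res.clusters == [{0, 1, 2}]

    def test_planted_cluster_recovered(self, arena):
        """Planted 50-fly clusters at CSC#2: ≥95% of memberships recovered
        across seeds, never a false member."""
        recovered, false_members = [], 0
        for seed in range(10):
            cfg, truth = gen_clustered_config(SceneParams(n_flies=50, seed=seed))
            tess = compute_residing_areas(cfg, px_per_mm=5.0)
            res = reconstruct_clusters(tess, cfg, csc_criteria(50, arena, 2))
            members = set().union(*res.clusters) if res.clusters else set()
            planted = set(truth.cluster_membership)
            recovered.append(len(members & planted) / len(planted))
            false_members += len(members - planted)
        assert np.mean(recovered) >= 0.95
        assert false_members == 0

    def test_dispersed_hardcore_yields_no_cluster(self, arena):
        """A hard-core pattern at 8 mm floor exceeds the CSC#1 distance
        threshold: no cluster should form."""
        n_with = 0
        for seed in range(20):
            cfg = gen_dispersed_config(50, arena, hardcore=8.0, seed=seed)
            tess = compute_residing_areas(cfg, px_per_mm=5.0)
            res = reconstruct_clusters(tess, cfg, csc_criteria(50, arena, 1))
            n_with += bool(res.clusters)
        assert n_with <= 1

    def test_ct_monotone_in_csc(self, arena):
        """Relaxing the criteria never shrinks the clustered fraction."""
        for seed in range(5):
            cfg, _ = gen_clustered_config(SceneParams(n_flies=50, seed=seed))
            tess = compute_residing_areas(cfg, px_per_mm=5.0)
            cts = []
            for k in range(1, 6):
                res = reconstruct_clusters(tess, cfg, csc_criteria(50, arena, k))
                m = cluster_metrics(res, tess, cfg)
                cts.append(m.ct_percent)
            assert all(a <= b + 1e-9 for a, b in zip(cts, cts[1:]))

    def test_expansion_fixpoint(self, arena):
        """After reconstruction no unclustered fly remains within the
        distance threshold of any cluster member (idempotence)."""
        cfg, _ = gen_clustered_config(SceneParams(n_flies=50, seed=3))
        tess = compute_residing_areas(cfg, px_per_mm=5.0)
        crit = csc_criteria(50, arena, 2)
        res = reconstruct_clusters(tess, cfg, crit)
        pos = {f.fly_id: np.array([f.x, f.y]) for f in cfg.flies}
        members = set().union(*res.clusters)
        for fid in cfg.ids():
            if fid in members:
                continue
            dmin = min(np.hypot(*(pos[fid] - pos[m])) for m in members)
            assert dmin >= crit.distance_threshold

    def test_insiders_invariant_under_relabelling(self, arena):
        cfg, _ = gen_clustered_config(SceneParams(n_flies=30, spacing=4.7, seed=8))
        tess = compute_residing_areas(cfg, px_per_mm=5.0)
        crit = csc_criteria(30, arena, 2)
        res = reconstruct_clusters(tess, cfg, crit)
        # permute ids
        perm = {f: (f * 7 + 3) % 97 for f in cfg.ids()}
        cfg2 = Configuration(
            arena,
            [
                FlyRecord(perm[f.fly_id], f.x, f.y, f.length, f.width, f.orientation)
                for f in cfg.flies
            ],
        )
        tess2 = compute_residing_areas(cfg2, px_per_mm=5.0)
        res2 = reconstruct_clusters(tess2, cfg2, crit)
        ins1 = {perm[f] for f, r in res.role.items() if r == "insider"}
        ins2 = {f for f, r in res2.role.items() if r == "insider"}
        assert ins1 == ins2


class TestMetrics:
    def test_hexagon_metrics(self, hexagon):
        """Zero-jitter lattice: the interior fly has connectivity 6 and a
        DCN spread of exactly zero."""
        cfg, tess = hexagon
        res = reconstruct_clusters(tess, cfg, csc_criteria(7, cfg.arena, 5))
        m = cluster_metrics(res, tess, cfg)
        assert m.ct_percent == 100.0
        assert m.insider_connectivity == 6.0
        assert m.dcn_sd_per_inner_fly == {0: 0.0}

    def test_ct_it_arithmetic(self, point_config):
        cfg = point_config([(k * 4.0 - 18.0, 0.0) for k in range(10)])
        tess = _toy_tessellation(
            {k: 10.0 for k in range(10)},
            [(k, k + 1) for k in range(9)],
            touches={k: k in (0, 9) for k in range(10)},
        )
        crit = ClusterCriteria(0.302, 100.0, 10.0, 50.0, 5.0, 2)
        res = reconstruct_clusters(tess, cfg, crit)
        m = cluster_metrics(res, tess, cfg)
        assert m.ct_percent == 100.0
        assert m.it_percent == 80.0  # ends touch the edge

    def test_no_insiders_marked_empty(self, point_config):
        cfg = point_config([(0.0, 0.0), (4.0, 0.0), (8.0, 0.0)])
        tess = _toy_tessellation(
            {0: 10.0, 1: 10.0, 2: 10.0},
            [(0, 1), (1, 2)],
            touches={0: True, 1: True, 2: True},
        )
        crit = ClusterCriteria(0.302, 100.0, 10.0, 50.0, 5.0, 2)
        res = reconstruct_clusters(tess, cfg, crit, min_cluster_size=3)
        m = cluster_metrics(res, tess, cfg)
        assert m.insider_connectivity is None
        assert m.insider_link_length is None

    def test_planted_link_length(self, arena):
        """Insider link lengths recover the planted spacing."""
        vals = []
        for seed in range(10):
            cfg, _ = gen_clustered_config(SceneParams(n_flies=50, seed=seed))
            tess = compute_residing_areas(cfg, px_per_mm=5.0)
            res = reconstruct_clusters(tess, cfg, csc_criteria(50, arena, 2))
            m = cluster_metrics(res, tess, cfg)
            if m.insider_link_length is not None:
                vals.append(m.insider_link_length)
        assert 4.2 <= np.mean(vals) <= 5.2

    def test_dcn_below_median_filter(self):
        dcn = {0: 0.1, 1: 0.5, 2: 0.9, 3: 1.5}
        kept = dcn_below_median(dcn)
        assert set(kept) == {0, 1}
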