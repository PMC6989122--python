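"""Synthetic arena scenes with known ground truth.

Three generators cover the downstream pipeline:

* clustered configurations — seeded growth on a triangular lattice with a
  target near-neighbour spacing (default 4.7 mm, the observed contiguous
  link length in clustered wild-type groups), isotropic positional jitter
  and a hard contact floor (default 2.5 mm);
* dispersed configurations — the hard-core "random dots" null dressed with
  fly bodies;
* scripted group trajectories — stationary flies plus constant-speed
  walkers realising dyadic encounters and cluster assembly, with the
  scripted event log returned as ground truth.

Body sizes are drawn from Normal(2.8, 0.2) mm truncated to [2.5, 3.3] mm
(lengths) and Normal(1.0, 0.08) truncated to [0.8, 1.2] mm (widths); the
arena holds ~50 flies of ~2.5–3.3 mm body length.  An image renderer
rasterises configurations for the detection stage.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    ArenaSpec,
    TrajectorySet,
    Configuration,
    FlyRecord,
    GroundTruth,
    InfeasibleGeometryError,
    InputError,
    ScriptError,
)
from .simulation import HardCoreParams, ellipses_overlap, sample_random_dots

__all__ = [
    "SceneParams",
    "ScriptedEncounter",
    "TrajectorySet",
    "gen_clustered_config",
    "gen_dispersed_config",
    "render_arena_image",
    "gen_group_trajectories",
    "gen_cluster_assembly",
]

BODY_LENGTH_MEAN = 2.8
BODY_LENGTH_SD = 0.2
BODY_LENGTH_RANGE = (2.5, 3.3)
BODY_WIDTH_MEAN = 1.0
BODY_WIDTH_SD = 0.08
BODY_WIDTH_RANGE = (0.8, 1.2)


@dataclass(frozen=True)
class SceneParams:
    """Shared knobs for scene generation."""

    n_flies: int = 50
    spacing: float = 4.7  # target near-neighbour distance, mm
    jitter_sd: float = 0.5  # positional noise around lattice sites, mm
    hardcore: float = 2.5  # contact floor, mm
    seed: int = 0
    frame_rate: float = 50.0  # frames/s

    def __post_init__(self):
        if self.n_flies < 1:
            raise InputError("n_flies must be >= 1")
        if not self.hardcore < self.spacing:
            raise InputError("hardcore must be below spacing")
        if self.frame_rate <= 0:
            raise InputError("frame_rate must be positive")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    out = np.empty(size)
    need = np.ones(size, dtype=bool)
    while need.any():
        draw = rng.normal(mean, sd, int(need.sum()))
        ok = (draw >= lo) & (draw <= hi)
        idx = np.nonzero(need)[0][: ok.sum()]
        out[idx] = draw[ok][: idx.size]
        need[idx] = False
    return out


def _draw_bodies(rng: np.random.Generator, n: int):
    lengths = _truncated_normal(
        rng, BODY_LENGTH_MEAN, BODY_LENGTH_SD, *BODY_LENGTH_RANGE, n
    )
    widths = _truncated_normal(rng, BODY_WIDTH_MEAN, BODY_WIDTH_SD, *BODY_WIDTH_RANGE, n)
    orientations = rng.uniform(0.0, 180.0, n)
    return lengths, widths, orientations


def _triangular_lattice_sites(spacing: float, n: int, centre=(0.0, 0.0)) -> np.ndarray:
    """The n lattice sites closest to ``centre`` on a triangular lattice of
    pitch ``spacing`` (seeded growth from the centre outward)."""
    m = int(np.ceil(np.sqrt(n))) + 3
    i, j = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1))
    x = spacing * (i + 0.5 * j) + centre[0]
    y = spacing * (np.sqrt(3) / 2.0) * j + centre[1]
    sites = np.column_stack([x.ravel(), y.ravel()])
    r = np.hypot(sites[:, 0] - centre[0], sites[:, 1] - centre[1])
    # stable order: radius, then angle — deterministic growth pattern
    ang = np.arctan2(sites[:, 1] - centre[1], sites[:, 0] - centre[0])
    order = np.lexsort((ang, np.round(r, 9)))
    return sites[order][:n]


def gen_clustered_config(
    params: SceneParams,
    arena: ArenaSpec = ArenaSpec(),
    cluster_centre: tuple[float, float] | None = None,
) -> tuple[Configuration, GroundTruth]:
    """Plant one crystal-like cluster: seeded growth on a triangular lattice
    of pitch ``params.spacing``, each site perturbed by isotropic Gaussian
    jitter, resampled (bounded retries) so no pair falls below the contact
    floor and every centre stays inside the arena.

    Real clusters nucleate anywhere in the dish, so by default the cluster
    centre is drawn uniformly over the positions where the lattice still
    fits; pass ``cluster_centre`` to pin it.
    """
    rng = np.random.default_rng(params.seed)
    sites0 = _triangular_lattice_sites(params.spacing, params.n_flies, arena.centre)
    max_r = np.hypot(
        sites0[:, 0] - arena.centre[0], sites0[:, 1] - arena.centre[1]
    ).max()
    if max_r + params.spacing > arena.radius:
        raise InfeasibleGeometryError(
            f"lattice of {params.n_flies} sites at pitch {params.spacing} mm "
            f"(extent {max_r:.1f} mm) does not fit an arena of radius "
            f"{arena.radius} mm"
        )
    if cluster_centre is None:
        slack = arena.radius - max_r - params.spacing
        r_off = slack * np.sqrt(rng.random())
        th_off = rng.uniform(0.0, 2 * np.pi)
        cluster_centre = (
            arena.centre[0] + r_off * np.cos(th_off),
            arena.centre[1] + r_off * np.sin(th_off),
        )
    sites = sites0 - np.asarray(arena.centre) + np.asarray(cluster_centre)
    placed = np.empty_like(sites)
    for k, site in enumerate(sites):
        for attempt in range(200):
            cand = site + rng.normal(0.0, params.jitter_sd, 2)
            if np.hypot(cand[0] - arena.centre[0], cand[1] - arena.centre[1]) > (
                arena.radius - 1.0
            ):
                continue
            if k and np.min(np.hypot(*(placed[:k] - cand).T)) < params.hardcore:
                continue
            placed[k] = cand
            break
        else:
            raise InfeasibleGeometryError(
                f"could not jitter site {k} without violating the "
                f"{params.hardcore} mm contact floor"
            )
    lengths, widths, orientations = _draw_bodies(rng, params.n_flies)
    flies = [
        FlyRecord(i, placed[i, 0], placed[i, 1], lengths[i], widths[i], orientations[i])
        for i in range(params.n_flies)
    ]
    truth = GroundTruth(
        cluster_membership={i: 0 for i in range(params.n_flies)},
        planted_spacing=params.spacing,
    )
    return Configuration(arena=arena, flies=flies), truth


def gen_dispersed_config(
    n: int,
    arena: ArenaSpec = ArenaSpec(),
    hardcore: float = 0.0,
    seed: int = 0,
    margin: float = 0.0,
) -> Configuration:
    """Hard-core-respecting uniform positions dressed with fly bodies.

    ``margin`` keeps centres at least that far from the wall (set it to
    half a body length when whole bodies must stay inside the dish)."""
    ss = np.random.SeedSequence(seed)
    s_dots, s_body = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    inner = (
        ArenaSpec(centre=arena.centre, radius=arena.radius - margin)
        if margin > 0
        else arena
    )
    dots = sample_random_dots(
        HardCoreParams(n=n, arena=inner, hardcore=hardcore, seed=s_dots)
    )
    rng = np.random.default_rng(s_body)
    lengths, widths, orientations = _draw_bodies(rng, n)
    flies = [
        FlyRecord(f.fly_id, f.x, f.y, lengths[i], widths[i], orientations[i])
        for i, f in enumerate(dots.flies)
    ]
    return Configuration(arena=arena, flies=flies)


def render_arena_image(
    config: Configuration,
    px_per_mm: float = 10.0,
    bg_level: int = 200,
    fly_level: int = 30,
) -> tuple[np.ndarray, dict]:
    """Rasterise a configuration: dark filled body ellipses on a bright
    background, everything outside the arena at background level.

    Returns (uint8 image, metadata).  Overlapping flies are drawn merged and
    reported under ``meta["merged_pairs"]``.
    """
    if px_per_mm <= 0:
        raise InputError("px_per_mm must be positive")
    if bg_level == fly_level:
        raise InputError("bg_level must differ from fly_level")
    arena = config.arena
    size = int(np.ceil(2 * arena.radius * px_per_mm))
    img = np.full((size, size), bg_level, dtype=np.uint8)
    ox = arena.centre[0] - arena.radius
    oy = arena.centre[1] - arena.radius

    # pixel-centre coordinate grids in mm (row -> y, col -> x)
    def px_to_mm(idx):
        return (idx + 0.5) / px_per_mm

    cols = np.arange(size)
    rows = np.arange(size)
    for fly in config.flies:
        a, b = fly.length / 2.0, fly.width / 2.0
        pad = a + 2.0 / px_per_mm
        c0 = max(0, int((fly.x - ox - pad) * px_per_mm))
        c1 = min(size, int(np.ceil((fly.x - ox + pad) * px_per_mm)) + 1)
        r0 = max(0, int((fly.y - oy - pad) * px_per_mm))
        r1 = min(size, int(np.ceil((fly.y - oy + pad) * px_per_mm)) + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        xs = px_to_mm(cols[c0:c1]) + ox - fly.x
        ys = px_to_mm(rows[r0:r1]) + oy - fly.y
        gx, gy = np.meshgrid(xs, ys)
        th = np.deg2rad(fly.orientation)
        u = gx * np.cos(th) + gy * np.sin(th)
        v = -gx * np.sin(th) + gy * np.cos(th)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        # clip to arena interior
        cxg = px_to_mm(cols[c0:c1]) + ox - arena.centre[0]
        cyg = px_to_mm(rows[r0:r1]) + oy - arena.centre[1]
        gcx, gcy = np.meshgrid(cxg, cyg)
        inside &= np.hypot(gcx, gcy) <= arena.radius
        patch = img[r0:r1, c0:c1]
        patch[inside] = fly_level
    merged = [
        (config.flies[i].fly_id, config.flies[j].fly_id)
        for i in range(len(config.flies))
        for j in range(i + 1, len(config.flies))
        if ellipses_overlap(config.flies[i], config.flies[j])
    ]
    meta = {
        "px_per_mm": px_per_mm,
        "origin_mm": (ox, oy),
        "bg_level": bg_level,
        "fly_level": fly_level,
        "merged_pairs": merged,
    }
    return img, meta


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScriptedEncounter:
    """One scripted dyadic encounter: the interactor starts walking so that
    the pair's separation crosses 1.5 body lengths at ``time_s``."""

    time_s: float
    interactor: int
    interactee: int
    interactor_outcome: str = "move"  # "stay" | "move"
    interactee_outcome: str = "stay"

    def __post_init__(self):
        for o in (self.interactor_outcome, self.interactee_outcome):
            if o not in ("stay", "move"):
                raise ScriptError(f"unknown outcome {o!r}")
        if self.interactor == self.interactee:
            raise ScriptError("interactor and interactee must differ")


def _walk_segment(pos, fly, t0_f, start, stop, speed, fps):
    """Fill a straight constant-speed walk into the position array; returns
    the arrival frame."""
    start = np.asarray(start, float)
    stop = np.asarray(stop, float)
    dist = np.hypot(*(stop - start))
    n_fr = max(1, int(np.ceil(dist / speed * fps)))
    t1_f = t0_f + n_fr
    if t1_f >= pos.shape[0]:
        raise ScriptError("walk extends past the end of the recording")
    frac = np.linspace(0.0, 1.0, n_fr + 1)[1:]
    pos[t0_f + 1 : t1_f + 1, fly] = start + frac[:, None] * (stop - start)
    pos[t1_f + 1 :, fly] = stop
    return t1_f


def gen_group_trajectories(
    params: SceneParams,
    script: list[ScriptedEncounter],
    arena: ArenaSpec = ArenaSpec(),
    duration_s: float | None = None,
    walk_speed: float = 5.0,
    approach_from: float = 10.0,
    stop_distance: float = 2.0,
    dwell_s: float = 0.6,
    depart_distance: float = 7.0,
) -> tuple[TrajectorySet, GroundTruth]:
    """Realise a scripted list of dyadic encounters.

    Each event gets its own station (two concentric rings inside the arena);
    the interactee sits there throughout, the interactor approaches along
    the inward radial corridor at ``walk_speed`` so the pair separation
    crosses 1.5 × mean body length exactly at the scripted time, dwells at
    ``stop_distance`` for ``dwell_s``, then both flies realise their
    scripted stay/move outcomes.  Flies not participating in any event sit
    parked near the rim.  The returned ground truth logs onset/offset
    frames and outcome labels per event.
    """
    script = list(script)
    if any(
        script[k].time_s > script[k + 1].time_s for k in range(len(script) - 1)
    ):
        raise ScriptError("script events must be time-ordered")
    fps = params.frame_rate
    n = params.n_flies
    participants = [e.interactor for e in script] + [e.interactee for e in script]
    if participants and max(participants) >= n:
        raise ScriptError("participant id outside 0..n_flies-1")
    # each fly belongs to exactly one pair; a pair may meet repeatedly
    partner: dict[int, int] = {}
    for ev in script:
        for a, b in ((ev.interactor, ev.interactee), (ev.interactee, ev.interactor)):
            if partner.setdefault(a, b) != b:
                raise ScriptError(f"fly {a} scripted with more than one partner")

    # one ring of stations: adjacent corridors stay > 8 mm apart, well
    # beyond the largest possible contact distance (1.5 x 3.3 mm)
    n_stations = 12
    station_angles = [2 * np.pi * k / n_stations for k in range(n_stations)]
    pairs_in_order: list[tuple[int, int]] = []
    for ev in script:
        key = (ev.interactor, ev.interactee)
        if key not in pairs_in_order and key[::-1] not in pairs_in_order:
            pairs_in_order.append(key)
    if len(pairs_in_order) > n_stations:
        raise ScriptError(f"at most {n_stations} scripted pairs per scene")
    station_of_pair = {p: k for k, p in enumerate(pairs_in_order)}

    rng = np.random.default_rng(params.seed)
    lengths, _, _ = _draw_bodies(rng, n)
    if duration_s is None:
        duration_s = (max((e.time_s for e in script), default=0.0) + 10.0)
    n_frames = int(round(duration_s * fps)) + 1
    pos = np.zeros((n_frames, n, 2))

    cx, cy = arena.centre
    homes = np.zeros((n, 2))
    used = set(participants)
    geom_of_pair: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for (ia, ie), k in station_of_pair.items():
        th = station_angles[k]
        p_station = np.array([cx + 30.0 * np.cos(th), cy + 30.0 * np.sin(th)])
        u_in = np.array([-np.cos(th), -np.sin(th)])  # toward the arena centre
        homes[ie] = p_station
        homes[ia] = p_station + approach_from * u_in
        geom_of_pair[(ia, ie)] = (p_station, u_in)
    idle = [i for i in range(n) if i not in used]
    for j, i in enumerate(idle):
        th = np.pi / n_stations + 2.399963 * j  # golden-angle spread between stations
        homes[i] = (cx + 42.0 * np.cos(th), cy + 42.0 * np.sin(th))
    pos[:] = homes[None, :, :]

    events_log: list[dict] = []
    pair_free_after: dict[tuple[int, int], float] = {}
    for ev in script:
        key = (ev.interactor, ev.interactee)
        if key not in geom_of_pair:
            raise ScriptError(
                f"pair {key} previously scripted with roles swapped"
            )
        p_station, u_in = geom_of_pair[key]
        bl_pair = 0.5 * (lengths[ev.interactor] + lengths[ev.interactee])
        contact = 1.5 * bl_pair
        if not (stop_distance < contact < approach_from):
            raise ScriptError("contact distance outside the approach corridor")
        t_onset = ev.time_s
        t_start = t_onset - (approach_from - contact) / walk_speed
        if t_start < 0.2:
            raise ScriptError(
                f"event at t={ev.time_s}s starts before the recording"
            )
        if t_start < pair_free_after.get(key, -np.inf):
            raise ScriptError(
                f"pair {key} re-scripted at t={ev.time_s}s before its "
                "previous event has resolved"
            )
        t_start_f = int(round(t_start * fps))
        stop_pt = p_station + stop_distance * u_in
        t_arr_f = _walk_segment(
            pos, ev.interactor, t_start_f, homes[ev.interactor], stop_pt,
            walk_speed, fps,
        )
        dwell_f = int(round(dwell_s * fps))
        # outcomes after the dwell
        t_out_f = t_arr_f + dwell_f
        if ev.interactor_outcome == "move":
            # retrace the corridor back home: unique, collision-free path
            _walk_segment(
                pos, ev.interactor, t_out_f, stop_pt, homes[ev.interactor],
                walk_speed, fps,
            )
        else:
            pair_free_after[key] = np.inf  # station blocked by the sitter
        if ev.interactee_outcome == "move":
            # leave at 135 deg from the interactor so the walk never faces it
            tang = np.array([-u_in[1], u_in[0]])
            u_dep = (-u_in + tang) / np.sqrt(2.0)  # outward-tangential
            _walk_segment(
                pos, ev.interactee, t_out_f, p_station,
                p_station + depart_distance * u_dep, walk_speed, fps,
            )
            pair_free_after[key] = np.inf  # interactee no longer at the station
        if key not in pair_free_after:
            return_s = (approach_from - stop_distance) / walk_speed
            pair_free_after[key] = t_out_f / fps + return_s + 1.0
        events_log.append(
            {
                "type": "encounter",
                "interactor": int(ev.interactor),
                "interactee": int(ev.interactee),
                "onset_s": float(t_onset),
                "onset_frame": int(round(t_onset * fps)),
                "offset_s": t_arr_f / fps,
                "offset_frame": int(t_arr_f),
                "interactor_outcome": ev.interactor_outcome,
                "interactee_outcome": ev.interactee_outcome,
            }
        )

    trajs = TrajectorySet(
        positions=pos,
        ids=list(range(n)),
        frame_rate=fps,
        body_lengths=lengths,
        arena=arena,
    )
    truth = GroundTruth(event_log=events_log)
    return trajs, truth


def gen_cluster_assembly(
    join_times_s: list[float],
    params: SceneParams | None = None,
    arena: ArenaSpec = ArenaSpec(),
    slot_spacing: float = 3.0,
    start_radius: float = 25.0,
    walk_speed: float = 5.0,
    duration_s: float | None = None,
    disperse_at_s: float | None = None,
) -> tuple[TrajectorySet, GroundTruth]:
    """A nascent cluster assembling at the arena centre: fly *i* leaves its
    start position on a ring at ``join_times_s[i]`` and walks straight to
    its lattice slot (pitch ``slot_spacing``), then sits; optionally all
    flies disperse back out at ``disperse_at_s``.

    Ground truth logs each arrival ("join") and departure frame.  Slot pitch
    3 mm keeps lattice neighbours within 1.5 body lengths (~3.75–4.2 mm for
    2.5–2.8 mm flies), so co-resident flies form one proximity component.
    """
    params = params or SceneParams(n_flies=len(join_times_s))
    if params.n_flies != len(join_times_s):
        raise ScriptError("one join time per fly required")
    n = params.n_flies
    fps = params.frame_rate
    rng = np.random.default_rng(params.seed)
    lengths, _, _ = _draw_bodies(rng, n)
    slots = _triangular_lattice_sites(slot_spacing, n, arena.centre)
    travel = np.array(
        [
            np.hypot(
                start_radius * np.cos(2 * np.pi * i / n) - slots[i, 0] + arena.centre[0],
                start_radius * np.sin(2 * np.pi * i / n) - slots[i, 1] + arena.centre[1],
            )
            for i in range(n)
        ]
    )
    arrivals = np.asarray(join_times_s) + travel / walk_speed
    if duration_s is None:
        duration_s = float(
            (disperse_at_s or arrivals.max()) + travel.max() / walk_speed + 10.0
        )
    if disperse_at_s is not None and disperse_at_s < arrivals.max():
        raise ScriptError("dispersal scripted before every fly has arrived")
    n_frames = int(round(duration_s * fps)) + 1
    pos = np.zeros((n_frames, n, 2))
    starts = np.column_stack(
        [
            arena.centre[0] + start_radius * np.cos(2 * np.pi * np.arange(n) / n),
            arena.centre[1] + start_radius * np.sin(2 * np.pi * np.arange(n) / n),
        ]
    )
    pos[:] = starts[None, :, :]
    events: list[dict] = []
    for i, t_join in enumerate(join_times_s):
        t0_f = int(round(t_join * fps))
        t_arr_f = _walk_segment(pos, i, t0_f, starts[i], slots[i], walk_speed, fps)
        events.append(
            {"type": "join", "fly": i, "frame": int(t_arr_f), "time_s": t_arr_f / fps}
        )
    if disperse_at_s is not None:
        td_f = int(round(disperse_at_s * fps))
        for i in range(n):
            _walk_segment(pos, i, td_f, slots[i], starts[i], walk_speed, fps)
            events.append(
                {"type": "departure", "fly": i, "frame": td_f, "time_s": td_f / fps}
            )
    trajs = TrajectorySet(
        positions=pos,
        ids=list(range(n)),
        frame_rate=fps,
        body_lengths=lengths,
        arena=arena,
    )
    truth = GroundTruth(
        cluster_membership={i: 0 for i in range(n)}, event_log=events
    )
    return trajs, truth
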