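"""Trajectory-level dynamics: encounters, small clusters, stages.

A dyadic encounter is asymmetric: a walking fly (the interactor) closes to
within 1.5 × the pair's mean body length of a stationary fly (the
interactee) that lies inside its frontal 180° field of view.  Qualifying
frames are merged into events, events closer than a short gap are fused,
and each participant's post-event net displacement classifies it as
"stay" or "move".

Small clusters are connected components (proximity graph at 1.5 body
lengths) of at least five flies, tracked across frames by member-set
Jaccard overlap; a tracked cluster living 5–60 s is a transient cluster,
one living longer than 60 s a mini-cluster (a candidate nucleus).  The
Nucleus Stability Index (NSI) is the signed relative size change over the
minute after onset.

"Stationary" is speed below 0.5 mm/s sustained over 0.5 s — well below
walking speeds (tens of mm/s); the threshold is a package choice, the
boundary being unobservable from centre positions alone.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import InputError, TrajectorySet

__all__ = [
    "KinematicSeries",
    "EncounterParams",
    "EncounterEvent",
    "SmallClusterParams",
    "SmallClusterEvent",
    "StageSummary",
    "kinematics",
    "detect_encounters",
    "classify_encounter_outcome",
    "net_outcome_difference",
    "small_cluster_events",
    "nucleus_stability_index",
    "largest_component_series",
    "stage_summary",
    "perievent_velocity",
]

CONTACT_BODY_LENGTHS = 1.5  # encounter / proximity threshold, body lengths
STAGE_WINDOWS_MIN = ((5.0, 10.0), (10.0, 15.0), (15.0, 20.0))
TRANSIENT_MIN_S = 5.0
TRANSIENT_MAX_S = 60.0


def _smooth(x: np.ndarray, window: int, axis: int = 0) -> np.ndarray:
    if window <= 1:
        return x
    return ndimage.uniform_filter1d(x, size=window, axis=axis, mode="nearest")


def _speed_series(
    positions: np.ndarray, frame_rate: float, smooth_window: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """(speed, velocity) from boxcar-smoothed positions, centred differences
    with one-sided ends.  positions is (T, ..., 2)."""
    p = _smooth(positions, smooth_window, axis=0)
    v = np.gradient(p, axis=0) * frame_rate  # centred diff, one-sided ends
    speed = np.hypot(v[..., 0], v[..., 1])
    return speed, v


@dataclass
class KinematicSeries:
    speed: np.ndarray  # mm/s per frame
    acceleration: np.ndarray  # mm/s^2 per frame (d speed / dt)
    mean_speed: float
    max_speed: float
    mean_accel: float  # over accelerating frames
    max_accel: float
    mean_decel: float  # magnitudes, over decelerating frames
    max_decel: float


def kinematics(
    trajs: TrajectorySet, fly_id: int, smooth_window: int = 5
) -> KinematicSeries:
    """Speed/acceleration series and summary statistics for one fly."""
    if trajs.n_frames < 3:
        raise InputError("kinematics needs at least 3 frames")
    k = trajs.index_of(fly_id)
    speed, _ = _speed_series(
        trajs.positions[:, k, :], trajs.frame_rate, smooth_window
    )
    accel = np.gradient(speed) * trajs.frame_rate
    acc = accel[accel > 0]
    dec = -accel[accel < 0]
    return KinematicSeries(
        speed=speed,
        acceleration=accel,
        mean_speed=float(speed.mean()),
        max_speed=float(speed.max()),
        mean_accel=float(acc.mean()) if acc.size else 0.0,
        max_accel=float(acc.max()) if acc.size else 0.0,
        mean_decel=float(dec.mean()) if dec.size else 0.0,
        max_decel=float(dec.max()) if dec.size else 0.0,
    )


@dataclass(frozen=True)
class EncounterParams:
    contact_bl: float = CONTACT_BODY_LENGTHS
    stationary_speed: float = 0.5  # mm/s
    sustained_s: float = 0.5  # stationarity must hold over this window
    merge_gap_s: float = 0.25  # events closer than this are fused
    smooth_window: int = 5  # frames, for speed/heading estimation


@dataclass
class EncounterEvent:
    interactor_id: int
    interactee_id: int
    onset_frame: int
    offset_frame: int
    duration_s: float
    outcome: tuple[str, str] | None = None  # (interactor, interactee)


def _qualifying_mask(
    trajs: TrajectorySet, p: EncounterParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """speed, velocity and per-fly sustained-stationarity masks."""
    speed, vel = _speed_series(trajs.positions, trajs.frame_rate, p.smooth_window)
    w = max(1, int(round(p.sustained_s * trajs.frame_rate)))
    # stationary only if the speed stays low across the whole window
    rolling_max = ndimage.maximum_filter1d(speed, size=w, axis=0, mode="nearest")
    stationary = rolling_max < p.stationary_speed
    return speed, vel, stationary


def detect_encounters(
    trajs: TrajectorySet, params: EncounterParams | None = None
) -> list[EncounterEvent]:
    """Find all asymmetric dyadic encounters in a scene.

    Per ordered pair and frame the predicate is: centre distance at most
    ``contact_bl`` × mean pair body length; interactor walking (speed above
    the stationary threshold); interactee stationary (sustained); and the
    interactee's bearing within ±90° of the interactor's heading.
    Contiguous qualifying frames form an event; events separated by less
    than ``merge_gap_s`` merge.
    """
    p = params or EncounterParams()
    if np.isnan(trajs.positions).any():
        bad = np.unique(np.nonzero(np.isnan(trajs.positions))[0])
        raise InputError(f"missing frames in trajectories: {bad[:10].tolist()}")
    speed, vel, stationary = _qualifying_mask(trajs, p)
    pos = trajs.positions
    n = trajs.n_flies
    fps = trajs.frame_rate
    merge_gap_f = int(round(p.merge_gap_s * fps))
    events: list[EncounterEvent] = []
    movers = [i for i in range(n) if np.any(speed[:, i] > p.stationary_speed)]
    for i in movers:
        vi = vel[:, i, :]
        for j in range(n):
            if j == i:
                continue
            contact = p.contact_bl * 0.5 * (
                trajs.body_lengths[i] + trajs.body_lengths[j]
            )
            delta = pos[:, j, :] - pos[:, i, :]
            dist = np.hypot(delta[:, 0], delta[:, 1])
            frontal = (delta * vi).sum(axis=1) >= 0.0
            q = (
                (dist <= contact)
                & (speed[:, i] > p.stationary_speed)
                & stationary[:, j]
                & frontal
            )
            if not q.any():
                continue
            idx = np.nonzero(q)[0]
            runs: list[list[int]] = [[idx[0], idx[0]]]
            for t in idx[1:]:
                if t - runs[-1][1] <= max(1, merge_gap_f):
                    runs[-1][1] = t
                else:
                    runs.append([t, t])
            for on, off in runs:
                events.append(
                    EncounterEvent(
                        interactor_id=trajs.ids[i],
                        interactee_id=trajs.ids[j],
                        onset_frame=int(on),
                        offset_frame=int(off),
                        duration_s=float((off - on) / fps),
                    )
                )
    events.sort(key=lambda e: (e.onset_frame, e.interactor_id, e.interactee_id))
    return events


def classify_encounter_outcome(
    event: EncounterEvent,
    trajs: TrajectorySet,
    window_s: float = 2.0,
    move_threshold_bl: float = 1.0,
) -> tuple[str, str]:
    """Label each participant "move" if its net displacement over
    ``window_s`` after the event offset exceeds ``move_threshold_bl`` body
    lengths, else "stay"; "undetermined" when coverage ends first.  The
    labels are stored on the event and returned (interactor, interactee).
    """
    t0 = event.offset_frame
    t1 = t0 + int(round(window_s * trajs.frame_rate))
    labels = []
    for fid in (event.interactor_id, event.interactee_id):
        if t1 >= trajs.n_frames:
            labels.append("undetermined")
            continue
        k = trajs.index_of(fid)
        disp = float(
            np.hypot(*(trajs.positions[t1, k, :] - trajs.positions[t0, k, :]))
        )
        labels.append(
            "move" if disp > move_threshold_bl * trajs.body_lengths[k] else "stay"
        )
    event.outcome = (labels[0], labels[1])
    return event.outcome


def net_outcome_difference(outcomes: list[tuple[str, str]]) -> float:
    """Percentage of both-stay events minus percentage of both-move events
    (the paired net-outcome statistic; single-mover events leave the local
    fly count unchanged and cancel out)."""
    n = len(outcomes)
    if n == 0:
        raise InputError("no outcomes")
    both_stay = sum(1 for a, b in outcomes if a == "stay" and b == "stay")
    both_move = sum(1 for a, b in outcomes if a == "move" and b == "move")
    return 100.0 * (both_stay - both_move) / n


# ---------------------------------------------------------------------------
# small clusters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SmallClusterParams:
    contact_bl: float = CONTACT_BODY_LENGTHS
    min_size: int = 5
    jaccard: float = 0.5  # frame-to-frame identity threshold
    min_lifetime_s: float = TRANSIENT_MIN_S
    transient_max_s: float = TRANSIENT_MAX_S


@dataclass
class SmallClusterEvent:
    onset_frame: int
    end_frame: int
    cls: str  # "transient" | "mini"
    size_series: list[int]
    member_sets: list[frozenset[int]]
    frame_rate: float
    nsi: float | None = None
    nsi_truncated: bool = False

    @property
    def lifetime_s(self) -> float:
        return (self.end_frame - self.onset_frame) / self.frame_rate


def _frame_components(
    pos_t: np.ndarray, body_lengths: np.ndarray, contact_bl: float, min_size: int
) -> list[frozenset[int]]:
    n = pos_t.shape[0]
    diff = pos_t[:, None, :] - pos_t[None, :, :]
    d = np.hypot(diff[..., 0], diff[..., 1])
    thr = contact_bl * 0.5 * (body_lengths[:, None] + body_lengths[None, :])
    adj = (d <= thr) & ~np.eye(n, dtype=bool)
    # union-find over the adjacency
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in zip(*np.nonzero(adj)):
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[rb] = ra
    groups: dict[int, set[int]] = {}
    for k in range(n):
        groups.setdefault(find(k), set()).add(k)
    return [frozenset(g) for g in groups.values() if len(g) >= min_size]


def small_cluster_events(
    trajs: TrajectorySet, params: SmallClusterParams | None = None
) -> list[SmallClusterEvent]:
    """Track ≥5-fly proximity components across frames and classify their
    lifetimes: transient ([5 s, 60 s]) or mini (> 60 s); shorter chains are
    discarded.  Identity across frames requires member-set Jaccard ≥ 0.5
    (greedy best match); an unmatched chain terminates.
    """
    p = params or SmallClusterParams()
    fps = trajs.frame_rate
    bl = np.asarray(trajs.body_lengths, dtype=float)
    active: list[dict] = []
    closed: list[dict] = []
    for t in range(trajs.n_frames):
        comps = _frame_components(trajs.positions[t], bl, p.contact_bl, p.min_size)
        matches: list[tuple[float, int, int]] = []
        for ci, comp in enumerate(comps):
            for ai, ch in enumerate(active):
                last = ch["members"][-1]
                jac = len(comp & last) / len(comp | last)
                if jac >= p.jaccard:
                    matches.append((jac, ai, ci))
        matches.sort(key=lambda m: (-m[0], m[1], m[2]))
        used_a, used_c = set(), set()
        for jac, ai, ci in matches:
            if ai in used_a or ci in used_c:
                continue
            used_a.add(ai)
            used_c.add(ci)
            active[ai]["members"].append(comps[ci])
            active[ai]["end"] = t
        survivors = []
        for ai, ch in enumerate(active):
            if ai in used_a:
                survivors.append(ch)
            else:
                closed.append(ch)
        active = survivors
        for ci, comp in enumerate(comps):
            if ci not in used_c:
                active.append({"onset": t, "end": t, "members": [comp]})
    closed.extend(active)
    events: list[SmallClusterEvent] = []
    for ch in closed:
        lifetime = (ch["end"] - ch["onset"]) / fps
        if lifetime < p.min_lifetime_s:
            continue
        cls = "transient" if lifetime <= p.transient_max_s else "mini"
        member_ids = [
            frozenset(trajs.ids[k] for k in comp) for comp in ch["members"]
        ]
        events.append(
            SmallClusterEvent(
                onset_frame=ch["onset"],
                end_frame=ch["end"],
                cls=cls,
                size_series=[len(c) for c in ch["members"]],
                member_sets=member_ids,
                frame_rate=fps,
            )
        )
    events.sort(key=lambda e: e.onset_frame)
    return events


def nucleus_stability_index(event: SmallClusterEvent) -> float:
    """Signed relative size change over the minute after onset:
    NSI = (size(onset + 60 s) − size(onset)) / size(onset).

    If the event ends before 60 s the last frame is used instead and the
    event is flagged ``nsi_truncated``.
    """
    idx60 = int(round(60.0 * event.frame_rate))
    if idx60 < len(event.size_series):
        later = event.size_series[idx60]
        event.nsi_truncated = False
    else:
        later = event.size_series[-1]
        event.nsi_truncated = True
    s0 = event.size_series[0]
    event.nsi = (later - s0) / s0
    return event.nsi


# ---------------------------------------------------------------------------
# stages and growth
# ---------------------------------------------------------------------------


def largest_component_series(
    trajs: TrajectorySet, contact_bl: float = CONTACT_BODY_LENGTHS
) -> np.ndarray:
    """Per-frame size of the largest proximity component (growth curve)."""
    bl = np.asarray(trajs.body_lengths, dtype=float)
    out = np.empty(trajs.n_frames, dtype=int)
    for t in range(trajs.n_frames):
        comps = _frame_components(trajs.positions[t], bl, contact_bl, 1)
        out[t] = max(len(c) for c in comps)
    return out


@dataclass
class StageSummary:
    encounter_count: tuple[int, int, int]  # stages 1-3
    cluster_size_curve: np.ndarray | None
    time_to_size: dict[int, float | None]  # target size -> minutes
    latency_first_transient_min: float | None
    transient_count: int
    mean_transient_duration_s: float | None
    partial: bool  # observation shorter than the full 20 min


def stage_summary(
    trajs: TrajectorySet,
    cluster_series: np.ndarray | None = None,
    encounters: list[EncounterEvent] | None = None,
    small_clusters: list[SmallClusterEvent] | None = None,
    size_targets: tuple[int, ...] = (10, 25, 45),
) -> StageSummary:
    """Summaries over the three 5-minute growth stages ([5,10), [10,15),
    [15,20) min): encounter counts per stage, first-crossing times of the
    cluster growth curve, and transient-cluster latency/count/duration."""
    fps = trajs.frame_rate
    duration_min = trajs.duration_s / 60.0
    partial = duration_min < STAGE_WINDOWS_MIN[-1][1]
    counts = [0, 0, 0]
    for ev in encounters or []:
        t_min = ev.onset_frame / fps / 60.0
        for s, (lo, hi) in enumerate(STAGE_WINDOWS_MIN):
            if lo <= t_min < hi:
                counts[s] += 1
    time_to_size: dict[int, float | None] = {}
    for target in size_targets:
        if cluster_series is None:
            time_to_size[target] = None
            continue
        hit = np.nonzero(np.asarray(cluster_series) >= target)[0]
        time_to_size[target] = float(hit[0] / fps / 60.0) if hit.size else None
    transients = [e for e in (small_clusters or []) if e.cls == "transient"]
    latency = (
        min(e.onset_frame for e in transients) / fps / 60.0 if transients else None
    )
    mean_dur = (
        float(np.mean([e.lifetime_s for e in transients])) if transients else None
    )
    return StageSummary(
        encounter_count=tuple(counts),
        cluster_size_curve=(
            np.asarray(cluster_series) if cluster_series is not None else None
        ),
        time_to_size=time_to_size,
        latency_first_transient_min=latency,
        transient_count=len(transients),
        mean_transient_duration_s=mean_dur,
        partial=partial,
    )


@dataclass
class PeriEventVelocity:
    lags_s: np.ndarray
    interactor_onset: np.ndarray  # (n_events, n_lags), NaN where truncated
    interactee_offset: np.ndarray
    mean_interactor: np.ndarray  # across fully covered events
    mean_interactee: np.ndarray
    truncated_events: list[int]


def perievent_velocity(
    events: list[EncounterEvent],
    trajs: TrajectorySet,
    half_window_s: float = 0.8,
    smooth_window: int = 5,
) -> PeriEventVelocity:
    """Speed traces around each event: the interactor around onset and the
    interactee around offset (±``half_window_s``), with across-event means
    over events whose windows are fully covered."""
    if not events:
        raise InputError("no events")
    fps = trajs.frame_rate
    w = int(round(half_window_s * fps))
    lags = np.arange(-w, w + 1) / fps
    speed, _ = _speed_series(trajs.positions, fps, smooth_window)
    a_tr = np.full((len(events), 2 * w + 1), np.nan)
    b_tr = np.full((len(events), 2 * w + 1), np.nan)
    truncated = []
    for e_i, ev in enumerate(events):
        ok = True
        for anchor, fid, store in (
            (ev.onset_frame, ev.interactor_id, a_tr),
            (ev.offset_frame, ev.interactee_id, b_tr),
        ):
            lo, hi = anchor - w, anchor + w
            if lo < 0 or hi >= trajs.n_frames:
                ok = False
                continue
            store[e_i] = speed[lo : hi + 1, trajs.index_of(fid)]
        if not ok:
            truncated.append(e_i)
    full = [k for k in range(len(events)) if k not in truncated]
    mean_a = np.nanmean(a_tr[full], axis=0) if full else np.full_like(lags, np.nan)
    mean_b = np.nanmean(b_tr[full], axis=0) if full else np.full_like(lags, np.nan)
    return PeriEventVelocity(
        lags_s=lags,
        interactor_onset=a_tr,
        interactee_offset=b_tr,
        mean_interactor=mean_a,
        mean_interactee=mean_b,
        truncated_events=truncated,
    )
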