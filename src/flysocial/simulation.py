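"""Null models and the attraction–repulsion force-field model.

Two null models mirror the study design: "random dots" are points placed
sequentially and uniformly in the dish subject to a hard-core (minimum
separation) constraint — with hard-core 0 this is binomial CSR; "random
flies" are real fly records resampled across arenas at their original
coordinates with overlapping bodies rejected, which preserves marginal
spatial structure (e.g. edge preference) while scrambling inter-fly
correlation.

The mechanistic model is a single walker in a static force field: every
set fly exerts a radial force f(d) = A·exp(-d/s_a) - R·exp(-d/s_r) on the
walker (positive = attraction toward the source), with a short repulsion
scale s_r and a long attraction scale s_a.  The zero crossing of the net
radial force defines the critical settling distance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from shapely.geometry import Polygon

from .core import (
    ArenaSpec,
    Configuration,
    FlyRecord,
    InfeasiblePackingError,
    InputError,
    InsufficientPoolError,
    NoInterfaceError,
    ellipse_polygon,
    pairwise_distances,
)

__all__ = [
    "HardCoreParams",
    "ForceFieldParams",
    "WalkerResult",
    "sample_random_dots",
    "sample_dots_torus",
    "sample_random_flies",
    "ellipses_overlap",
    "net_force",
    "critical_distance",
    "simulate_walker",
]


@dataclass(frozen=True)
class HardCoreParams:
    """Sequential hard-core sampling parameters (n 5–100, hard-core 0–10 mm typical)."""

    n: int
    arena: ArenaSpec = ArenaSpec()
    hardcore: float = 0.0
    seed: int = 0
    max_attempts_per_point: int = 10_000

    def __post_init__(self):
        if self.n < 1:
            raise InputError("n must be >= 1")
        if self.hardcore < 0:
            raise InputError("hardcore distance must be >= 0")


def _uniform_in_disc(rng: np.random.Generator, arena: ArenaSpec, size: int) -> np.ndarray:
    r = arena.radius * np.sqrt(rng.random(size))
    th = rng.uniform(0.0, 2 * np.pi, size)
    return np.column_stack(
        [arena.centre[0] + r * np.cos(th), arena.centre[1] + r * np.sin(th)]
    )


def sample_random_dots(p: HardCoreParams) -> Configuration:
    """Sequentially place ``p.n`` uniform points in the dish, rejecting any
    candidate within ``p.hardcore`` of an already accepted point.

    Raises :class:`InfeasiblePackingError` (carrying the achieved count) when
    a point cannot be placed within ``max_attempts_per_point`` candidates.
    Points are returned as point-like fly records (tiny circular bodies) so
    downstream stages accept them unchanged.
    """
    rng = np.random.default_rng(p.seed)
    accepted: list[np.ndarray] = []
    for i in range(p.n):
        placed = False
        for _ in range(p.max_attempts_per_point):
            cand = _uniform_in_disc(rng, p.arena, 1)[0]
            if accepted and p.hardcore > 0:
                d = np.hypot(*(np.asarray(accepted) - cand).T)
                if np.min(d) < p.hardcore:
                    continue
            accepted.append(cand)
            placed = True
            break
        if not placed:
            raise InfeasiblePackingError(
                f"could not place point {i + 1}/{p.n} with hard-core "
                f"{p.hardcore} mm after {p.max_attempts_per_point} attempts",
                achieved=len(accepted),
            )
    flies = [
        FlyRecord(fly_id=i, x=pt[0], y=pt[1], length=0.4, width=0.4, orientation=0.0)
        for i, pt in enumerate(accepted)
    ]
    return Configuration(arena=p.arena, flies=flies)


def sample_dots_torus(
    n: int, side: float, seed: int = 0, hardcore: float = 0.0,
    max_attempts_per_point: int = 10_000,
) -> np.ndarray:
    """Edge-free variant: points on a ``side`` × ``side`` torus.

    Used for closed-form CSR checks (mean NND = 1/(2·sqrt(lambda)) holds
    exactly only without edge effects).  Returns an (n, 2) array.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    for i in range(n):
        placed = False
        for _ in range(max_attempts_per_point):
            cand = rng.uniform(0.0, side, 2)
            if pts and hardcore > 0:
                diff = np.abs(np.asarray(pts) - cand)
                diff = np.minimum(diff, side - diff)
                if np.min(np.hypot(diff[:, 0], diff[:, 1])) < hardcore:
                    continue
            pts.append(cand)
            placed = True
            break
        if not placed:
            raise InfeasiblePackingError(
                f"could not place torus point {i + 1}/{n}", achieved=len(pts)
            )
    return np.asarray(pts)


def torus_nnd(points: np.ndarray, side: float) -> np.ndarray:
    """Per-point nearest-neighbour distance under periodic boundary conditions."""
    pts = np.asarray(points, dtype=float)
    diff = np.abs(pts[:, None, :] - pts[None, :, :])
    diff = np.minimum(diff, side - diff)
    d = np.hypot(diff[..., 0], diff[..., 1])
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def ellipses_overlap(a: FlyRecord, b: FlyRecord, n_vertices: int = 32) -> bool:
    """True iff the two body ellipses intersect.

    Decided on 32-vertex polygonal outlines; a bounding-circle test short-cuts
    the common far-apart case.
    """
    dc = np.hypot(a.x - b.x, a.y - b.y)
    if dc > (a.length + b.length) / 2.0:
        return False
    if dc < (a.width + b.width) / 2.0:
        return True
    pa = Polygon(ellipse_polygon(a, n_vertices))
    pb = Polygon(ellipse_polygon(b, n_vertices))
    return bool(pa.intersects(pb))


def sample_random_flies(
    source: list[Configuration],
    n: int,
    arena: ArenaSpec,
    seed: int = 0,
) -> Configuration:
    """Resample fly records across source arenas at their original
    coordinates, rejecting candidates whose body overlaps an accepted fly,
    until ``n`` flies are placed.

    Raises :class:`InsufficientPoolError` if the pool is exhausted first.
    """
    pool: list[FlyRecord] = [f for cfg in source for f in cfg.flies]
    if not pool:
        raise InsufficientPoolError("empty source pool")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    accepted: list[FlyRecord] = []
    for idx in order:
        cand = pool[idx]
        if any(ellipses_overlap(cand, f) for f in accepted):
            continue
        accepted.append(
            FlyRecord(
                fly_id=len(accepted),
                x=cand.x,
                y=cand.y,
                length=cand.length,
                width=cand.width,
                orientation=cand.orientation,
            )
        )
        if len(accepted) == n:
            return Configuration(arena=arena, flies=accepted)
    raise InsufficientPoolError(
        f"pool exhausted at {len(accepted)}/{n} non-overlapping flies"
    )


@dataclass(frozen=True)
class ForceFieldParams:
    """Exponential attraction/repulsion profiles.

    Defaults give a zero-force interface at ln(repel_amp/attract_amp) /
    (1/repel_scale - 1/attract_scale) = ln(50)/0.45 ≈ 8.69 mm from a single
    source.  ``c_factor`` is the repulsion/attraction amplitude ratio.
    """

    attract_amp: float = 1.0
    attract_scale: float = 20.0
    repel_amp: float = 50.0
    repel_scale: float = 2.0

    def __post_init__(self):
        if min(self.attract_amp, self.attract_scale, self.repel_scale) <= 0:
            raise InputError("amplitudes and scales must be positive")
        if self.repel_amp < 0:
            raise InputError("repel_amp must be >= 0")
        if self.repel_amp > 0 and not self.repel_scale < self.attract_scale:
            raise InputError("need repel_scale < attract_scale (local repulsion)")

    @property
    def c_factor(self) -> float:
        return self.repel_amp / self.attract_amp

    def radial_force(self, d: np.ndarray) -> np.ndarray:
        """Scalar force at distance d; positive = toward the source."""
        d = np.asarray(d, dtype=float)
        return self.attract_amp * np.exp(-d / self.attract_scale) - self.repel_amp * np.exp(
            -d / self.repel_scale
        )

    def with_c_factor(self, c: float) -> "ForceFieldParams":
        return ForceFieldParams(
            attract_amp=self.attract_amp,
            attract_scale=self.attract_scale,
            repel_amp=c * self.attract_amp,
            repel_scale=self.repel_scale,
        )


def net_force(
    test_pos: np.ndarray, set_flies: np.ndarray, p: ForceFieldParams
) -> np.ndarray:
    """Vector sum of the radial forces every set fly exerts on ``test_pos``."""
    pos = np.asarray(test_pos, dtype=float)
    src = np.atleast_2d(np.asarray(set_flies, dtype=float))
    delta = src - pos  # toward each source
    d = np.hypot(delta[:, 0], delta[:, 1])
    if np.any(d == 0):
        raise InputError("test position coincides with a set fly")
    f = p.radial_force(d)
    return (delta * (f / d)[:, None]).sum(axis=0)


def critical_distance(
    p: ForceFieldParams,
    set_flies: np.ndarray,
    direction: np.ndarray,
    d_max: float = 200.0,
) -> float:
    """Distance along ``direction`` from the set's nearest member at which
    the net radial force crosses zero, by bracketed root finding.
    """
    src = np.atleast_2d(np.asarray(set_flies, dtype=float))
    u = np.asarray(direction, dtype=float)
    u = u / np.hypot(*u)
    # probe from the member nearest to the ray direction's side
    origin = src[np.argmax(src @ u)]

    def radial(t: float) -> float:
        f = net_force(origin + t * u, src, p)
        return float(-f @ u)  # positive = pulled back toward the set

    ts = np.linspace(1e-3, d_max, 512)
    vals = np.array([radial(t) for t in ts])
    sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    if sign_change.size == 0:
        raise NoInterfaceError("no zero crossing of the net radial force")
    i = sign_change[0]
    return float(brentq(radial, ts[i], ts[i + 1]))


@dataclass
class WalkerResult:
    trajectory: np.ndarray  # (steps+1, 2)
    settle_distance: float  # final distance to nearest set fly, mm
    settled: bool
    force_at_end: float = 0.0


def simulate_walker(
    start: np.ndarray,
    set_flies: np.ndarray,
    p: ForceFieldParams,
    noise_sd: float = 0.0,
    steps: int = 4000,
    seed: int = 0,
    gain: float = 2.0,
    max_step: float = 1.0,
    settle_window: int = 50,
    settle_tol: float = 0.02,
) -> WalkerResult:
    """Overdamped walker: each step moves ``gain`` × net force (capped at
    ``max_step`` mm) plus isotropic Gaussian noise.

    The walker is settled when its distance to the nearest set fly drifts by
    less than max(settle_tol, noise_sd) over a trailing window; the settle
    distance is the trailing-window mean of that distance.
    """
    rng = np.random.default_rng(seed)
    src = np.atleast_2d(np.asarray(set_flies, dtype=float))
    pos = np.asarray(start, dtype=float).copy()
    traj = np.empty((steps + 1, 2))
    traj[0] = pos
    dist_hist = np.empty(steps + 1)
    dist_hist[0] = np.min(np.hypot(*(src - pos).T))
    settled = False
    end = steps
    for k in range(1, steps + 1):
        f = net_force(pos, src, p)
        step = gain * f
        norm = np.hypot(*step)
        if norm > max_step:
            step *= max_step / norm
        if noise_sd > 0:
            step = step + rng.normal(0.0, noise_sd, 2)
        pos = pos + step
        traj[k] = pos
        dist_hist[k] = np.min(np.hypot(*(src - pos).T))
        if k >= settle_window:
            win = dist_hist[k - settle_window : k + 1]
            drift = abs(win[-1] - win[0])
            tol = max(settle_tol, noise_sd)
            if drift < tol and np.ptp(win) < 5 * tol:
                settled = True
                end = k
                break
    win = dist_hist[max(0, end - settle_window) : end + 1]
    settle_distance = float(np.mean(win))
    f_end = net_force(traj[end], src, p)
    return WalkerResult(
        trajectory=traj[: end + 1],
        settle_distance=settle_distance,
        settled=settled,
        force_at_end=float(np.hypot(*f_end)),
    )
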