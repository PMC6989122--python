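"""Core domain types: arena geometry, fly records, arena configurations.

All coordinates are in millimetres with the origin at the arena centre
unless noted otherwise.  Orientations are degrees; a body-shape orientation
lives in [0, 180) (an ellipse has no front), a heading in [0, 360).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CONFIG_COLUMNS = [
    "frame",
    "fly_id",
    "x_mm",
    "y_mm",
    "length_mm",
    "width_mm",
    "orientation_deg",
]


class InputError(ValueError):
    """Invalid input to an analysis operation."""


class InfeasibleGeometryError(RuntimeError):
    """Requested placement cannot fit inside the arena."""


class InfeasiblePackingError(RuntimeError):
    """Sequential hard-core sampler could not place all points."""

    def __init__(self, message: str, achieved: int):
        super().__init__(message)
        self.achieved = achieved


class InsufficientPoolError(RuntimeError):
    """Resampling pool exhausted before the target count was reached."""


class AmbiguousSilhouetteError(RuntimeError):
    """Fly silhouettes overlap at the requested resolution."""

    def __init__(self, message: str, ids: Sequence):
        super().__init__(message)
        self.ids = list(ids)


class NoInterfaceError(RuntimeError):
    """Force profiles admit no zero crossing along the probed ray."""


class ScriptError(ValueError):
    """A scripted trajectory is kinematically unrealisable."""


@dataclass(frozen=True)
class ArenaSpec:
    """Circular arena; the default matches a 90 mm internal-diameter dish."""

    centre: tuple[float, float] = (0.0, 0.0)
    radius: float = 45.0
    height_note: str = ""

    def __post_init__(self):
        if self.radius <= 0:
            raise InputError("arena radius must be positive")

    @property
    def area(self) -> float:
        return float(np.pi * self.radius**2)

    def contains(self, xy: np.ndarray, slack: float = 1e-9) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        d = np.hypot(xy[:, 0] - self.centre[0], xy[:, 1] - self.centre[1])
        return d <= self.radius + slack


@dataclass
class FlyRecord:
    """One fly as an ellipse: centre of mass, body axes, orientation."""

    fly_id: int
    x: float
    y: float
    length: float  # major axis, mm
    width: float  # minor axis, mm
    orientation: float  # degrees

    def __post_init__(self):
        if not (self.length >= self.width > 0):
            raise InputError(
                f"fly {self.fly_id}: need length >= width > 0, "
                f"got {self.length}, {self.width}"
            )

    @property
    def centre(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class Configuration:
    """A snapshot of one arena: the dish plus every fly in it."""

    arena: ArenaSpec
    flies: list[FlyRecord] = field(default_factory=list)
    timestamp: float | None = None

    def __post_init__(self):
        ids = [f.fly_id for f in self.flies]
        if len(ids) != len(set(ids)):
            raise InputError("fly_ids must be unique within a configuration")
        if self.flies:
            pos = self.positions()
            if not np.all(self.arena.contains(pos)):
                bad = [
                    f.fly_id
                    for f, ok in zip(self.flies, self.arena.contains(pos))
                    if not ok
                ]
                raise InputError(f"flies outside the arena: {bad}")

    def __len__(self) -> int:
        return len(self.flies)

    def ids(self) -> list[int]:
        return [f.fly_id for f in self.flies]

    def positions(self) -> np.ndarray:
        """(n, 2) array of body centres, in fly order."""
        return np.array([[f.x, f.y] for f in self.flies], dtype=float)

    def to_frame(self, frame: int = 0) -> pd.DataFrame:
        rows = [
            (frame, f.fly_id, f.x, f.y, f.length, f.width, f.orientation)
            for f in self.flies
        ]
        return pd.DataFrame(rows, columns=CONFIG_COLUMNS)

    def to_csv(self, path, frame: int = 0) -> None:
        self.to_frame(frame).to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, arena: ArenaSpec, timestamp: float | None = None
    ) -> "Configuration":
        flies = [
            FlyRecord(
                fly_id=int(r.fly_id),
                x=float(r.x_mm),
                y=float(r.y_mm),
                length=float(r.length_mm),
                width=float(r.width_mm),
                orientation=float(r.orientation_deg),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(arena=arena, flies=flies, timestamp=timestamp)

    @classmethod
    def from_csv(cls, path, arena: ArenaSpec) -> "Configuration":
        df = pd.read_csv(path)
        missing = set(CONFIG_COLUMNS) - set(df.columns)
        if missing:
            raise InputError(f"configuration CSV missing columns: {sorted(missing)}")
        return cls.from_frame(df, arena)


@dataclass
class GroundTruth:
    """Planted structure accompanying a synthetic scene."""

    cluster_membership: dict[int, int | None] = field(default_factory=dict)
    planted_spacing: float | None = None
    event_log: list[dict] = field(default_factory=list)


def pairwise_distances(positions: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix for an (n, 2) point array."""
    pos = np.asarray(positions, dtype=float)
    diff = pos[:, None, :] - pos[None, :, :]
    return np.hypot(diff[..., 0], diff[..., 1])


def ellipse_polygon(fly: FlyRecord, n_vertices: int = 32) -> np.ndarray:
    """(n, 2) polygonal approximation of a fly's body outline."""
    t = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    a, b = fly.length / 2.0, fly.width / 2.0
    th = np.deg2rad(fly.orientation)
    ex = a * np.cos(t)
    ey = b * np.sin(t)
    x = fly.x + ex * np.cos(th) - ey * np.sin(th)
    y = fly.y + ex * np.sin(th) + ey * np.cos(th)
    return np.column_stack([x, y])


@dataclass
class TrajectorySet:
    """Time-aligned group trajectories at a fixed frame rate."""

    positions: np.ndarray  # (n_frames, n_flies, 2), mm
    ids: list[int]
    frame_rate: float
    body_lengths: np.ndarray  # (n_flies,), mm
    arena: ArenaSpec = ArenaSpec()
    headings: np.ndarray | None = None  # (n_frames, n_flies), deg, optional

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_flies(self) -> int:
        return self.positions.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def index_of(self, fly_id: int) -> int:
        return self.ids.index(fly_id)

    def to_frame(self) -> pd.DataFrame:
        n_t, n_f = self.positions.shape[:2]
        frames = np.repeat(np.arange(n_t), n_f)
        ids = np.tile(np.asarray(self.ids), n_t)
        xy = self.positions.reshape(-1, 2)
        return pd.DataFrame(
            {"frame": frames, "fly_id": ids, "x_mm": xy[:, 0], "y_mm": xy[:, 1]}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df, frame_rate: float, body_lengths, arena=ArenaSpec()):
        ids = sorted(df["fly_id"].unique().tolist())
        frames = np.sort(df["frame"].unique())
        n_t, n_f = len(frames), len(ids)
        pos = np.full((n_t, n_f, 2), np.nan)
        id_idx = {fid: k for k, fid in enumerate(ids)}
        f_idx = {fr: k for k, fr in enumerate(frames)}
        for r in df.itertuples(index=False):
            pos[f_idx[r.frame], id_idx[r.fly_id]] = (r.x_mm, r.y_mm)
        if np.isnan(pos).any():
            raise InputError("trajectory CSV has missing (frame, fly) entries")
        bl = np.asarray(
            [body_lengths[i] if hasattr(body_lengths, "__getitem__") else body_lengths
             for i in ids],
            dtype=float,
        ) if not np.isscalar(body_lengths) else np.full(n_f, float(body_lengths))
        return cls(positions=pos, ids=ids, frame_rate=frame_rate, body_lengths=bl,
                   arena=arena)
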