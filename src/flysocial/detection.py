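"""Fly detection from arena image stacks.

The pipeline mirrors classic arena tracking: a static background is the
per-pixel maximum over time (flies are dark on a bright substrate; use the
minimum for bright flies), each frame is background-subtracted and
thresholded inside an arena mask, connected pixel groups become candidate
flies, and each component is reduced to its moment-equivalent ellipse
(centroid, axis lengths from the second central moments, major-axis
orientation).

Touching flies are not split: overlapping bodies yield one merged
component, which is flagged by a fill-factor check (a merged blob fills
its moment ellipse poorly) and otherwise fitted as-is.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .core import ArenaSpec, Configuration, FlyRecord, InputError

__all__ = [
    "ArenaMask",
    "ImageStack",
    "compute_background",
    "segment_flies",
    "fit_ellipses",
    "detect_configuration",
]


@dataclass
class ArenaMask:
    """Binary arena-interior mask plus its fitted circle (pixel units)."""

    mask: np.ndarray
    centre_px: tuple[float, float]  # (col, row)
    radius_px: float
    fit_residual_px: float = 0.0

    @classmethod
    def from_arena(
        cls, arena: ArenaSpec, px_per_mm: float, shape: tuple[int, int] | None = None
    ) -> "ArenaMask":
        size = int(np.ceil(2 * arena.radius * px_per_mm))
        shape = shape or (size, size)
        rows, cols = np.indices(shape)
        cc = (shape[1]) / 2.0
        cr = (shape[0]) / 2.0
        r_px = arena.radius * px_per_mm
        mask = np.hypot(cols + 0.5 - cc, rows + 0.5 - cr) <= r_px
        return cls(mask=mask, centre_px=(cc, cr), radius_px=r_px)

    @classmethod
    def from_image(cls, binary: np.ndarray, residual_tol_px: float = 2.0) -> "ArenaMask":
        """Fit a circle (Kasa least squares) to the boundary of a labelled
        arena mask; the fit residual must stay below ``residual_tol_px``."""
        binary = binary.astype(bool)
        if not binary.any():
            raise InputError("empty arena mask")
        boundary = binary & ~ndimage.binary_erosion(binary)
        rr, cc = np.nonzero(boundary)
        x, y = cc + 0.5, rr + 0.5
        A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
        b = x**2 + y**2
        (cx, cy, c), *_ = np.linalg.lstsq(A, b, rcond=None)
        radius = float(np.sqrt(c + cx**2 + cy**2))
        resid = float(np.mean(np.abs(np.hypot(x - cx, y - cy) - radius)))
        if resid > residual_tol_px:
            raise InputError(
                f"arena boundary is not circular (residual {resid:.2f} px)"
            )
        return cls(
            mask=binary,
            centre_px=(float(cx), float(cy)),
            radius_px=radius,
            fit_residual_px=resid,
        )


@dataclass
class ImageStack:
    """Ordered grayscale frames at a fixed scale and frame rate."""

    frames: np.ndarray  # (T, H, W)
    px_per_mm: float
    frame_rate: float = 50.0

    def __post_init__(self):
        if self.frames.ndim != 3:
            raise InputError("frames must be a (T, H, W) array")
        if self.px_per_mm <= 0:
            raise InputError("px_per_mm must be positive")

    @classmethod
    def from_files(
        cls, paths, px_per_mm: float, frame_rate: float = 50.0
    ) -> "ImageStack":
        """Read an ordered list of PNG/TIFF frame files."""
        import imageio.v3 as iio

        frames = [np.asarray(iio.imread(p)) for p in paths]
        if not frames:
            raise InputError("no frame files given")
        if any(f.shape != frames[0].shape for f in frames):
            raise InputError("all frames must share one shape")
        return cls(
            frames=np.stack(frames), px_per_mm=px_per_mm, frame_rate=frame_rate
        )


def compute_background(stack: ImageStack, dark_flies: bool = True) -> np.ndarray:
    """Static background: per-pixel maximum over the stack (dark flies on a
    bright substrate vanish wherever they move; minimum for bright flies).

    A fly that never moves survives into the background and is invisible to
    subtraction — a documented limitation of the method.
    """
    if stack.frames.shape[0] < 2:
        raise InputError("background estimation needs at least 2 frames")
    op = np.max if dark_flies else np.min
    return op(stack.frames, axis=0)


@dataclass
class Segmentation:
    labels: np.ndarray  # 0 = background
    n_components: int
    threshold: float
    suspect_merged: list[int] = field(default_factory=list)  # label values


def segment_flies(
    frame: np.ndarray,
    background: np.ndarray,
    mask: ArenaMask,
    threshold: float | str = "auto",
    min_area_frac: float = 0.25,
) -> Segmentation:
    """Label connected fly-pixel components of |background − frame| inside
    the arena mask.

    ``threshold="auto"`` uses Otsu on the masked difference image.
    Components smaller than ``min_area_frac`` × the median component area
    are dropped as noise.  Components that fill their moment-equivalent
    ellipse poorly (fill factor outside [0.85, 1.15]) are flagged as
    possibly merged flies.
    """
    if frame.shape != background.shape or frame.shape != mask.mask.shape:
        raise InputError("frame, background and mask shapes differ")
    diff = np.abs(background.astype(np.int32) - frame.astype(np.int32))
    diff[~mask.mask] = 0
    if threshold == "auto":
        vals = diff[mask.mask]
        if vals.max() == vals.min():
            return Segmentation(
                labels=np.zeros_like(diff), n_components=0, threshold=float(vals.max())
            )
        thr = float(threshold_otsu(vals))
    else:
        thr = float(threshold)
    binary = diff > thr
    labels = cc_label(binary, connectivity=2)
    if labels.max() == 0:
        return Segmentation(labels=labels, n_components=0, threshold=thr)
    areas = np.bincount(labels.ravel())[1:]
    min_area = min_area_frac * float(np.median(areas))
    keep = np.nonzero(areas >= min_area)[0] + 1
    relabel = np.zeros(labels.max() + 1, dtype=np.int32)
    relabel[keep] = np.arange(1, len(keep) + 1)
    labels = relabel[labels]
    suspects = []
    for lab in range(1, len(keep) + 1):
        rr, cc = np.nonzero(labels == lab)
        npx = rr.size
        if npx < 5:
            continue
        cov = np.cov(np.stack([cc, rr]).astype(float))
        lam = np.linalg.eigvalsh(cov)
        ell_area = np.pi * 4.0 * np.sqrt(max(lam[0], 1e-12) * max(lam[1], 1e-12))
        fill = npx / ell_area
        if not 0.85 <= fill <= 1.15:
            suspects.append(lab)
    return Segmentation(
        labels=labels,
        n_components=int(labels.max()),
        threshold=thr,
        suspect_merged=suspects,
    )


def fit_ellipses(
    labels: np.ndarray,
    px_per_mm: float,
    origin_mm: tuple[float, float] = (0.0, 0.0),
) -> tuple[list[FlyRecord], list[int]]:
    """Moment-equivalent ellipse per labelled component.

    Centre = centroid; the axis lengths are four times the square roots of
    the second-central-moment eigenvalues (exact for a filled ellipse);
    orientation is the major-axis angle in [0, 180).  Coordinates are
    converted to mm via ``px_per_mm`` and ``origin_mm`` (the mm position of
    the image corner).  Returns (records, degenerate_ids) where degenerate
    components (near-zero width) had their width floored at one pixel.
    """
    n = int(labels.max())
    if n < 1:
        raise InputError("no components to fit")
    records: list[FlyRecord] = []
    degenerate: list[int] = []
    ox, oy = origin_mm
    for lab in range(1, n + 1):
        rr, cc = np.nonzero(labels == lab)
        x = (cc + 0.5) / px_per_mm + ox
        y = (rr + 0.5) / px_per_mm + oy
        cx_, cy_ = float(x.mean()), float(y.mean())
        dx, dy = x - cx_, y - cy_
        mu20 = float(np.mean(dx * dx))
        mu02 = float(np.mean(dy * dy))
        mu11 = float(np.mean(dx * dy))
        common = np.sqrt(max((mu20 - mu02) ** 2 + 4 * mu11**2, 0.0))
        lam1 = (mu20 + mu02 + common) / 2.0
        lam2 = (mu20 + mu02 - common) / 2.0
        length = 4.0 * np.sqrt(max(lam1, 0.0))
        width = 4.0 * np.sqrt(max(lam2, 0.0))
        floor = 1.0 / px_per_mm
        if width < floor:
            width = floor
            length = max(length, floor)
            degenerate.append(lab)
        theta = np.degrees(0.5 * np.arctan2(2 * mu11, mu20 - mu02)) % 180.0
        records.append(
            FlyRecord(
                fly_id=lab - 1,
                x=cx_,
                y=cy_,
                length=float(length),
                width=float(width),
                orientation=float(theta),
            )
        )
    return records, degenerate


def detect_configuration(
    frame: np.ndarray,
    background: np.ndarray,
    mask: ArenaMask,
    px_per_mm: float,
    arena: ArenaSpec,
    threshold: float | str = "auto",
) -> tuple[Configuration, Segmentation]:
    """Full single-frame pipeline: segment, fit, wrap into a Configuration
    with mm coordinates centred on the arena."""
    seg = segment_flies(frame, background, mask, threshold)
    if seg.n_components == 0:
        return Configuration(arena=arena, flies=[]), seg
    origin = (arena.centre[0] - arena.radius, arena.centre[1] - arena.radius)
    records, _ = fit_ellipses(seg.labels, px_per_mm, origin)
    return Configuration(arena=arena, flies=records), seg
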