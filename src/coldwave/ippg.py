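"""Imaging PPG signal formation from video frames and ROI polygons.

A camera pointed at the skin records blood-volume pulsations as tiny
intensity fluctuations.  The iPPG signal is formed by spatially smoothing
each frame, averaging all pixels inside a region-of-interest polygon
(forehead, cheeks, or their union as the "super" ROI), inverting the trace
so that systole points upward like in contact PPG, and linearly
interpolating from the video frame rate onto the contact-PPG sampling grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from matplotlib.path import Path as MplPath

from .signals import SampledSignal

__all__ = [
    "FrameSequence",
    "RoiPolygon",
    "rasterize",
    "spatial_smooth",
    "extract_roi_signal",
    "invert_and_resample",
]

DEFAULT_SMOOTH_WIDTH = 10  # pixels
DEFAULT_TARGET_FS = 2000.0  # Hz, matches contact PPG
CHANNELS = ("red", "green", "blue")


@dataclass(frozen=True)
class FrameSequence:
    """A stack of equally shaped intensity frames.

    frames : ndarray, shape (n, H, W) or (n, H, W, C)
    fps : frame rate in Hz
    bit_depth : sensor bit depth (12 for the emulated camera)
    channels : labels of the colour axis when present
    """

    frames: np.ndarray
    fps: float
    bit_depth: int = 12
    channels: tuple[str, ...] = CHANNELS
    t0: float = 0.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim not in (3, 4):
            raise ValueError("frames must be (n, H, W) or (n, H, W, C)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        object.__setattr__(self, "frames", f)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    def channel(self, label: str) -> np.ndarray:
        """Frames of one colour channel as (n, H, W)."""
        if self.frames.ndim == 3:
            return self.frames
        try:
            c = self.channels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}; have {self.channels}") from None
        return self.frames[..., c]


@dataclass(frozen=True)
class RoiPolygon:
    """Ordered polygon vertices in pixel coordinates (x right, y down,
    0-based).  Labels follow the face ROIs: forehead, left_cheek,
    right_cheek."""

    vertices: np.ndarray
    label: str = "forehead"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        object.__setattr__(self, "vertices", v)

    @property
    def area(self) -> float:
        """Shoelace area in square pixels."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def rasterize(polygon: RoiPolygon, frame_shape: tuple[int, int]) -> np.ndarray:
    """Boolean pixel mask: a pixel belongs to the ROI iff its centre lies
    inside the polygon (even-odd rule).

    Raises
    ------
    ValueError
        if the mask comes out empty (degenerate or out-of-frame ROI).
    """
    if polygon.area == 0:
        raise ValueError("degenerate polygon (zero area)")
    h, w = frame_shape
    path = MplPath(polygon.vertices)
    xs, ys = np.meshgrid(np.arange(w, dtype=float),
                         np.arange(h, dtype=float))
    centers = np.column_stack([xs.ravel(), ys.ravel()])
    # radius=... nudges boundary handling; pixel centres exactly on an edge
    # are resolved towards inclusion of the lower-left rule via tiny radius
    mask = path.contains_points(centers, radius=1e-9).reshape(h, w)
    if not mask.any():
        raise ValueError(f"ROI {polygon.label!r} covers no pixel centres")
    return mask


def union_mask(polygons: list[RoiPolygon],
               frame_shape: tuple[int, int]) -> np.ndarray:
    """Union of several ROI masks (the "super" ROI)."""
    mask = np.zeros(frame_shape, dtype=bool)
    for poly in polygons:
        mask |= rasterize(poly, frame_shape)
    if not mask.any():
        raise ValueError("super ROI covers no pixel centres")
    return mask


def spatial_smooth(frame: np.ndarray,
                   width: int = DEFAULT_SMOOTH_WIDTH) -> np.ndarray:
    """Box-average each pixel over a width x width neighbourhood.

    Borders are handled by reflection; interior pixels equal the plain
    moving-average of their neighbourhood.
    """
    if width < 1:
        raise ValueError("smoothing width must be >= 1")
    frame = np.asarray(frame, dtype=float)
    if width > min(frame.shape[:2]):
        raise ValueError("smoothing width exceeds frame size")
    if width == 1:
        return frame.copy()
    size = (width, width) + (1,) * (frame.ndim - 2)
    return ndimage.uniform_filter(frame, size=size, mode="reflect")


def extract_roi_signal(frames: FrameSequence,
                       roi: RoiPolygon | list[RoiPolygon],
                       channel: str = "green",
                       smooth_width: int = DEFAULT_SMOOTH_WIDTH
                       ) -> SampledSignal:
    """ROI-mean trace: smooth the selected channel of every frame, then
    average all pixels inside the ROI (or the union of ROIs).

    Green is the default channel; red is selectable for sensors or lighting
    where the green band carries less pulsatile signal.
    """
    if frames.n_frames == 0:
        raise ValueError("frame sequence is empty")
    if isinstance(roi, RoiPolygon):
        mask = rasterize(roi, frames.frame_shape)
        label = roi.label
    else:
        mask = union_mask(roi, frames.frame_shape)
        label = "super"
    stack = frames.channel(channel)
    if smooth_width > 1:
        if smooth_width > min(frames.frame_shape):
            raise ValueError("smoothing width exceeds frame size")
        # size 1 on the time axis: frames are smoothed independently
        smoothed = ndimage.uniform_filter(
            stack, size=(1, smooth_width, smooth_width), mode="reflect")
    else:
        smoothed = stack
    values = smoothed[:, mask].mean(axis=1)
    return SampledSignal(values=values, fs=frames.fps, t0=frames.t0,
                         meta={"roi": label, "channel": channel,
                               "kind": "ippg_raw"})


def invert_and_resample(signal: SampledSignal,
                        target_fs: float = DEFAULT_TARGET_FS) -> SampledSignal:
    """Invert the ROI trace and linearly interpolate onto a uniform
    ``target_fs`` grid spanning the same time range.

    Values at the original sample instants are preserved (negated) exactly.
    """
    if target_fs <= 0:
        raise ValueError("target sampling rate must be positive")
    if signal.n < 2:
        raise ValueError("need at least two samples to interpolate")
    t_old = signal.times
    n_new = int(np.floor((t_old[-1] - t_old[0]) * target_fs)) + 1
    t_new = t_old[0] + np.arange(n_new) / target_fs
    values = np.interp(t_new, t_old, -signal.values)
    meta = dict(signal.meta)
    meta["kind"] = "ippg"
    return SampledSignal(values=values, fs=target_fs, t0=signal.t0, meta=meta)
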