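"""Video stack I/O, calibration and per-pixel trace handling for PVM data.

Polarized video microscopy (PVM) records transmitted intensity between
crossed polarizers; a crystal's birefringence makes lattice rearrangements
visible as per-pixel intensity changes.  This module reads grayscale video
stacks (multi-page TIFF or a directory of frame images), converts RGB
frames to luma, selects square regions of interest, and applies the
centered moving-average smoothing used upstream of derivative analysis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "IntensityVideo",
    "OpticsCalibration",
    "RoiSpec",
    "PixelTrace",
    "load_video_frames",
    "save_video",
    "to_grayscale",
    "extract_roi",
    "extract_traces",
    "smooth_trace",
    "smooth_stack",
    "diffraction_limit",
    "moving_average",
]

#: ITU-R BT.601 luma weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: PVM camera pixel size in nm.
DEFAULT_PIXEL_SIZE_NM = 24.75


@dataclass
class IntensityVideo:
    """A T x H x W grayscale intensity stack with time/space calibration.

    ``time_zero_frame`` records the index, in the *original* recording, of
    the first retained frame; times reported by :attr:`times` are relative
    to that frame.
    """

    data: np.ndarray
    frame_interval: float
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM
    time_zero_frame: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"video data must be T x H x W, got shape {self.data.shape}")
        if self.data.shape[0] < 2:
            raise ValueError("video must contain at least 2 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("video intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds, zero at the first retained frame."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class OpticsCalibration:
    """Microscope optics: wavelength (nm), numerical aperture, pixel size (nm)."""

    wavelength: float
    numerical_aperture: float
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not 0 < self.numerical_aperture <= 1.7:
            raise ValueError("numerical aperture must lie in (0, 1.7]")


@dataclass(frozen=True)
class RoiSpec:
    """Square region of interest: top-left corner (row, col) and side length."""

    row: int
    col: int
    side: int

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("ROI side must be positive")
        if self.row < 0 or self.col < 0:
            raise ValueError("ROI corner must be non-negative")


@dataclass
class PixelTrace:
    """One pixel's intensity time series."""

    pixel: int
    row: int
    col: int
    intensities: np.ndarray
    frame_interval: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.intensities)) * self.frame_interval


def to_grayscale(stack: np.ndarray) -> np.ndarray:
    """Convert an RGB frame stack to grayscale luma (BT.601 weights).

    Already-grayscale input (no trailing 3-channel axis) passes through
    unchanged.
    """
    stack = np.asarray(stack)
    if stack.ndim >= 1 and stack.shape[-1] == 3:
        return stack.astype(np.float64) @ LUMA_WEIGHTS
    if stack.ndim in (2, 3):  # single frame or T x H x W
        return stack
    raise ValueError(f"expected grayscale or ...x3 RGB data, got shape {stack.shape}")


def _read_frame(path: Path) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)


def load_video_frames(
    path: str | os.PathLike,
    frame_interval: float,
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM,
    start_frame: int = 0,
) -> IntensityVideo:
    """Load a multi-page TIFF or a directory of ordered frame images.

    Frames before ``start_frame`` are dropped, so original frame ``j`` maps
    to time ``(j - start_frame) * frame_interval``.  RGB frames are
    converted to grayscale luma on load.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.is_file())
        if not files:
            raise IOError(f"no frame files in directory {path}")
        frames = [_read_frame(p) for p in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise IOError(f"inconsistent frame shapes in {path}: {sorted(shapes)}")
        data = np.stack(frames)
    else:
        import tifffile

        try:
            data = tifffile.imread(path)
        except Exception as exc:  # pragma: no cover - delegated parser detail
            raise IOError(f"could not read video stack {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[-1] == 3:  # stack of RGB frames
        data = to_grayscale(data)
    if data.ndim == 2:
        data = data[None]
    if not 0 <= start_frame < data.shape[0]:
        raise ValueError(f"start_frame {start_frame} outside stack of {data.shape[0]} frames")
    return IntensityVideo(
        data=np.asarray(data[start_frame:], dtype=np.float32),
        frame_interval=frame_interval,
        pixel_size=pixel_size,
        time_zero_frame=start_frame,
    )


def save_video(video: IntensityVideo, path: str | os.PathLike) -> None:
    """Write a video as a multi-page float32 TIFF (round-trips bit-exactly)."""
    import tifffile

    tifffile.imwrite(
        Path(path), np.asarray(video.data, dtype=np.float32), photometric="minisblack"
    )


def extract_roi(video: IntensityVideo, roi: RoiSpec) -> IntensityVideo:
    """Copy out a square ROI; yields ``side**2`` pixel traces."""
    if roi.row + roi.side > video.height or roi.col + roi.side > video.width:
        raise ValueError(
            f"ROI {roi} exceeds frame of {video.height} x {video.width} pixels"
        )
    sub = video.data[:, roi.row : roi.row + roi.side, roi.col : roi.col + roi.side].copy()
    return replace(video, data=sub)


def extract_traces(video: IntensityVideo) -> list[PixelTrace]:
    """Unravel a video into per-pixel traces in row-major pixel order."""
    T, H, W = video.data.shape
    flat = video.data.reshape(T, H * W)
    return [
        PixelTrace(
            pixel=i,
            row=i // W,
            col=i % W,
            intensities=flat[:, i].astype(np.float64),
            frame_interval=video.frame_interval,
        )
        for i in range(H * W)
    ]


def window_steps(window_seconds: float, frame_interval: float) -> int:
    """Convert a window in seconds to an odd number of frame steps.

    Rounds to the nearest integer and bumps even counts up by one so the
    window is centered (e.g. 15.2 s at 0.3897 s/frame -> 39 steps).
    """
    if window_seconds < frame_interval:
        raise ValueError("smoothing window must be at least one frame interval")
    n = int(round(window_seconds / frame_interval))
    if n % 2 == 0:
        n += 1
    return max(n, 1)


def moving_average(x: np.ndarray, n: int, axis: int = 0) -> np.ndarray:
    """Centered moving average of odd width ``n`` with shrinking edge windows.

    At the edges the window is truncated to the available samples, which
    keeps early/late features unbiased in position (no reflection).
    """
    if n % 2 == 0 or n < 1:
        raise ValueError("window length must be odd and positive")
    x = np.asarray(x, dtype=np.float64)
    T = x.shape[axis]
    if n > 2 * T - 1:
        raise ValueError(f"window of {n} steps is too long for {T} samples")
    if n == 1:
        return x.copy()
    x_moved = np.moveaxis(x, axis, 0)
    half = n // 2
    csum = np.concatenate(
        [np.zeros((1,) + x_moved.shape[1:]), np.cumsum(x_moved, axis=0)], axis=0
    )
    idx = np.arange(T)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, T)
    out = (csum[hi] - csum[lo]) / (hi - lo).reshape((-1,) + (1,) * (x_moved.ndim - 1))
    return np.moveaxis(out, 0, axis)


def smooth_trace(
    trace: np.ndarray, window_seconds: float, frame_interval: float
) -> np.ndarray:
    """Sliding-window (boxcar) time smoothing of an intensity trace.

    The window is ``round(window_seconds / frame_interval)`` steps, forced
    odd; edges use shrinking windows.  Length is preserved.
    """
    n = window_steps(window_seconds, frame_interval)
    trace = np.asarray(trace, dtype=np.float64)
    if n > 2 * len(trace) - 1:
        raise ValueError("smoothing window longer than trace")
    return moving_average(trace, n, axis=0)


def smooth_stack(video: IntensityVideo, window_seconds: float) -> IntensityVideo:
    """Apply :func:`smooth_trace` to every pixel of a video (vectorized)."""
    n = window_steps(window_seconds, video.frame_interval)
    out = moving_average(video.data, n, axis=0)
    return replace(video, data=out.astype(np.float32))


def diffraction_limit(cal: OpticsCalibration) -> float:
    """Theoretical lateral resolution Δx = λ / (2 NA), in nm."""
    return cal.wavelength / (2.0 * cal.numerical_aperture)
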