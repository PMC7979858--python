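"""Per-pixel transition detection in -dI/dt derivative traces.

A lattice phase transition shows up as a sharp drop in transmitted
intensity, i.e. a peak in the negated time derivative.  Detection follows
the classic smoothed-slope zero-crossing scheme: smooth the derivative,
find downward zero-crossings of its point-to-point slope that clear slope
and amplitude thresholds, then fit a Gaussian to the log of the points
around each apex (a parabola in log space) to obtain the transition time
(fitted center), amplitude, and duration (half-width at half-max).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .video import IntensityVideo, moving_average, window_steps

__all__ = [
    "DerivativeTrace",
    "PeakFindParams",
    "TransitionEvent",
    "PixelTransitionSet",
    "negated_derivative",
    "find_peaks",
    "detect_pixel_transitions",
    "trace_summary",
    "fastsmooth",
]

logger = logging.getLogger(__name__)

#: Derivative smoothing window used for peak analysis (s).
DEFAULT_DERIV_SMOOTH_S = 7.78

#: Intensity smoothing window applied before differentiation (s).
DEFAULT_TRACE_SMOOTH_S = 15.2

#: Half-width at half-max of the derivative of a logistic step, per unit tau.
LOGISTIC_HWHM_PER_TAU = math.log(3 + 2 * math.sqrt(2))


@dataclass
class DerivativeTrace:
    """-dI/dt over time, with the smoothing window that produced it."""

    values: np.ndarray
    frame_interval: float
    smooth_seconds: float = 0.0
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) * self.frame_interval


@dataclass(frozen=True)
class PeakFindParams:
    """Peak-finding knobs (matched to the Matlab-style findpeaks routine).

    ``smooth_width`` and ``fit_width`` are in points; thresholds are in the
    derivative's own units when ``amp_mode="raw"`` (default), or as a
    fraction of the trace's maximum smoothed derivative when
    ``amp_mode="normalized"``.
    """

    slope_threshold: float = 1e-5
    amp_threshold: float = 0.6
    smooth_width: int = 50
    fit_width: int = 39
    smooth_type: str = "pseudo-gaussian"
    peak_group: int = 2
    amp_mode: str = "raw"

    def __post_init__(self) -> None:
        if self.slope_threshold < 0 or self.amp_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.smooth_width < 3 or self.fit_width < 3:
            raise ValueError("smooth_width and fit_width must be >= 3 points")
        if self.smooth_type not in {"rect", "triangular", "pseudo-gaussian"}:
            raise ValueError(f"unknown smooth_type {self.smooth_type!r}")
        if self.peak_group < 1:
            raise ValueError("peak_group must be >= 1")
        if self.amp_mode not in {"raw", "normalized"}:
            raise ValueError(f"unknown amp_mode {self.amp_mode!r}")


@dataclass
class TransitionEvent:
    """One detected transition: fitted peak center, HWHM and amplitude."""

    time: float
    half_width: float
    amplitude: float
    pixel: int = -1
    label: str | None = None


@dataclass
class PixelTransitionSet:
    """All events detected in a video, plus per-pixel bookkeeping.

    ``events`` is a DataFrame with columns pixel, row, col, time_s,
    half_width_s, amplitude; ``counts`` is the per-pixel event count
    (row-major), and ``count_histogram`` maps event count -> #pixels.
    """

    events: "object"
    counts: np.ndarray
    frame_interval: float
    n_failed: int = 0

    @property
    def count_histogram(self) -> dict[int, int]:
        vals, n = np.unique(self.counts, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, n)}


def _odd(n: int) -> int:
    n = int(round(n))
    return n if n % 2 == 1 else n + 1


def fastsmooth(y: np.ndarray, width: int, smooth_type: str = "rect") -> np.ndarray:
    """Multi-pass boxcar smoothing with shrinking edges.

    ``rect`` is one pass of the full width; ``triangular`` two passes of
    ~width/2; ``pseudo-gaussian`` three passes of ~width/3 — in each case
    the nominal width is the total effective width of the kernel.
    """
    passes = {"rect": 1, "triangular": 2, "pseudo-gaussian": 3}[smooth_type]
    w = max(3, _odd(math.ceil(width / passes)))
    out = np.asarray(y, dtype=np.float64)
    for _ in range(passes):
        out = moving_average(out, min(w, 2 * len(out) - 1), axis=0)
    return out


def negated_derivative(
    trace: np.ndarray,
    frame_interval: float,
    smooth_seconds: float = DEFAULT_DERIV_SMOOTH_S,
    t0: float = 0.0,
) -> DerivativeTrace:
    """-dI/dt by central finite differences, then boxcar smoothing.

    One-sided differences are used at the endpoints; pass
    ``smooth_seconds=0`` to skip the smoothing step.  Length is preserved.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1 or len(trace) < 3:
        raise ValueError("trace must be 1D with at least 3 samples")
    d = -np.gradient(trace, frame_interval)
    if smooth_seconds > 0:
        n = window_steps(max(smooth_seconds, frame_interval), frame_interval)
        d = moving_average(d, min(n, 2 * len(d) - 1), axis=0)
    return DerivativeTrace(
        values=d, frame_interval=frame_interval, smooth_seconds=smooth_seconds, t0=t0
    )


def _fit_gaussian_log_parabola(
    x: np.ndarray, y: np.ndarray, group: int
) -> tuple[float, float, float] | None:
    """Gaussian fit via parabola on log-heights of grouped points.

    Consecutive points are averaged in bins of ``group``; non-positive bins
    are excluded.  Returns (center, hwhm, height) or None if the fit is
    degenerate (fewer than 3 usable bins or non-concave parabola).
    """
    n = len(x)
    if group > 1:
        nb = n // group
        if nb < 3:
            nb, group = n, 1
        x = x[: nb * group].reshape(nb, group).mean(axis=1)
        y = y[: nb * group].reshape(nb, group).mean(axis=1)
    good = y > 0
    if good.sum() < 3:
        return None
    xg, yg = x[good], np.log(y[good])
    xc = xg.mean()
    c2, c1, c0 = np.polyfit(xg - xc, yg, 2)
    if c2 >= 0:
        return None
    center = xc - c1 / (2 * c2)
    sigma = math.sqrt(-1.0 / (2 * c2))
    height = math.exp(c0 - c1**2 / (4 * c2))
    hwhm = math.sqrt(2 * math.log(2)) * sigma
    return center, hwhm, height


def find_peaks(deriv: DerivativeTrace, params: PeakFindParams | None = None) -> list[TransitionEvent]:
    """Detect and fit peaks in a -dI/dt trace.

    Candidates are downward zero-crossings of the slope of the smoothed
    trace whose preceding slope exceeds ``slope_threshold`` and whose
    height clears ``amp_threshold``; each candidate is refined by a
    Gaussian (log-parabola) fit over ``fit_width`` points around the apex.
    Candidates whose fitted centers lie closer than half a fit window are
    merged, keeping the taller.  Failed fits are dropped.
    """
    params = params or PeakFindParams()
    y = np.asarray(deriv.values, dtype=np.float64)
    if not np.any(np.isfinite(y)):
        raise ValueError("derivative trace has no finite values")
    n = len(y)
    dt = deriv.frame_interval
    ys = fastsmooth(y, params.smooth_width, params.smooth_type)
    slope = np.diff(ys)

    amp_floor = params.amp_threshold
    if params.amp_mode == "normalized":
        top = float(np.max(ys))
        if top <= 0:
            return []
        amp_floor = params.amp_threshold * top

    # downward zero-crossings of the smoothed slope
    cross = np.flatnonzero((slope[:-1] > 0) & (slope[1:] <= 0)) + 1
    w = _odd(params.fit_width)
    half = w // 2
    events: list[TransitionEvent] = []
    tgrid = deriv.times
    for j in cross:
        if slope[j - 1] <= params.slope_threshold:
            continue
        if y[j] <= amp_floor:
            continue
        lo = max(0, j - half)
        hi = min(n, j + half + 1)
        apex = lo + int(np.argmax(y[lo:hi]))
        lo = max(0, apex - half)
        hi = min(n, apex + half + 1)
        fit = _fit_gaussian_log_parabola(tgrid[lo:hi], y[lo:hi], params.peak_group)
        if fit is None:
            logger.debug("dropping candidate at index %d: degenerate fit", j)
            continue
        center, hwhm, height = fit
        if not (tgrid[0] <= center <= tgrid[-1]) or hwhm <= 0:
            logger.debug("dropping candidate at index %d: center out of span", j)
            continue
        events.append(TransitionEvent(time=center, half_width=hwhm, amplitude=height))

    events.sort(key=lambda e: e.time)
    merged: list[TransitionEvent] = []
    min_sep = (w / 2.0) * dt
    for ev in events:
        if merged and ev.time - merged[-1].time < min_sep:
            if ev.amplitude > merged[-1].amplitude:
                merged[-1] = ev
        else:
            merged.append(ev)
    return merged


def detect_pixel_transitions(
    video: IntensityVideo,
    trace_smooth_seconds: float = DEFAULT_TRACE_SMOOTH_S,
    deriv_smooth_seconds: float = DEFAULT_DERIV_SMOOTH_S,
    params: PeakFindParams | None = None,
    chunk_pixels: int = 4096,
) -> PixelTransitionSet:
    """Smooth, differentiate and peak-fit every pixel trace of a video.

    Per-pixel failures are logged and recorded as zero detections; the run
    never aborts.  Deterministic for fixed input.
    """
    import pandas as pd

    params = params or PeakFindParams()
    T, H, W = video.data.shape
    if T < 50:
        raise ValueError("video too short for transition detection (need >= 50 frames)")
    npix = H * W
    flat = video.data.reshape(T, npix)
    n_smooth = window_steps(trace_smooth_seconds, video.frame_interval)
    n_dsm = window_steps(max(deriv_smooth_seconds, video.frame_interval), video.frame_interval)

    rows: list[tuple] = []
    counts = np.zeros(npix, dtype=int)
    n_failed = 0
    for p0 in range(0, npix, chunk_pixels):
        p1 = min(p0 + chunk_pixels, npix)
        block = moving_average(flat[:, p0:p1], n_smooth, axis=0)
        dblock = -np.gradient(block, video.frame_interval, axis=0)
        if deriv_smooth_seconds > 0:
            dblock = moving_average(dblock, n_dsm, axis=0)
        for k in range(p1 - p0):
            pix = p0 + k
            deriv = DerivativeTrace(
                values=dblock[:, k],
                frame_interval=video.frame_interval,
                smooth_seconds=deriv_smooth_seconds,
            )
            try:
                evs = find_peaks(deriv, params)
            except Exception:
                logger.warning("pixel %d: peak detection failed", pix, exc_info=True)
                n_failed += 1
                continue
            counts[pix] = len(evs)
            for ev in evs:
                rows.append((pix, pix // W, pix % W, ev.time, ev.half_width, ev.amplitude))

    events = pd.DataFrame(
        rows, columns=["pixel", "row", "col", "time_s", "half_width_s", "amplitude"]
    )
    if n_failed:
        logger.info("detection finished with %d failed pixels of %d", n_failed, npix)
    return PixelTransitionSet(
        events=events, counts=counts, frame_interval=video.frame_interval, n_failed=n_failed
    )


def trace_summary(trace: np.ndarray, edge_fraction: float = 0.05) -> tuple[float, float, float]:
    """(initial, final, fractional loss) of a trace.

    Initial/final are means over the first/last ``edge_fraction`` of
    frames; loss = 1 - final/initial.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1 or len(trace) < 2:
        raise ValueError("trace must be 1D with at least 2 samples")
    k = max(1, int(round(edge_fraction * len(trace))))
    initial = float(trace[:k].mean())
    final = float(trace[-k:].mean())
    if initial == 0:
        raise ZeroDivisionError("initial intensity is zero; fractional loss undefined")
    return initial, final, 1.0 - final / initial
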