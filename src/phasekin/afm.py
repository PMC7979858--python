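"""Unit-cell measurement from AFM topographs via 2D autocorrelation.

An AFM height image of a crystal face is a noisy, tilted sample of a
periodic surface.  The workflow mirrors standard scanning-probe practice:
line-by-line first-order flattening, optional denoising (FFT low-pass or
correlation averaging), normalized 2D autocorrelation, and reading the
in-plane lattice vectors off the most prominent autocorrelation peaks with
sub-pixel quadratic refinement.  A c-axis time series over an image
sequence, with nearest-reference phase labels (AUC / TUC1 / TUC2 ...),
summarizes a lattice transition.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Topograph",
    "AutocorrelationMap",
    "UnitCellMeasurement",
    "LatticeTimeSeries",
    "PHASE_REFERENCES_NM",
    "load_topograph",
    "flatten_lines",
    "denoise",
    "autocorrelate",
    "measure_unit_cell",
    "measure_regions",
    "caxis_timeseries",
]

logger = logging.getLogger(__name__)

#: Reference c-axis lengths (nm) of the lattice phases traversed during the
#: ligand-triggered transition: apo cell, transition cells 1 and 2.
PHASE_REFERENCES_NM = {"AUC": 9.3, "TUC1": 7.9, "TUC2": 12.4}

#: A measurement is labeled with the nearest reference phase only if the
#: c-axis deviates by at most this much (nm); otherwise "intermediate".
PHASE_MAX_DEVIATION_NM = 1.0


@dataclass
class Topograph:
    """An H x W height map in nm with nm-per-pixel calibration."""

    heights: np.ndarray
    nm_per_px: float
    index: int | None = None
    time_s: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2D array")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if self.nm_per_px <= 0:
            raise ValueError("nm_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape  # type: ignore[return-value]


def load_topograph(path: str | os.PathLike, nm_per_px: float, **meta) -> Topograph:
    """Read a topograph from TIFF or a whitespace-delimited text matrix."""
    from pathlib import Path

    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        h = tifffile.imread(path)
    else:
        h = np.loadtxt(path)
    return Topograph(heights=np.asarray(h, dtype=np.float64), nm_per_px=nm_per_px, **meta)


def flatten_lines(topo: Topograph) -> Topograph:
    """Per-row first-order flattening: subtract each row's least-squares
    line (removes sample tilt, as applied line-by-line during scanning)."""
    h = topo.heights
    H, W = h.shape
    if W < 3:
        raise ValueError("need at least 3 columns to flatten")
    x = np.arange(W, dtype=np.float64)
    xc = x - x.mean()
    denom = float(xc @ xc)
    slopes = (h @ xc) / denom
    means = h.mean(axis=1)
    flat = h - means[:, None] - slopes[:, None] * xc[None, :]
    return replace(topo, heights=flat)


def denoise(
    topo: Topograph,
    mode: str = "fft_lowpass",
    cutoff_per_nm: float | None = None,
    patch_px: int | None = None,
) -> Topograph:
    """Remove random noise before autocorrelation.

    ``fft_lowpass`` zeroes spatial frequencies above ``cutoff_per_nm``
    (cycles/nm, defaulting to half Nyquist) and inverse-transforms.
    ``correlation_average`` tiles the image into ``patch_px``-sized patches,
    registers each to the central patch by cross-correlation, averages
    them, and tiles the average back over the image.
    """
    h = topo.heights
    if mode == "fft_lowpass":
        nyquist = 1.0 / (2.0 * topo.nm_per_px)
        if cutoff_per_nm is None:
            cutoff_per_nm = 0.5 * nyquist
        if not 0 < cutoff_per_nm <= nyquist:
            raise ValueError(f"cutoff must lie in (0, {nyquist:.4g}] cycles/nm")
        fy = np.fft.fftfreq(h.shape[0], d=topo.nm_per_px)
        fx = np.fft.fftfreq(h.shape[1], d=topo.nm_per_px)
        # separable mask so cutoff = Nyquist is the exact identity
        keep = (np.abs(fy[:, None]) <= cutoff_per_nm) & (np.abs(fx[None, :]) <= cutoff_per_nm)
        out = np.real(np.fft.ifft2(np.fft.fft2(h) * keep))
        return replace(topo, heights=out)
    if mode == "correlation_average":
        if patch_px is None or patch_px < 2:
            raise ValueError("correlation_average requires patch_px >= 2 (≈ one cell)")
        return _correlation_average(topo, patch_px)
    raise ValueError(f"unknown denoise mode {mode!r}")


def _correlation_average(topo: Topograph, patch_px: int) -> Topograph:
    from scipy.signal import fftconvolve

    h = topo.heights
    H, W = h.shape
    ny, nx = H // patch_px, W // patch_px
    if ny * nx < 2:
        raise ValueError("image smaller than two patches")
    patches = [
        h[i * patch_px : (i + 1) * patch_px, j * patch_px : (j + 1) * patch_px]
        for i in range(ny)
        for j in range(nx)
    ]
    ref = patches[len(patches) // 2]
    refz = ref - ref.mean()
    aligned = []
    for p in patches:
        pz = p - p.mean()
        xc = fftconvolve(refz, pz[::-1, ::-1], mode="same")
        dy, dx = np.unravel_index(np.argmax(xc), xc.shape)
        shift = (dy - patch_px // 2, dx - patch_px // 2)
        aligned.append(np.roll(pz, shift, axis=(0, 1)) + p.mean())
    avg = np.mean(aligned, axis=0)
    out = np.tile(avg, (ny, nx))
    full = h.copy()
    full[: ny * patch_px, : nx * patch_px] = out
    return replace(topo, heights=full)


@dataclass
class AutocorrelationMap:
    """Normalized 2D autocorrelation: value 1 at zero lag, centro-symmetric.

    ``values`` has shape (2H-1, 2W-1) with the origin at ``center``; lags
    are calibrated by ``nm_per_px``.
    """

    values: np.ndarray
    nm_per_px: float
    center: tuple[int, int]

    def lag_nm(self, row: int, col: int) -> tuple[float, float]:
        return (
            (row - self.center[0]) * self.nm_per_px,
            (col - self.center[1]) * self.nm_per_px,
        )

    def debiased(self) -> np.ndarray:
        """Overlap-corrected copy of :attr:`values`.

        The zero-padded (linear) autocorrelation tapers linearly with lag,
        which drags peak maxima toward the origin; dividing by the
        fractional overlap (H-|dy|)(W-|dx|)/(HW) removes that taper so
        peak positions are unbiased.
        """
        H, W = self.center[0] + 1, self.center[1] + 1
        dy = np.abs(np.arange(2 * H - 1) - (H - 1))
        dx = np.abs(np.arange(2 * W - 1) - (W - 1))
        overlap = np.outer(H - dy, W - dx) / (H * W)
        return self.values / overlap


def autocorrelate(topo: Topograph) -> AutocorrelationMap:
    """Mean-subtracted, normalized autocorrelation via FFT.

    Computes the full linear autocorrelation (zero-padded, so values taper
    toward large lags) and normalizes by the zero-lag value.
    """
    from scipy.signal import fftconvolve

    x = topo.heights - topo.heights.mean()
    norm = float(np.sum(x * x))
    if norm == 0:
        raise ValueError("constant image: autocorrelation normalization undefined")
    acf = fftconvolve(x, x[::-1, ::-1], mode="full")
    acf /= norm
    H, W = x.shape
    return AutocorrelationMap(values=acf, nm_per_px=topo.nm_per_px, center=(H - 1, W - 1))


@dataclass
class UnitCellMeasurement:
    """In-plane lattice vectors read from an autocorrelation map.

    Lengths are reported sorted (a <= c) with the inter-vector angle in
    degrees; ``ok`` is False (lengths NaN) when fewer than two acceptable
    peaks were found.
    """

    a_len_nm: float
    c_len_nm: float
    angle_deg: float
    prominences: tuple[float, float] = (np.nan, np.nan)
    method: str = "acf"
    ok: bool = True
    index: int | None = None
    time_s: float | None = None
    region: int | None = None

    @staticmethod
    def failure(**meta) -> "UnitCellMeasurement":
        return UnitCellMeasurement(np.nan, np.nan, np.nan, ok=False, **meta)


def _refine_subpixel(values: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Sub-pixel peak refinement by least-squares 2D quadratic on the 3x3
    neighborhood; offsets clipped to half a pixel."""
    r, c = peak
    win = values[r - 1 : r + 2, c - 1 : c + 2]
    dy, dx = np.mgrid[-1:2, -1:2]
    A = np.column_stack(
        [np.ones(9), dx.ravel(), dy.ravel(), dx.ravel() ** 2, (dx * dy).ravel(), dy.ravel() ** 2]
    )
    coef, *_ = np.linalg.lstsq(A, win.ravel(), rcond=None)
    _, b1, b2, b3, b4, b5 = coef
    Hmat = np.array([[2 * b3, b4], [b4, 2 * b5]])
    try:
        off = np.linalg.solve(Hmat, -np.array([b1, b2]))
    except np.linalg.LinAlgError:
        return float(r), float(c)
    off = np.clip(off, -0.5, 0.5)
    return float(r + off[1]), float(c + off[0])


def _vector_angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def _refine_by_harmonic(
    vec_nm: np.ndarray,
    values: np.ndarray,
    center: tuple[int, int],
    nm_per_px: float,
    floor: float,
    search_px: int = 3,
) -> np.ndarray:
    """Refine a lattice vector against its highest well-supported harmonic.

    The first-order ACF peak of a lattice spanning only a few periods can
    be dragged up to ~1 px toward the origin by partial-period sampling;
    reading the k-th order peak and dividing by k shrinks that error by k.
    The harmonic must keep at least ~40% image overlap and clear
    ``floor`` in debiased correlation, else the next lower order is tried.
    """
    cy, cx = center
    H, W = cy + 1, cx + 1
    v_px = vec_nm / nm_per_px
    kmax = int(min(
        (0.6 * H) / abs(v_px[1]) if abs(v_px[1]) > 1e-9 else np.inf,
        (0.6 * W) / abs(v_px[0]) if abs(v_px[0]) > 1e-9 else np.inf,
    ))
    for k in range(max(kmax, 1), 1, -1):
        tc = cx + k * v_px[0]
        tr = cy + k * v_px[1]
        r0, r1 = int(round(tr)) - search_px, int(round(tr)) + search_px + 1
        c0, c1 = int(round(tc)) - search_px, int(round(tc)) + search_px + 1
        if r0 < 1 or c0 < 1 or r1 > values.shape[0] - 1 or c1 > values.shape[1] - 1:
            continue
        win = values[r0:r1, c0:c1]
        rr, cc = np.unravel_index(np.argmax(win), win.shape)
        if win[rr, cc] < floor:
            continue
        pr, pc = _refine_subpixel(values, (r0 + rr, c0 + cc))
        return np.array([(pc - cx) * nm_per_px / k, (pr - cy) * nm_per_px / k])
    return vec_nm


def measure_unit_cell(
    acf: AutocorrelationMap,
    min_spacing_nm: float = 2.0,
    max_spacing_nm: float = 20.0,
    peak_floor: float = 0.05,
    min_angle_deg: float = 20.0,
    **meta,
) -> UnitCellMeasurement:
    """Read the two shortest non-collinear lattice vectors off an ACF.

    Local maxima (excluding the origin) with normalized correlation above
    ``peak_floor`` and spacing inside [min, max] nm are ranked; the
    shortest vector and the shortest vector at more than ``min_angle_deg``
    to it (lines compared modulo 180°) define the cell.  Peaks are refined
    to sub-pixel positions by a 3x3 quadratic fit.  Returns a failure
    result (not an exception) when fewer than two acceptable peaks exist.
    """
    from scipy.ndimage import maximum_filter

    v = acf.debiased()
    cy, cx = acf.center
    local_max = (v == maximum_filter(v, size=3)) & (v >= peak_floor)
    local_max[0, :] = local_max[-1, :] = False
    local_max[:, 0] = local_max[:, -1] = False
    rows, cols = np.nonzero(local_max)
    lag_nm = np.hypot(rows - cy, cols - cx) * acf.nm_per_px
    sel = (lag_nm >= max(min_spacing_nm, 2 * acf.nm_per_px)) & (lag_nm <= max_spacing_nm)
    # keep one representative of each centro-symmetric pair (upper half-plane)
    upper = (rows > cy) | ((rows == cy) & (cols > cx))
    sel &= upper
    rows, cols = rows[sel], cols[sel]
    if len(rows) < 2:
        return UnitCellMeasurement.failure(**meta)

    vecs = []
    for r, c in zip(rows, cols):
        rr, cc = _refine_subpixel(v, (r, c))
        vecs.append(
            (
                np.array([(cc - cx) * acf.nm_per_px, (rr - cy) * acf.nm_per_px]),
                float(v[r, c]),
            )
        )
    vecs.sort(key=lambda t: np.linalg.norm(t[0]))
    v1, p1 = vecs[0]
    for v2, p2 in vecs[1:]:
        ang = _vector_angle_deg(v1, v2)
        line_ang = min(ang, 180.0 - ang)
        if line_ang > min_angle_deg:
            v1r = _refine_by_harmonic(v1, v, acf.center, acf.nm_per_px, peak_floor)
            v2r = _refine_by_harmonic(v2, v, acf.center, acf.nm_per_px, peak_floor)
            ang = _vector_angle_deg(v1r, v2r)
            l1, l2 = float(np.linalg.norm(v1r)), float(np.linalg.norm(v2r))
            a_len, c_len = sorted((l1, l2))
            return UnitCellMeasurement(
                a_len_nm=a_len,
                c_len_nm=c_len,
                angle_deg=ang,
                prominences=(p1, p2),
                **meta,
            )
    return UnitCellMeasurement.failure(**meta)


def measure_regions(
    topo: Topograph,
    regions: list[tuple[int, int, int, int]],
    min_spacing_nm: float = 2.0,
    max_spacing_nm: float = 20.0,
    **kwargs,
) -> list[UnitCellMeasurement]:
    """Measure each rectangular region (row/col half-open bounds) of a
    mixed-phase image: flatten -> autocorrelate -> measure per region.
    Per-region failures yield failure results; the others proceed."""
    out = []
    for i, (r0, r1, c0, c1) in enumerate(regions):
        try:
            sub = Topograph(
                heights=topo.heights[r0:r1, c0:c1].copy(), nm_per_px=topo.nm_per_px
            )
            m = measure_unit_cell(
                autocorrelate(flatten_lines(sub)),
                min_spacing_nm,
                max_spacing_nm,
                region=i,
                index=topo.index,
                **kwargs,
            )
        except Exception:
            logger.warning("region %d failed", i, exc_info=True)
            m = UnitCellMeasurement.failure(region=i, index=topo.index)
        out.append(m)
    return out


@dataclass
class LatticeTimeSeries:
    """c-axis length vs serial image number with phase labels; gaps are
    explicit rows with NaN c and label 'gap'."""

    table: "object"  # pandas DataFrame

    def phase_changes(self) -> int:
        labels = [
            l for l in self.table["phase"] if l not in {"gap", "unassigned", "intermediate"}
        ]
        return sum(1 for a, b in zip(labels, labels[1:]) if a != b)


def caxis_timeseries(
    measurements: list[UnitCellMeasurement],
    references_nm: dict[str, float] | None = PHASE_REFERENCES_NM,
    max_deviation_nm: float = PHASE_MAX_DEVIATION_NM,
) -> LatticeTimeSeries:
    """Assemble a c-axis time series and assign phase labels.

    Each measurement is labeled with the nearest reference phase if its
    c-axis lies within ``max_deviation_nm`` of that reference, else
    "intermediate"; failed measurements become "gap" rows; with no
    references every row is "unassigned".
    """
    import pandas as pd

    if not measurements:
        raise ValueError("need at least one measurement")
    rows = []
    for i, m in enumerate(measurements):
        idx = m.index if m.index is not None else i
        if not m.ok or not np.isfinite(m.c_len_nm):
            phase = "gap"
        elif not references_nm:
            phase = "unassigned"
        else:
            name, ref = min(references_nm.items(), key=lambda kv: abs(kv[1] - m.c_len_nm))
            phase = name if abs(ref - m.c_len_nm) <= max_deviation_nm else "intermediate"
        rows.append(
            {
                "image_index": idx,
                "time_s": m.time_s,
                "region": m.region,
                "c_len_nm": m.c_len_nm,
                "a_len_nm": m.a_len_nm,
                "angle_deg": m.angle_deg,
                "phase": phase,
            }
        )
    table = pd.DataFrame(rows).sort_values(["image_index", "region"], na_position="first")
    return LatticeTimeSeries(table=table.reset_index(drop=True))
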