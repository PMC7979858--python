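"""Synthetic PVM videos and AFM topographs with known ground truth.

The generators emulate the two kinds of data the analysis pipelines
consume, with every parameter of the underlying model exposed:

* Per-pixel transmitted-intensity traces that decay through a sequence of
  logistic (sigmoidal) steps — the birefringence signature of a crystal
  converting through successive lattice phases (T1, T2a, T2b, T3), with
  ~50% total intensity loss by default.
* Periodic height maps (Gaussian motifs on an oblique 2D lattice) imitating
  AFM topographs of a crystal face, with tilt, roughness and optional
  mixed-phase regions.

Because the ground truth (per-pixel transition times, true lattice
vectors) is returned alongside the data, every downstream stage can be
tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .video import IntensityVideo

__all__ = [
    "TransitionSpec",
    "SyntheticTraceParams",
    "SyntheticVideoParams",
    "SyntheticLatticeParams",
    "RegionSpec",
    "MotifSite",
    "default_transitions",
    "generate_trace",
    "generate_video",
    "generate_topograph",
    "generate_mixed_topograph",
]

TRANSITION_LABELS = ("T1", "T2a", "T2b", "T3")

#: Frame interval implied by a 15.2 s / 39-step smoothing window (s).
DEFAULT_FRAME_INTERVAL = 0.3897

#: AFM calibration: 100 nm scan at 256 pixels.
DEFAULT_NM_PER_PX = 100.0 / 256.0


@dataclass(frozen=True)
class TransitionSpec:
    """One logistic intensity step: I drops by ``amplitude * I0`` around
    ``center_s`` with timescale ``tau_s`` (logistic time constant)."""

    label: str
    center_s: float
    tau_s: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError(f"{self.label}: tau must be positive")
        if not 0 < self.amplitude <= 1:
            raise ValueError(f"{self.label}: amplitude fraction must lie in (0, 1]")


def default_transitions() -> tuple[TransitionSpec, ...]:
    """Default four-step transition sequence.

    T1 is sharp and centered at 227 s; the later steps are spaced and
    broadened to give the characteristic multiphasic decay (the exact
    centers/timescales of T2a, T2b and T3 are model choices, overridable).
    Amplitudes sum to 0.5, i.e. 50% total intensity loss.
    """
    return (
        TransitionSpec("T1", 227.0, 1.0, 0.20),
        TransitionSpec("T2a", 347.0, 4.0, 0.10),
        TransitionSpec("T2b", 377.0, 6.0, 0.10),
        TransitionSpec("T3", 487.0, 8.0, 0.10),
    )


@dataclass
class SyntheticTraceParams:
    """Parameters of one multiphasic sigmoidal intensity trace.

    ``noise_sd`` is additive i.i.d. Gaussian camera noise in intensity
    units (default 1% of the baseline).
    """

    baseline_intensity: float = 200.0
    transitions: tuple[TransitionSpec, ...] = field(default_factory=default_transitions)
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        self.transitions = tuple(self.transitions)
        if self.baseline_intensity <= 0:
            raise ValueError("baseline intensity must be positive")
        if not self.transitions:
            raise ValueError("at least one transition is required")
        total = sum(t.amplitude for t in self.transitions)
        if not 0 < total <= 1:
            raise ValueError(f"amplitude fractions must sum into (0, 1], got {total}")
        centers = [t.center_s for t in self.transitions]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("transition centers must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def total_loss_fraction(self) -> float:
        return sum(t.amplitude for t in self.transitions)


def _logistic(u: np.ndarray) -> np.ndarray:
    # numerically safe sigmoid
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out


def generate_trace(
    params: SyntheticTraceParams,
    times: np.ndarray,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Evaluate I(t) = I0 [1 - Σ_k a_k S((t - t_k)/τ_k)] + ε(t).

    ``S`` is the logistic function, so each step loses half of its
    amplitude exactly at its center time; ε is i.i.d. Gaussian noise.
    """
    times = np.asarray(times, dtype=np.float64)
    if times.ndim != 1 or len(times) < 2:
        raise ValueError("times must be a 1D array of at least 2 samples")
    dt = np.diff(times)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0]):
        raise ValueError("times must be uniformly spaced and increasing")
    drop = np.zeros_like(times)
    for tr in params.transitions:
        drop += tr.amplitude * _logistic((times - tr.center_s) / tr.tau_s)
    trace = params.baseline_intensity * (1.0 - drop)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        trace = trace + rng.normal(0.0, params.noise_sd, size=trace.shape)
    return trace


@dataclass
class SyntheticVideoParams:
    """A video of jittered multiphasic traces.

    ``jitter_sd`` maps transition labels to the Gaussian spread (s) of
    per-pixel center times; the default 1.5 s for T1 makes ~90% of pixels
    transition within a 5 s window.  ``spatial_mode`` controls the
    deterministic part of the spatial field:

    * ``synchronous`` — none: jitter only (spatially uncorrelated);
    * ``gradient`` — linear left-to-right delay ramp of
      ``gradient_span_s`` seconds edge to edge (a synchrony
      counterexample);
    * ``nucleation`` — radial delay from the frame center at
      ``nucleation_speed_s_per_px`` seconds per pixel of distance.
    """

    trace_params: SyntheticTraceParams = field(default_factory=SyntheticTraceParams)
    height: int = 180
    width: int = 180
    n_frames: int = 1550
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    jitter_sd: dict[str, float] = field(
        default_factory=lambda: {lbl: 1.5 for lbl in TRANSITION_LABELS}
    )
    spatial_mode: str = "synchronous"
    gradient_span_s: float = 10.0
    nucleation_speed_s_per_px: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0 or self.n_frames < 2:
            raise ValueError("video dimensions must be positive (and >= 2 frames)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if any(s < 0 for s in self.jitter_sd.values()):
            raise ValueError("jitter sd must be non-negative")
        if self.spatial_mode not in {"synchronous", "gradient", "nucleation"}:
            raise ValueError(f"unknown spatial_mode {self.spatial_mode!r}")
        last = max(t.center_s for t in self.trace_params.transitions)
        max_tau = max(t.tau_s for t in self.trace_params.transitions)
        if self.n_frames * self.frame_interval <= last + 5 * max_tau:
            raise ValueError(
                "video too short: need n_frames * frame_interval > "
                f"{last + 5 * max_tau:.1f} s to cover the last transition"
            )


def _spatial_delay_field(params: SyntheticVideoParams) -> np.ndarray:
    H, W = params.height, params.width
    if params.spatial_mode == "gradient":
        ramp = np.linspace(0.0, params.gradient_span_s, W)
        return np.broadcast_to(ramp, (H, W)).copy()
    if params.spatial_mode == "nucleation":
        r = np.hypot(
            np.arange(H)[:, None] - (H - 1) / 2.0,
            np.arange(W)[None, :] - (W - 1) / 2.0,
        )
        return params.nucleation_speed_s_per_px * r
    return np.zeros((H, W))


def generate_video(
    params: SyntheticVideoParams,
) -> tuple[IntensityVideo, dict[str, np.ndarray]]:
    """Generate a jittered multiphasic video plus its ground-truth catalog.

    Returns the video and a mapping label -> (H, W) array of true per-pixel
    center times.  Deterministic for a fixed ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    tp = params.trace_params
    H, W, T = params.height, params.width, params.n_frames
    times = np.arange(T) * params.frame_interval
    delay = _spatial_delay_field(params)

    truth: dict[str, np.ndarray] = {}
    for tr in tp.transitions:
        sd = params.jitter_sd.get(tr.label, 0.0)
        centers = tr.center_s + delay
        if sd > 0:
            centers = centers + rng.normal(0.0, sd, size=(H, W))
        truth[tr.label] = centers

    data = np.empty((T, H, W), dtype=np.float32)
    # accumulate frame blocks to bound memory on large videos
    block = max(1, int(2e7 // (H * W)))
    for f0 in range(0, T, block):
        f1 = min(f0 + block, T)
        tblk = times[f0:f1][:, None, None]
        drop = np.zeros((f1 - f0, H, W), dtype=np.float64)
        for tr in tp.transitions:
            drop += tr.amplitude * _logistic((tblk - truth[tr.label]) / tr.tau_s)
        blk = tp.baseline_intensity * (1.0 - drop)
        if tp.noise_sd > 0:
            blk = blk + rng.normal(0.0, tp.noise_sd, size=blk.shape)
        data[f0:f1] = blk.astype(np.float32)

    video = IntensityVideo(data=data, frame_interval=params.frame_interval)
    return video, truth


# ---------------------------------------------------------------------------
# AFM topographs


@dataclass(frozen=True)
class MotifSite:
    """One Gaussian bump per unit cell: fractional cell position, width
    sigma (nm) and height (nm)."""

    frac_a: float = 0.0
    frac_c: float = 0.0
    sigma_nm: float = 1.2
    height_nm: float = 1.0


@dataclass
class SyntheticLatticeParams:
    """A periodic crystal-surface height model.

    The in-plane cell has vector ``a`` (length ``a_length`` nm, along the
    image x/column axis) and vector ``c`` (length ``c_length`` nm at
    ``cell_angle`` degrees from ``a``).  Defaults correspond to the apo
    lattice of the adenine-riboswitch crystal face: a = 4.83 nm,
    c = 9.3 nm, imaged at 100 nm / 256 px.
    """

    a_length: float = 4.83
    c_length: float = 9.3
    cell_angle: float = 90.0
    motif: tuple[MotifSite, ...] = (MotifSite(),)
    nm_per_px: float = DEFAULT_NM_PER_PX
    image_size: int | tuple[int, int] = 256
    tilt_plane: tuple[float, float] = (0.0, 0.0)
    roughness_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.motif = tuple(self.motif)
        if self.nm_per_px <= 0:
            raise ValueError("nm_per_px must be positive")
        if min(self.a_length, self.c_length) <= 2 * self.nm_per_px:
            raise ValueError("cell lengths must exceed 2 pixels")
        if not 0 < self.cell_angle < 180:
            raise ValueError("cell angle must lie in (0, 180) degrees")
        if self.roughness_sd < 0:
            raise ValueError("roughness_sd must be non-negative")
        H, W = self.shape
        span_a = W * self.nm_per_px / self.a_length
        span_c = H * self.nm_per_px / (self.c_length * np.sin(np.radians(self.cell_angle)))
        if span_a < 4 or span_c < 4:
            raise ValueError("image must cover at least 4 cells per axis")

    @property
    def shape(self) -> tuple[int, int]:
        if isinstance(self.image_size, int):
            return (self.image_size, self.image_size)
        return tuple(self.image_size)  # type: ignore[return-value]

    @property
    def lattice_matrix(self) -> np.ndarray:
        """Columns are the a and c lattice vectors in nm (x right, y down)."""
        beta = np.radians(self.cell_angle)
        a_vec = np.array([self.a_length, 0.0])
        c_vec = np.array([self.c_length * np.cos(beta), self.c_length * np.sin(beta)])
        return np.column_stack([a_vec, c_vec])

    def true_cell(self) -> dict[str, float]:
        return {
            "a_nm": self.a_length,
            "c_nm": self.c_length,
            "angle_deg": self.cell_angle,
            "row_spacing_px": self.c_length
            * np.sin(np.radians(self.cell_angle))
            / self.nm_per_px,
        }


def _lattice_height(params: SyntheticLatticeParams) -> np.ndarray:
    """Noise-free periodic height field (exact by construction).

    Pixels are mapped to fractional lattice coordinates; each motif site
    contributes Gaussians from its 3x3 nearest periodic images, so the
    field is exactly lattice-periodic.
    """
    H, W = params.shape
    M = params.lattice_matrix
    Minv = np.linalg.inv(M)
    x = np.arange(W) * params.nm_per_px
    y = np.arange(H) * params.nm_per_px
    X, Y = np.meshgrid(x, y)
    frac = np.tensordot(Minv, np.stack([X, Y]), axes=1)  # (2, H, W)
    h = np.zeros((H, W))
    offsets = [(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)]
    for site in params.motif:
        du = frac[0] - site.frac_a
        dv = frac[1] - site.frac_c
        du -= np.round(du)
        dv -= np.round(dv)
        for oi, oj in offsets:
            dx = M[0, 0] * (du + oi) + M[0, 1] * (dv + oj)
            dy = M[1, 0] * (du + oi) + M[1, 1] * (dv + oj)
            h += site.height_nm * np.exp(-(dx**2 + dy**2) / (2 * site.sigma_nm**2))
    return h


def generate_topograph(params: SyntheticLatticeParams):
    """Generate a lattice topograph plus its true cell constants.

    Returns ``(Topograph, dict)`` where the dict holds the designed
    a/c lengths (nm), cell angle (deg) and the c-lattice row spacing in px.
    """
    from .afm import Topograph

    H, W = params.shape
    h = _lattice_height(params)
    sx, sy = params.tilt_plane
    if sx or sy:
        h = h + sx * np.arange(W)[None, :] + sy * np.arange(H)[:, None]
    if params.roughness_sd > 0:
        rng = np.random.default_rng(params.seed)
        h = h + rng.normal(0.0, params.roughness_sd, size=h.shape)
    return Topograph(heights=h, nm_per_px=params.nm_per_px), params.true_cell()


@dataclass(frozen=True)
class RegionSpec:
    """A rectangle (0-based, half-open pixel bounds) filled from one lattice."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int
    lattice: SyntheticLatticeParams = field(default_factory=SyntheticLatticeParams)

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError("region bounds must be non-empty half-open ranges")

    @property
    def bounds(self) -> tuple[int, int, int, int]:
        return (self.row_start, self.row_stop, self.col_start, self.col_stop)


def generate_mixed_topograph(
    regions: list[RegionSpec],
    noise_sd: float = 0.0,
    seed: int = 0,
    blend_px: int = 2,
):
    """Compose a topograph from per-region lattices (e.g. a mixed-phase
    surface caught mid-transition, with different c-axes in different
    areas).

    Regions must be non-overlapping rectangles tiling the full canvas
    (inferred from their maximal extents); boundaries are blended over at
    most ``blend_px`` pixels.  Returns the composite Topograph and the
    per-region ground truths.
    """
    from scipy.ndimage import uniform_filter

    from .afm import Topograph

    if len(regions) < 2:
        raise ValueError("need at least two regions (use generate_topograph otherwise)")
    nm_per_px = regions[0].lattice.nm_per_px
    if any(abs(r.lattice.nm_per_px - nm_per_px) > 1e-12 for r in regions):
        raise ValueError("all regions must share one nm_per_px calibration")
    H = max(r.row_stop for r in regions)
    W = max(r.col_stop for r in regions)
    cover = np.zeros((H, W), dtype=int)
    for r in regions:
        cover[r.row_start : r.row_stop, r.col_start : r.col_stop] += 1
    if cover.max() > 1:
        raise ValueError("regions overlap")
    if cover.min() < 1:
        raise ValueError("regions must tile the full canvas")

    height = np.zeros((H, W))
    weight = np.zeros((H, W))
    truths = []
    for r in regions:
        lat = replace(r.lattice, image_size=(H, W), roughness_sd=0.0, tilt_plane=(0.0, 0.0))
        field_h = _lattice_height(lat)
        mask = np.zeros((H, W))
        mask[r.row_start : r.row_stop, r.col_start : r.col_stop] = 1.0
        if blend_px > 0:
            mask = uniform_filter(mask, size=2 * blend_px - 1, mode="nearest")
        height += mask * field_h
        weight += mask
        truths.append(lat.true_cell())
    height /= weight
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        height = height + rng.normal(0.0, noise_sd, size=height.shape)
    return Topograph(heights=height, nm_per_px=nm_per_px), truths
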