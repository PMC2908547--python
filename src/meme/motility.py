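"""Skeleton-derived motility metrics.

From a time series of arc-length-resampled midlines this module computes
the standard undulation read-outs for C. elegans locomotion:

* head/tail trajectories,
* the curvature kymograph kappa(s, t) — curvature along the body (s = 0 at
  the head end, s = 1 at the tail) over time, whose diagonal stripes are the
  signature of a traveling bending wave,
* the body bending frequency f from per-position 1-D FFTs of kappa(s_i, t),
* the wave speed c and wavelength lambda from the phase gradient of the
  dominant Fourier component along the body (the slope of the stripes), and
* PCA-aligned posture envelopes and the undulation amplitude.

Curvature is kappa = d(phi)/ds with phi the tangent angle along the
midline; it is evaluated on a smoothing-spline fit of the midline so that
pixel-level jitter does not leak into the derivatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .errors import ContractViolation, UndulationWarning

__all__ = [
    "SkeletonTimeSeries",
    "CurvatureField",
    "FrequencyResult",
    "WaveResult",
    "MotilityMetrics",
    "PostureEnvelope",
    "track_path",
    "curvature_profile",
    "curvature_field",
    "bending_frequency",
    "wave_speed_and_wavelength",
    "posture_envelope",
    "compute_metrics",
]


@dataclass
class SkeletonTimeSeries:
    """Stack of resampled midlines: (T, n_points, 2) as (row, col) floats."""

    points: NDArray[np.float64]
    fps: float
    pixel_size_mm: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 3 or self.points.shape[2] != 2:
            raise ContractViolation("series must have shape (T, n_points, 2)")
        if not self.fps > 0:
            raise ContractViolation("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_points(self) -> int:
        return self.points.shape[1]

    def body_length_px(self) -> float:
        seg = np.diff(self.points, axis=1)
        return float(np.mean(np.sum(np.hypot(seg[..., 0], seg[..., 1]), axis=1)))


@dataclass
class CurvatureField:
    """Curvature kymograph kappa[s_i, t_j] in 1/pixels on s in [0, 1]."""

    kappa: NDArray[np.float64]  # (n_points, T)
    s: NDArray[np.float64]      # (n_points,) in [0, 1], 0 = head end
    fps: float
    body_length_px: float

    @property
    def n_frames(self) -> int:
        return self.kappa.shape[1]


@dataclass
class FrequencyResult:
    frequency_hz: float
    per_position_hz: NDArray[np.float64]
    defined: bool
    low_resolution: bool = False


@dataclass
class WaveResult:
    speed_bl_per_s: float
    wavelength_bl: float
    coherent: bool
    phase_r2: float

    @property
    def speed_px_per_s(self) -> float:  # filled by compute_metrics when known
        raise AttributeError("use MotilityMetrics for pixel-unit speed")


@dataclass
class PostureEnvelope:
    aligned: NDArray[np.float64]   # (T, n_points, 2) in the body frame (x, y)
    lower: NDArray[np.float64]
    upper: NDArray[np.float64]
    amplitude_px: float


@dataclass
class MotilityMetrics:
    frequency_hz: float
    wave_speed_bl_per_s: float
    wavelength_bl: float
    beating_period_s: float
    amplitude_px: float
    body_length_px: float
    frequency: FrequencyResult | None = None
    wave: WaveResult | None = None

    def to_dict(self) -> dict:
        return {
            "frequency_hz": self.frequency_hz,
            "wave_speed_bl_per_s": self.wave_speed_bl_per_s,
            "wavelength_bl": self.wavelength_bl,
            "beating_period_s": self.beating_period_s,
            "amplitude_px": self.amplitude_px,
            "body_length_px": self.body_length_px,
        }


def track_path(series: SkeletonTimeSeries, end: str = "head") -> NDArray[np.float64]:
    """Per-frame coordinate of the chosen body end ('head' = index 0)."""
    if series.n_frames == 0:
        raise ContractViolation("empty series")
    if end not in ("head", "tail"):
        raise ContractViolation("end must be 'head' or 'tail'")
    idx = 0 if end == "head" else -1
    return series.points[:, idx, :].copy()


def curvature_profile(
    points: NDArray[np.float64], smooth_sigma_pts: float = 1.5
) -> NDArray[np.float64]:
    """Signed curvature kappa(s) in 1/px along a resampled midline.

    The coordinates are lightly smoothed with a Gaussian along the point
    index (sigma in sample spacings), the tangent angle phi = atan2(dy, dx)
    is unwrapped along the body and kappa = d(phi)/ds is taken by centered
    differences on the cumulative arc length.  Positive curvature is
    counterclockwise turning in (x=col, y=row) image coordinates.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    n = len(pts)
    if n < 5:
        raise ContractViolation("need at least 5 points for curvature")
    seg = np.hypot(*np.diff(pts, axis=0).T)
    if np.any(seg == 0.0):
        raise ContractViolation("repeated points in midline")
    sm = gaussian_filter1d(pts, smooth_sigma_pts, axis=0, mode="nearest")
    x, y = sm[:, 1], sm[:, 0]
    dx, dy = np.gradient(x), np.gradient(y)
    phi = np.unwrap(np.arctan2(dy, dx))
    step = np.hypot(dx, dy)
    s = np.concatenate([[0.0], np.cumsum(0.5 * (step[1:] + step[:-1]))])
    return np.gradient(phi, s)


def curvature_field(
    series: SkeletonTimeSeries, smooth_sigma_pts: float = 1.5
) -> CurvatureField:
    """Stack per-frame curvature profiles into a kymograph.

    Frame-to-frame orientation is enforced first: a skeleton whose point
    order is closer to the previous frame's when reversed is flipped, so the
    head end stays at s = 0 throughout.
    """
    pts = series.points.copy()
    for t in range(1, series.n_frames):
        same = np.sum((pts[t] - pts[t - 1]) ** 2)
        flipped = np.sum((pts[t, ::-1] - pts[t - 1]) ** 2)
        if flipped < same:
            pts[t] = pts[t, ::-1]
    n = series.n_points
    T = series.n_frames
    kappa = np.full((n, T), np.nan)
    for t in range(T):
        try:
            kappa[:, t] = curvature_profile(pts[t], smooth_sigma_pts)
        except ContractViolation:
            continue  # leave the column masked as NaN
    seg = np.diff(pts, axis=1)
    L = float(np.mean(np.sum(np.hypot(seg[..., 0], seg[..., 1]), axis=1)))
    return CurvatureField(
        kappa=kappa, s=np.linspace(0.0, 1.0, n), fps=series.fps, body_length_px=L
    )


def _dominant_bin(power: NDArray[np.float64]) -> int | None:
    """Index of the dominant non-DC bin, or None when it is not above noise."""
    if len(power) < 2:
        return None
    body = power[1:]
    peak = int(np.argmax(body)) + 1
    noise = np.median(body)
    if power[peak] <= 4.0 * max(noise, 1e-300):
        return None
    return peak


def bending_frequency(
    field: CurvatureField, fps: float | None = None
) -> FrequencyResult:
    """Body bending frequency from per-position FFTs of the kymograph.

    Each interior body position (s in [0.2, 0.8]) contributes the frequency
    of its dominant spectral peak (mean-detrended, Hann-windowed); the
    reported frequency is the median over positions.  Records shorter than
    two periods are flagged low-resolution; a field with no peak above the
    noise floor is flagged undefined.
    """
    fps = fps or field.fps
    kappa = field.kappa
    T = kappa.shape[1]
    if T < 4:
        return FrequencyResult(np.nan, np.array([]), defined=False)
    interior = np.nonzero((field.s >= 0.2) & (field.s <= 0.8))[0]
    freqs = np.fft.rfftfreq(T, d=1.0 / fps)
    window = signal.windows.hann(T)
    per_pos = []
    for i in interior:
        row = kappa[i]
        if not np.all(np.isfinite(row)):
            continue
        # effectively constant rows carry no undulation signal (guard
        # against float dust posing as a spectral peak)
        if np.ptp(row) < 1e-9 * max(1.0, np.abs(row).max()):
            continue
        spec = np.abs(np.fft.rfft((row - row.mean()) * window)) ** 2
        peak = _dominant_bin(spec)
        if peak is not None:
            per_pos.append(freqs[peak])
    per_pos_arr = np.asarray(per_pos)
    if len(per_pos_arr) == 0:
        warnings.warn(
            "no spectral peak above the noise floor; frequency undefined",
            UndulationWarning,
            stacklevel=2,
        )
        return FrequencyResult(np.nan, per_pos_arr, defined=False)
    f = float(np.median(per_pos_arr))
    low_res = f > 0 and (T / fps) < 2.0 / f
    if low_res:
        warnings.warn(
            "record shorter than two undulation periods; frequency estimate "
            "is poorly resolved",
            UndulationWarning,
            stacklevel=2,
        )
    return FrequencyResult(f, per_pos_arr, defined=True, low_resolution=low_res)


def wave_speed_and_wavelength(
    field: CurvatureField,
    fps: float | None = None,
    frequency: FrequencyResult | None = None,
) -> WaveResult:
    """Wave speed and wavelength from the stripe slope of the kymograph.

    The complex Fourier coefficient of each body position at the dominant
    temporal frequency gives a phase profile along s; its linear slope is
    -2*pi / lambda (lambda in body lengths).  A negative slope means the
    wave travels head to tail (forward motion, positive speed).  The speed
    is c = sign * f * lambda in body lengths per second; an incoherent phase
    profile (R^2 < 0.5) is flagged.
    """
    fps = fps or field.fps
    if frequency is None:
        frequency = bending_frequency(field, fps)
    if not frequency.defined:
        return WaveResult(np.nan, np.nan, coherent=False, phase_r2=0.0)
    kappa = field.kappa
    T = kappa.shape[1]
    freqs = np.fft.rfftfreq(T, d=1.0 / fps)
    bin_idx = int(np.argmin(np.abs(freqs - frequency.frequency_hz)))
    window = signal.windows.hann(T)
    interior = np.nonzero((field.s >= 0.15) & (field.s <= 0.85))[0]
    coeffs = []
    s_used = []
    for i in interior:
        row = kappa[i]
        if not np.all(np.isfinite(row)):
            continue
        coeffs.append(np.fft.rfft((row - row.mean()) * window)[bin_idx])
        s_used.append(field.s[i])
    if len(coeffs) < 3:
        return WaveResult(np.nan, np.nan, coherent=False, phase_r2=0.0)
    phase = np.unwrap(np.angle(np.asarray(coeffs)))
    s_arr = np.asarray(s_used)
    # Robust phase gradient: the median of local increments.  For a
    # traveling wave the increments are uniform; for a standing wave they
    # are ~zero except for a pi jump at the node, so the median correctly
    # reports no propagation.
    slope = float(np.median(np.diff(phase) / np.diff(s_arr)))
    intercept = float(np.median(phase - slope * s_arr))
    fitted = slope * s_arr + intercept
    ss_tot = float(np.sum((phase - phase.mean()) ** 2))
    ss_res = float(np.sum((phase - fitted) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if abs(slope) < 1e-9 or r2 < 0.5:
        warnings.warn(
            "phase profile incoherent; no traveling wave detected",
            UndulationWarning,
            stacklevel=2,
        )
        return WaveResult(np.nan, np.nan, coherent=False, phase_r2=r2)
    wavelength = 2.0 * np.pi / abs(slope)
    direction = -np.sign(slope)  # negative slope: head -> tail (forward)
    speed = float(direction * frequency.frequency_hz * wavelength)
    return WaveResult(
        speed_bl_per_s=speed,
        wavelength_bl=float(wavelength),
        coherent=True,
        phase_r2=r2,
    )


def posture_envelope(
    series: SkeletonTimeSeries, period_s: float | None = None
) -> PostureEnvelope:
    """PCA-aligned posture stack and its transverse min/max envelope.

    Each skeleton is translated to its centroid and rotated so its first
    principal axis is horizontal with the head end at negative x; the
    envelope is the per-position min/max transverse excursion over one
    beating period (or the whole record when no period is given), and the
    amplitude is the maximum envelope half-width.
    """
    if series.n_frames < 1:
        raise ContractViolation("empty series")
    pts = series.points
    aligned = np.empty_like(pts)
    for t in range(series.n_frames):
        p = pts[t] - pts[t].mean(axis=0)
        xy = np.stack([p[:, 1], p[:, 0]], axis=1)  # (x, y)
        _, _, vt = np.linalg.svd(xy, full_matrices=False)
        axis = vt[0]
        rot = np.array([[axis[0], axis[1]], [-axis[1], axis[0]]])
        a = xy @ rot.T
        if a[0, 0] > 0:  # head at negative x
            a = -a
        aligned[t, :, 1] = a[:, 0]  # store x in col slot
        aligned[t, :, 0] = a[:, 1]  # y in row slot
    # Canonical transverse sign: net positive excursion over the record.
    if aligned[..., 0].sum() < 0:
        aligned[..., 0] = -aligned[..., 0]
    if period_s is not None and period_s > 0:
        n_keep = max(1, min(series.n_frames, int(round(period_s * series.fps))))
    else:
        n_keep = series.n_frames
    y = aligned[:n_keep, :, 0]
    lower = y.min(axis=0)
    upper = y.max(axis=0)
    amplitude = float(np.max((upper - lower) / 2.0))
    return PostureEnvelope(
        aligned=aligned, lower=lower, upper=upper, amplitude_px=amplitude
    )


def compute_metrics(series: SkeletonTimeSeries) -> MotilityMetrics:
    """Full metric set for a skeleton time series."""
    field = curvature_field(series)
    freq = bending_frequency(field)
    wave = wave_speed_and_wavelength(field, frequency=freq)
    period = 1.0 / freq.frequency_hz if freq.defined and freq.frequency_hz > 0 else None
    env = posture_envelope(series, period_s=period)
    if wave.coherent:
        assert np.isclose(
            wave.wavelength_bl * freq.frequency_hz, abs(wave.speed_bl_per_s),
            rtol=1e-6,
        )
    return MotilityMetrics(
        frequency_hz=freq.frequency_hz,
        wave_speed_bl_per_s=wave.speed_bl_per_s,
        wavelength_bl=wave.wavelength_bl,
        beating_period_s=period if period is not None else np.nan,
        amplitude_px=env.amplitude_px,
        body_length_px=field.body_length_px,
        frequency=freq,
        wave=wave,
    )
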