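"""Wavefield-to-dispersion processing chain.

Mirrors the measurement pipeline of ultrasound vibrometry of a fluid-filled
compartment wall: beamformed IQ frames -> phase-based autocorrelation
particle velocity (Kasai) -> 3x3 spatial median filtering -> wall-profile
extraction along the wall centerline (arc-length resampled, median across
the wall thickness) -> 2D-FFT k-space phase-velocity estimation -> median
over replicate acquisitions -> the mean phase velocity variance (MPVV)
noise summary.

Median-based aggregation is used throughout because the velocity and
k-space estimators are nonlinear: outliers from acoustically dead regions
or bubbles otherwise dominate mean-based averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal.windows import tukey

from .curves import AcquisitionSet, DispersionCurve

__all__ = [
    "IQSequence",
    "VelocityMovie",
    "WallGeometry",
    "KSpaceSpectrum",
    "KSpaceConfig",
    "kasai_velocity",
    "median_filter_movie",
    "wall_profile",
    "kspace_spectrum",
    "kspace_dispersion",
    "median_over_acquisitions",
    "mpvv",
]


@dataclass
class IQSequence:
    """Complex beamformed IQ frames over (depth, lateral, time).

    ``prf`` is the effective frame rate after any compounding; ``f_demod``
    the demodulation frequency; ``c_us`` the assumed ultrasound sound
    speed; ``dx``/``dz`` the lateral/axial pixel pitches [m].
    """

    frames: np.ndarray
    prf: float
    f_demod: float
    c_us: float = 1540.0
    dx: float = 3e-4
    dz: float = 1.5e-4

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=complex)
        if self.frames.ndim != 3 or self.frames.shape[-1] < 2:
            raise ValueError("frames must be (depth, lateral, time) with >= 2 frames")
        if not self.prf > 0 or not self.f_demod > 0:
            raise ValueError("prf and f_demod must be positive")


@dataclass
class VelocityMovie:
    """Particle-velocity record [m/s].

    Full-movie form: v has shape (depth, lateral, time); wall-profile form:
    (arc-length position, time).  ``dx`` is the spatial pitch of the second
    -to-last axis interpretation (lateral pitch for movies, arc-length step
    for profiles); ``dt`` the frame interval.
    """

    v: np.ndarray
    dx: float
    dt: float

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim not in (2, 3):
            raise ValueError("v must be 2-D (profile) or 3-D (movie)")
        if not self.dx > 0 or not self.dt > 0:
            raise ValueError("dx and dt must be positive")

    @property
    def is_profile(self) -> bool:
        return self.v.ndim == 2


@dataclass
class WallGeometry:
    """Binary wall mask over (depth, lateral); pixel pitches [m].

    The centerline is the mask's mean depth per lateral column; the wall
    thickness at a column is the span of masked pixels there.
    """

    mask: np.ndarray
    dx: float
    dz: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError("mask must be a nonempty 2-D boolean array")


@dataclass
class KSpaceSpectrum:
    """2D-FFT magnitude over (frequency row, wavenumber column)."""

    magnitude: np.ndarray  # (n_f, n_k), nonnegative
    f: np.ndarray  # Hz, one-sided
    k: np.ndarray  # rad/m, two-sided (fftshifted ascending)


@dataclass(frozen=True)
class KSpaceConfig:
    """Peak-picking settings for k-space phase-velocity estimation."""

    pad: int = 4  # zero-padding factor per axis
    tukey_alpha: float = 0.1
    snr_min: float = 2.0
    direction_ratio_min: float = 0.25  # vs the stronger half-plane's peak
    min_positions: int = 16
    min_frames: int = 32


def kasai_velocity(iq: IQSequence, ensemble: int = 2) -> VelocityMovie:
    """Phase-based autocorrelation (Kasai) particle velocity.

    v = (c_us * prf / (4 pi f_demod)) * arg( sum of lag-1 products
    IQ_t * conj(IQ_{t+1}) over the ensemble window ).  Positive velocity is
    motion toward the transducer.  Velocities beyond
    c_us * prf / (4 * f_demod) alias (phase wraps).
    """
    if ensemble < 2:
        raise ValueError("ensemble must be >= 2 frames")
    nt = iq.frames.shape[-1]
    if nt < ensemble:
        raise ValueError(f"need at least {ensemble} frames, got {nt}")
    lag1 = iq.frames[..., :-1] * np.conj(iq.frames[..., 1:])
    win = ensemble - 1  # number of lag-1 products per estimate
    if win == 1:
        acc = lag1
    else:
        csum = np.cumsum(lag1, axis=-1)
        acc = np.concatenate([csum[..., win - 1:win],
                              csum[..., win:] - csum[..., :-win]], axis=-1)
    scale = iq.c_us * iq.prf / (4.0 * math.pi * iq.f_demod)
    return VelocityMovie(v=scale * np.angle(acc), dx=iq.dx, dt=1.0 / iq.prf)


def median_filter_movie(movie: VelocityMovie) -> VelocityMovie:
    """Per-frame spatial 3x3 median filter; borders by edge replication."""
    if movie.v.ndim != 3:
        raise ValueError("median filtering applies to (depth, lateral, time) movies")
    if movie.v.shape[0] < 3 or movie.v.shape[1] < 3:
        raise ValueError("spatial dimensions must be at least 3x3")
    out = ndimage.median_filter(movie.v, size=(3, 3, 1), mode="nearest")
    return VelocityMovie(v=out, dx=movie.dx, dt=movie.dt)


def wall_profile(movie: VelocityMovie, wall: WallGeometry) -> VelocityMovie:
    """Collapse a movie to a wall profile (arc length x time).

    Per lateral column, the velocity is the median across the masked wall
    thickness (robust to a corrupted row inside the wall).  The lateral
    coordinate is then re-parameterized as cumulative arc length along the
    wall centerline and resampled to a uniform step equal to the lateral
    pitch, compensating wall curvature to first order.  Columns with an
    empty mask are dropped before resampling (gap recorded via the
    returned profile's length).
    """
    if movie.v.ndim != 3:
        raise ValueError("wall_profile expects a (depth, lateral, time) movie")
    nz, nx, nt = movie.v.shape
    if wall.mask.shape != (nz, nx):
        raise ValueError(f"mask shape {wall.mask.shape} does not match movie "
                         f"spatial shape {(nz, nx)}")
    cols = [j for j in range(nx) if wall.mask[:, j].any()]
    if not cols:
        raise ValueError("wall mask does not overlap the movie support")
    # median across thickness, and centerline depth per retained column
    med = np.empty((len(cols), nt))
    zc = np.empty(len(cols))
    for i, j in enumerate(cols):
        rows = np.nonzero(wall.mask[:, j])[0]
        med[i] = np.median(movie.v[rows, j, :], axis=0)
        zc[i] = rows.mean()
    if len(cols) >= 5:
        # moving-average smoothing of the centerline suppresses the pixel
        # -quantization staircase that would inflate the arc length
        pad_z = np.concatenate([zc[:2][::-1], zc, zc[-2:][::-1]])
        zc = np.convolve(pad_z, np.full(5, 0.2), mode="valid")
    x = np.asarray(cols, dtype=float) * wall.dx
    z = zc * wall.dz
    seg = np.hypot(np.diff(x), np.diff(z))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("degenerate wall centerline (zero arc length)")
    ds = movie.dx
    s_uniform = np.arange(0.0, s[-1] + 0.5 * ds, ds)
    prof = np.empty((s_uniform.size, nt))
    for t in range(nt):
        prof[:, t] = np.interp(s_uniform, s, med[:, t])
    return VelocityMovie(v=prof, dx=ds, dt=movie.dt)


def kspace_spectrum(profile: VelocityMovie,
                    cfg: KSpaceConfig | None = None) -> KSpaceSpectrum:
    """Windowed, zero-padded 2D FFT magnitude of a wall profile.

    Tukey windows on both axes, padding factor ``cfg.pad``; rows are
    one-sided in frequency, columns two-sided in wavenumber (direction
    resolved; a wave travelling toward +x appears at negative k on the
    positive-frequency side with the FFT sign convention used here).
    """
    cfg = cfg or KSpaceConfig()
    if profile.v.ndim != 2:
        raise ValueError("kspace_spectrum expects a (position, time) profile")
    ns, nt = profile.v.shape
    if ns < cfg.min_positions or nt < cfg.min_frames:
        raise ValueError(f"profile too small: need >= {cfg.min_positions} "
                         f"positions and >= {cfg.min_frames} frames, got {ns}x{nt}")
    w = np.outer(tukey(ns, cfg.tukey_alpha), tukey(nt, cfg.tukey_alpha))
    spec = np.fft.fft2(profile.v * w, s=(cfg.pad * ns, cfg.pad * nt))
    k = 2.0 * math.pi * np.fft.fftfreq(cfg.pad * ns, d=profile.dx)
    f = np.fft.fftfreq(cfg.pad * nt, d=profile.dt)
    pos_f = f >= 0
    mag = np.abs(spec).T[pos_f][:, :]  # rows = f, cols = k
    order = np.argsort(k)
    return KSpaceSpectrum(magnitude=mag[:, order], f=f[pos_f], k=k[order])


def _quadratic_peak(kvals: np.ndarray, mags: np.ndarray, i: int) -> float:
    """Sub-bin quadratic interpolation of a peak location."""
    if 0 < i < len(mags) - 1:
        y0, y1, y2 = mags[i - 1], mags[i], mags[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # genuine local max
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            return float(kvals[i] + delta * (kvals[1] - kvals[0]))
    return float(kvals[i])


def kspace_dispersion(profile: VelocityMovie, f_grid,
                      cfg: KSpaceConfig | None = None
                      ) -> tuple[DispersionCurve, pd.DataFrame]:
    """Phase velocities from k-space magnitude peaks, c = 2 pi f / k.

    For each requested frequency (mapped to the nearest FFT row) the two
    direction half-planes (k < 0, k > 0) are searched separately; peaks
    below one pre-padding wavenumber bin of |k| = 0 are rejected (no
    spatial propagation).  Per half-plane SNR is the peak magnitude over
    the median magnitude of the frequency row; estimates with SNR below
    ``cfg.snr_min`` are dropped, and surviving directions are merged by
    median.  Returns the curve plus a per-frequency diagnostics table
    (snr_neg, snr_pos, c_neg, c_pos, reason for dropped samples).
    """
    cfg = cfg or KSpaceConfig()
    spec = kspace_spectrum(profile, cfg)
    ns = profile.v.shape[0]
    k_min = 2.0 * math.pi / (ns * profile.dx)  # one unpadded bin
    rows = []
    fs, cs = [], []
    for f_req in np.atleast_1d(np.asarray(f_grid, dtype=float)):
        i_f = int(np.argmin(np.abs(spec.f - f_req)))
        f_bin = float(spec.f[i_f])
        if f_bin <= 0:
            rows.append({"frequency_hz": f_req, "reason": "nonpositive bin"})
            continue
        row = spec.magnitude[i_f]
        row_median = float(np.median(row))
        i_global = int(np.argmax(row))
        if abs(spec.k[i_global]) < k_min:
            rows.append({"frequency_hz": f_bin, "snr_neg": np.nan,
                         "snr_pos": np.nan, "c_neg": np.nan, "c_pos": np.nan,
                         "reason": "peak at k ~ 0 (no spatial propagation)"})
            continue
        ests, snrs, peaks = {}, {}, {}
        for sign in (-1, 1):
            half = (spec.k * sign) >= k_min
            if not half.any():
                continue
            kv = spec.k[half]
            mv = row[half]
            ipk = int(np.argmax(mv))
            k_pk = abs(_quadratic_peak(kv, mv, ipk))
            snr = mv[ipk] / row_median if row_median > 0 else np.inf
            snrs[sign] = snr
            peaks[sign] = float(mv[ipk])
            if k_pk < k_min:
                continue
            if snr >= cfg.snr_min:
                ests[sign] = 2.0 * math.pi * f_bin / k_pk
        if peaks and ests:
            # a half-plane whose peak is only leakage from the other
            # direction sits far below the dominant peak: gate it out
            top = max(peaks.values())
            ests = {s: c for s, c in ests.items()
                    if peaks[s] >= cfg.direction_ratio_min * top}
        rec = {"frequency_hz": f_bin,
               "snr_neg": snrs.get(-1, np.nan), "snr_pos": snrs.get(1, np.nan),
               "c_neg": ests.get(-1, np.nan), "c_pos": ests.get(1, np.nan)}
        if ests:
            c = float(np.median(list(ests.values())))
            rec["reason"] = ""
            fs.append(f_bin)
            cs.append(c)
        else:
            rec["reason"] = "below SNR threshold or k ~ 0"
        rows.append(rec)
    diag = pd.DataFrame(rows)
    fs = np.asarray(fs)
    cs = np.asarray(cs)
    order = np.argsort(fs)
    fs, cs = fs[order], cs[order]
    keep = np.concatenate([[True], np.diff(fs) > 0]) if fs.size else np.array([], bool)
    return DispersionCurve(fs[keep], cs[keep]), diag


def median_over_acquisitions(acqset: AcquisitionSet,
                             bin_tol: float | None = None) -> DispersionCurve:
    """Per-frequency median across replicate curves.

    Curves on slightly different grids are aligned by nearest bin: samples
    whose frequencies agree within ``bin_tol`` (default half the smallest
    frequency step present) share a bin.  Frequencies present in half the
    acquisitions or fewer are dropped.
    """
    if len(acqset) == 0:
        raise ValueError("empty acquisition set")
    if len(acqset) == 1:
        return acqset.curves[0]
    steps = [float(np.min(np.diff(c.f))) for c in acqset.curves if len(c) > 1]
    if bin_tol is None:
        bin_tol = 0.5 * min(steps) if steps else 0.0
    bins: list[float] = []
    values: dict[int, list[float]] = {}
    for curve in acqset.curves:
        for f, c in zip(curve.f, curve.c):
            hit = None
            for i, fb in enumerate(bins):
                if abs(f - fb) <= bin_tol:
                    hit = i
                    break
            if hit is None:
                bins.append(float(f))
                hit = len(bins) - 1
                values[hit] = []
            values[hit].append(float(c))
    need = len(acqset) / 2.0
    out = [(fb, float(np.median(values[i])))
           for i, fb in enumerate(bins) if len(values[i]) > need]
    out.sort()
    if not out:
        raise ValueError("no frequency bin present in more than half the acquisitions")
    f_arr = np.array([p[0] for p in out])
    c_arr = np.array([p[1] for p in out])
    first = acqset.curves[0]
    return DispersionCurve(f_arr, c_arr, fill_volume_ml=first.fill_volume_ml)


def mpvv(acqset: AcquisitionSet, bin_tol: float | None = None) -> float:
    """Mean phase velocity variance [m^2/s^2].

    Sample variance (ddof=1) of phase velocity across replicate
    acquisitions per (fill volume, frequency) cell, averaged (unweighted)
    over all cells with at least two replicates.  A single scalar noise
    summary per experiment.
    """
    if len(acqset) == 0:
        raise ValueError("empty acquisition set")
    cells: dict[tuple[float | None, float], list[float]] = {}
    fills = acqset.fill_volumes or [None]
    for fill in fills:
        curves = (acqset.for_fill(fill).curves if fill is not None
                  else [c for c in acqset.curves if c.fill_volume_ml is None])
        steps = [float(np.min(np.diff(c.f))) for c in curves if len(c) > 1]
        tol = bin_tol if bin_tol is not None else (0.5 * min(steps) if steps else 0.0)
        bins: list[float] = []
        for curve in curves:
            for f, c in zip(curve.f, curve.c):
                hit = None
                for fb in bins:
                    if abs(f - fb) <= tol:
                        hit = fb
                        break
                if hit is None:
                    bins.append(float(f))
                    hit = float(f)
                cells.setdefault((fill, hit), []).append(float(c))
    variances = [np.var(v, ddof=1) for v in cells.values() if len(v) >= 2]
    if not variances:
        raise ValueError("no (fill, frequency) cell has two or more replicates")
    return float(np.mean(variances))
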