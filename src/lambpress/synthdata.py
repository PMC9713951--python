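"""Seeded generators for every input the pipeline consumes.

Each generator is the documented inverse of a processing stage:

* :func:`simulate_filling_experiment` <-> the forward mechanics that
  :mod:`lambpress.inversion` inverts (paired pressure–volume series),
* :func:`simulate_dispersion_measurements` <-> ``estimate_pressure``
  (replicate dispersion curves with noise and bubble-like outliers),
* :func:`simulate_wavefield` <-> ``kspace_dispersion`` (dispersive plane
  -wave superposition),
* :func:`simulate_iq` <-> ``kasai_velocity`` (exact phase-ramp inverse of
  the autocorrelation estimator),
* :func:`make_method_comparison_dataset` <-> ``lin_ccc_repeated``
  (crossed variance-component draws with a known population concordance).

All randomness flows from explicit integer seeds; outputs record them.

Default study conditions: a compartment with reference volume 200 ml,
undeformed half-thickness 2.75 mm, Demiray–Fung wall with mu0 = 5 kPa and
b = 5, filled in 10 ml increments from 210 to 360 ml — numbers chosen so
the forward pressures sweep ~1–50 mmHg, the physiological detrusor range,
with fill volumes comparable to ex vivo bladder protocols (initial volumes
of a few hundred ml, 10 ml increments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import AcquisitionSet, DispersionCurve
from .dispersion import CharacteristicContext, forward_dispersion_curve
from .mechanics import (CompartmentGeometry, FluidModel, MaterialModel,
                        demiray_fung_stress_difference, pressure_from_volume,
                        stretches_from_volumes)
from .units import ml_to_m3, pa_to_mmhg
from .wavefield import IQSequence, VelocityMovie

__all__ = [
    "NoiseSpec",
    "FillingProtocol",
    "DEFAULT_MATERIAL",
    "default_fill_volumes_ml",
    "simulate_filling_experiment",
    "simulate_dispersion_measurements",
    "simulate_wavefield",
    "simulate_iq",
    "make_method_comparison_dataset",
    "raised_cosine_spectrum",
]

DEFAULT_MATERIAL = MaterialModel(mu0=5e3, b_stiff=5.0)
DEFAULT_V0_ML = 200.0
DEFAULT_H0 = 2.75e-3


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model shared by the generators.

    ``sigma_c``: additive Gaussian noise on phase velocity [m/s];
    ``outlier_fraction``: fraction of samples replaced by multiplicative
    corruption (uniform on [0.5, 3] x truth), emulating bubble artifacts;
    ``pixel_sigma``: additive Gaussian pixel noise on wavefield movies
    [m/s]; ``seed``: RNG seed recorded in every artifact.
    """

    sigma_c: float = 0.0
    outlier_fraction: float = 0.0
    pixel_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_c < 0 or self.pixel_sigma < 0:
            raise ValueError("noise sigmas must be nonnegative")
        if not 0 <= self.outlier_fraction <= 1:
            raise ValueError("outlier_fraction must be in [0, 1]")


@dataclass
class FillingProtocol:
    """Forward-simulated filling experiment: per-fill geometry, stress and
    ground-truth pressure."""

    table: pd.DataFrame  # V_ml, lam1, lam2, h_m, t_diff_pa, P_true_pa, P_true_mmhg
    material: MaterialModel
    V0_ml: float
    h0: float


def default_fill_volumes_ml(start: float = 210.0, stop: float = 360.0,
                            step: float = 10.0) -> np.ndarray:
    return np.arange(start, stop + 0.5 * step, step)


def simulate_filling_experiment(fill_volumes_ml=None,
                                material: MaterialModel = DEFAULT_MATERIAL,
                                V0_ml: float = DEFAULT_V0_ML,
                                h0: float = DEFAULT_H0) -> FillingProtocol:
    """Forward mechanics over a filling protocol.

    Per fill: stretches from volumes, Demiray–Fung stress difference,
    thin-wall pressure, deformed half-thickness h = lam2 * h0.  Fills at or
    below the reference volume are rejected (slack wall carries no stress).
    """
    if fill_volumes_ml is None:
        fill_volumes_ml = default_fill_volumes_ml()
    fill_volumes_ml = np.asarray(fill_volumes_ml, dtype=float)
    V0 = ml_to_m3(V0_ml)
    rows = []
    for v_ml in fill_volumes_ml:
        V = ml_to_m3(v_ml)
        if V <= V0:
            raise ValueError(f"fill volume {v_ml} ml does not exceed the "
                             f"reference volume {V0_ml} ml (slack wall)")
        geom = CompartmentGeometry(V=V, V0=V0, h0=h0)
        defm = stretches_from_volumes(V, V0)
        t_diff = demiray_fung_stress_difference(defm, material).t_diff
        P = pressure_from_volume(geom, material)
        rows.append({"V_ml": v_ml, "lam1": defm.lam1, "lam2": defm.lam2,
                     "h_m": geom.h, "t_diff_pa": t_diff, "P_true_pa": P,
                     "P_true_mmhg": pa_to_mmhg(P)})
    return FillingProtocol(table=pd.DataFrame(rows), material=material,
                           V0_ml=V0_ml, h0=h0)


def simulate_dispersion_measurements(P: float, geom: CompartmentGeometry,
                                     freqs, n_replicates: int = 5,
                                     noise: NoiseSpec = NoiseSpec(),
                                     b_stiff: float = 5.0,
                                     fluid: FluidModel | None = None,
                                     fill_volume_ml: float | None = None,
                                     **ctx_kwargs) -> AcquisitionSet:
    """Replicate noisy dispersion curves around the forward-model truth.

    Each replicate is truth + iid N(0, sigma_c^2) per sample, with a
    fraction of samples replaced by uniform [0.5, 3] x truth outliers.
    """
    fluid = fluid or FluidModel()
    ctx = CharacteristicContext(P=P, geometry=geom, b_stiff=b_stiff,
                                fluid=fluid, **ctx_kwargs)
    truth = forward_dispersion_curve(np.asarray(freqs, dtype=float), ctx)
    rng = np.random.default_rng(noise.seed)
    curves = []
    for rep in range(n_replicates):
        c = truth.c + rng.normal(0.0, noise.sigma_c, size=truth.c.shape)
        if noise.outlier_fraction > 0:
            hit = rng.random(truth.c.shape) < noise.outlier_fraction
            c = np.where(hit, truth.c * rng.uniform(0.5, 3.0, size=truth.c.shape), c)
        c = np.maximum(c, 1e-3)  # velocities stay positive
        curves.append(DispersionCurve(truth.f.copy(), c,
                                      fill_volume_ml=fill_volume_ml,
                                      acquisition=rep))
    return AcquisitionSet(curves)


def raised_cosine_spectrum(f: np.ndarray, f_lo: float = 100.0,
                           f_hi: float = 600.0,
                           rolloff: float = 50.0) -> np.ndarray:
    """Flat amplitude over [f_lo, f_hi] with raised-cosine rolloff edges,
    loosely emulating the excitation band of a ~400 us radiation-force
    tone burst."""
    a = np.zeros_like(f, dtype=float)
    core = (f >= f_lo) & (f <= f_hi)
    a[core] = 1.0
    lo_edge = (f >= f_lo - rolloff) & (f < f_lo)
    a[lo_edge] = 0.5 * (1.0 + np.cos(math.pi * (f_lo - f[lo_edge]) / rolloff))
    hi_edge = (f > f_hi) & (f <= f_hi + rolloff)
    a[hi_edge] = 0.5 * (1.0 + np.cos(math.pi * (f[hi_edge] - f_hi) / rolloff))
    return a


def simulate_wavefield(curve: DispersionCurve, extent: float, duration: float,
                       dx: float, dt: float,
                       amplitude=None,
                       bidirectional: bool = False,
                       noise: NoiseSpec = NoiseSpec(),
                       amplitude_scale: float = 1e-3) -> VelocityMovie:
    """Dispersive plane-wave superposition v(x, t) on a (position, time) grid.

    v(x,t) = sum_f A(f) [cos(2 pi f t - k(f) x + phi_f)
                         (+ cos(2 pi f t + k(f) x + phi'_f) if bidirectional)]
    with k(f) = 2 pi f / c(f) from the input dispersion curve, random
    per-component phases, additive pixel noise and multiplicative outlier
    pixels.  Sampling must resolve the band: dt <= 1/(2 f_max) and dx at
    most half the smallest wavelength on the curve.
    """
    if len(curve) == 0:
        raise ValueError("empty dispersion curve")
    f = curve.f
    c = curve.c
    f_max = float(f.max())
    lam_min = float((c / f).min())
    if dt > 1.0 / (2.0 * f_max):
        raise ValueError(f"dt = {dt} s undersamples the band (need <= "
                         f"{1.0 / (2.0 * f_max):.2e} s)")
    if dx > 0.5 * lam_min:
        raise ValueError(f"dx = {dx} m undersamples the shortest wavelength "
                         f"(need <= {0.5 * lam_min:.2e} m)")
    if amplitude is None:
        amp = raised_cosine_spectrum(f)
    elif callable(amplitude):
        amp = np.asarray(amplitude(f), dtype=float)
    else:
        amp = np.asarray(amplitude, dtype=float)
    rng = np.random.default_rng(noise.seed)
    x = np.arange(0.0, extent, dx)
    t = np.arange(0.0, duration, dt)
    k = 2.0 * math.pi * f / c
    w = 2.0 * math.pi * f
    v = np.zeros((x.size, t.size))
    phases = rng.uniform(0.0, 2.0 * math.pi, size=(2, f.size))
    for i in range(f.size):
        arg = w[i] * t[None, :] - k[i] * x[:, None] + phases[0, i]
        v += amp[i] * np.cos(arg)
        if bidirectional:
            v += amp[i] * np.cos(w[i] * t[None, :] + k[i] * x[:, None]
                                 + phases[1, i])
    v *= amplitude_scale
    if noise.pixel_sigma > 0:
        v = v + rng.normal(0.0, noise.pixel_sigma, size=v.shape)
    if noise.outlier_fraction > 0:
        hit = rng.random(v.shape) < noise.outlier_fraction
        v = np.where(hit, v * rng.uniform(0.5, 3.0, size=v.shape), v)
    return VelocityMovie(v=v, dx=dx, dt=dt)


def simulate_iq(movie: VelocityMovie, f_demod: float = 5e6,
                c_us: float = 1540.0, phase_noise: float = 0.0,
                seed: int = 0) -> IQSequence:
    """IQ frames whose Kasai estimate reproduces ``movie`` exactly.

    Builds a static random speckle phase field and accumulates the
    inter-frame phase decrement 4 pi f_demod v dt / c_us (positive velocity
    = motion toward the transducer).  Supra-Nyquist velocities wrap on
    decoding, as in real autocorrelation estimators.  A profile-form movie
    (positions x time) is lifted to a 3-frame-thick dummy depth axis.
    """
    rng = np.random.default_rng(seed)
    v = movie.v
    if v.ndim == 2:
        v = np.repeat(v[None, :, :], 3, axis=0)
    nz, nx, nt = v.shape
    prf = 1.0 / movie.dt
    speckle = rng.uniform(0.0, 2.0 * math.pi, size=(nz, nx))
    dphi = 4.0 * math.pi * f_demod * v * movie.dt / c_us
    if phase_noise > 0:
        dphi = dphi + rng.normal(0.0, phase_noise, size=dphi.shape)
    # frame t carries the accumulated phase of all preceding increments
    phase = np.concatenate([np.zeros((nz, nx, 1)),
                            np.cumsum(-dphi[..., :-1], axis=-1)], axis=-1)
    frames = np.exp(1j * (speckle[..., None] + phase))
    return IQSequence(frames=frames, prf=prf, f_demod=f_demod, c_us=c_us,
                      dx=movie.dx, dz=movie.dx)


def make_method_comparison_dataset(n_subjects: int, n_repeats: int,
                                   sigma2_s: float, sigma2_sn: float,
                                   sigma2_sm: float, sigma2_mn: float,
                                   sigma2_e: float,
                                   mean: float = 20.0,
                                   method_offset: float = 0.0,
                                   seed: int = 0) -> pd.DataFrame:
    """Paired two-method measurement table from crossed variance components.

    y_{smn} = mean + offset_m + a_s + (ab)_sm + (ac)_sn + (bc)_mn + e_smn
    with each random effect iid zero-mean Gaussian at the stated variance.
    The population concordance of the two methods is
    (s + sn) / (s + sn + sm + mn + e) — the plug-in recovery target for
    :func:`lambpress.metrics.lin_ccc_repeated`.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    for name, v in [("sigma2_s", sigma2_s), ("sigma2_sn", sigma2_sn),
                    ("sigma2_sm", sigma2_sm), ("sigma2_mn", sigma2_mn),
                    ("sigma2_e", sigma2_e)]:
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    rng = np.random.default_rng(seed)
    S, M, N = n_subjects, 2, n_repeats
    a_s = rng.normal(0.0, math.sqrt(sigma2_s), S)
    ab = rng.normal(0.0, math.sqrt(sigma2_sm), (S, M))
    ac = rng.normal(0.0, math.sqrt(sigma2_sn), (S, N))
    bc = rng.normal(0.0, math.sqrt(sigma2_mn), (M, N))
    e = rng.normal(0.0, math.sqrt(sigma2_e), (S, M, N))
    rows = []
    for s in range(S):
        for m in range(M):
            for n in range(N):
                rows.append({
                    "subject": s, "method": m, "repeat": n,
                    "value": (mean + (method_offset if m == 1 else 0.0)
                              + a_s[s] + ab[s, m] + ac[s, n] + bc[m, n]
                              + e[s, m, n]),
                })
    return pd.DataFrame(rows)
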