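"""Pressure estimation by curve fitting the dispersion relation.

Given a measured dispersion curve (f_i, c_i), the internal pressure is the
minimizer of the summed squared characteristic residual

    P_est = argmin_P  sum_i Theta_i(P) * conj(Theta_i(P)),

found by Nelder–Mead simplex search from a fixed initial guess.  The only
free parameter is P: the strain-stiffening exponent b and the undeformed
half-thickness h0 are fixed (defaults b = 5, h0 = 2.75 mm), and the
reference volume V0 is inferred per fill from measured wall thickness and
averaged.  The default fitting band is 150–500 Hz with initializer
100 mmHg, matching the acquisition band of ultrasound bladder vibrometry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .curves import AcquisitionSet, DispersionCurve
from .dispersion import CharacteristicContext, characteristic_residual
from .mechanics import CompartmentGeometry, FluidModel
from .units import mmhg_to_pa, pa_to_mmhg

__all__ = [
    "FitConfig",
    "PressureEstimate",
    "pressure_objective",
    "estimate_pressure",
    "infer_reference_volume",
    "sensitivity_analysis",
]


@dataclass(frozen=True)
class FitConfig:
    """Fitting band, fixed parameters and optimizer settings."""

    f_min: float = 150.0  # Hz
    f_max: float = 500.0  # Hz
    p_init_mmhg: float = 100.0
    b_stiff: float = 5.0
    h0: float = 2.75e-3  # m
    beta_variant: str = "derived"
    xi_convention: str = "sqrt"
    fluid_term: str = "ratio"
    xatol_mmhg: float = 1e-3  # simplex diameter tolerance
    fatol_rel: float = 1e-10  # relative objective-change tolerance
    max_iter: int = 500

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class PressureEstimate:
    """Fitted pressure with optimizer diagnostics."""

    P_pa: float
    objective_value: float
    n_freqs_used: int
    converged: bool
    n_iterations: int
    n_evaluations: int

    @property
    def P_mmhg(self) -> float:
        return pa_to_mmhg(self.P_pa)


def _context(P_pa: float, geom: CompartmentGeometry, cfg: FitConfig,
             fluid: FluidModel) -> CharacteristicContext:
    return CharacteristicContext(P=P_pa, geometry=geom, b_stiff=cfg.b_stiff,
                                 fluid=fluid,
                                 beta_variant=cfg.beta_variant,
                                 xi_convention=cfg.xi_convention,
                                 fluid_term=cfg.fluid_term)


def pressure_objective(P_pa: float, curve: DispersionCurve,
                       geom: CompartmentGeometry, cfg: FitConfig,
                       fluid: FluidModel | None = None) -> float:
    """sum_i |Theta_i(P)|^2 over the curve samples inside [f_min, f_max]."""
    fluid = fluid or FluidModel()
    sub = curve.restrict(cfg.f_min, cfg.f_max)
    if len(sub) == 0:
        raise ValueError(f"no dispersion samples inside the fitting band "
                         f"[{cfg.f_min}, {cfg.f_max}] Hz")
    ctx = _context(P_pa, geom, cfg, fluid)
    total = 0.0
    for f, c in zip(sub.f, sub.c):
        th = characteristic_residual(float(c), float(f), ctx)
        val = (th * th.conjugate()).real
        if not np.isfinite(val):
            raise ValueError(f"nonfinite characteristic residual at "
                             f"f = {f} Hz (P = {P_pa} Pa)")
        total += val
    return total


def estimate_pressure(curve: DispersionCurve, geom: CompartmentGeometry,
                      cfg: FitConfig | None = None,
                      fluid: FluidModel | None = None) -> PressureEstimate:
    """Nelder–Mead minimization of the dispersion misfit over P.

    Optimization runs in mmHg (scale ~10–100, keeping the simplex well
    conditioned); negative trial pressures are handled by a quadratic
    penalty rather than hard bounds so the simplex stays plain.  The
    returned estimate is in Pa (``P_mmhg`` property for display).
    """
    cfg = cfg or FitConfig()
    fluid = fluid or FluidModel()
    sub = curve.restrict(cfg.f_min, cfg.f_max)
    if len(sub) == 0:
        raise ValueError(f"no dispersion samples inside the fitting band "
                         f"[{cfg.f_min}, {cfg.f_max}] Hz")

    scale = None  # objective at the initializer, for the penalty scale

    def objective(x: np.ndarray) -> float:
        nonlocal scale
        p_mmhg = float(x[0])
        if p_mmhg <= 0.0:
            # quadratic pushback anchored at the initializer's misfit
            base = scale if scale is not None else 1.0
            return base * (1.0 + p_mmhg * p_mmhg)
        val = pressure_objective(mmhg_to_pa(p_mmhg), sub, geom, cfg, fluid)
        if scale is None:
            scale = val
        return val

    val0 = objective(np.array([cfg.p_init_mmhg]))
    res = minimize(objective, x0=np.array([cfg.p_init_mmhg]),
                   method="Nelder-Mead",
                   options={"xatol": cfg.xatol_mmhg,
                            "fatol": cfg.fatol_rel * max(val0, 1e-300),
                            "maxiter": cfg.max_iter,
                            "maxfev": 4 * cfg.max_iter})
    p_mmhg = max(float(res.x[0]), 0.0)
    return PressureEstimate(P_pa=mmhg_to_pa(p_mmhg),
                            objective_value=float(res.fun),
                            n_freqs_used=len(sub),
                            converged=bool(res.success),
                            n_iterations=int(res.nit),
                            n_evaluations=int(res.nfev))


def median_over_replicates(acqset: AcquisitionSet) -> DispersionCurve:
    """Per-frequency median across replicate curves (pre-fit aggregation).

    Thin wrapper over :func:`lambpress.wavefield.median_over_acquisitions`
    so fitting code does not need to import the processing module.
    """
    from .wavefield import median_over_acquisitions

    return median_over_acquisitions(acqset)


def infer_reference_volume(fills: list[tuple[float, float]], h0: float) -> float:
    """Average reference volume from per-fill (V, measured half-thickness h).

    Applies V0 = (h/h0)**(3/2) * V to each fill and averages arithmetically:
    each fill yields its own V0 estimate; their mean is used for fitting.
    """
    if not fills:
        raise ValueError("at least one (V, h) fill measurement is required")
    v0s = []
    for V, h in fills:
        if not V > 0 or not h > 0:
            raise ValueError(f"fill entries must be positive, got (V={V}, h={h})")
        v0s.append((h / h0) ** 1.5 * V)
    return float(np.mean(v0s))


def sensitivity_analysis(curve: DispersionCurve, geom: CompartmentGeometry,
                         cfg: FitConfig, fluid: FluidModel,
                         b_grid: list[float], h0_grid: list[float]):
    """P_est over the Cartesian grid of fixed parameters (b_stiff, h0).

    Since V0 is inferred through h0 (V0 proportional to h0**-3/2), each h0
    cell rescales the reference volume accordingly before refitting.
    Returns a DataFrame with columns (b_stiff, h0_m, P_est_mmhg,
    rel_change_vs_default, converged, error); per-cell fit failures are
    recorded, not raised.
    """
    import pandas as pd

    if not b_grid or not h0_grid:
        raise ValueError("b_grid and h0_grid must be nonempty")
    rows = []
    default = None
    for b in b_grid:
        for h0 in h0_grid:
            cell_cfg = replace(cfg, b_stiff=float(b), h0=float(h0))
            v0_scaled = geom.V0 * (cfg.h0 / h0) ** 1.5
            cell_geom = CompartmentGeometry(V=geom.V, V0=v0_scaled, h0=float(h0))
            try:
                est = estimate_pressure(curve, cell_geom, cell_cfg, fluid)
                rows.append({"b_stiff": b, "h0_m": h0,
                             "P_est_mmhg": est.P_mmhg,
                             "converged": est.converged, "error": ""})
                if b == cfg.b_stiff and h0 == cfg.h0:
                    default = est.P_mmhg
            except Exception as exc:  # noqa: BLE001 - per-cell isolation
                rows.append({"b_stiff": b, "h0_m": h0, "P_est_mmhg": np.nan,
                             "converged": False, "error": str(exc)})
    df = pd.DataFrame(rows)
    if default is None:
        ok = df.dropna(subset=["P_est_mmhg"])
        default = float(ok["P_est_mmhg"].iloc[0]) if len(ok) else np.nan
    df["rel_change_vs_default"] = (df["P_est_mmhg"] - default) / default
    return df
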