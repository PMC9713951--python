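"""Pre-stressed, fluid-loaded (leaky) Lamb-wave dispersion.

The wall is treated as an incompressible plate of half-thickness h under
equibiaxial pre-stress, immersed in fluid on both faces.  Small-amplitude
antisymmetric transverse waves obey the characteristic equation

    Theta = gamma*s1*(1+s2^2)^2*tanh(s1*k*h)
          - gamma*s2*(1+s1^2)^2*tanh(s2*k*h)
          + rhoF*c^2*(s1^2 - s2^2)/xi  =  0,

with k = 2*pi*f/c, xi = sqrt(1 - c^2/cp^2) the leaky fluid-loading factor,
and s1^2, s2^2 the roots of the quartic (quadratic in s^2)

    gamma*s^4 - (2*beta - rho*c^2)*s^2 + (alpha - rho*c^2) = 0,

where (alpha, gamma, 2*beta) are the acoustoelastic incremental moduli of
:mod:`lambpress.mechanics`.  With the moduli written in terms of pressure
and geometry, Theta(c, f; P) = 0 is a dispersion relation parameterized by
the internal pressure P — the object inverted by :mod:`lambpress.inversion`.

Root finding uses the reduced function Theta / (s1^2 - s2^2): the raw
Theta vanishes identically wherever the quartic has a double root (both
plate terms cancel and the fluid term carries the factor s1^2 - s2^2), so
dividing it out removes those spurious zeros.  The reduced function is
also real-valued in both regimes (real s^2 roots, where each term is
real even for imaginary s_i, and complex-conjugate roots, where numerator
and denominator are both purely imaginary), making bracketed sign-change
search well posed.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .curves import DispersionCurve
from .mechanics import CompartmentGeometry, FluidModel, Moduli, moduli_from_pressure

__all__ = [
    "RootPair",
    "CharacteristicContext",
    "DegenerateStateError",
    "NoRootError",
    "quadratic_wave_roots",
    "xi_factor",
    "characteristic_residual",
    "normalized_residual",
    "forward_phase_velocity",
    "forward_dispersion_curve",
    "classical_leaky_lamb_residual",
]

XI_CONVENTIONS = ("sqrt", "linear")
FLUID_TERM_READINGS = ("ratio", "product")


class DegenerateStateError(ValueError):
    """The characteristic equation degenerates (gamma = 0, i.e. P = 0);
    use the unstressed classical branch instead."""


class NoRootError(RuntimeError):
    """No dispersion root found in the scanned velocity range."""

    def __init__(self, msg: str, f: float | None = None,
                 scan: np.ndarray | None = None):
        super().__init__(msg)
        self.f = f
        self.scan = scan


@dataclass(frozen=True)
class RootPair:
    """Roots s1^2, s2^2 of the acoustoelastic quartic; s1sq has the larger
    real part (ties broken by larger imaginary part)."""

    s1sq: complex
    s2sq: complex


@dataclass(frozen=True)
class CharacteristicContext:
    """Everything needed to evaluate Theta(c, f) at a given pressure."""

    P: float  # Pa
    geometry: CompartmentGeometry
    b_stiff: float
    fluid: FluidModel = field(default_factory=FluidModel)
    rho_solid: float = 1000.0
    beta_variant: str = "derived"
    xi_convention: str = "sqrt"
    fluid_term: str = "ratio"
    moduli_override: Moduli | None = None  # bypass the pressure path (e.g.
    # to run the solver at exact classical-limit coefficients)

    def moduli(self) -> Moduli:
        if self.moduli_override is not None:
            return self.moduli_override
        return moduli_from_pressure(self.P, self.geometry, self.b_stiff,
                                    self.beta_variant)


def quadratic_wave_roots(moduli: Moduli, rho_solid: float, c: float) -> RootPair:
    """Solve gamma*x^2 - (2beta - rho c^2)*x + (alpha - rho c^2) = 0 for x = s^2.

    Complex arithmetic throughout; a negative discriminant yields a
    conjugate pair.  In the unstressed classical limit
    (alpha = gamma = mu0, 2beta = 2mu0) the quartic factors as
    (s^2 - 1)(mu0 s^2 - (mu0 - rho c^2)), giving roots {1, 1 - rho c^2/mu0}.
    """
    if moduli.gamma == 0.0:
        raise DegenerateStateError(
            "gamma = 0 (zero pre-stress): the stressed characteristic "
            "equation degenerates; evaluate the unstressed classical "
            "leaky-Lamb equation instead")
    g = complex(moduli.gamma)
    bq = complex(moduli.beta2 - rho_solid * c * c)
    aq = complex(moduli.alpha - rho_solid * c * c)
    disc = cmath.sqrt(bq * bq - 4.0 * g * aq)
    x1 = (bq + disc) / (2.0 * g)
    x2 = (bq - disc) / (2.0 * g)
    if (x1.real, x1.imag) < (x2.real, x2.imag):
        x1, x2 = x2, x1
    return RootPair(s1sq=x1, s2sq=x2)


def xi_factor(c: float, cp: float, convention: str = "sqrt") -> float:
    """Fluid-loading factor xi.

    ``sqrt`` (default): xi = sqrt(1 - c^2/cp^2), the standard leaky-plate
    convention; ``linear``: the literal reading xi = 1 - c^2/cp^2.
    """
    if c >= cp:
        raise ValueError(f"phase velocity {c} m/s must stay below the fluid "
                         f"sound speed {cp} m/s for the real-xi leaky branch")
    q = 1.0 - (c / cp) ** 2
    if convention == "sqrt":
        return math.sqrt(q)
    if convention == "linear":
        return q
    raise ValueError(f"xi convention must be one of {XI_CONVENTIONS}, got {convention!r}")


def _theta_terms(c: float, f: float, ctx: CharacteristicContext
                 ) -> tuple[complex, complex, complex, complex]:
    """(plate term 1, plate term 2, fluid term, s1^2 - s2^2) at (c, f)."""
    mod = ctx.moduli()
    roots = quadratic_wave_roots(mod, ctx.rho_solid, c)
    s1 = cmath.sqrt(roots.s1sq)
    s2 = cmath.sqrt(roots.s2sq)
    k = 2.0 * math.pi * f / c
    h = ctx.geometry.h
    t1 = mod.gamma * s1 * (1.0 + roots.s2sq) ** 2 * cmath.tanh(s1 * k * h)
    t2 = mod.gamma * s2 * (1.0 + roots.s1sq) ** 2 * cmath.tanh(s2 * k * h)
    xi = xi_factor(c, ctx.fluid.cp, ctx.xi_convention)
    ssdiff = roots.s1sq - roots.s2sq
    if ctx.fluid_term == "ratio":
        tf = ctx.fluid.rho_fluid * c * c * ssdiff / xi
    elif ctx.fluid_term == "product":
        tf = ctx.fluid.rho_fluid * c * c * ssdiff * xi
    else:
        raise ValueError(f"fluid_term must be one of {FLUID_TERM_READINGS}, "
                         f"got {ctx.fluid_term!r}")
    return t1, t2, tf, ssdiff


def characteristic_residual(c: float, f: float,
                            ctx: CharacteristicContext) -> complex:
    """Theta(c, f): the left-hand side of the characteristic equation."""
    if not f > 0:
        raise ValueError(f"frequency must be positive, got {f}")
    if not 0 < c < ctx.fluid.cp:
        raise ValueError(f"phase velocity must lie in (0, cp), got {c}")
    t1, t2, tf, _ = _theta_terms(c, f, ctx)
    return t1 - t2 + tf


def normalized_residual(c: float, f: float, ctx: CharacteristicContext) -> float:
    """|Theta| scaled by the largest of its three terms' magnitudes."""
    t1, t2, tf, _ = _theta_terms(c, f, ctx)
    scale = max(abs(t1), abs(t2), abs(tf))
    if scale == 0.0:
        return 0.0
    return abs(t1 - t2 + tf) / scale


def _theta_reduced(c: float, f: float, ctx: CharacteristicContext) -> float:
    """Real-valued Theta / (s1^2 - s2^2), regular at double roots."""
    t1, t2, tf, ssdiff = _theta_terms(c, f, ctx)
    if abs(ssdiff) < 1e-300:
        # exact double root on a grid point: nudge off it
        return _theta_reduced(c * (1.0 + 1e-9), f, ctx)
    val = (t1 - t2 + tf) / ssdiff
    return val.real + val.imag  # one of the two is roundoff-level zero


def forward_phase_velocity(f: float, ctx: CharacteristicContext,
                           c_range: tuple[float, float] = (0.2, 15.0),
                           c_seed: float | None = None,
                           scan_step: float = 0.25,
                           xtol: float = 1e-12,
                           residual_tol: float = 1e-8) -> float:
    """Smallest phase velocity c in ``c_range`` solving Theta(c, f) = 0.

    Brackets sign changes of the reduced characteristic function on a
    uniform scan (step ``scan_step`` m/s), refines with Brent's method, and
    validates the raw-Theta normalized residual.  When ``c_seed`` is given
    (branch-continuity seeding from a neighbouring frequency), a window
    around the seed is searched first.
    """
    lo, hi = c_range
    if not (0.0 < lo < hi < ctx.fluid.cp):
        raise ValueError(f"c_range must satisfy 0 < lo < hi < cp, got {c_range}")

    def search(a: float, b: float) -> float | None:
        n = max(int(math.ceil((b - a) / scan_step)), 8) + 1
        grid = np.linspace(a, b, n)
        vals = np.array([_theta_reduced(float(c), f, ctx) for c in grid])
        for i in range(len(grid) - 1):
            va, vb = vals[i], vals[i + 1]
            if not (np.isfinite(va) and np.isfinite(vb)):
                continue
            if va == 0.0:
                return float(grid[i])
            if va * vb < 0.0:
                return float(brentq(lambda c: _theta_reduced(c, f, ctx),
                                    grid[i], grid[i + 1], xtol=xtol))
        return None

    root = None
    if c_seed is not None:
        a = max(lo, c_seed - 1.5)
        b = min(hi, c_seed + 1.5)
        if a < b:
            root = search(a, b)
    if root is None:
        root = search(lo, hi)
    if root is None:
        grid = np.linspace(lo, hi, 64)
        scan = np.array([[c, _theta_reduced(float(c), f, ctx)] for c in grid])
        raise NoRootError(f"no dispersion root in c range {c_range} at "
                          f"f = {f} Hz", f=f, scan=scan)
    res = normalized_residual(root, f, ctx)
    if res > residual_tol:
        raise NoRootError(f"bracketed root at c = {root:.4f} m/s, f = {f} Hz "
                          f"failed residual check ({res:.2e} > {residual_tol})",
                          f=f)
    return root


def forward_dispersion_curve(freqs, ctx: CharacteristicContext,
                             c_range: tuple[float, float] = (0.2, 15.0),
                             **kwargs) -> DispersionCurve:
    """Solve the A0-like branch over an ascending frequency grid.

    Each frequency's root seeds the next (branch continuity); root failures
    propagate with the offending frequency identified.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size and np.any(np.diff(freqs) <= 0):
        raise ValueError("freqs must be sorted strictly ascending")
    cs = []
    seed = None
    for f in freqs:
        c = forward_phase_velocity(float(f), ctx, c_range=c_range,
                                   c_seed=seed, **kwargs)
        cs.append(c)
        seed = c
    return DispersionCurve(freqs, np.array(cs))


def classical_leaky_lamb_residual(c: float, f: float, mu0: float,
                                  rho_solid: float, fluid: FluidModel,
                                  h: float,
                                  xi_convention: str = "sqrt") -> float:
    """Unstressed incompressible leaky-Lamb characteristic function (reduced).

    Independent of the pre-stressed machinery: uses the explicit factored
    roots s1^2 = 1, s2^2 = 1 - rho c^2 / mu0 of the unstressed quartic.
    Used as the zero-pressure reference branch and as a cross-check of the
    stressed solver in the classical limit.
    """
    if not 0 < c < fluid.cp:
        raise ValueError(f"phase velocity must lie in (0, cp), got {c}")
    s2sq = complex(1.0 - rho_solid * c * c / mu0)
    s2 = cmath.sqrt(s2sq)
    k = 2.0 * math.pi * f / c
    t1 = mu0 * (1.0 + s2sq) ** 2 * cmath.tanh(k * h)
    t2 = mu0 * s2 * 4.0 * cmath.tanh(s2 * k * h)
    xi = xi_factor(c, fluid.cp, xi_convention)
    ssdiff = 1.0 - s2sq
    if abs(ssdiff) < 1e-300:
        ssdiff = 1e-300
    val = (t1 - t2 + fluid.rho_fluid * c * c * ssdiff / xi) / ssdiff
    return val.real + val.imag
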