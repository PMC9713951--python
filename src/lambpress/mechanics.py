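"""Finite-deformation mechanics of an inflating thin-walled sphere.

The compartment wall is an incompressible, isotropic, hyperelastic membrane
following the Demiray–Fung exponential strain-energy function

    W = (mu0 / 2b) * (exp(b * (I1 - 3)) - 1)

where ``mu0`` is the initial shear modulus and ``b`` the strain-stiffening
exponent.  Inflation of a sphere is equibiaxial: the in-plane stretches are
equal (lam1 = lam3) and incompressibility forces the through-thickness
stretch to lam2 = lam1**-2.  This module provides:

* kinematics: stretches and thickness from volume ratios,
* statics: the thin-wall (Laplace) pressure law and its thick-wall
  logarithmic parent used as an oracle,
* the Demiray–Fung principal Cauchy stress difference t1 - t2,
* the acoustoelastic incremental moduli (alpha, gamma, 2*beta) governing
  small-amplitude wave propagation superposed on the finite pre-strain.

All quantities are SI (Pa, m, kg/m^3).  mmHg appears only at I/O
boundaries (:mod:`lambpress.units`).

Notes on the 2*beta modulus
---------------------------
alpha and gamma follow model-independently from the stress difference:
``alpha = lam1^2 (t1-t2)/(lam1^2-lam2^2)`` and gamma likewise with lam2^2.
2*beta requires second derivatives of the energy.  Differentiating the
constrained energy ``W~(lam1, lam2) = W(lam1, lam2, 1/(lam1*lam2))`` gives
the closed form

    2*beta = 2*mu0*b*E*(lam1^2 - lam2^2)^2 + mu0*E*(lam1^2 + lam2^2),
    E = exp(b*(I1 - 3)),

which recovers the classical incompressible limit (mu0, mu0, 2*mu0) as
lam1 -> 1.  Two published algebraic variants that differ from this form by
a factor of two in one term each are available behind
``beta_variant={"derived", "eq17", "eq19"}`` for reproduction studies;
``derived`` is the default and the only variant consistent with the
classical limit and with direct finite-difference differentiation of the
energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MaterialModel",
    "FluidModel",
    "CompartmentGeometry",
    "DeformationState",
    "StressState",
    "Moduli",
    "StretchCoefficients",
    "BETA_VARIANTS",
    "radius_from_volume",
    "stretches_from_volumes",
    "reference_volume_from_thickness",
    "thin_wall_pressure",
    "log_wall_pressure",
    "demiray_fung_stress_difference",
    "incremental_moduli",
    "stretch_coefficients",
    "moduli_from_pressure",
    "pressure_from_volume",
]

BETA_VARIANTS = ("derived", "eq17", "eq19")

WATER_DENSITY = 1000.0  # kg/m^3, both wall and bath are ~ water


@dataclass(frozen=True)
class MaterialModel:
    """Demiray–Fung wall material: initial shear modulus ``mu0`` [Pa],
    strain-stiffening exponent ``b_stiff`` [-], density ``rho_solid`` [kg/m^3]."""

    mu0: float
    b_stiff: float
    rho_solid: float = WATER_DENSITY

    def __post_init__(self) -> None:
        if not self.mu0 > 0:
            raise ValueError(f"mu0 must be positive, got {self.mu0}")
        if self.b_stiff < 0:
            raise ValueError(f"b_stiff must be nonnegative, got {self.b_stiff}")
        if not self.rho_solid > 0:
            raise ValueError(f"rho_solid must be positive, got {self.rho_solid}")


@dataclass(frozen=True)
class FluidModel:
    """Loading fluid on both faces of the wall (water bath / fill fluid)."""

    rho_fluid: float = WATER_DENSITY
    cp: float = 1480.0  # compressional sound speed, m/s

    def __post_init__(self) -> None:
        if not self.rho_fluid > 0:
            raise ValueError(f"rho_fluid must be positive, got {self.rho_fluid}")
        if not self.cp > 0:
            raise ValueError(f"cp must be positive, got {self.cp}")


@dataclass(frozen=True)
class DeformationState:
    """Principal stretches of the equibiaxially inflated wall.

    lam1 = lam3 are in-plane, lam2 is through-thickness; incompressibility
    gives lam1**2 * lam2 = 1.  I1 is the first invariant of the left
    Cauchy-Green tensor, I1 = 2*lam1**2 + lam2**2.
    """

    lam1: float
    lam2: float
    lam3: float
    I1: float


@dataclass(frozen=True)
class StressState:
    """Principal Cauchy stress difference t1 - t2 [Pa].

    The hydrostatic Lagrange multiplier enforcing incompressibility cancels
    in the difference and is never stored.
    """

    t_diff: float


@dataclass(frozen=True)
class Moduli:
    """Acoustoelastic incremental moduli [Pa].

    ``beta2`` is the quantity 2*beta as it enters the wave equation's
    quartic; alpha and gamma multiply the shear-like terms.
    """

    alpha: float
    gamma: float
    beta2: float


@dataclass(frozen=True)
class StretchCoefficients:
    """Dimensionless moduli-per-unit-stress coefficients A and B.

    alpha = A_coef * (t1 - t2) and 2*beta = B_coef * (t1 - t2); both are
    functions of the volume ratio V/V0 and of b_stiff only, which is what
    lets the wave equation be written purely in terms of pressure and
    geometry with no shear modulus.
    """

    A_coef: float
    B_coef: float


@dataclass(frozen=True)
class CompartmentGeometry:
    """Deformed/reference volumes [m^3] and undeformed half-thickness [m].

    Derived properties give the deformed radius/half-thickness and the
    inner/outer radii used by the thick-wall oracle (a = r, b_out = r + 2h).
    """

    V: float
    V0: float
    h0: float

    def __post_init__(self) -> None:
        for name in ("V", "V0", "h0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def r(self) -> float:
        return radius_from_volume(self.V)

    @property
    def r0(self) -> float:
        return radius_from_volume(self.V0)

    @property
    def stretches(self) -> DeformationState:
        return stretches_from_volumes(self.V, self.V0)

    @property
    def h(self) -> float:
        return self.stretches.lam2 * self.h0

    @property
    def a(self) -> float:
        return self.r

    @property
    def b_out(self) -> float:
        return self.r + 2.0 * self.h


def radius_from_volume(V: float) -> float:
    """Radius of a sphere of volume ``V``: r = (3V / 4 pi)**(1/3)."""
    if not V > 0:
        raise ValueError(f"volume must be positive, got {V}")
    return (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0)


def stretches_from_volumes(V: float, V0: float) -> DeformationState:
    """Principal stretches of the spherical wall from the volume ratio.

    lam1 = (V/V0)**(1/3) (in-plane), lam2 = (V0/V)**(2/3) (thickness),
    lam3 = lam1.
    """
    if not V > 0 or not V0 > 0:
        raise ValueError(f"volumes must be positive, got V={V}, V0={V0}")
    lam1 = (V / V0) ** (1.0 / 3.0)
    lam2 = (V0 / V) ** (2.0 / 3.0)
    return DeformationState(lam1=lam1, lam2=lam2, lam3=lam1,
                            I1=2.0 * lam1 * lam1 + lam2 * lam2)


def reference_volume_from_thickness(h: float, h0: float, V: float) -> float:
    """Reference volume from a measured deformed half-thickness.

    Inverts h/h0 = lam2 = (V0/V)**(2/3): V0 = (h/h0)**(3/2) * V.  This is
    the practical route to V0, which is hard to observe directly (the
    volume at which the wall is just taut).
    """
    if not h > 0 or not h0 > 0 or not V > 0:
        raise ValueError(f"inputs must be positive, got h={h}, h0={h0}, V={V}")
    return (h / h0) ** 1.5 * V


def thin_wall_pressure(t_diff: float, h: float, r: float) -> float:
    """Laplace law for a thin spherical shell: P = (t1 - t2) * 4h / r."""
    if not h > 0 or not r > 0:
        raise ValueError(f"h and r must be positive, got h={h}, r={r}")
    return t_diff * 4.0 * h / r


def log_wall_pressure(t_diff: float, a: float, b_out: float) -> float:
    """Thick-wall pressure with homogeneous stress: P = 2 (t1-t2) ln(b/a).

    First-order Taylor expansion about b/a = 1 recovers the thin-wall law;
    this form serves as its oracle in tests.
    """
    if not a > 0:
        raise ValueError(f"inner radius must be positive, got {a}")
    if b_out < a:
        raise ValueError(f"outer radius {b_out} smaller than inner {a}")
    return 2.0 * t_diff * math.log(b_out / a)


def demiray_fung_stress_difference(defm: DeformationState,
                                   mat: MaterialModel) -> StressState:
    """Principal Cauchy stress difference for the Demiray–Fung wall.

    t1 - t2 = (lam1^2 - lam2^2) * mu0 * exp(b * (I1 - 3)).
    """
    E = math.exp(mat.b_stiff * (defm.I1 - 3.0))
    t_diff = (defm.lam1 ** 2 - defm.lam2 ** 2) * mat.mu0 * E
    return StressState(t_diff=t_diff)


def _beta2_coefficients(beta_variant: str) -> tuple[float, float]:
    """(multiplier of b*(l1^2-l2^2)^2, multiplier of (l1^2+l2^2)), each x mu0*E."""
    if beta_variant == "derived":
        return 2.0, 1.0
    if beta_variant == "eq17":
        return 2.0, 2.0
    if beta_variant == "eq19":
        return 1.0, 1.0
    raise ValueError(f"beta_variant must be one of {BETA_VARIANTS}, got {beta_variant!r}")


def incremental_moduli(defm: DeformationState, mat: MaterialModel,
                       beta_variant: str = "derived") -> Moduli:
    """Acoustoelastic moduli (alpha, gamma, 2*beta) at a finite pre-strain.

    The lam1 = lam2 singularity of the generic alpha/gamma expressions is
    removable for this model (t1 - t2 carries the same lam1^2 - lam2^2
    factor), so the analytically cancelled forms are used:

        alpha = lam1^2 * mu0 * E,   gamma = lam2^2 * mu0 * E,

    with E = exp(b*(I1-3)); beta2 per the module docstring.  All three are
    continuous through lam1 = 1 with limit (mu0, mu0, 2*mu0).
    """
    cb, cs = _beta2_coefficients(beta_variant)
    l1sq = defm.lam1 ** 2
    l2sq = defm.lam2 ** 2
    E = math.exp(mat.b_stiff * (defm.I1 - 3.0))
    alpha = l1sq * mat.mu0 * E
    gamma = l2sq * mat.mu0 * E
    beta2 = mat.mu0 * E * (cb * mat.b_stiff * (l1sq - l2sq) ** 2 + cs * (l1sq + l2sq))
    return Moduli(alpha=alpha, gamma=gamma, beta2=beta2)


def stretch_coefficients(V: float, V0: float, b_stiff: float,
                         beta_variant: str = "derived") -> StretchCoefficients:
    """Dimensionless A and B such that alpha = A*(t1-t2), 2*beta = B*(t1-t2).

    A = lam1^2/(lam1^2 - lam2^2);
    B = [cb*b*(lam1^2-lam2^2)^2 + cs*(lam1^2+lam2^2)]/(lam1^2 - lam2^2)
    with (cb, cs) set by ``beta_variant``.  Both diverge as V -> V0, where
    t1 - t2 -> 0; the products (the moduli) stay finite.
    """
    if V == V0:
        raise ValueError("stretch coefficients are singular at V == V0 "
                         "(stress difference vanishes there)")
    cb, cs = _beta2_coefficients(beta_variant)
    defm = stretches_from_volumes(V, V0)
    l1sq = defm.lam1 ** 2
    l2sq = defm.lam2 ** 2
    d = l1sq - l2sq
    return StretchCoefficients(
        A_coef=l1sq / d,
        B_coef=(cb * b_stiff * d * d + cs * (l1sq + l2sq)) / d,
    )


def moduli_from_pressure(P: float, geom: CompartmentGeometry, b_stiff: float,
                         beta_variant: str = "derived") -> Moduli:
    """Moduli from pressure and geometry alone — no shear modulus needed.

    Inverts the thin-wall law for the stress difference, t1 - t2 = P*r/(4h),
    then applies the stretch coefficients.  This is the path the inverse
    problem uses: every material scale enters through P itself, leaving
    b_stiff as the only material parameter.
    """
    if P < 0:
        raise ValueError(f"pressure must be nonnegative, got {P}")
    coefs = stretch_coefficients(geom.V, geom.V0, b_stiff, beta_variant)
    defm = geom.stretches
    t_diff = P * geom.r / (4.0 * geom.h)
    alpha = coefs.A_coef * t_diff
    gamma = (defm.lam2 ** 2 / defm.lam1 ** 2) * alpha
    return Moduli(alpha=alpha, gamma=gamma, beta2=coefs.B_coef * t_diff)


def pressure_from_volume(geom: CompartmentGeometry, mat: MaterialModel) -> float:
    """Forward chain: volumes -> stretches -> wall stress -> thin-wall P."""
    defm = geom.stretches
    stress = demiray_fung_stress_difference(defm, mat)
    return thin_wall_pressure(stress.t_diff, geom.h, geom.r)
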