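"""One-dimensional Pennes bioheat slab model solved in the Laplace domain.

The model describes the temperature ``T(x, t)`` of a tumor slab heated (or
cooled) by a constant heat flux at the touched face::

    rho c dT/dt = lambda d2T/dx2 + w (T_ar - T) + Q

with ``w = m_b c_b`` the lumped blood-perfusion exchange coefficient,
``T_ar`` the arterial temperature and ``Q`` the metabolic volumetric
source.  Dividing by ``rho c`` gives the reduced form

    dT/dt = alpha d2T/dx2 - a T + a T_ar + b Q,
    a = w / (rho c),   b = 1 / (rho c),   alpha = lambda / (rho c).

Coordinates: ``x = 0`` is the touched tumor surface, ``x`` increases into
the tissue.  Boundary and initial conditions:

* constant contact flux ``-lambda dT/dx(0, t) = phi``;
* far boundary either held at the initial temperature ``T(omega, t) = T_i``
  (finite slab of thickness omega, the default) or bounded as
  ``x -> infinity`` (semi-infinite variant);
* uniform initial state ``T(x, 0) = T_i``.

In the shifted variable ``u = T - T_i`` the Laplace transform
``theta(x, s)`` satisfies a constant-coefficient ODE whose bounded/stable
solution is

    theta(x, s) = P(s) [1 - cosh(beta x)/cosh(beta omega)]
                  + phi/(lambda s beta) * sinh(beta (omega-x))/cosh(beta omega)

with ``beta = sqrt((s+a)/alpha)`` and the particular part
``P(s) = (a (T_ar - T_i) + b Q) / (s (s + a))``.  The hyperbolic ratios are
evaluated in an overflow-safe exponential form.  Time-domain fields are
recovered with the Gaver-Stehfest scheme (:mod:`thermotouch.stehfest`);
a Crank-Nicolson finite-difference oracle (:func:`fd_oracle`) and the
closed-form steady state (:func:`steady_state`) provide independent
verification routes.

All quantities are SI internally (m, s, J, W) with temperatures in degrees
Celsius.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .stehfest import DEFAULT_ORDER, StehfestScheme, stehfest_weights

__all__ = [
    "TissueProperties",
    "BloodPerfusion",
    "SourceTerms",
    "FarBoundary",
    "SlabGeometry",
    "SlabProblem",
    "TemperatureTrace",
    "FluxTrace",
    "UNFROZEN_TUMOR_TISSUE",
    "FROZEN_TUMOR_TISSUE",
    "BLOOD_UNPERFUSED",
    "BLOOD_PERFUSED",
    "default_problem",
    "flux_study_problem",
    "derived_coefficients",
    "laplace_solution",
    "temperature",
    "heat_flux",
    "temperature_profile",
    "flux_profile",
    "fd_oracle",
    "steady_state",
]


def _require_positive(name: str, value: float) -> float:
    value = float(value)
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value}")
    return value


def _require_nonnegative(name: str, value: float) -> float:
    value = float(value)
    if not value >= 0:
        raise ValueError(f"{name} must be non-negative, got {value}")
    return value


@dataclass(frozen=True)
class TissueProperties:
    """Bulk thermal properties of the tissue.

    density [kg/m^3], specific_heat [J/(kg C)], conductivity [W/(m C)].
    """

    density: float
    specific_heat: float
    conductivity: float

    def __post_init__(self) -> None:
        for name in ("density", "specific_heat", "conductivity"):
            object.__setattr__(self, name, _require_positive(name, getattr(self, name)))

    @property
    def diffusivity(self) -> float:
        """Thermal diffusivity alpha = conductivity/(density*specific_heat), m^2/s."""
        return self.conductivity / (self.density * self.specific_heat)


@dataclass(frozen=True)
class BloodPerfusion:
    """Blood perfusion exchange parameters.

    perfusion_rate [kg/(m^3 s)] is the blood mass flow per tissue volume;
    only the product ``w = perfusion_rate * blood_specific_heat`` (the
    lumped exchange coefficient, W/(m^3 C)) enters the model.
    """

    perfusion_rate: float = 0.0
    blood_specific_heat: float = 3640.0
    arterial_temperature: float = 37.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "perfusion_rate", _require_nonnegative("perfusion_rate", self.perfusion_rate)
        )
        object.__setattr__(
            self,
            "blood_specific_heat",
            _require_positive("blood_specific_heat", self.blood_specific_heat),
        )
        object.__setattr__(self, "arterial_temperature", float(self.arterial_temperature))

    @property
    def exchange_coefficient(self) -> float:
        """Lumped coefficient w = perfusion_rate * blood_specific_heat, W/(m^3 C)."""
        return self.perfusion_rate * self.blood_specific_heat


@dataclass(frozen=True)
class SourceTerms:
    """Volumetric and boundary heat sources.

    metabolic_heat [W/m^3] (>= 0); surface_flux [W/m^2], the constant
    contact-face flux phi, positive when heating the tissue.
    """

    metabolic_heat: float = 0.0
    surface_flux: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "metabolic_heat", _require_nonnegative("metabolic_heat", self.metabolic_heat)
        )
        object.__setattr__(self, "surface_flux", float(self.surface_flux))


class FarBoundary(str, enum.Enum):
    """Far-boundary condition at depth x = thickness."""

    DIRICHLET_INITIAL = "dirichlet_initial"
    SEMI_INFINITE = "semi_infinite"


@dataclass(frozen=True)
class SlabGeometry:
    """Slab thickness [m] and far-boundary type.

    thickness is ignored for the semi-infinite variant.
    """

    thickness: float = 0.007
    far_boundary: FarBoundary = FarBoundary.DIRICHLET_INITIAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "far_boundary", FarBoundary(self.far_boundary))
        if self.far_boundary is FarBoundary.DIRICHLET_INITIAL:
            object.__setattr__(self, "thickness", _require_positive("thickness", self.thickness))
        else:
            object.__setattr__(self, "thickness", float(self.thickness))


@dataclass(frozen=True)
class SlabProblem:
    """Full specification of one bioheat boundary-value problem."""

    tissue: TissueProperties
    blood: BloodPerfusion = BloodPerfusion()
    sources: SourceTerms = SourceTerms()
    geometry: SlabGeometry = SlabGeometry()
    initial_temperature: float = 40.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "initial_temperature", float(self.initial_temperature))

    @property
    def coefficients(self) -> tuple[float, float, float]:
        """Reduced coefficients (a [1/s], b [(m^3 C)/J], alpha [m^2/s])."""
        rc = self.tissue.density * self.tissue.specific_heat
        return (
            self.blood.exchange_coefficient / rc,
            1.0 / rc,
            self.tissue.diffusivity,
        )

    @property
    def forcing(self) -> float:
        """Constant forcing c = a(T_ar - T_i) + bQ of the shifted equation, C/s."""
        a, b, _ = self.coefficients
        return a * (self.blood.arterial_temperature - self.initial_temperature) + (
            b * self.sources.metabolic_heat
        )

    def with_thickness(self, thickness: float) -> "SlabProblem":
        """Copy of the problem with a different slab thickness."""
        return replace(self, geometry=replace(self.geometry, thickness=thickness))


# ---------------------------------------------------------------------------
# Presets read off the cryoprobe-literature property table: specific heats
# printed in kJ/(kg C), conductivities in 1e-3 kJ/(m s C) = W/(m C).

UNFROZEN_TUMOR_TISSUE = TissueProperties(density=1000.0, specific_heat=4200.0, conductivity=0.55)
FROZEN_TUMOR_TISSUE = TissueProperties(density=1000.0, specific_heat=1230.0, conductivity=2.25)

#: Pure-conduction default: only the product m_b*c_b enters the model and the
#: source gives no perfusion speed, so w = 0 is the shipped default.
BLOOD_UNPERFUSED = BloodPerfusion(perfusion_rate=0.0)

#: Representative perfused preset, w = 0.5 * 3640 = 1820 W/(m^3 C).
BLOOD_PERFUSED = BloodPerfusion(perfusion_rate=0.5)


def default_problem(
    initial_temperature: float = 40.0,
    surface_flux: float = 100.0,
    thickness: float = 0.007,
    tissue: TissueProperties = UNFROZEN_TUMOR_TISSUE,
    blood: BloodPerfusion = BLOOD_UNPERFUSED,
    metabolic_heat: float = 0.0,
) -> SlabProblem:
    """The repository-default tumor slab problem.

    Unfrozen tumor tissue, no perfusion, no metabolic source, phi = 100
    W/m^2 on a 7 mm slab: the contact-face steady temperature rise
    phi*omega/lambda = 1.27 C falls inside the 1-3 C band reported for
    tumor-surface touch, and the transient settles well before 600 s.
    """
    return SlabProblem(
        tissue=tissue,
        blood=blood,
        sources=SourceTerms(metabolic_heat=metabolic_heat, surface_flux=surface_flux),
        geometry=SlabGeometry(thickness=thickness),
        initial_temperature=initial_temperature,
    )


def flux_study_problem(thickness: float, surface_flux: float = 100.0) -> SlabProblem:
    """Preset for the far-boundary flux vs tumor-thickness study.

    Uses the frozen-tissue properties (diffusivity ~1.8e-6 m^2/s): in this
    fast-conduction regime the transmitted flux through a 2.5-3.3 mm slab
    shows the reported two-phase behavior, a sharp rise completing within
    ~10 s followed by a plateau at phi.  With unfrozen properties the same
    rise takes on the order of a minute.
    """
    return SlabProblem(
        tissue=FROZEN_TUMOR_TISSUE,
        blood=BLOOD_UNPERFUSED,
        sources=SourceTerms(metabolic_heat=0.0, surface_flux=surface_flux),
        geometry=SlabGeometry(thickness=thickness),
        initial_temperature=40.0,
    )


# ---------------------------------------------------------------------------
# Traces


def _trace_to_csv(df: pd.DataFrame, path) -> None:
    # RFC-4180: CRLF-free minimal quoting is compliant for pure numeric fields
    df.to_csv(path, index=False, lineterminator="\n")


@dataclass(frozen=True)
class TemperatureTrace:
    """Sampled temperature field T(x, t) on a rectangular grid.

    ``values[i, j]`` is the temperature at ``times[i]``, ``positions[j]``.
    """

    positions: np.ndarray
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (self.times.size, self.positions.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"|times| x |positions| = ({self.times.size}, {self.positions.size})"
            )

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns (t_seconds, x_meters, value)."""
        tt, xx = np.meshgrid(self.times, self.positions, indexing="ij")
        return pd.DataFrame(
            {"t_seconds": tt.ravel(), "x_meters": xx.ravel(), "value": self.values.ravel()}
        )

    def to_csv(self, path) -> None:
        _trace_to_csv(self.to_frame(), path)


@dataclass(frozen=True)
class FluxTrace:
    """Sampled heat flux q(x0, t) at a fixed depth ``position``."""

    position: float
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", float(self.position))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != self.times.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match times shape {self.times.shape}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_seconds": self.times,
                "x_meters": np.full(self.times.size, self.position),
                "value": self.values,
            }
        )

    def to_csv(self, path) -> None:
        _trace_to_csv(self.to_frame(), path)


# ---------------------------------------------------------------------------
# Operations


def derived_coefficients(problem: SlabProblem) -> tuple[float, float, float]:
    """Reduced PDE coefficients ``(a, b, alpha)`` of the problem.

    ``a = m_b c_b / (rho c)`` [1/s], ``b = 1/(rho c)`` [(m^3 C)/J],
    ``alpha = lambda/(rho c)`` [m^2/s].
    """
    return problem.coefficients


def _check_position(problem: SlabProblem, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"position x must be >= 0, got minimum {x.min()}")
    if problem.geometry.far_boundary is FarBoundary.DIRICHLET_INITIAL:
        omega = problem.geometry.thickness
        if np.any(x > omega * (1 + 1e-12)):
            raise ValueError(
                f"position x must be <= thickness {omega}, got maximum {x.max()}"
            )
        x = np.minimum(x, omega)
    return x


def laplace_solution(problem: SlabProblem, x, s: float) -> np.ndarray | float:
    """Laplace-domain shifted temperature ``theta(x, s)``.

    ``theta`` is the transform of ``T(x, t) - T_i``.  ``s`` must be real
    and strictly positive (the Stehfest scheme only samples the transform
    on the positive real axis, so no complex path is needed).  ``x`` may be
    a scalar or an array within the slab domain.
    """
    s = float(s)
    if not s > 0:
        raise ValueError(f"Laplace variable s must have positive real part, got {s}")
    x = _check_position(problem, x)
    a, _, alpha = problem.coefficients
    lam = problem.tissue.conductivity
    phi = problem.sources.surface_flux
    c = problem.forcing

    beta = math.sqrt((s + a) / alpha)
    particular = c / (s * (s + a)) if c != 0.0 else 0.0

    if problem.geometry.far_boundary is FarBoundary.SEMI_INFINITE:
        theta = particular + phi / (lam * s * beta) * np.exp(-beta * x)
    else:
        omega = problem.geometry.thickness
        e2om = math.exp(-2.0 * beta * omega)
        # cosh(beta x)/cosh(beta omega) and sinh(beta (omega-x))/cosh(beta omega)
        # in overflow-safe form (all exponents <= 0).
        cosh_ratio = np.exp(beta * (x - omega)) * (1.0 + np.exp(-2.0 * beta * x)) / (1.0 + e2om)
        sinh_ratio = (
            np.exp(-beta * x) * (1.0 - np.exp(-2.0 * beta * (omega - x))) / (1.0 + e2om)
        )
        theta = particular * (1.0 - cosh_ratio) + phi / (lam * s * beta) * sinh_ratio
    return theta if np.ndim(x) else float(theta)


def _flux_transform(problem: SlabProblem, x, s: float) -> np.ndarray | float:
    """Laplace transform of the heat flux, ``-lambda theta'(x, s)``."""
    s = float(s)
    if not s > 0:
        raise ValueError(f"Laplace variable s must have positive real part, got {s}")
    x = _check_position(problem, x)
    a, _, alpha = problem.coefficients
    lam = problem.tissue.conductivity
    phi = problem.sources.surface_flux
    c = problem.forcing

    beta = math.sqrt((s + a) / alpha)
    particular = c / (s * (s + a)) if c != 0.0 else 0.0

    if problem.geometry.far_boundary is FarBoundary.SEMI_INFINITE:
        q = (phi / s) * np.exp(-beta * x)
    else:
        omega = problem.geometry.thickness
        e2om = math.exp(-2.0 * beta * omega)
        sinh_x_ratio = np.exp(beta * (x - omega)) * (1.0 - np.exp(-2.0 * beta * x)) / (1.0 + e2om)
        cosh_rev_ratio = (
            np.exp(-beta * x) * (1.0 + np.exp(-2.0 * beta * (omega - x))) / (1.0 + e2om)
        )
        q = lam * particular * beta * sinh_x_ratio + (phi / s) * cosh_rev_ratio
    return q if np.ndim(x) else float(q)


def _stehfest_field(problem, x, t, scheme, transform) -> np.ndarray | float:
    ln2_t = math.log(2.0) / t
    acc = 0.0
    for j, v in zip(range(1, scheme.order + 1), scheme.weights):
        acc = acc + v * transform(problem, x, j * ln2_t)
    return ln2_t * acc


def temperature(
    problem: SlabProblem, x, t: float, scheme: StehfestScheme | None = None
) -> np.ndarray | float:
    """Temperature T(x, t) in degrees Celsius by Stehfest inversion.

    The inversion formula is singular at ``t = 0``; there the exact initial
    condition ``T = T_i`` is returned instead.
    """
    if scheme is None:
        scheme = stehfest_weights(DEFAULT_ORDER)
    t = float(t)
    if t < 0:
        raise ValueError(f"time t must be non-negative, got {t}")
    x = _check_position(problem, x)
    if t == 0.0:
        out = np.full_like(x, problem.initial_temperature)
        return out if np.ndim(x) else float(problem.initial_temperature)
    shifted = _stehfest_field(problem, x, t, scheme, laplace_solution)
    return shifted + problem.initial_temperature


def heat_flux(
    problem: SlabProblem, x, t: float, scheme: StehfestScheme | None = None
) -> np.ndarray | float:
    """Heat flux ``q(x, t) = -lambda dT/dx`` in W/m^2 by Stehfest inversion.

    At ``t = 0`` the field is uniform and the internal flux is exactly 0.
    """
    if scheme is None:
        scheme = stehfest_weights(DEFAULT_ORDER)
    t = float(t)
    if t < 0:
        raise ValueError(f"time t must be non-negative, got {t}")
    x = _check_position(problem, x)
    if t == 0.0:
        return np.zeros_like(x) if np.ndim(x) else 0.0
    return _stehfest_field(problem, x, t, scheme, _flux_transform)


def _check_times(times) -> np.ndarray:
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size == 0:
        raise ValueError("times grid must be non-empty")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    return times


def temperature_profile(
    problem: SlabProblem,
    positions: Sequence[float],
    times: Sequence[float],
    scheme: StehfestScheme | None = None,
) -> TemperatureTrace:
    """Dense temperature evaluation over a (times x positions) grid."""
    positions = np.atleast_1d(np.asarray(positions, dtype=float))
    if positions.size == 0:
        raise ValueError("positions grid must be non-empty")
    times = _check_times(times)
    values = np.empty((times.size, positions.size))
    for i, t in enumerate(times):
        values[i] = temperature(problem, positions, t, scheme)
    return TemperatureTrace(positions=positions, times=times, values=values)


def flux_profile(
    problem: SlabProblem,
    position: float,
    times: Sequence[float],
    scheme: StehfestScheme | None = None,
) -> FluxTrace:
    """Heat flux at one depth over a time grid.

    For the thickness study the interesting depth is the far boundary
    ``x = thickness`` (the contact face carries the imposed phi by
    construction).
    """
    times = _check_times(times)
    values = np.array([heat_flux(problem, position, t, scheme) for t in times])
    return FluxTrace(position=position, times=times, values=values)


def steady_state(problem: SlabProblem, x) -> np.ndarray | float:
    """Closed-form long-time temperature limit, unshifted (degrees C).

    Finite slab: solves ``0 = alpha u'' - a u + c`` with ``-lambda u'(0) =
    phi`` and ``u(omega) = 0`` in the shifted variable.  Semi-infinite with
    ``a > 0``: bounded solution ``c/a + (phi/(lambda mu)) exp(-mu x)``.
    Semi-infinite, pure conduction with any nonzero forcing has no bounded
    steady state and raises.
    """
    x = _check_position(problem, x)
    a, _, alpha = problem.coefficients
    lam = problem.tissue.conductivity
    phi = problem.sources.surface_flux
    c = problem.forcing
    ti = problem.initial_temperature

    if problem.geometry.far_boundary is FarBoundary.SEMI_INFINITE:
        if a == 0.0:
            if phi != 0.0 or c != 0.0:
                raise ValueError(
                    "semi-infinite medium with a = 0 and nonzero forcing has no "
                    "bounded steady state"
                )
            return np.full_like(x, ti) if np.ndim(x) else ti
        mu = math.sqrt(a / alpha)
        u = c / a + phi / (lam * mu) * np.exp(-mu * x)
        return u + ti

    omega = problem.geometry.thickness
    if a > 0.0:
        mu = math.sqrt(a / alpha)
        e2om = math.exp(-2.0 * mu * omega)
        cosh_ratio = np.exp(mu * (x - omega)) * (1.0 + np.exp(-2.0 * mu * x)) / (1.0 + e2om)
        sinh_ratio = np.exp(-mu * x) * (1.0 - np.exp(-2.0 * mu * (omega - x))) / (1.0 + e2om)
        u = (c / a) * (1.0 - cosh_ratio) + phi / (lam * mu) * sinh_ratio
    else:
        # alpha u'' + c = 0 with flux and Dirichlet conditions
        u = c * (omega**2 - x**2) / (2.0 * alpha) + (phi / lam) * (omega - x)
    return u + ti


def fd_oracle(
    problem: SlabProblem,
    nx: int,
    nt: int,
    t_end: float,
    substeps: int = 4,
) -> TemperatureTrace:
    """Crank-Nicolson finite-difference solution of the slab problem.

    Independent verification oracle for the Laplace-domain route: an
    unconditionally stable theta=1/2 discretisation of the reduced PDE on a
    uniform grid of ``nx`` nodes, second-order convergent in space.  The
    constant-flux boundary is imposed with a second-order ghost node; the
    far boundary must be Dirichlet.  Output rows are ``nt`` times uniformly
    spanning [0, t_end]; ``substeps`` internal steps are taken per output
    interval, with the first output interval integrated by damped implicit
    half-steps to suppress Crank-Nicolson ringing from the impulsive
    flux start.
    """
    if problem.geometry.far_boundary is not FarBoundary.DIRICHLET_INITIAL:
        raise ValueError("fd_oracle requires a finite slab with a Dirichlet far boundary")
    nx, nt, substeps = int(nx), int(nt), int(substeps)
    if nx < 3:
        raise ValueError(f"nx must be >= 3, got {nx}")
    if nt < 2:
        raise ValueError(f"nt must be >= 2, got {nt}")
    if substeps < 1:
        raise ValueError(f"substeps must be >= 1, got {substeps}")
    t_end = _require_positive("t_end", t_end)

    a, _, alpha = problem.coefficients
    lam = problem.tissue.conductivity
    phi = problem.sources.surface_flux
    c = problem.forcing
    omega = problem.geometry.thickness

    x = np.linspace(0.0, omega, nx)
    dx = x[1] - x[0]
    r = alpha / dx**2
    src0 = 2.0 * alpha * phi / (lam * dx) + c  # ghost-node flux source at x=0

    def banded_matrix(weight: float, dt: float) -> np.ndarray:
        ab = np.zeros((3, nx))
        ab[0, 2:] = -weight * dt * r
        ab[1, 1:-1] = 1.0 + weight * dt * (2.0 * r + a)
        ab[2, :-2] = -weight * dt * r
        ab[1, 0] = 1.0 + weight * dt * (2.0 * r + a)
        ab[0, 1] = -weight * dt * 2.0 * r
        ab[1, -1] = 1.0
        ab[0, -1] = 0.0
        ab[2, -2] = 0.0
        return ab

    def rhs(u: np.ndarray, weight: float, dt: float) -> np.ndarray:
        f = np.empty_like(u)
        expl = 1.0 - weight
        f[0] = u[0] + expl * dt * (2.0 * r * (u[1] - u[0]) - a * u[0]) + dt * src0
        f[1:-1] = (
            u[1:-1]
            + expl * dt * (r * (u[2:] - 2.0 * u[1:-1] + u[:-2]) - a * u[1:-1])
            + dt * c
        )
        f[-1] = 0.0
        return f

    u = np.zeros(nx)
    times = np.linspace(0.0, t_end, nt)
    out = np.empty((nt, nx))
    out[0] = 0.0
    dt = t_end / ((nt - 1) * substeps)
    startup = True
    for i in range(1, nt):
        for _ in range(substeps):
            if startup:
                # Rannacher smoothing: two implicit-Euler half steps
                for _ in range(2):
                    ab = banded_matrix(1.0, dt / 2.0)
                    u = solve_banded((1, 1), ab, rhs(u, 1.0, dt / 2.0))
                startup = False
            else:
                ab = banded_matrix(0.5, dt)
                u = solve_banded((1, 1), ab, rhs(u, 0.5, dt))
        out[i] = u
    return TemperatureTrace(positions=x, times=times, values=out + problem.initial_temperature)
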