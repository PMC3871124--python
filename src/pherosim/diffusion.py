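"""Finite-domain diffusion of alpha-factor between two agarose compartments.

The geometry is one-dimensional along the gradient axis: the pheromone
source occupies ``[0, h]`` and the reporter compartment ``[h, l]``, with
reflecting (zero-flux) walls at ``x = 0`` and ``x = l``.  The initial step
of concentration ``C0`` in the source relaxes by diffusion; the bounded
domain is handled by the method of images, which turns the free-space
solution into an erf series:

    C(x, t) = (C0 / 2) * sum_n [ erf((h + 2 n l - x) / (2 sqrt(D t)))
                                + erf((h - 2 n l + x) / (2 sqrt(D t))) ]

with the sum truncated at ``n in [-N, N]``.  The effective diffusivity in
the hydrogel is the free-solution Stokes-Einstein value reduced by the
Amsden obstruction factor.

Units throughout: lengths in mm, times in s, concentrations in uM,
diffusivities in mm^2/s.  The hydrogel parameters use nm because that is
the scale of solute and fiber radii.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded
from scipy.special import erf

__all__ = [
    "Geometry",
    "TransportParams",
    "HydrogelParams",
    "SecretionSource",
    "ConcentrationField",
    "estimate_stokes_einstein_d0",
    "hydrogel_corrected_d",
    "step_source_concentration",
    "concentration_profile",
    "secretion_concentration",
    "calibrate_secretion_rate",
    "fd_reference_solver",
    "induction_extent",
    "default_transport_params",
]

BOLTZMANN_J_PER_K = 1.380649e-23
AVOGADRO_PER_MOL = 6.02214076e23

#: Series values whose magnitude falls below TRUNCATION_TOL * C0 are
#: clamped to zero (truncation noise of the image series).
TRUNCATION_TOL = 1e-12


class InvalidParameterError(ValueError):
    """A physical parameter violates its domain."""


class CalibrationError(RuntimeError):
    """Secretion-rate calibration could not be anchored."""


@dataclass(frozen=True)
class Geometry:
    """Two-compartment geometry along the gradient axis.

    ``source_extent_h`` is the extent of the pheromone source compartment
    (default 5 mm) and ``domain_length_l`` the total closed domain
    (default 10 mm).  Distance from the compartment boundary is
    ``d = x - h``.
    """

    source_extent_h: float = 5.0
    domain_length_l: float = 10.0

    def __post_init__(self) -> None:
        h, l = self.source_extent_h, self.domain_length_l
        if not (math.isfinite(h) and math.isfinite(l) and 0.0 < h < l):
            raise InvalidParameterError(
                f"require 0 < h < l and finite, got h={h}, l={l}"
            )


@dataclass(frozen=True)
class TransportParams:
    """Diffusivity and initial condition of the step source."""

    d0_free: float
    d_effective: float
    c0_initial: float = 10.0
    n_image_terms: int = 12

    def __post_init__(self) -> None:
        if not 0.0 < self.d_effective <= self.d0_free:
            raise InvalidParameterError(
                "require 0 < d_effective <= d0_free, got "
                f"{self.d_effective} vs {self.d0_free}"
            )
        if self.c0_initial < 0:
            raise InvalidParameterError("c0_initial must be >= 0")
        if self.n_image_terms < 1:
            raise InvalidParameterError("n_image_terms must be >= 1")


@dataclass(frozen=True)
class HydrogelParams:
    """Amsden obstruction-model parameters for the agarose network.

    All radii and the scaling constant are in nm; the polymer volume
    fraction is dimensionless.  Defaults describe 1% (w/v) agarose.
    """

    solute_radius: float = 0.7885
    fiber_radius: float = 1.9
    polymer_volume_fraction: float = 0.0064
    scaling_constant: float = 1.0

    def __post_init__(self) -> None:
        if min(self.solute_radius, self.fiber_radius, self.scaling_constant) <= 0:
            raise InvalidParameterError("radii and scaling constant must be > 0")
        if not 0.0 < self.polymer_volume_fraction < 1.0:
            raise InvalidParameterError(
                "polymer_volume_fraction must lie in (0, 1), got "
                f"{self.polymer_volume_fraction}"
            )


@dataclass(frozen=True)
class SecretionSource:
    """Constant volumetric pheromone source from secreting cells in [0, h].

    The source strength is ``per_od_rate * od600`` (uM/s), active during
    ``active_interval`` (s).  ``per_od_rate`` is a calibrated quantity,
    see :func:`calibrate_secretion_rate`.
    """

    od600: float
    per_od_rate: float
    active_interval: tuple[float, float] = (0.0, math.inf)

    def __post_init__(self) -> None:
        if self.od600 < 0 or self.per_od_rate < 0:
            raise InvalidParameterError("od600 and per_od_rate must be >= 0")
        t0, t1 = self.active_interval
        if t0 < 0 or t1 < t0:
            raise InvalidParameterError("active_interval must satisfy 0 <= t0 <= t1")


@dataclass
class ConcentrationField:
    """Concentration grid indexed (time, position)."""

    positions: np.ndarray
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.times.size, self.positions.size):
            raise InvalidParameterError(
                f"values shape {self.values.shape} does not match "
                f"(times, positions) = ({self.times.size}, {self.positions.size})"
            )
        if np.any(np.diff(self.positions) <= 0):
            raise InvalidParameterError("positions must be strictly increasing")
        if np.any(np.diff(self.times) < 0):
            raise InvalidParameterError("times must be nondecreasing")
        if np.any(self.values < 0):
            raise InvalidParameterError("concentrations must be nonnegative")

    def to_dataframe(self) -> pd.DataFrame:
        t, x = np.meshgrid(self.times, self.positions, indexing="ij")
        return pd.DataFrame(
            {"time_s": t.ravel(), "x_mm": x.ravel(), "conc_uM": self.values.ravel()}
        )


def estimate_stokes_einstein_d0(
    molecular_weight: float = 1700.0,
    temperature: float = 303.0,
    viscosity: float = 7.97e-4,
    partial_specific_volume: float = 0.73,
) -> float:
    """Free-solution diffusivity of a globular solute by Stokes-Einstein.

    The hydrodynamic radius is taken as the radius of the sphere with the
    solute's anhydrous molecular volume, r = (3 M vbar / (4 pi N_A))^(1/3).

    Parameters
    ----------
    molecular_weight : Da (g/mol)
    temperature : K
    viscosity : Pa*s
    partial_specific_volume : cm^3/g

    Returns
    -------
    float
        D0 in mm^2/s.
    """
    args = (molecular_weight, temperature, viscosity, partial_specific_volume)
    if any(a <= 0 for a in args):
        raise InvalidParameterError(f"all arguments must be positive, got {args}")
    volume_m3 = molecular_weight * partial_specific_volume / AVOGADRO_PER_MOL * 1e-6
    radius_m = (3.0 * volume_m3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    d_m2_s = BOLTZMANN_J_PER_K * temperature / (6.0 * math.pi * viscosity * radius_m)
    return d_m2_s * 1e6  # m^2/s -> mm^2/s


def solute_radius_nm(
    molecular_weight: float = 1700.0, partial_specific_volume: float = 0.73
) -> float:
    """Sphere-equivalent solute radius in nm (for the obstruction model)."""
    volume_m3 = molecular_weight * partial_specific_volume / AVOGADRO_PER_MOL * 1e-6
    return (3.0 * volume_m3 / (4.0 * math.pi)) ** (1.0 / 3.0) * 1e9


def hydrogel_corrected_d(d0: float, gel: HydrogelParams) -> float:
    """Reduce a free-solution diffusivity by the Amsden obstruction factor.

    D/D0 = exp(-pi * ((r_s + r_f) / (k_s * phi^(-1/2) + 2 r_f))^2): the
    solute passes the fiber network only through openings whose mean size
    scales as phi^(-1/2).
    """
    if d0 <= 0:
        raise InvalidParameterError("d0 must be > 0")
    opening = gel.scaling_constant * gel.polymer_volume_fraction ** -0.5 + 2.0 * gel.fiber_radius
    ratio = (gel.solute_radius + gel.fiber_radius) / opening
    return d0 * math.exp(-math.pi * ratio * ratio)


def _step_series(
    x: np.ndarray,
    t: np.ndarray,
    geom: Geometry,
    d_effective: float,
    c0: float,
    n_terms: int,
) -> np.ndarray:
    """Broadcast evaluation of the image series; t = 0 handled as the step."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    h, l = geom.source_extent_h, geom.domain_length_l
    xb, tb = np.broadcast_arrays(x, t)
    out = np.empty(xb.shape, dtype=float)

    zero = tb == 0.0
    if np.any(zero):
        xz = xb[zero]
        out[zero] = np.where(xz < h, c0, np.where(xz == h, 0.5 * c0, 0.0))

    pos = ~zero
    if np.any(pos):
        xp = xb[pos][..., None]
        denom = 2.0 * np.sqrt(d_effective * tb[pos])[..., None]
        # n_terms is a floor: at very large t the diffusion length exceeds
        # the domain and more image charges are needed for convergence.
        t_max = float(tb[pos].max())
        n_needed = math.ceil((6.0 * math.sqrt(d_effective * t_max) + l) / l)
        n_eff = max(n_terms, n_needed)
        n = np.arange(-n_eff, n_eff + 1, dtype=float)
        terms = erf((h + 2.0 * n * l - xp) / denom) + erf((h - 2.0 * n * l + xp) / denom)
        vals = 0.5 * c0 * terms.sum(axis=-1)
        vals[np.abs(vals) < TRUNCATION_TOL * max(c0, 1.0)] = 0.0
        out[pos] = np.maximum(vals, 0.0)
    return out


def step_source_concentration(
    x, t, geom: Geometry, params: TransportParams
):
    """Concentration of the initial-step source at position x (mm), time t (s).

    At ``t = 0`` the exact step is returned (C0 inside the source, C0/2 on
    the boundary, 0 beyond).  Scalar and array arguments broadcast.
    """
    xa, ta = np.asarray(x, dtype=float), np.asarray(t, dtype=float)
    if np.any(xa < 0) or np.any(xa > geom.domain_length_l):
        raise InvalidParameterError("x must lie within [0, l]")
    if np.any(ta < 0):
        raise InvalidParameterError("t must be >= 0")
    out = _step_series(
        xa, ta, geom, params.d_effective, params.c0_initial, params.n_image_terms
    )
    if out.ndim == 0:
        return float(out)
    return out


def concentration_profile(
    positions: Sequence[float],
    times: Sequence[float],
    geom: Geometry,
    params: TransportParams,
) -> ConcentrationField:
    """Step-source concentration on a (times x positions) grid."""
    pos = np.asarray(positions, dtype=float)
    tim = np.asarray(times, dtype=float)
    vals = step_source_concentration(pos[None, :], tim[:, None], geom, params)
    vals = np.atleast_2d(vals)
    return ConcentrationField(positions=pos, times=tim, values=vals)


# -- continuous secretion source ---------------------------------------------

_QUAD_NODES = 257  # Simpson nodes for the Duhamel time integral (odd)


def _unit_step_time_integral(
    x, upper: float, geom: Geometry, params: TransportParams
) -> np.ndarray:
    """integral_0^upper u(x, s) ds for the unit-C0 step solution u.

    Substituting s = upper * w^2 clusters nodes near s = 0 where the step
    solution varies fastest; the integrand is then smooth in w and a
    composite Simpson rule converges quickly.
    """
    xa = np.asarray(x, dtype=float)
    if upper <= 0:
        return np.zeros(xa.shape) if xa.ndim else np.array(0.0)
    w = np.linspace(0.0, 1.0, _QUAD_NODES)
    s = upper * w**2
    u = _step_series(
        xa[..., None] if xa.ndim else xa,
        s,
        geom,
        params.d_effective,
        1.0,
        params.n_image_terms,
    )
    integrand = u * (2.0 * upper * w)
    dw = w[1] - w[0]
    weights = np.ones(_QUAD_NODES)
    weights[1:-1:2] = 4.0
    weights[2:-1:2] = 2.0
    return (integrand * weights).sum(axis=-1) * dw / 3.0


def secretion_concentration(
    x, t, geom: Geometry, source: SecretionSource, params: TransportParams
):
    """Concentration due to secreting cells distributed through the source compartment.

    By linearity of the diffusion equation, a constant volumetric source of
    strength q = per_od_rate * od600 acting on [0, h] produces
    ``C(x, t) = q * integral_0^t u(x, s) ds`` with u the unit-step solution;
    a finite active interval shifts the integration window accordingly.
    """
    ta = np.asarray(t, dtype=float)
    if np.any(ta < 0):
        raise InvalidParameterError("t must be >= 0")
    q = source.per_od_rate * source.od600
    if q == 0.0:
        xa = np.asarray(x, dtype=float)
        z = np.zeros(np.broadcast_shapes(xa.shape, ta.shape))
        return float(z) if z.ndim == 0 else z
    t0, t1 = source.active_interval
    if ta.ndim:
        raise InvalidParameterError("secretion_concentration expects scalar t")
    t_sc = float(ta)
    hi = min(t_sc, t1) - t0
    lo = max(0.0, t_sc - t1) if math.isfinite(t1) else 0.0
    if hi <= 0:
        xa = np.asarray(x, dtype=float)
        z = np.zeros(xa.shape)
        return float(z) if z.ndim == 0 else z
    # window [t0, min(t, t1)] of activity -> integral over elapsed-time
    # offsets [t - min(t,t1), t - t0]
    a = t_sc - min(t_sc, t1)
    b = t_sc - t0
    val = q * (
        _unit_step_time_integral(x, b, geom, params)
        - _unit_step_time_integral(x, a, geom, params)
    )
    val = np.maximum(val, 0.0)
    return float(val) if np.ndim(val) == 0 else val


def calibrate_secretion_rate(
    geom: Geometry,
    params: TransportParams,
    reference_c0: float = 10.0,
    reference_od: float = 0.75,
    reference_time: float = 6 * 3600.0,
) -> float:
    """Anchor the per-OD secretion rate to the synthetic-pheromone setup.

    The returned rate q (uM/s per unit OD600) makes a compartment of
    secreting cells at ``reference_od`` reproduce, at the compartment
    boundary and at ``reference_time``, the concentration of the
    ``reference_c0`` step source.  The relation is linear, so q is the
    ratio of the two boundary values.
    """
    if min(reference_c0, reference_od, reference_time) <= 0:
        raise InvalidParameterError("calibration references must be positive")
    h = geom.source_extent_h
    ref_params = TransportParams(
        d0_free=params.d0_free,
        d_effective=params.d_effective,
        c0_initial=reference_c0,
        n_image_terms=params.n_image_terms,
    )
    target = step_source_concentration(h, reference_time, geom, ref_params)
    unit_integral = float(_unit_step_time_integral(np.asarray(h), reference_time, geom, params))
    if target <= 0 or unit_integral <= 0:
        raise CalibrationError("reference solution evaluates to zero at the anchor")
    return target / (unit_integral * reference_od)


# -- finite-difference oracle -------------------------------------------------

def fd_reference_solver(
    geom: Geometry,
    d_effective: float,
    initial_profile: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    volumetric_source: Callable[[np.ndarray], np.ndarray] | np.ndarray | None,
    t_end: float,
    grid_spacing: float = 0.05,
    time_step: float = 1.0,
    save_times: Sequence[float] | None = None,
    method: str = "crank-nicolson",
) -> ConcentrationField:
    """Second-order finite-difference solution of dC/dt = D C_xx + S(x).

    Zero-flux boundaries at x = 0 and x = l (mirror discretization, which
    conserves the trapezoid mass of the semi-discrete system exactly).
    Crank-Nicolson time stepping with four half-step backward-Euler
    startup steps to damp the odd-even mode excited by a discontinuous
    initial profile; ``method="explicit"`` selects forward Euler instead
    (with the usual r <= 1/2 stability requirement).
    """
    if grid_spacing <= 0 or time_step <= 0:
        raise InvalidParameterError("grid_spacing and time_step must be > 0")
    l = geom.domain_length_l
    m = l / grid_spacing
    if abs(m - round(m)) > 1e-9 or abs(
        geom.source_extent_h / grid_spacing - round(geom.source_extent_h / grid_spacing)
    ) > 1e-9:
        raise InvalidParameterError("grid must resolve h and l exactly")
    n_pts = int(round(m)) + 1
    x = np.linspace(0.0, l, n_pts)

    c = np.asarray(initial_profile(x) if callable(initial_profile) else initial_profile,
                   dtype=float).copy()
    if c.shape != x.shape:
        raise InvalidParameterError("initial profile does not match the grid")
    if volumetric_source is None:
        s = np.zeros_like(x)
    else:
        s = np.asarray(
            volumetric_source(x) if callable(volumetric_source) else volumetric_source,
            dtype=float,
        )

    r = d_effective * time_step / grid_spacing**2
    if method == "explicit" and r > 0.5:
        raise InvalidParameterError(
            f"explicit scheme unstable: D*dt/dx^2 = {r:.3g} > 0.5"
        )

    save = sorted(set(float(ts) for ts in (save_times if save_times is not None else [t_end])))
    if save and save[-1] > t_end + 1e-9:
        raise InvalidParameterError("save_times must not exceed t_end")

    def lap(v: np.ndarray) -> np.ndarray:
        out = np.empty_like(v)
        out[1:-1] = v[2:] - 2.0 * v[1:-1] + v[:-2]
        out[0] = 2.0 * (v[1] - v[0])
        out[-1] = 2.0 * (v[-2] - v[-1])
        return out

    def banded(theta_r: float) -> np.ndarray:
        """(I - theta_r * L) in solve_banded layout."""
        ab = np.zeros((3, n_pts))
        ab[1, :] = 1.0 + 2.0 * theta_r
        ab[0, 1:] = -theta_r
        ab[2, :-1] = -theta_r
        ab[0, 1] = -2.0 * theta_r
        ab[2, -2] = -2.0 * theta_r
        return ab

    saved: list[np.ndarray] = []
    save_idx = 0
    t_now = 0.0
    eps = 1e-9 * max(time_step, 1.0)
    while save_idx < len(save) and save[save_idx] <= t_now + eps:
        saved.append(c.copy())
        save_idx += 1

    n_startup = 4  # Rannacher smoothing: implicit-Euler half steps
    startup_left = n_startup if method != "explicit" else 0

    while t_now < t_end - eps:
        dt = min(time_step, t_end - t_now)
        if save_idx < len(save):
            dt = min(dt, save[save_idx] - t_now)
        rr = d_effective * dt / grid_spacing**2
        if method == "explicit":
            c = c + rr * lap(c) + dt * s
        elif startup_left > 0:
            half = dt / 2.0
            rh = d_effective * half / grid_spacing**2
            for _ in range(2):
                c = solve_banded((1, 1), banded(rh), c + half * s)
            startup_left -= 1
        else:
            rhs = c + 0.5 * rr * lap(c) + dt * s
            c = solve_banded((1, 1), banded(0.5 * rr), rhs)
        t_now += dt
        while save_idx < len(save) and save[save_idx] <= t_now + eps:
            saved.append(c.copy())
            save_idx += 1

    values = np.maximum(np.array(saved), 0.0)
    return ConcentrationField(positions=x, times=np.array(save), values=values)


# -- induction extent ----------------------------------------------------------

def induction_extent(
    t: float,
    threshold: float,
    geom: Geometry,
    params: TransportParams,
    source: SecretionSource | None = None,
    tol_mm: float = 1e-4,
) -> float:
    """Farthest distance beyond the boundary where C >= threshold at time t.

    The step (and time-integrated secretion) profiles are nonincreasing in
    x, so the threshold crossing is located by bisection on
    d in [0, l - h].  Returns 0 if the threshold is not met at the
    boundary, and l - h if it is met everywhere.
    """
    if threshold <= 0:
        raise InvalidParameterError("threshold must be > 0")
    if t <= 0:
        raise InvalidParameterError("t must be > 0")
    h = geom.source_extent_h
    d_max = geom.domain_length_l - h

    def conc(d: float) -> float:
        x = h + d
        if source is None:
            return step_source_concentration(x, t, geom, params)
        return secretion_concentration(x, t, geom, source, params)

    if conc(0.0) < threshold:
        return 0.0
    if conc(d_max) >= threshold:
        return d_max
    lo, hi = 0.0, d_max
    while hi - lo > tol_mm:
        mid = 0.5 * (lo + hi)
        if conc(mid) >= threshold:
            lo = mid
        else:
            hi = mid
    return lo


def default_transport_params(
    c0_initial: float = 10.0,
    gel: HydrogelParams | None = None,
    n_image_terms: int = 12,
) -> TransportParams:
    """Stokes-Einstein D0 with the Amsden agarose correction applied."""
    d0 = estimate_stokes_einstein_d0()
    gel = gel if gel is not None else HydrogelParams()
    return TransportParams(
        d0_free=d0,
        d_effective=hydrogel_corrected_d(d0, gel),
        c0_initial=c0_initial,
        n_image_terms=n_image_terms,
    )
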