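"""Temperature and moisture scalars for litter/soil decomposition.

Every scheme maps its forcing variable into [0, 1] after clamping and is
normalized so its optimum yields 1.  The two schemes exercised in the swap
experiment are the Lloyd-Taylor temperature response with a piecewise
("subsection") moisture response floored at 0.25 (variable: soil water
content as a fraction of porosity), and the standard Q10 temperature
response with a single smooth parabolic-type moisture response (variable:
soil water content as a fraction of saturation).  The remaining registry
entries are reconstructions from each model's cited description and are
flagged as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .model_core import N_POOLS, PoolLayout, DEFAULT_LAYOUT, ValidationError

__all__ = [
    "ScalarScheme",
    "ScalarField",
    "lloyd_taylor_scalar",
    "q10_scalar",
    "beps_moisture_scalar",
    "cable_moisture_scalar",
    "lpj_moisture_scalar",
    "environmental_scalar_matrix",
    "get_scheme",
    "list_schemes",
]

# Lloyd-Taylor constants (K); reference temperature in degC.
E0_DEFAULT = 308.56
T0_DEFAULT = 227.13
T_REF_DEFAULT = 10.0
KELVIN = 273.15

Q10_DEFAULT = 2.0


def _clamp01(x):
    return np.clip(x, 0.0, 1.0)


def lloyd_taylor_scalar(
    t_soil,
    e0: float = E0_DEFAULT,
    t0: float = T0_DEFAULT,
    t_ref: float = T_REF_DEFAULT,
    clamp: bool = True,
):
    """Exponential temperature scalar, equal to 1 at the reference temperature.

    xi_t = exp(e0 * (1/(T_ref - t0) - 1/(T - t0))) with temperatures in K.
    Below the singularity temperature (t0 in degC) the scalar is 0 and a
    warning is issued rather than raising.
    """
    t = np.asarray(t_soil, dtype=float)
    t_k = t + KELVIN
    sing = t0  # Kelvin
    frozen = t_k <= sing
    if np.any(frozen):
        warnings.warn(
            "soil temperature at/below the Lloyd-Taylor singularity; scalar set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        xi = np.exp(e0 * (1.0 / (t_ref + KELVIN - t0) - 1.0 / (t_k - t0)))
    xi = np.where(frozen, 0.0, xi)
    if clamp:
        xi = _clamp01(xi)
    return float(xi) if np.isscalar(t_soil) else xi


def q10_scalar(
    t_soil,
    q10: float = Q10_DEFAULT,
    t_ref: float = T_REF_DEFAULT,
    clamp: bool = True,
):
    """Standard Q10 temperature scalar: q10 ** ((T - T_ref) / 10), clamped.

    Equals 1 at the reference temperature.
    """
    if q10 <= 1.0:
        raise ValidationError(f"Q10 must be > 1, got {q10}")
    t = np.asarray(t_soil, dtype=float)
    xi = np.power(q10, (t - t_ref) / 10.0)
    if clamp:
        xi = _clamp01(xi)
    return float(xi) if np.isscalar(t_soil) else xi


# BEPS-style subsection moisture response parameters.
BEPS_MOISTURE_FLOOR = 0.25
BEPS_MOISTURE_OPTIMUM = 0.75
BEPS_MOISTURE_AT_SATURATION = 0.75


def beps_moisture_scalar(
    swc,
    porosity,
    floor: float = BEPS_MOISTURE_FLOOR,
    k_opt: float = BEPS_MOISTURE_OPTIMUM,
    xi_sat: float = BEPS_MOISTURE_AT_SATURATION,
):
    """Piecewise moisture scalar of k = swc / porosity with a 0.25 floor.

    Rises linearly from the floor at k = 0 to 1 at the optimum k, then
    declines linearly toward ``xi_sat`` at saturation; never leaves
    [floor, 1].
    """
    poro = np.asarray(porosity, dtype=float)
    if np.any(poro <= 0):
        raise ValidationError("porosity must be > 0")
    swc_a = np.asarray(swc, dtype=float)
    k = swc_a / poro
    if np.any(k > 1.0 + 1e-12) or np.any(k < -1e-12):
        warnings.warn("swc outside [0, porosity]; clamping", RuntimeWarning, stacklevel=2)
    k = _clamp01(k)
    rising = floor + (1.0 - floor) * k / k_opt
    falling = 1.0 - (1.0 - xi_sat) * (k - k_opt) / (1.0 - k_opt)
    xi = np.where(k <= k_opt, rising, falling)
    xi = np.clip(xi, floor, 1.0)
    return float(xi) if np.isscalar(swc) and np.isscalar(porosity) else xi


CABLE_MOISTURE_OPTIMUM = 0.5
CABLE_MOISTURE_CURVATURE = 0.9


def cable_moisture_scalar(
    theta_frac,
    theta_opt: float = CABLE_MOISTURE_OPTIMUM,
    curvature: float = CABLE_MOISTURE_CURVATURE,
):
    """Single smooth parabolic-type moisture scalar of the saturation fraction.

    xi = 1 - curvature * (theta - theta_opt)^2: one function covers the whole
    range, normalized to 1 at the optimum, declining toward both the dry and
    the saturated end.
    """
    th = np.asarray(theta_frac, dtype=float)
    if np.any(th > 1.0 + 1e-12) or np.any(th < -1e-12):
        warnings.warn("saturation fraction outside [0, 1]; clamping", RuntimeWarning, stacklevel=2)
    th = _clamp01(th)
    xi = 1.0 - curvature * (th - theta_opt) ** 2
    xi = _clamp01(xi)
    return float(xi) if np.isscalar(theta_frac) else xi


def lpj_moisture_scalar(w1):
    """Linear moisture scalar of the upper-layer SWC fraction: 0.25 + 0.75 * W1."""
    w = np.asarray(w1, dtype=float)
    if np.any(w > 1.0 + 1e-12) or np.any(w < -1e-12):
        warnings.warn("W1 outside [0, 1]; clamping", RuntimeWarning, stacklevel=2)
    w = _clamp01(w)
    xi = 0.25 + 0.75 * w
    return float(xi) if np.isscalar(w1) else xi


# --- reconstructed schemes (formulas taken from each model's cited source) ---


def _orchidee_moisture(theta):
    # quadratic ramp clamped to [0.25, 1]
    th = _clamp01(np.asarray(theta, dtype=float))
    xi = -1.1 * th**2 + 2.4 * th - 0.29
    xi = np.clip(xi, 0.25, 1.0)
    return float(xi) if np.isscalar(theta) else xi


def _century_moisture(x):
    # logistic response to the precipitation / potential-evaporation ratio
    xa = np.asarray(x, dtype=float)
    xi = 1.0 / (1.0 + 30.0 * np.exp(-8.5 * np.clip(xa, 0.0, None)))
    xi = _clamp01(xi)
    return float(xi) if np.isscalar(x) else xi


def _century_temperature(t_soil):
    # arctangent response normalized to its 35 degC value
    t = np.asarray(t_soil, dtype=float)
    raw = 0.56 + 1.46 * np.arctan(np.pi * 0.0309 * (t - 15.7)) / np.pi
    ref = 0.56 + 1.46 * np.arctan(np.pi * 0.0309 * (35.0 - 15.7)) / np.pi
    xi = _clamp01(raw / ref)
    return float(xi) if np.isscalar(t_soil) else xi


def _casa_moisture(p):
    # water-budget ratio p = (PPT + SOILW) / PET; plateau near p ~ 1-2
    pa = np.clip(np.asarray(p, dtype=float), 0.0, None)
    rising = 0.1 + 0.9 * pa
    flat = np.ones_like(pa)
    falling = 1.0 - 0.3 * (pa - 2.0)
    xi = np.where(pa < 1.0, rising, np.where(pa <= 2.0, flat, falling))
    xi = np.clip(xi, 0.1, 1.0)
    return float(xi) if np.isscalar(p) else xi


@dataclass(frozen=True)
class ScalarScheme:
    """A named (temperature, moisture) scalar pair plus its moisture variable."""

    name: str
    temperature_fn: Callable
    moisture_fn: Callable
    moisture_variable: str
    reconstructed: bool = False


def _beps_moisture_of_k(k):
    return beps_moisture_scalar(k, 1.0)


_REGISTRY: dict[str, ScalarScheme] = {}


def _register(scheme: ScalarScheme) -> None:
    _REGISTRY[scheme.name] = scheme


_register(ScalarScheme("beps", lloyd_taylor_scalar, _beps_moisture_of_k, "porosity_fraction"))
_register(ScalarScheme("cable", q10_scalar, cable_moisture_scalar, "saturation_fraction"))
_register(ScalarScheme("casa", q10_scalar, _casa_moisture, "water_budget_ratio", True))
_register(ScalarScheme("intec", lloyd_taylor_scalar, _beps_moisture_of_k, "porosity_fraction", True))
_register(ScalarScheme("ibis", lloyd_taylor_scalar, _beps_moisture_of_k, "soil_water_content", True))
_register(ScalarScheme("lpj", lloyd_taylor_scalar, lpj_moisture_scalar, "upper_layer_swc"))
_register(ScalarScheme("orchidee", q10_scalar, _orchidee_moisture, "soil_water_content", True))
_register(ScalarScheme("dlem", lloyd_taylor_scalar, cable_moisture_scalar, "soil_water_content", True))
_register(ScalarScheme("century", _century_temperature, _century_moisture, "water_budget_ratio", True))


def get_scheme(name: str) -> ScalarScheme:
    """Look up a registered scalar scheme by name."""
    try:
        return _REGISTRY[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown scheme {name!r}; known schemes: {sorted(_REGISTRY)}"
        ) from None


def list_schemes() -> list[str]:
    return sorted(_REGISTRY)


@dataclass(frozen=True)
class ScalarField:
    """Per-cell temperature scalar, moisture scalar, and their product."""

    xi_t: np.ndarray
    xi_w: np.ndarray
    xi: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        xi_t = np.asarray(self.xi_t, dtype=float)
        xi_w = np.asarray(self.xi_w, dtype=float)
        object.__setattr__(self, "xi_t", xi_t)
        object.__setattr__(self, "xi_w", xi_w)
        if self.xi is None:
            object.__setattr__(self, "xi", xi_t * xi_w)
        if np.any((self.xi_t < 0) | (self.xi_t > 1)) or np.any((self.xi_w < 0) | (self.xi_w > 1)):
            raise ValidationError("scalars must lie in [0, 1]")
        if not np.allclose(self.xi, self.xi_t * self.xi_w):
            raise ValidationError("xi must equal xi_t * xi_w elementwise")


def environmental_scalar_matrix(
    xi_t: float, xi_w: float, layout: PoolLayout = DEFAULT_LAYOUT
) -> np.ndarray:
    """Expand cell scalars to the 13x13 diagonal environmental matrix.

    Vegetation pools are unlimited (diagonal 1); all litter and soil pools
    share the product xi_t * xi_w.
    """
    diag = np.full(N_POOLS, float(xi_t) * float(xi_w))
    diag[layout.vegetation_slice] = 1.0
    return np.diag(diag)
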