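"""Constitutive equations for a thixotropic, strain-stiffening Kelvin-Voigt solid.

The model targets fibrin networks probed in oscillatory shear.  The shear
stress is split into an elastic and a viscous branch,

    tau = G00 * x * f(gamma) * gamma + eta0 * g(gamma) * gamma_dot,

where ``f`` and ``g`` are even, monotone strain-stiffening factors and the
dimensionless network state parameter ``x`` carries the deformation history
(cycle-over-cycle softening during large-amplitude shear, slow recovery
afterwards).  ``x`` relaxes towards a strain-dependent equilibrium
``x_inf(gamma) = exp(-a*|gamma|**b)`` with separate rate constants for
softening (``c_d``, when x > x_inf) and recovery (``c_i``, when x <= x_inf).

All functions in this module are pure and pointwise; they accept scalars or
numpy arrays for the kinematic arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "ModelParameters",
    "NetworkState",
    "FIT_PARAM_NAMES",
    "PARAM_NAMES",
    "stiffening_factor",
    "viscous_factor",
    "x_infinity",
    "nsp_rate",
    "stress",
]

#: The eight constants determined by the staged fitting procedure, in the
#: canonical order used by the fitting and sensitivity modules.
FIT_PARAM_NAMES: tuple[str, ...] = ("c_d", "c_i", "a", "b", "k1", "n1", "k2", "n2")

#: All ten constitutive constants (linear moduli first).
PARAM_NAMES: tuple[str, ...] = ("G00", "eta0") + FIT_PARAM_NAMES


@dataclass(frozen=True)
class ModelParameters:
    """The ten constitutive constants.

    Attributes
    ----------
    G00 : float
        Low-strain shear modulus of the virgin network [Pa].
    eta0 : float
        Low-strain viscosity [Pa s].
    c_d : float
        Softening rate constant of the network state [1/s].
    c_i : float
        Recovery rate constant of the network state [1/s].
    a, b : float
        Amplitude coefficient and strain exponent of the equilibrium state
        ``x_inf = exp(-a*|gamma|**b)`` [-].
    k1, n1 : float
        Strain coefficient and exponent of the elastic stiffening factor
        ``f = (1 + k1*gamma**2)**n1`` [-].
    k2, n2 : float
        Strain coefficient and exponent of the viscous factor
        ``g = (1 + k2*gamma**2)**n2`` [-].

    With ``k1 = k2 = 0`` and ``x = 1`` the model reduces exactly to the
    linear Kelvin-Voigt law ``tau = G00*gamma + eta0*gamma_dot``.
    """

    G00: float
    eta0: float
    c_d: float
    c_i: float
    a: float
    b: float
    k1: float
    n1: float
    k2: float
    n2: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v!r}")
        if self.G00 <= 0:
            raise ValueError(f"G00 must be > 0, got {self.G00!r}")
        if self.b <= 0:
            raise ValueError(f"b must be > 0, got {self.b!r}")

    def to_dict(self) -> dict[str, float]:
        """Flat name -> value mapping in canonical order."""
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParameters":
        missing = set(PARAM_NAMES) - set(d)
        if missing:
            raise KeyError(f"missing parameters: {sorted(missing)}")
        extra = set(d) - set(PARAM_NAMES)
        if extra:
            raise KeyError(f"unknown parameters: {sorted(extra)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def replace(self, **changes: float) -> "ModelParameters":
        return replace(self, **changes)

    def fit_values(self) -> np.ndarray:
        """The eight fit parameters as an array in ``FIT_PARAM_NAMES`` order."""
        return np.array([getattr(self, n) for n in FIT_PARAM_NAMES], dtype=float)


@dataclass(frozen=True)
class NetworkState:
    """Instantaneous network state: dimensionless state ``x`` at time ``t``.

    ``x`` is non-negative and equals one at the reference state, taken as the
    start of the first large-amplitude sequence.
    """

    x: float
    t: float

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ValueError(f"network state x must be >= 0, got {self.x!r}")


def _check_factor_params(k: float, n: float, kname: str, nname: str) -> None:
    if k < 0:
        raise ValueError(f"{kname} must be >= 0, got {k!r}")
    if n < 0:
        raise ValueError(f"{nname} must be >= 0, got {n!r}")


def stiffening_factor(gamma, k1: float, n1: float):
    """Elastic strain-stiffening factor ``f(gamma) = (1 + k1*gamma**2)**n1``.

    Even in strain, equal to one at zero strain and monotone non-decreasing
    in |gamma| for admissible (non-negative) parameters.
    """
    _check_factor_params(k1, n1, "k1", "n1")
    gamma = np.asarray(gamma, dtype=float)
    out = (1.0 + k1 * gamma * gamma) ** n1
    return out if out.ndim else float(out)


def viscous_factor(gamma, k2: float, n2: float):
    """Viscous strain factor ``g(gamma) = (1 + k2*gamma**2)**n2``.

    Same functional form and contract as :func:`stiffening_factor`.
    """
    _check_factor_params(k2, n2, "k2", "n2")
    gamma = np.asarray(gamma, dtype=float)
    out = (1.0 + k2 * gamma * gamma) ** n2
    return out if out.ndim else float(out)


def x_infinity(gamma, a: float, b: float):
    """Equilibrium network state ``x_inf(gamma) = exp(-a*|gamma|**b)``.

    Lies in (0, 1], equals one at zero strain, is even in strain and monotone
    non-increasing in |gamma|.  The instantaneous strain is used, so during a
    deformation cycle ``x_inf`` oscillates, reaching one at every strain zero
    crossing; net softening arises because ``c_d`` typically far exceeds
    ``c_i``.
    """
    if a < 0:
        raise ValueError(f"a must be >= 0, got {a!r}")
    if b <= 0:
        raise ValueError(f"b must be > 0, got {b!r}")
    gamma = np.asarray(gamma, dtype=float)
    out = np.exp(-a * np.abs(gamma) ** b)
    return out if out.ndim else float(out)


def nsp_rate(x, x_inf, c_d: float, c_i: float):
    """Rate of change of the network state parameter.

    dx/dt = -c_d*(x - x_inf)  when x > x_inf   (softening)
          = -c_i*(x - x_inf)  otherwise        (recovery)

    Both branches vanish at x = x_inf, so the rate is continuous across the
    branch switch.
    """
    if c_d < 0 or c_i < 0:
        raise ValueError("rate constants c_d and c_i must be >= 0")
    x = np.asarray(x, dtype=float)
    x_inf = np.asarray(x_inf, dtype=float)
    c = np.where(x > x_inf, c_d, c_i)
    out = -c * (x - x_inf)
    return out if out.ndim else float(out)


def stress(gamma, gamma_dot, x, params: ModelParameters):
    """Shear stress at a kinematic state.

    tau = G00*x*(1 + k1*gamma**2)**n1 * gamma
        + eta0*(1 + k2*gamma**2)**n2 * gamma_dot   [Pa]

    Odd under a simultaneous sign flip of (gamma, gamma_dot).  At strain-rate
    reversal points (gamma_dot = 0) the stress reduces exactly to the elastic
    branch G00*x*f(gamma)*gamma, which is what the peak-stress feature
    extraction relies on.
    """
    gamma = np.asarray(gamma, dtype=float)
    gamma_dot = np.asarray(gamma_dot, dtype=float)
    x = np.asarray(x, dtype=float)
    elastic = params.G00 * x * stiffening_factor(gamma, params.k1, params.n1) * gamma
    viscous = params.eta0 * viscous_factor(gamma, params.k2, params.n2) * gamma_dot
    out = elastic + viscous
    return out if out.ndim else float(out)
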