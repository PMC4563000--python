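"""Staged parameter estimation from oscillatory shear data.

The ten constitutive constants are determined in three consecutive steps,
each a bounded trust-region-reflective nonlinear least-squares problem with
random multistart, preceded by a direct linear-moduli step:

0. ``G00`` and ``eta0`` from the storage/loss moduli of the 0.01-amplitude
   lead-in (linear regime):  G00 = mean G', eta0 = mean G''/omega.
1. The network-state kinetics (c_d, c_i, a, b) from the per-cycle x_e
   observations of the LAOS ladder plus the slow recovery trace, the latter
   down-weighted so it does not dominate by sheer sample count.
2. The stiffening pair (k1, n1) from the per-cycle f_e(gamma0) curve.
3. The viscous pair (k2, n2) from the stresses at gamma = 0.5*gamma0 and
   (sqrt(2)/2)*gamma0 on both branches, with everything else held fixed.

Each step uses only quantities fixed by the previous ones; the ordering is
part of the method, not an implementation accident.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .features import (
    SQRT2_HALF,
    SAOSRecord,
    extract_cycle_features,
    extract_moduli,
)
from .model import ModelParameters
from .protocol import StrainProtocol
from .simulate import integrate_nsp
from .simulate import LINEAR_AMPLITUDE

__all__ = [
    "FitError",
    "StepFit",
    "FitResult",
    "multistart",
    "fit_linear_moduli",
    "fit_nsp_kinetics",
    "fit_stiffening",
    "fit_viscous",
    "fit_three_step",
    "DEFAULT_BOUNDS",
]

#: Default search intervals per fit parameter.  Broad by design: they cover
#: the spread of fitted values reported for fibrin networks with a wide
#: margin, and multistart initial values are drawn from them (log-uniformly
#: for the scale-like parameters).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "c_d": (1e-5, 10.0),
    "c_i": (1e-5, 10.0),
    "a": (1e-3, 50.0),
    "b": (0.1, 5.0),
    "k1": (0.0, 1e3),
    "n1": (0.0, 10.0),
    "k2": (0.0, 1e3),
    "n2": (0.0, 10.0),
}

#: Parameters whose starting values are drawn log-uniformly.
LOG_SCALE_PARAMS = frozenset({"c_d", "c_i", "a", "k1", "k2"})

#: Squared-residual weight of the recovery phase relative to the LAOS phase
#: (applied after normalizing the two phases to equal observation counts).
RECOVERY_WEIGHT = 0.01

DEFAULT_N_STARTS = 20


class FitError(RuntimeError):
    """Raised when no multistart run converges; carries the best candidate."""

    def __init__(self, message: str, best: "StepFit | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class StepFit:
    """Outcome of one fitting step."""

    names: tuple[str, ...]
    values: tuple[float, ...]
    cost: float
    converged: bool
    n_starts: int
    seed: int
    bounds: tuple[tuple[float, float], ...]
    degenerate: tuple[str, ...] = ()
    message: str = ""

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


@dataclass(frozen=True)
class FitResult:
    """Full three-step fit: the assembled parameter set plus per-step detail."""

    params: ModelParameters
    steps: dict[str, StepFit] = field(default_factory=dict)

    @property
    def residual_norms(self) -> dict[str, float]:
        return {k: s.cost for k, s in self.steps.items()}

    @property
    def converged(self) -> dict[str, bool]:
        return {k: s.converged for k, s in self.steps.items()}


def _draw_starts(
    rng: np.random.Generator,
    names: tuple[str, ...],
    lo: np.ndarray,
    hi: np.ndarray,
    n_starts: int,
) -> np.ndarray:
    """Random starting points, log-uniform for scale-like parameters."""
    starts = np.empty((n_starts, len(names)))
    for j, name in enumerate(names):
        if name in LOG_SCALE_PARAMS:
            l = np.log10(max(lo[j], 1e-3))
            h = np.log10(hi[j])
            starts[:, j] = 10.0 ** rng.uniform(l, h, size=n_starts)
        else:
            starts[:, j] = rng.uniform(lo[j], hi[j], size=n_starts)
    return np.clip(starts, lo, hi)


def multistart(
    residual,
    names: tuple[str, ...],
    bounds: dict[str, tuple[float, float]],
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
) -> StepFit:
    """Bounded trust-region-reflective least squares from random starts.

    Runs ``scipy.optimize.least_squares`` (method ``trf``) from ``n_starts``
    random starting points and returns the lowest-cost converged result.
    Fully reproducible given ``seed``.  Raises :class:`FitError` when no
    start converges.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    lo = np.array([bounds[n][0] for n in names], dtype=float)
    hi = np.array([bounds[n][1] for n in names], dtype=float)
    rng = np.random.default_rng(seed)
    starts = _draw_starts(rng, names, lo, hi, n_starts)
    best = None
    best_cost = np.inf
    any_converged = False
    message = ""
    for x0 in starts:
        try:
            res = least_squares(residual, x0, bounds=(lo, hi), method="trf")
        except Exception as exc:  # solver blow-up on a bad start
            message = str(exc)
            continue
        if res.cost < best_cost:
            best, best_cost = res, res.cost
            any_converged = any_converged or bool(res.success)
        elif res.success and not any_converged:
            any_converged = True
    if best is None:
        raise FitError(f"all {n_starts} starts failed: {message}")
    degenerate = tuple(
        n
        for n, v, l, h in zip(names, best.x, lo, hi)
        if (v - l) <= 1e-8 * max(1.0, h - l) or (h - v) <= 1e-8 * max(1.0, h - l)
    )
    fit = StepFit(
        names=names,
        values=tuple(float(v) for v in best.x),
        cost=float(best.cost),
        converged=bool(best.success),
        n_starts=n_starts,
        seed=seed,
        bounds=tuple((float(l), float(h)) for l, h in zip(lo, hi)),
        degenerate=degenerate,
        message=str(best.message),
    )
    if not fit.converged:
        raise FitError("no multistart run converged", best=fit)
    return fit


def fit_linear_moduli(lead_in: list[SAOSRecord]) -> tuple[float, float]:
    """Linear moduli from the small-amplitude lead-in.

    G00 is the mean storage modulus; eta0 the mean loss modulus divided by
    the angular drive frequency.
    """
    if not lead_in:
        raise FitError("no linear-regime records supplied")
    if any(r.amplitude > LINEAR_AMPLITUDE for r in lead_in):
        raise ValueError("lead-in records must be in the linear regime")
    G00 = float(np.mean([r.G_prime for r in lead_in]))
    omega = 2.0 * np.pi * np.mean([r.frequency for r in lead_in])
    eta0 = float(np.mean([r.G_double_prime for r in lead_in]) / omega)
    return G00, eta0


def _nsp_params(theta: np.ndarray) -> ModelParameters:
    c_d, c_i, a, b = theta
    return ModelParameters(
        G00=1.0, eta0=0.0, c_d=c_d, c_i=c_i, a=a, b=b, k1=0.0, n1=0.0, k2=0.0, n2=0.0
    )


def fit_nsp_kinetics(
    t_obs: np.ndarray,
    x_obs: np.ndarray,
    is_recovery: np.ndarray,
    protocol: StrainProtocol,
    x0: float = 1.0,
    dt: float = 5e-3,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
    recovery_weight: float = RECOVERY_WEIGHT,
    bounds: dict[str, tuple[float, float]] | None = None,
    reading_strain: np.ndarray | None = None,
) -> StepFit:
    """Fit the network-state kinetics (c_d, c_i, a, b).

    Minimizes weighted squared residuals between observed x_e and the
    integrated state evaluated at the observation times.  Recovery-phase
    residuals carry a squared weight of ``recovery_weight`` relative to the
    LAOS phase after normalizing both phases to equal observation counts, so
    the long recovery trace informs c_i without swamping the ladder.

    ``reading_strain`` (optional, one value per observation) is the strain
    at which each modulus reading was taken: 0.05 for the two-point window
    linearization, the cycle amplitude for the small-amplitude secant, and
    the drive amplitude for moduli records.  A reading at strain w measures
    G00*x*f(w), not G00*x, so every x_e carries the (at this stage unknown)
    stiffening factor at its reading strain.  When reading strains are
    supplied, a single nuisance scale s = f(w_ref) at the reference reading
    strain w_ref = max(w) is co-estimated and each prediction is multiplied
    by s**(w_i/w_ref)**2 (the small-strain limit of the stiffening law, for
    which ln f is proportional to w**2).  This removes a systematic bias in
    c_d and a without using any step-2 quantity.
    """
    t_obs = np.asarray(t_obs, dtype=float)
    x_obs = np.asarray(x_obs, dtype=float)
    is_recovery = np.asarray(is_recovery, dtype=bool)
    keep = np.isfinite(t_obs) & np.isfinite(x_obs)
    if reading_strain is not None:
        reading_strain = np.asarray(reading_strain, dtype=float)[keep]
    t_obs, x_obs, is_recovery = t_obs[keep], x_obs[keep], is_recovery[keep]
    if len(t_obs) < 4:
        raise FitError("too few network-state observations")
    amplitudes = {
        protocol.segments[protocol.segment_at(t)[0]].amplitude for t in t_obs
    }
    if len(amplitudes) < 2:
        raise FitError("observations must span at least two amplitude steps")
    n_rec = int(is_recovery.sum())
    n_laos = len(t_obs) - n_rec
    w = np.ones(len(t_obs))
    if n_rec and n_laos:
        w[is_recovery] = np.sqrt(recovery_weight * n_laos / n_rec)

    names: tuple[str, ...] = ("c_d", "c_i", "a", "b")
    b = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    if reading_strain is None:

        def residual(theta: np.ndarray) -> np.ndarray:
            traj = integrate_nsp(protocol, _nsp_params(theta), x0=x0, dt=dt)
            return w * (traj.at(t_obs) - x_obs)

    else:
        w_ref = float(np.max(reading_strain))
        q = (reading_strain / w_ref) ** 2
        names = names + ("reading_scale",)
        b.setdefault("reading_scale", (1.0, 2.0))

        def residual(theta: np.ndarray) -> np.ndarray:
            traj = integrate_nsp(protocol, _nsp_params(theta[:4]), x0=x0, dt=dt)
            scale = theta[4] ** q
            return w * (scale * traj.at(t_obs) - x_obs)

    fit = multistart(residual, names, b, n_starts=n_starts, seed=seed)
    if reading_strain is None:
        return fit
    return StepFit(
        names=fit.names[:4],
        values=fit.values[:4],
        cost=fit.cost,
        converged=fit.converged,
        n_starts=fit.n_starts,
        seed=fit.seed,
        bounds=fit.bounds[:4],
        degenerate=tuple(d for d in fit.degenerate if d != "reading_scale"),
        message=fit.message
        + f" [reading_scale={fit.values[4]:.4f} at w={w_ref:g}]",
    )


def fit_stiffening(
    gamma0: np.ndarray,
    f_e: np.ndarray,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> StepFit:
    """Fit the stiffening pair (k1, n1) to the per-cycle f_e(gamma0) curve.

    If the data carry no stiffening signal at all (every f_e equal to one),
    returns k1 = 0 with n1 flagged unidentifiable instead of optimizing.
    """
    gamma0 = np.asarray(gamma0, dtype=float)
    f_e = np.asarray(f_e, dtype=float)
    keep = np.isfinite(gamma0) & np.isfinite(f_e) & (gamma0 > 0)
    gamma0, f_e = gamma0[keep], f_e[keep]
    if len(np.unique(np.round(gamma0, 6))) < 3:
        raise FitError("need at least three distinct amplitudes with valid f_e")
    b = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    if np.allclose(f_e, 1.0, atol=1e-9):
        lo_hi = (b["k1"], b["n1"])
        return StepFit(
            names=("k1", "n1"),
            values=(0.0, 1.0),
            cost=0.0,
            converged=True,
            n_starts=0,
            seed=seed,
            bounds=lo_hi,
            degenerate=("k1", "n1"),
            message="no stiffening signal; k1 = 0, n1 unidentifiable",
        )

    def residual(theta: np.ndarray) -> np.ndarray:
        k1, n1 = theta
        return (1.0 + k1 * gamma0**2) ** n1 - f_e

    return multistart(residual, ("k1", "n1"), b, n_starts=n_starts, seed=seed)


def _fraction_times(
    features: pd.DataFrame, protocol: StrainProtocol
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Times, strains, strain rates and observed stresses of the four
    fraction readings of every cycle with complete data."""
    times, gammas, gdots, obs = [], [], [], []
    cols = {
        (0.5, +1): "tau_half_up",
        (0.5, -1): "tau_half_down",
        (SQRT2_HALF, +1): "tau_sqrt2_up",
        (SQRT2_HALF, -1): "tau_sqrt2_down",
    }
    for _, row in features.iterrows():
        seg = protocol.segments[int(row["segment"])]
        if any(not np.isfinite(row[c]) for c in cols.values()):
            continue
        g0 = row["gamma0"]
        for (frac, sign), col in cols.items():
            theta = np.arcsin(frac)
            if sign < 0:
                theta = np.pi - theta
            times.append(row["t_start"] + theta / seg.omega)
            gammas.append(frac * g0)
            gdots.append(sign * g0 * seg.omega * np.sqrt(1.0 - frac**2))
            obs.append(row[col])
    return (
        np.asarray(times),
        np.asarray(gammas),
        np.asarray(gdots),
        np.asarray(obs),
    )


def fit_viscous(
    features: pd.DataFrame,
    fixed: ModelParameters,
    protocol: StrainProtocol,
    x0: float = 1.0,
    dt: float = 5e-3,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> StepFit:
    """Fit the viscous pair (k2, n2) to the four fraction stresses per cycle.

    All other parameters are held at ``fixed``; since (k2, n2) do not enter
    the state ODE, the state at the fraction times is integrated once and the
    residual is closed-form in (k2, n2).
    """
    times, gammas, gdots, obs = _fraction_times(features, protocol)
    if len(times) < 4:
        raise FitError("no cycles with complete fraction stresses")
    b = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    if fixed.eta0 == 0.0:
        # closed loops: the viscous branch never enters the stress and the
        # residual carries no information on (k2, n2)
        return StepFit(
            names=("k2", "n2"),
            values=(b["k2"][0], 1.0),
            cost=0.0,
            converged=True,
            n_starts=0,
            seed=seed,
            bounds=(b["k2"], b["n2"]),
            degenerate=("k2", "n2"),
            message="eta0 = 0: no viscous signal; k2 at lower bound",
        )
    traj = integrate_nsp(protocol, fixed, x0=x0, dt=dt)
    x_at = traj.at(times)
    elastic = (
        fixed.G00 * x_at * (1.0 + fixed.k1 * gammas**2) ** fixed.n1 * gammas
    )

    def residual(theta: np.ndarray) -> np.ndarray:
        k2, n2 = theta
        visc = fixed.eta0 * (1.0 + k2 * gammas**2) ** n2 * gdots
        return (elastic + visc) - obs

    return multistart(residual, ("k2", "n2"), b, n_starts=n_starts, seed=seed)


def fit_three_step(
    laos_series,
    protocol: StrainProtocol,
    saos_records: list[SAOSRecord] | None = None,
    seed: int = 0,
    n_starts: int = DEFAULT_N_STARTS,
    dt: float = 5e-3,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> FitResult:
    """Run the complete staged fit on one experiment.

    ``laos_series`` is the sampled first LAOS ladder; ``saos_records`` the
    moduli of the subsequent recovery interval (optional, needed to identify
    c_i).  The per-step RNG seeds are derived deterministically from
    ``seed``.
    """
    lead_in = extract_moduli(laos_series, protocol)
    G00, eta0 = fit_linear_moduli(lead_in)

    features = extract_cycle_features(laos_series, protocol, G00=G00)
    if not len(features):
        raise FitError("no full cycles found in the series")

    from .features import G0_WINDOW

    t_obs = [features["t_mid"].to_numpy()]
    x_obs = [features["x_e"].to_numpy()]
    rec_flags = [np.zeros(len(features), dtype=bool)]
    gamma0 = features["gamma0"].to_numpy()
    reading = [np.minimum(gamma0, G0_WINDOW)]
    if saos_records:
        t_obs.append(np.array([r.t for r in saos_records]))
        x_obs.append(np.array([r.G_prime / G00 for r in saos_records]))
        rec_flags.append(np.ones(len(saos_records), dtype=bool))
        reading.append(np.array([r.amplitude for r in saos_records]))
    step1 = fit_nsp_kinetics(
        np.concatenate(t_obs),
        np.concatenate(x_obs),
        np.concatenate(rec_flags),
        protocol,
        dt=dt,
        n_starts=n_starts,
        seed=seed * 3 + 1,
        bounds=bounds,
        reading_strain=np.concatenate(reading),
    )

    step2 = fit_stiffening(
        features["gamma0"].to_numpy(),
        features["f_e"].to_numpy(),
        n_starts=n_starts,
        seed=seed * 3 + 2,
        bounds=bounds,
    )

    partial = ModelParameters(
        G00=G00,
        eta0=eta0,
        **step1.as_dict(),
        **step2.as_dict(),
        k2=0.0,
        n2=0.0,
    )
    step3 = fit_viscous(
        features,
        partial,
        protocol,
        dt=dt,
        n_starts=n_starts,
        seed=seed * 3 + 3,
        bounds=bounds,
    )
    params = partial.replace(**step3.as_dict())
    return FitResult(
        params=params,
        steps={"nsp_kinetics": step1, "stiffening": step2, "viscous": step3},
    )
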