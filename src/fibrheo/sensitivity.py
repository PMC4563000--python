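"""Variance-based global sensitivity analysis of the eight fit parameters.

Three scalar outputs summarize the three nonlinear features on the unit
amplitude (gamma_0 = 1) interval of the LAOS ladder, simulated with a warm
start from the reference state through the preceding amplitude steps:

* ``O_so`` - softening: relative drop of the cycle-peak stress between the
  first and last full cycle of the interval,
* ``O_ss`` - stiffening: peak stress of the first full cycle normalized by
  the virgin low-strain modulus G00,
* ``O_vi`` - viscous dissipation: stress difference between the rising and
  falling branch at gamma = (sqrt(2)/2)*gamma_0 on the first full cycle.

Main (first-order) and total Sobol indices are estimated with Jansen's
formulas inside Saltelli's paired-matrix design (cost n_base*(k+2) model
runs; base points from Latin hypercube sampling).  Negative estimates, which
can occur through Monte-Carlo noise, are reported as-is.

Model evaluations are vectorized across parameter draws: the state ODE is
stepped once per time step for the whole sample matrix, which is what makes
tens of thousands of runs tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .model import FIT_PARAM_NAMES, ModelParameters
from .protocol import StrainProtocol, standard_laos_protocol
from .simulate import simulate

__all__ = [
    "OutputTriple",
    "SaltelliSample",
    "SensitivityResult",
    "compute_outputs",
    "batch_outputs",
    "sample_parameter_space",
    "sobol_indices",
    "run_sensitivity",
    "default_ranges",
    "ranges_from_fits",
]

OUTPUT_NAMES = ("O_so", "O_ss", "O_vi")

SQRT2_HALF = np.sqrt(2.0) / 2.0

#: Integrator step for sensitivity runs [s]; coarser than the simulation
#: default because only cycle-level stress summaries are needed.
SENSITIVITY_DT = 2e-3


@dataclass(frozen=True)
class OutputTriple:
    """The three LAOS summary outputs."""

    O_so: float
    O_ss: float
    O_vi: float

    def as_array(self) -> np.ndarray:
        return np.array([self.O_so, self.O_ss, self.O_vi])


def _target_segment(protocol: StrainProtocol) -> int:
    amps = [s.amplitude for s in protocol.segments]
    return int(np.argmax(amps))


def compute_outputs(
    params: ModelParameters,
    protocol: StrainProtocol | None = None,
    dt: float = SENSITIVITY_DT,
    warm_start: bool = True,
    x0: float = 1.0,
) -> OutputTriple:
    """The three outputs for a single parameter set (reference path).

    With ``warm_start`` the simulation starts at the reference state and
    runs through the amplitude steps preceding the maximum-amplitude
    interval; without it only that interval is simulated from ``x0``.
    """
    if protocol is None:
        protocol = standard_laos_protocol()
    si = _target_segment(protocol)
    if not warm_start:
        protocol = StrainProtocol(
            segments=(protocol.segments[si],), sample_rate=protocol.sample_rate
        )
        si = 0
    series = simulate(protocol, params, x0=x0, dt=dt)
    seg = protocol.segments[si]
    t0 = protocol.segment_starts[si]
    period = 1.0 / seg.frequency
    if np.isnan(series.tau).any():
        raise FloatingPointError("simulation produced non-finite stress")

    def cycle_max(tc: float) -> float:
        m = (series.t >= tc - 1e-9) & (series.t <= tc + period + 1e-9)
        return float(series.tau[m].max())

    tau_max = cycle_max(t0)
    tau_min = cycle_max(t0 + seg.duration - period)
    # exact-phase fraction stresses on the first full cycle
    g0 = seg.amplitude
    x_up = float(np.interp(t0 + period / 8.0, series.t, series.x))
    x_dn = float(np.interp(t0 + 3.0 * period / 8.0, series.t, series.x))
    gam = SQRT2_HALF * g0
    gdot = seg.omega * g0 * SQRT2_HALF
    f = (1.0 + params.k1 * gam**2) ** params.n1
    g = (1.0 + params.k2 * gam**2) ** params.n2
    tau_up = params.G00 * x_up * f * gam + params.eta0 * g * gdot
    tau_down = params.G00 * x_dn * f * gam - params.eta0 * g * gdot
    return OutputTriple(
        O_so=(tau_max - tau_min) / tau_max,
        O_ss=tau_max / params.G00,
        O_vi=tau_up - tau_down,
    )


def batch_outputs(
    fit_matrix: np.ndarray,
    G00: float,
    eta0: float,
    protocol: StrainProtocol | None = None,
    dt: float = SENSITIVITY_DT,
    x0: float = 1.0,
) -> np.ndarray:
    """The three outputs for every row of a fit-parameter matrix.

    ``fit_matrix`` has shape (N, 8) with columns in ``FIT_PARAM_NAMES``
    order.  The state ODE (explicit midpoint, branch per stage, identical to
    the scalar simulator) is advanced for all rows simultaneously; stresses
    are evaluated only on the first and last cycle of the maximum-amplitude
    interval.  Returns an (N, 3) array of (O_so, O_ss, O_vi).
    """
    if protocol is None:
        protocol = standard_laos_protocol()
    fit_matrix = np.atleast_2d(np.asarray(fit_matrix, dtype=float))
    c_d, c_i, a, b, k1, n1, k2, n2 = fit_matrix.T.copy()
    N = fit_matrix.shape[0]
    si = _target_segment(protocol)
    x = np.full(N, float(x0))

    def x_inf(abs_gamma: float) -> np.ndarray:
        if abs_gamma <= 0.0:
            return np.ones(N)
        return np.exp(-a * np.exp(b * np.log(abs_gamma)))

    tau_max1 = np.full(N, -np.inf)
    tau_maxL = np.full(N, -np.inf)
    x_frac = np.full((2, N), np.nan)

    for j, (seg, t_seg) in enumerate(zip(protocol.segments, protocol.segment_starts)):
        n = max(1, int(round(seg.duration / dt)))
        h = seg.duration / n
        if h > 1.0 / (20.0 * seg.frequency):
            raise ValueError("dt too coarse for this protocol")
        amp, om = seg.amplitude, seg.omega
        period = 1.0 / seg.frequency
        m = int(round(period / h))
        record = j == si
        if record:
            g0 = amp
            xw1 = np.empty((m + 1, N))
            xwL = np.empty((m + 1, N))
            xw1[0] = x
            t_up = period / 8.0
            t_dn = 3.0 * period / 8.0
        for i in range(n):
            t_lo = i * h
            if record and i >= n - m:
                xwL[i - (n - m)] = x
            xi0 = x_inf(abs(amp * np.sin(om * t_lo)))
            r1 = np.where(x > xi0, c_d, c_i) * (xi0 - x)
            xm = x + 0.5 * h * r1
            xim = x_inf(abs(amp * np.sin(om * (t_lo + 0.5 * h))))
            r2 = np.where(xm > xim, c_d, c_i) * (xim - xm)
            x = np.maximum(x + h * r2, 0.0)
            if record:
                if i < m:
                    xw1[i + 1] = x
                    # linear interpolation of x at the fraction times
                    for idx, t_star in enumerate((t_up, t_dn)):
                        if t_lo < t_star <= t_lo + h:
                            w = (t_star - t_lo) / h
                            x_frac[idx] = (1.0 - w) * xw1[i] + w * x
        if record:
            xwL[m] = x
            th = om * h * np.arange(m + 1)
            gam = g0 * np.sin(th)
            gdot = g0 * om * np.cos(th)
            for gam_j, gdot_j, xw_row in zip(gam, gdot, xw1):
                f = np.exp(n1 * np.log1p(k1 * gam_j**2))
                gv = np.exp(n2 * np.log1p(k2 * gam_j**2))
                tau = G00 * xw_row * f * gam_j + eta0 * gv * gdot_j
                np.maximum(tau_max1, tau, out=tau_max1)
            for gam_j, gdot_j, xw_row in zip(gam, gdot, xwL):
                f = np.exp(n1 * np.log1p(k1 * gam_j**2))
                gv = np.exp(n2 * np.log1p(k2 * gam_j**2))
                tau = G00 * xw_row * f * gam_j + eta0 * gv * gdot_j
                np.maximum(tau_maxL, tau, out=tau_maxL)
            gam_s = SQRT2_HALF * g0
            gdot_s = g0 * om * SQRT2_HALF
            f = np.exp(n1 * np.log1p(k1 * gam_s**2))
            gv = np.exp(n2 * np.log1p(k2 * gam_s**2))
            tau_up = G00 * x_frac[0] * f * gam_s + eta0 * gv * gdot_s
            tau_down = G00 * x_frac[1] * f * gam_s - eta0 * gv * gdot_s
    out = np.empty((N, 3))
    out[:, 0] = (tau_max1 - tau_maxL) / tau_max1
    out[:, 1] = tau_max1 / G00
    out[:, 2] = tau_up - tau_down
    return out


@dataclass(frozen=True)
class SaltelliSample:
    """Paired sample matrices of the Saltelli scheme.

    ``A`` and ``B`` are independent (n_base, k) draws; ``AB[i]`` equals A
    with column i replaced by B's.  Parameters with zero-width ranges are
    held fixed and excluded from index estimation (``active`` mask).
    """

    names: tuple[str, ...]
    A: np.ndarray
    B: np.ndarray
    AB: np.ndarray  # (k_active, n_base, k)
    active: np.ndarray
    ranges: np.ndarray  # (k, 2)
    seed: int

    @property
    def n_base(self) -> int:
        return self.A.shape[0]

    @property
    def n_runs(self) -> int:
        return self.n_base * (int(self.active.sum()) + 2)

    def all_rows(self) -> np.ndarray:
        """All evaluation points stacked: A, B, then each AB matrix."""
        return np.concatenate([self.A, self.B, *self.AB], axis=0)

    def split_outputs(self, y: np.ndarray):
        """Split stacked outputs back into (yA, yB, yAB)."""
        n = self.n_base
        yA, yB = y[:n], y[n : 2 * n]
        k_act = self.AB.shape[0]
        yAB = y[2 * n :].reshape(k_act, n, *y.shape[1:])
        return yA, yB, yAB


def sample_parameter_space(
    ranges: dict[str, tuple[float, float]] | np.ndarray,
    n_base: int,
    seed: int = 0,
    names: tuple[str, ...] = FIT_PARAM_NAMES,
    method: str = "lhs",
) -> SaltelliSample:
    """Build the Saltelli design over a hyper-rectangle.

    Base points come from a space-filling design in 2k dimensions whose
    halves form the A and B matrices: ``method="lhs"`` (default) uses Latin
    hypercube sampling, ``method="sobol"`` a scrambled Sobol' sequence,
    which converges considerably faster and is preferable when the model is
    cheap.  Lower bounds are clipped at zero.  Total model evaluations:
    n_base * (k_active + 2).
    """
    if n_base < 2:
        raise ValueError("n_base must be >= 2")
    if isinstance(ranges, dict):
        rng_arr = np.array([ranges[n] for n in names], dtype=float)
    else:
        rng_arr = np.asarray(ranges, dtype=float)
    if rng_arr.shape != (len(names), 2):
        raise ValueError(f"ranges must be ({len(names)}, 2)")
    rng_arr = np.maximum(rng_arr, 0.0)
    if np.any(rng_arr[:, 1] < rng_arr[:, 0]):
        raise ValueError("upper bounds must be >= lower bounds")
    k = len(names)
    active = rng_arr[:, 1] > rng_arr[:, 0]
    if method == "lhs":
        sampler = qmc.LatinHypercube(d=2 * k, seed=np.random.default_rng(seed))
        u = sampler.random(n_base)
    elif method == "sobol":
        sampler = qmc.Sobol(d=2 * k, scramble=True, seed=np.random.default_rng(seed))
        u = sampler.random(n_base)
    else:
        raise ValueError(f"unknown sampling method {method!r}")
    lo, wid = rng_arr[:, 0], rng_arr[:, 1] - rng_arr[:, 0]
    A = lo + wid * u[:, :k]
    B = lo + wid * u[:, k:]
    AB = np.empty((int(active.sum()), n_base, k))
    for row, i in enumerate(np.nonzero(active)[0]):
        AB[row] = A
        AB[row, :, i] = B[:, i]
    return SaltelliSample(
        names=tuple(names), A=A, B=B, AB=AB, active=active,
        ranges=rng_arr, seed=seed,
    )


@dataclass(frozen=True)
class SensitivityResult:
    """Main and total Sobol indices per parameter per output."""

    names: tuple[str, ...]
    outputs: tuple[str, ...]
    main: np.ndarray  # (k, n_outputs)
    total: np.ndarray
    main_se: np.ndarray
    total_se: np.ndarray
    n_base: int
    n_runs: int
    ranges: np.ndarray
    degenerate_outputs: tuple[str, ...] = ()

    @property
    def sum_main(self) -> np.ndarray:
        """Sum of main indices per output (< 1 signals interactions)."""
        return np.nansum(self.main, axis=0)

    def main_index(self, param: str, output: str) -> float:
        return float(
            self.main[self.names.index(param), self.outputs.index(output)]
        )

    def total_index(self, param: str, output: str) -> float:
        return float(
            self.total[self.names.index(param), self.outputs.index(output)]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.names):
            for j, o in enumerate(self.outputs):
                rows.append(
                    {
                        "parameter": p,
                        "output": o,
                        "main": self.main[i, j],
                        "total": self.total[i, j],
                        "main_se": self.main_se[i, j],
                        "total_se": self.total_se[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _jansen(yA: np.ndarray, yB: np.ndarray, yAB: np.ndarray):
    """Jansen estimators for one output vector set."""
    V = np.var(np.concatenate([yA, yB]), ddof=0)
    if V == 0.0:
        nan = np.full(yAB.shape[0], np.nan)
        return V, nan, nan
    S = (V - 0.5 * np.mean((yB[None, :] - yAB) ** 2, axis=1)) / V
    ST = 0.5 * np.mean((yA[None, :] - yAB) ** 2, axis=1) / V
    return V, S, ST


def sobol_indices(
    sample: SaltelliSample,
    y: np.ndarray,
    output_names: tuple[str, ...] = OUTPUT_NAMES,
    n_boot: int = 200,
    boot_seed: int = 0,
) -> SensitivityResult:
    """Main and total Sobol indices from stacked model outputs.

    ``y`` holds one row per evaluation point of ``sample.all_rows()`` and
    one column per output.  Jansen's estimators are used; negative values
    (Monte-Carlo noise) are not clipped.  Bootstrap standard errors resample
    base points.  Outputs with (numerically) zero variance are flagged and
    their indices set to NaN.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] == sample.n_runs and y.ndim == 2:
        pass
    else:
        raise ValueError(f"expected {sample.n_runs} output rows, got {y.shape[0]}")
    n_out = y.shape[1]
    if n_out != len(output_names):
        raise ValueError("output_names length mismatch")
    bad = ~np.isfinite(y).all(axis=1)
    if bad.any():
        frac = bad.mean()
        if frac >= 0.01:
            raise ValueError(f"{frac:.1%} of evaluations invalid (>= 1% limit)")
        # replace invalid rows by the column means so estimators stay defined
        col_mean = np.nanmean(np.where(np.isfinite(y), y, np.nan), axis=0)
        y = np.where(np.isfinite(y), y, col_mean[None, :])
    yA, yB, yAB = sample.split_outputs(y)
    k = len(sample.names)
    k_act = yAB.shape[0]
    act_idx = np.nonzero(sample.active)[0]
    main = np.full((k, n_out), np.nan)
    total = np.full((k, n_out), np.nan)
    main_se = np.full((k, n_out), np.nan)
    total_se = np.full((k, n_out), np.nan)
    degenerate = []
    rng = np.random.default_rng(boot_seed)
    n = sample.n_base
    boot_idx = rng.integers(0, n, size=(n_boot, n)) if n_boot else None
    for j, oname in enumerate(output_names):
        V, S, ST = _jansen(yA[:, j], yB[:, j], yAB[:, :, j])
        scale = max(np.abs(yA[:, j]).max(), 1.0)
        if V <= (1e-14 * scale) ** 2:
            degenerate.append(oname)
            continue
        main[act_idx, j] = S
        total[act_idx, j] = ST
        if n_boot:
            Sb = np.empty((n_boot, k_act))
            STb = np.empty((n_boot, k_act))
            for t in range(n_boot):
                idx = boot_idx[t]
                _, Sb[t], STb[t] = _jansen(
                    yA[idx, j], yB[idx, j], yAB[:, idx, j]
                )
            main_se[act_idx, j] = Sb.std(axis=0, ddof=1)
            total_se[act_idx, j] = STb.std(axis=0, ddof=1)
    return SensitivityResult(
        names=sample.names,
        outputs=tuple(output_names),
        main=main,
        total=total,
        main_se=main_se,
        total_se=total_se,
        n_base=sample.n_base,
        n_runs=sample.n_runs,
        ranges=sample.ranges,
        degenerate_outputs=tuple(degenerate),
    )


def default_ranges(
    params: ModelParameters, rel_width: float = 0.5
) -> dict[str, tuple[float, float]]:
    """Symmetric ranges around a center parameter set: value*(1 +/- rel)."""
    out = {}
    for name in FIT_PARAM_NAMES:
        v = getattr(params, name)
        out[name] = (max(v * (1.0 - rel_width), 0.0), v * (1.0 + rel_width))
    return out


def ranges_from_fits(
    fits: list[ModelParameters], n_sd: float = 2.0
) -> dict[str, tuple[float, float]]:
    """Ranges as mean +/- n_sd standard deviations over fitted parameter
    sets (sample SD; clipped at zero), mirroring replicate experiments."""
    if len(fits) < 2:
        raise ValueError("need at least two parameter sets")
    out = {}
    for name in FIT_PARAM_NAMES:
        vals = np.array([getattr(p, name) for p in fits])
        m, sd = vals.mean(), vals.std(ddof=1)
        out[name] = (max(m - n_sd * sd, 0.0), m + n_sd * sd)
    return out


def run_sensitivity(
    center: ModelParameters,
    ranges: dict[str, tuple[float, float]] | None = None,
    protocol: StrainProtocol | None = None,
    n_base: int = 512,
    seed: int = 0,
    dt: float = SENSITIVITY_DT,
    n_boot: int = 200,
) -> SensitivityResult:
    """End-to-end sensitivity analysis of the LAOS outputs.

    Samples the eight fit parameters (G00 and eta0 stay at the center
    values), evaluates the batch forward model, and estimates Sobol indices.
    """
    if ranges is None:
        ranges = default_ranges(center)
    sample = sample_parameter_space(ranges, n_base, seed=seed)
    y = batch_outputs(
        sample.all_rows(), center.G00, center.eta0, protocol=protocol, dt=dt
    )
    return sobol_indices(sample, y, n_boot=n_boot, boot_seed=seed + 1)
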