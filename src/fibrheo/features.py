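"""Per-cycle feature extraction from oscillatory shear stress time series.

A stress time series is segmented into full deformation cycles (delimited by
upward zero crossings of the strain) and each cycle is reduced to the handful
of Lissajous-loop quantities the staged fitting procedure consumes:

* ``gamma0``  - strain amplitude of the cycle,
* ``tau0``    - stress at maximal strain (strain rate is zero there, so this
  is a purely elastic reading),
* ``G0``      - minimal-strain modulus, the local slope d tau/d gamma at
  gamma = 0, estimated from the rising branch of the loop at gamma = +/-0.05
  (the viscous offset is identical at the two points and cancels in the
  slope),
* stresses at gamma = 0.5*gamma0 and (sqrt(2)/2)*gamma0 on the rising and
  falling branches (where the viscous contribution is large),
* ``x_e = G0/G00``  - the experimental network state parameter, and
* ``f_e = tau0/(G00*x_e*gamma0)``  - the experimental stiffening factor.

Linear-regime (SAOS) intervals are reduced to storage and loss moduli by
least-squares projection of the stress onto the in-phase and quadrature
components of the drive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .simulate import StressTimeSeries
from .protocol import StrainProtocol

__all__ = [
    "SQRT2_HALF",
    "CycleSpan",
    "CycleFeatures",
    "SAOSRecord",
    "segment_cycles",
    "estimate_G0",
    "stresses_at_fractions",
    "extract_nsp",
    "extract_stiffening",
    "extract_cycle_features",
    "extract_moduli",
    "saos_to_series",
]

SQRT2_HALF = math.sqrt(2.0) / 2.0

#: Half-width of the strain window used for the minimal-strain modulus.
G0_WINDOW = 0.05

#: Amplitude at or below which a segment is treated as linear (SAOS).
LINEAR_AMPLITUDE = 0.02


class CycleSpan(NamedTuple):
    """Index range of one full cycle: samples ``start..stop`` inclusive."""

    start: int
    stop: int
    segment: int


@dataclass(frozen=True)
class CycleFeatures:
    cycle_index: int
    t_start: float
    t_end: float
    gamma0: float
    tau0: float
    G0: float
    tau_half_up: float
    tau_half_down: float
    tau_sqrt2_up: float
    tau_sqrt2_down: float
    x_e: float = float("nan")
    f_e: float = float("nan")

    @property
    def t_mid(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


@dataclass(frozen=True)
class SAOSRecord:
    """Storage/loss moduli of one linear-regime interval."""

    t: float
    G_prime: float
    G_double_prime: float
    amplitude: float
    frequency: float

    def __post_init__(self) -> None:
        if self.G_prime < 0 or self.G_double_prime < 0:
            raise ValueError("moduli must be non-negative")


def segment_cycles(
    series: StressTimeSeries, protocol: StrainProtocol
) -> list[CycleSpan]:
    """Split a series into full oscillation cycles.

    Cycles are delimited by upward zero crossings of the strain within each
    protocol segment; partial cycles at segment boundaries are discarded, as
    are segments sampled below 20 points per cycle (e.g. the sparse envelope
    sampling of long SAOS intervals).
    """
    if len(series) == 0:
        return []
    t = series.t
    if t[-1] > protocol.total_duration + 1e-6:
        raise ValueError("series extends beyond the protocol duration")
    spans: list[CycleSpan] = []
    starts = protocol.segment_starts
    for si, (seg, t0) in enumerate(zip(protocol.segments, starts)):
        lo = int(np.searchsorted(t, t0 - 1e-9))
        hi = int(np.searchsorted(t, t0 + seg.duration + 1e-9))
        if hi - lo < 2:
            continue
        dt_med = np.median(np.diff(t[lo:hi]))
        if dt_med * seg.frequency > 1.0 / 20.0:
            continue  # undersampled (envelope) segment
        # look one sample past the segment end so a crossing sitting exactly
        # on the boundary sample is still detected
        g = series.gamma[lo : min(hi + 1, len(t))]
        up = np.nonzero((g[:-1] <= 0.0) & (g[1:] > 0.0))[0] + lo
        up = up[up < hi]
        period = 1.0 / seg.frequency
        up = list(up)
        # the final sample of the protocol closes its last cycle if it sits
        # at a phase-zero point one period after the previous crossing
        if up and hi == len(t):
            last = hi - 1
            near_zero = abs(series.gamma[last]) <= 2.0 * seg.amplitude * seg.omega * dt_med
            if near_zero and last != up[-1] and abs((t[last] - t[up[-1]]) - period) <= 2.0 * dt_med:
                up.append(last)
        for z0, z1 in zip(up[:-1], up[1:]):
            if abs((t[z1] - t[z0]) - period) <= 2.0 * dt_med:
                spans.append(CycleSpan(int(z0), int(z1), si))
    return spans


def _branch_interp(
    gamma: np.ndarray, tau: np.ndarray, mask: np.ndarray, targets: Sequence[float]
) -> np.ndarray:
    """Interpolate tau at the target strains along one monotone branch."""
    g = gamma[mask]
    s = tau[mask]
    if len(g) < 2:
        return np.full(len(targets), np.nan)
    order = np.argsort(g)
    g, s = g[order], s[order]
    out = np.interp(targets, g, s, left=np.nan, right=np.nan)
    return np.asarray(out, dtype=float)


def estimate_G0(
    gamma: np.ndarray,
    gamma_dot: np.ndarray,
    tau: np.ndarray,
    gamma0: float,
    window: float = G0_WINDOW,
) -> float:
    """Minimal-strain modulus of one cycle [Pa].

    For ``gamma0 > window``: the slope of the loop's rising branch between
    gamma = -window and +window (two-point linearization; the viscous stress
    is the same at the two points and drops out).  For smaller amplitudes the
    loop never reaches the window and the secant through the peak,
    ``tau0/gamma0``, is used instead.  Returns NaN when extraction fails.
    """
    if gamma0 <= 0:
        return float("nan")
    if gamma0 > window:
        lo, hi = _branch_interp(
            gamma, tau, gamma_dot > 0, (-window, window)
        )
        if np.isnan(lo) or np.isnan(hi):
            return float("nan")
        return float((hi - lo) / (2.0 * window))
    i = int(np.argmax(gamma))
    return float(tau[i] / gamma[i])


def stresses_at_fractions(
    gamma: np.ndarray,
    gamma_dot: np.ndarray,
    tau: np.ndarray,
    gamma0: float,
    fractions: Sequence[float] = (0.5, SQRT2_HALF),
) -> tuple[float, ...]:
    """Stresses at gamma = c*gamma0 on the rising and falling branches.

    Returns (up, down) per fraction, flattened in fraction order.  Linear
    interpolation in strain along each monotone branch; unreachable strains
    yield NaN.
    """
    targets = [f * gamma0 for f in fractions]
    up = _branch_interp(gamma, tau, gamma_dot > 0, targets)
    down = _branch_interp(gamma, tau, gamma_dot < 0, targets)
    out: list[float] = []
    for u, d in zip(up, down):
        out.extend((float(u), float(d)))
    return tuple(out)


def extract_nsp(G0, G00: float):
    """Experimental network state parameter x_e = G0/G00 (NaN propagates)."""
    if G00 <= 0:
        raise ValueError("G00 must be positive")
    return np.asarray(G0, dtype=float) / G00


def extract_stiffening(tau0, gamma0, x_e, G00: float):
    """Experimental stiffening factor f_e = tau0/(G00*x_e*gamma0)."""
    if G00 <= 0:
        raise ValueError("G00 must be positive")
    tau0 = np.asarray(tau0, dtype=float)
    denom = G00 * np.asarray(x_e, dtype=float) * np.asarray(gamma0, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, tau0 / denom, np.nan)
    return out


def extract_cycle_features(
    series: StressTimeSeries,
    protocol: StrainProtocol,
    G00: float | None = None,
    window: float = G0_WINDOW,
) -> pd.DataFrame:
    """Per-cycle feature table (one row per full cycle).

    When ``G00`` is given, the derived columns ``x_e`` and ``f_e`` are
    filled; otherwise they are NaN.
    """
    spans = segment_cycles(series, protocol)
    rows = []
    for ci, span in enumerate(spans):
        sl = slice(span.start, span.stop + 1)
        g = series.gamma[sl]
        gd = series.gamma_dot[sl]
        s = series.tau[sl]
        i_pk = int(np.argmax(g))
        gamma0 = float(g[i_pk])
        tau0 = float(s[i_pk])
        G0 = estimate_G0(g, gd, s, gamma0, window=window)
        thu, thd, tsu, tsd = stresses_at_fractions(g, gd, s, gamma0)
        rows.append(
            {
                "cycle_index": ci,
                "segment": span.segment,
                "t_start": float(series.t[span.start]),
                "t_end": float(series.t[span.stop]),
                "gamma0": gamma0,
                "tau0": tau0,
                "G0": G0,
                "tau_half_up": thu,
                "tau_half_down": thd,
                "tau_sqrt2_up": tsu,
                "tau_sqrt2_down": tsd,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["t_mid"] = 0.5 * (df["t_start"] + df["t_end"])
        if G00 is not None:
            df["x_e"] = extract_nsp(df["G0"].to_numpy(), G00)
            df["f_e"] = extract_stiffening(
                df["tau0"].to_numpy(),
                df["gamma0"].to_numpy(),
                df["x_e"].to_numpy(),
                G00,
            )
        else:
            df["x_e"] = np.nan
            df["f_e"] = np.nan
    return df


def extract_moduli(
    series: StressTimeSeries,
    protocol: StrainProtocol,
    max_amplitude: float = LINEAR_AMPLITUDE,
) -> list[SAOSRecord]:
    """Storage/loss moduli per cycle of the linear-regime segments.

    The stress of each cycle is projected (least squares) onto the in-phase
    and quadrature components of the drive:  tau ~ gamma0*(G' sin + G'' cos).
    """
    spans = segment_cycles(series, protocol)
    records: list[SAOSRecord] = []
    for span in spans:
        seg = protocol.segments[span.segment]
        if seg.amplitude > max_amplitude or seg.amplitude == 0:
            continue
        sl = slice(span.start, span.stop + 1)
        sin_part = series.gamma[sl] / seg.amplitude
        cos_part = series.gamma_dot[sl] / (seg.amplitude * seg.omega)
        A = np.column_stack([sin_part, cos_part]) * seg.amplitude
        coef, *_ = np.linalg.lstsq(A, series.tau[sl], rcond=None)
        records.append(
            SAOSRecord(
                t=float(0.5 * (series.t[span.start] + series.t[span.stop])),
                G_prime=float(max(coef[0], 0.0)),
                G_double_prime=float(max(coef[1], 0.0)),
                amplitude=seg.amplitude,
                frequency=seg.frequency,
            )
        )
    return records


def saos_to_series(
    records: Sequence[SAOSRecord], samples_per_cycle: int = 100
) -> StressTimeSeries:
    """Reconstruct a strain/stress time series from moduli records.

    Each record is rendered as one full cycle starting at its timestamp:
    gamma = gamma0*sin(omega*t'), tau = gamma0*(G' sin(omega*t') +
    G'' cos(omega*t')).  Records must be spaced at least one period apart.
    """
    ts, gs, gds, taus = [], [], [], []
    for rec in records:
        period = 1.0 / rec.frequency
        t_local = np.linspace(0.0, period, samples_per_cycle, endpoint=False)
        phase = 2.0 * np.pi * rec.frequency * t_local
        g = rec.amplitude * np.sin(phase)
        gd = rec.amplitude * 2.0 * np.pi * rec.frequency * np.cos(phase)
        tau = rec.amplitude * (
            rec.G_prime * np.sin(phase) + rec.G_double_prime * np.cos(phase)
        )
        ts.append(rec.t + t_local)
        gs.append(g)
        gds.append(gd)
        taus.append(tau)
    if not ts:
        return StressTimeSeries(
            t=np.empty(0), gamma=np.empty(0), gamma_dot=np.empty(0), tau=np.empty(0)
        )
    return StressTimeSeries(
        t=np.concatenate(ts),
        gamma=np.concatenate(gs),
        gamma_dot=np.concatenate(gds),
        tau=np.concatenate(taus),
    )
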