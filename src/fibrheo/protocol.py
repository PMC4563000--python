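"""Piecewise-sinusoidal strain schedules for oscillatory shear experiments.

A protocol is an ordered list of segments, each a sinusoid at fixed amplitude
and frequency.  Every segment starts at phase zero, so the strain is
continuous (zero) at segment boundaries while the strain rate may jump when
the amplitude steps.  This mirrors a strain-controlled rheometer switching
amplitude between cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProtocolSegment",
    "StrainProtocol",
    "standard_laos_protocol",
    "LAOS_AMPLITUDES",
]

#: Amplitude ladder of the standard protocol: a 0.01 lead-in (which supplies
#: the linear moduli) followed by six large-amplitude steps.
LAOS_AMPLITUDES: tuple[float, ...] = (0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class ProtocolSegment:
    """One constant-amplitude sinusoidal interval.

    amplitude : strain amplitude gamma_0 [-]
    frequency : oscillation frequency [Hz]  (angular frequency is 2*pi*f)
    duration  : segment length [s]
    label     : free text, e.g. "SAOS-pre", "LAOS-0.25", "SAOS-recovery"
    """

    amplitude: float
    frequency: float
    duration: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude!r}")
        if self.frequency <= 0:
            raise ValueError(f"frequency must be > 0, got {self.frequency!r}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration!r}")

    @property
    def omega(self) -> float:
        """Angular frequency [rad/s]."""
        return 2.0 * np.pi * self.frequency

    def to_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "frequency": self.frequency,
            "duration": self.duration,
            "label": self.label,
        }


@dataclass(frozen=True)
class StrainProtocol:
    """An ordered sequence of sinusoidal segments plus a sampling rate."""

    segments: tuple[ProtocolSegment, ...]
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        fmax = max(s.frequency for s in self.segments)
        if self.sample_rate < 20.0 * fmax:
            raise ValueError(
                f"sample_rate {self.sample_rate} Hz undersamples the fastest "
                f"segment ({fmax} Hz); need >= 20 samples per cycle"
            )

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    @property
    def segment_starts(self) -> np.ndarray:
        """Start time of each segment [s]."""
        durs = np.array([s.duration for s in self.segments])
        return np.concatenate([[0.0], np.cumsum(durs)[:-1]])

    def segment_at(self, t: float) -> tuple[int, float]:
        """Segment index and local time for an absolute time ``t``.

        The right endpoint of the final segment belongs to that segment.
        """
        if t < 0 or t > self.total_duration + 1e-12:
            raise ValueError(
                f"time {t} outside protocol [0, {self.total_duration}]"
            )
        starts = self.segment_starts
        i = int(np.searchsorted(starts, t, side="right") - 1)
        i = min(i, len(self.segments) - 1)
        return i, t - starts[i]

    def strain_at(self, t):
        """Strain and strain rate at time(s) ``t``.

        Within a segment starting at t0 the strain is
        ``gamma = gamma_0*sin(2*pi*f*(t - t0))`` and the strain rate its
        analytic derivative.  Returns a pair of scalars for scalar input, a
        pair of arrays otherwise.
        """
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if t_arr.size and (t_arr.min() < 0 or t_arr.max() > self.total_duration + 1e-9):
            raise ValueError("time outside protocol range")
        starts = self.segment_starts
        idx = np.clip(
            np.searchsorted(starts, t_arr, side="right") - 1,
            0,
            len(self.segments) - 1,
        )
        amp = np.array([s.amplitude for s in self.segments])[idx]
        om = np.array([s.omega for s in self.segments])[idx]
        phase = om * (t_arr - starts[idx])
        gamma = amp * np.sin(phase)
        gamma_dot = amp * om * np.cos(phase)
        if np.isscalar(t) or np.asarray(t).ndim == 0:
            return float(gamma[0]), float(gamma_dot[0])
        return gamma, gamma_dot

    def time_grid(self, dt: float | None = None) -> np.ndarray:
        """Uniform sample times covering the whole protocol (incl. endpoint)."""
        if dt is None:
            dt = 1.0 / self.sample_rate
        n = int(round(self.total_duration / dt))
        return np.arange(n + 1) * dt

    def to_list(self) -> list[dict]:
        return [s.to_dict() for s in self.segments]

    @classmethod
    def from_list(cls, items: list[dict], sample_rate: float = 1000.0) -> "StrainProtocol":
        return cls(
            segments=tuple(ProtocolSegment(**it) for it in items),
            sample_rate=sample_rate,
        )


def standard_laos_protocol(
    include_recovery: bool = False,
    include_second_laos: bool = False,
    frequency: float = 1.0,
    step_duration: float = 60.0,
    recovery_duration: float = 7200.0,
    sample_rate: float = 1000.0,
) -> StrainProtocol:
    """The stepped LAOS schedule used throughout this package.

    At 1 Hz: seven 60 s segments with amplitudes 0.01, 0.05, 0.1, 0.25, 0.5,
    0.75, 1.0 (the 0.01 lead-in probes the linear moduli); optionally a
    7200 s small-amplitude recovery segment at 0.01 and a repeat of the
    ladder.  The lead-in is assumed to last 60 s like the other steps.
    """
    def ladder(tag: str) -> list[ProtocolSegment]:
        return [
            ProtocolSegment(amp, frequency, step_duration, f"{tag}-{amp:g}")
            for amp in LAOS_AMPLITUDES
        ]

    segments = ladder("LAOS")
    if include_recovery:
        segments.append(
            ProtocolSegment(0.01, frequency, recovery_duration, "SAOS-recovery")
        )
    if include_second_laos:
        if not include_recovery:
            raise ValueError("second LAOS sequence requires the recovery segment")
        segments.extend(ladder("LAOS2"))
    return StrainProtocol(segments=tuple(segments), sample_rate=sample_rate)
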