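"""Synthetic rheometer experiments with known ground truth.

Emulates the numerical output of a strain-controlled cone-plate rheometer
running the stepped LAOS protocol: densely sampled strain/stress series for
the oscillatory ladders, per-interval storage/loss moduli for the long
small-amplitude recovery phases (raw small-amplitude samples are too noisy
to be useful on a real instrument, so only moduli are emitted, obtained here
as on the instrument by least-squares projection of the stress onto the
in-phase and quadrature drive components), and the noise-free network-state
trajectory as ground truth.

Noise is additive Gaussian on the stress only (strain is the controlled
variable), with standard deviation ``noise_floor + noise_rel*|tau|`` - an
absolute floor plus a relative term, so the signal-to-noise ratio is worst
at low torque, as in the instrument.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .features import SAOSRecord
from .model import ModelParameters, stress
from .protocol import StrainProtocol, standard_laos_protocol
from .simulate import (
    LINEAR_AMPLITUDE,
    NSPTrajectory,
    StressTimeSeries,
    simulate,
    _is_envelope_segment,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticExperiment",
    "default_truth",
    "generate_experiment",
]


def default_truth() -> ModelParameters:
    """The frozen synthetic ground-truth parameter set.

    G00, k2 and n2 match values reported for fibrin networks polymerized for
    two hours; eta0 is set so the loss modulus is far below the storage
    modulus (the networks are predominantly elastic); the remaining five
    constants are round values chosen once to produce realistic loops: peak
    stresses of order 100 Pa at unit strain amplitude, softening that levels
    off within a 60 s step, and recovery over tens of minutes.
    """
    return ModelParameters(
        G00=11.6,
        eta0=0.1,
        c_d=0.1,
        c_i=1e-3,
        a=1.5,
        b=1.2,
        k1=3.0,
        n1=2.0,
        k2=4.5,
        n2=1.9,
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings: truth, protocol, noise model and seed."""

    true_params: ModelParameters = field(default_factory=default_truth)
    protocol: StrainProtocol = field(
        default_factory=lambda: standard_laos_protocol(
            include_recovery=True, include_second_laos=True
        )
    )
    noise_rel: float = 0.01
    noise_floor: float = 0.005  # Pa
    seed: int = 0
    sample_rate: float = 1000.0
    saos_record_interval: float = 30.0  # s between emitted moduli records
    saos_window_cycles: int = 2

    def __post_init__(self) -> None:
        if self.noise_rel < 0 or self.noise_floor < 0:
            raise ValueError("noise levels must be >= 0")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SyntheticExperiment:
    """One generated experiment.

    ``laos`` holds one noisy series per contiguous oscillatory (densely
    sampled) phase; ``saos`` the moduli records of the slow recovery phases;
    ``nsp_truth`` the noise-free state trajectory over the whole protocol.
    """

    laos: tuple[StressTimeSeries, ...]
    saos: tuple[SAOSRecord, ...]
    nsp_truth: NSPTrajectory
    config: SyntheticConfig

    def fitting_protocol(self) -> StrainProtocol:
        """The protocol up to the end of the first recovery phase (the part
        the staged fit consumes)."""
        segs = []
        for seg in self.config.protocol.segments:
            segs.append(seg)
            if _is_envelope_segment(seg):
                break
        return StrainProtocol(
            segments=tuple(segs), sample_rate=self.config.protocol.sample_rate
        )

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, series in enumerate(self.laos, start=1):
            series.write_csv(out / f"laos_{i}.csv")
        pd.DataFrame(
            [
                {
                    "time_s": r.t,
                    "G_prime_Pa": r.G_prime,
                    "G_double_prime_Pa": r.G_double_prime,
                    "amplitude": r.amplitude,
                    "frequency_Hz": r.frequency,
                }
                for r in self.saos
            ]
        ).to_csv(out / "saos_records.csv", index=False)
        self.nsp_truth.write_csv(out / "nsp_truth.csv")
        sidecar = {
            "true_params": self.config.true_params.to_dict(),
            "noise_rel": self.config.noise_rel,
            "noise_floor": self.config.noise_floor,
            "seed": self.config.seed,
            "protocol": self.config.protocol.to_list(),
        }
        (out / "truth.json").write_text(json.dumps(sidecar, indent=2))


def _noisy(tau: np.ndarray, rng: np.random.Generator, cfg: SyntheticConfig):
    sd = cfg.noise_floor + cfg.noise_rel * np.abs(tau)
    return tau + rng.standard_normal(tau.shape) * sd


def _project_moduli(phase, tau, amplitude):
    A = amplitude * np.column_stack([np.sin(phase), np.cos(phase)])
    coef, *_ = np.linalg.lstsq(A, tau, rcond=None)
    return float(coef[0]), float(coef[1])


def generate_experiment(config: SyntheticConfig | None = None) -> SyntheticExperiment:
    """Simulate the protocol with the true parameters and emit noisy data.

    With zero noise the emitted stresses equal the simulator output bitwise.
    Reproducible: the same config (incl. seed) yields identical data.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    proto = cfg.protocol
    clean = simulate(proto, cfg.true_params, x0=1.0, dt=1.0 / cfg.sample_rate)
    nsp_truth = NSPTrajectory(t=clean.t, x=clean.x)

    laos_series: list[StressTimeSeries] = []
    saos_records: list[SAOSRecord] = []
    # group contiguous non-envelope segments into one dense series
    run_start: float | None = None
    run_end = 0.0

    def flush_run() -> None:
        nonlocal run_start
        if run_start is None:
            return
        m = (clean.t >= run_start - 1e-9) & (clean.t <= run_end + 1e-9)
        laos_series.append(
            StressTimeSeries(
                t=clean.t[m],
                gamma=clean.gamma[m],
                gamma_dot=clean.gamma_dot[m],
                tau=_noisy(clean.tau[m], rng, cfg),
                x=None,
            )
        )
        run_start = None

    for seg, t0 in zip(proto.segments, proto.segment_starts):
        if _is_envelope_segment(seg):
            flush_run()
            # emit moduli records from short noisy windows along the phase
            n_win = int(seg.duration // cfg.saos_record_interval)
            win_dur = cfg.saos_window_cycles / seg.frequency
            n_s = int(round(win_dur * cfg.sample_rate))
            for w in range(n_win):
                t_w = t0 + w * cfg.saos_record_interval
                t_local = np.arange(n_s) / cfg.sample_rate
                phase = seg.omega * ((t_w - t0) + t_local)
                gamma = seg.amplitude * np.sin(phase)
                gamma_dot = seg.amplitude * seg.omega * np.cos(phase)
                x_w = np.interp(t_w + t_local, clean.t, clean.x)
                tau = _noisy(
                    stress(gamma, gamma_dot, x_w, cfg.true_params), rng, cfg
                )
                Gp, Gpp = _project_moduli(phase, tau, seg.amplitude)
                saos_records.append(
                    SAOSRecord(
                        t=t_w + 0.5 * win_dur,
                        G_prime=max(Gp, 0.0),
                        G_double_prime=max(Gpp, 0.0),
                        amplitude=seg.amplitude,
                        frequency=seg.frequency,
                    )
                )
        else:
            if run_start is None:
                run_start = t0
            run_end = t0 + seg.duration
    flush_run()
    return SyntheticExperiment(
        laos=tuple(laos_series),
        saos=tuple(saos_records),
        nsp_truth=nsp_truth,
        config=cfg,
    )
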