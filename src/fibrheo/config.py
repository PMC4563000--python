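"""YAML configuration: model parameters plus deformation protocol.

The file is a flat mapping with two mandatory sections::

    params:            # the ten constitutive constants, SI units
      G00: 11.6
      eta0: 0.1
      c_d: 0.1
      c_i: 0.001
      a: 1.5
      b: 1.2
      k1: 3.0
      n1: 2.0
      k2: 4.5
      n2: 1.9
    protocol:
      sample_rate: 1000.0
      segments:
        - {amplitude: 0.01, frequency: 1.0, duration: 60.0, label: LAOS-0.01}
        # ...

and optional ``x0``, ``noise: {rel, floor}`` and ``seed`` entries used by
the simulation and synthetic-data commands.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .model import ModelParameters
from .protocol import StrainProtocol

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    params: ModelParameters
    protocol: StrainProtocol
    x0: float = 1.0
    noise_rel: float = 0.01
    noise_floor: float = 0.005
    seed: int = 0


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "params" not in raw or "protocol" not in raw:
        raise ValueError("config must contain 'params' and 'protocol' sections")
    params = ModelParameters.from_dict(raw["params"])
    proto_raw = raw["protocol"]
    protocol = StrainProtocol.from_list(
        proto_raw["segments"], sample_rate=float(proto_raw.get("sample_rate", 1000.0))
    )
    noise = raw.get("noise", {})
    return RunConfig(
        params=params,
        protocol=protocol,
        x0=float(raw.get("x0", 1.0)),
        noise_rel=float(noise.get("rel", 0.01)),
        noise_floor=float(noise.get("floor", 0.005)),
        seed=int(raw.get("seed", 0)),
    )


def save_config(cfg: RunConfig, path) -> None:
    doc = {
        "params": cfg.params.to_dict(),
        "protocol": {
            "sample_rate": cfg.protocol.sample_rate,
            "segments": cfg.protocol.to_list(),
        },
        "x0": cfg.x0,
        "noise": {"rel": cfg.noise_rel, "floor": cfg.noise_floor},
        "seed": cfg.seed,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
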