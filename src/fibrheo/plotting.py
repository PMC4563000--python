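"""Lissajous-Bowditch plot export."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .features import segment_cycles
from .protocol import StrainProtocol
from .simulate import StressTimeSeries

__all__ = ["plot_lissajous"]


def plot_lissajous(
    series: StressTimeSeries,
    protocol: StrainProtocol,
    path,
    every: int = 5,
) -> None:
    """Stress-versus-strain loops, one line per plotted cycle.

    ``every`` thins the cycles (plot every n-th) to keep the figure legible.
    """
    spans = segment_cycles(series, protocol)
    fig, ax = plt.subplots(figsize=(5, 4))
    cmap = plt.get_cmap("viridis")
    for j, span in enumerate(spans[::every]):
        sl = slice(span.start, span.stop + 1)
        ax.plot(
            series.gamma[sl],
            series.tau[sl],
            lw=0.7,
            color=cmap(j / max(len(spans[::every]) - 1, 1)),
        )
    ax.set_xlabel("strain [-]")
    ax.set_ylabel("stress [Pa]")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
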