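"""Kaplan-Meier overlay plots for pooled groups."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from .datatypes import IPDSet
from .survival import km_estimate

__all__ = ["km_overlay_plot"]


def km_overlay_plot(groups: Mapping[str, IPDSet], path: str | Path, endpoint: str) -> None:
    """Overlay the pooled KM step curves of several groups in one figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for name, ipd in groups.items():
        km = km_estimate(ipd)
        xs = [0.0, *km.event_times.tolist()]
        ys = [1.0, *km.surv.tolist()]
        ax.step(xs, ys, where="post", label=f"{name} (n={ipd.size})")
    ax.set_xlabel("Time (months)")
    ax.set_ylabel("Survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(f"Pooled Kaplan-Meier curves ({endpoint})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
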