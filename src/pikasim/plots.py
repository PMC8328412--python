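"""Optional sweep plots (requires matplotlib).

Box plots of λ per density group and mean ± min-max bands for parameter
sweeps, written as image files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .experiments import SweepRecord

__all__ = ["plot_density_sweep", "plot_parameter_sweep"]


def _groups(records: list[SweepRecord]) -> dict:
    out: dict = {}
    for r in records:
        out.setdefault(r.value, []).append(r.lam)
    return out


def plot_density_sweep(records: list[SweepRecord], path) -> None:
    """Box plot of λ per (Q_min, Q_max) group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = _groups(records)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.boxplot(list(groups.values()), tick_labels=[str(k) for k in groups])
    ax.set_xlabel("pikas per burrow system (Q_min, Q_max)")
    ax.set_ylabel("lambda (ha)")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)


def plot_parameter_sweep(records: list[SweepRecord], path) -> None:
    """Mean λ with min-max band against the swept parameter value."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = _groups(records)
    xs = sorted(groups)
    mean = [float(np.mean(groups[x])) for x in xs]
    lo = [float(np.min(groups[x])) for x in xs]
    hi = [float(np.max(groups[x])) for x in xs]
    name = records[0].parameter if records else "value"
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.fill_between(xs, lo, hi, alpha=0.3, label="min-max over trials")
    ax.plot(xs, mean, marker="o", label="mean")
    ax.set_xlabel(name)
    ax.set_ylabel("lambda (ha)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
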