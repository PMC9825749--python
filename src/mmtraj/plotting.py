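"""Minimal static rendering of trajectories (data frames are the primary output)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .trajectory import MMIResult, TrajectoryCurve


def plot_trajectory(
    curve: TrajectoryCurve, mmi: MMIResult, path: str | Path, n_grid: int = 200
) -> None:
    """Scatter of per-sample MMI with the fitted curve and its band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.linspace(*curve.t_range, n_grid)
    lo, hi = curve.band(t)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.fill_between(t, lo, hi, alpha=0.2, label=f"{curve.interval_kind} band")
    ax.plot(t, curve(t), lw=2, label="trajectory")
    out = ~mmi.frame["within_interval"]
    ax.scatter(mmi.frame["time"][~out], mmi.frame["mmi"][~out], s=12, label="samples")
    if out.any():
        ax.scatter(mmi.frame["time"][out], mmi.frame["mmi"][out], s=16, marker="x",
                   color="crimson", label="outliers")
    ax.set_xlabel("time")
    ax.set_ylabel("MMI (predicted time)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
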