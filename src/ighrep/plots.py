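"""Optional matplotlib figures for repertoire reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .stats import Cdr3Distribution

__all__ = ["plot_cdr3_histogram", "plot_usage"]


def plot_cdr3_histogram(dist: Cdr3Distribution, path: str | Path) -> None:
    """CDR3 length histogram with the fitted Gaussian overlaid (if any)."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    xs = dist.lengths.index.to_numpy()
    ax.bar(xs, dist.lengths.to_numpy(), width=min(2.4, 0.8 * (xs[1] - xs[0])
           if len(xs) > 1 else 1.0), color="#4477aa", label="observed")
    if dist.fitted:
        import numpy as np
        grid = np.linspace(xs.min(), xs.max(), 200)
        ax.plot(grid, dist.amplitude
                * np.exp(-((grid - dist.mean) ** 2) / (2 * dist.sd ** 2)),
                color="#cc3311",
                label=f"Gaussian fit (R$^2$={dist.r_squared:.2f})")
    ax.set_xlabel("CDR3 length (nt)")
    ax.set_ylabel("sequences")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_usage(usage_table, segment_type: str, path: str | Path) -> None:
    """Bar chart of family/gene usage frequencies for one segment type."""
    sub = usage_table[usage_table.segment_type == segment_type]
    fig, ax = plt.subplots(figsize=(max(3.0, 0.5 * len(sub)), 3.2))
    ax.bar(sub["category"], 100 * sub["frequency"], color="#4477aa")
    ax.set_ylabel("% of sequences")
    ax.set_title(f"{segment_type} usage")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
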