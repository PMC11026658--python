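"""Figure helpers: recovery scatter plots and correlation heatmaps."""

from __future__ import annotations

import numpy as np

__all__ = ["recovery_scatter", "correlation_heatmap"]


def recovery_scatter(result, param: str = "alpha", run: int = 0, path=None):
    """Scatter of simulated vs recovered values for one recovery run."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rec = result.runs[run]
    sim, est = rec[f"{param}_sim"], rec[f"{param}_rec"]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(sim, est, s=8, alpha=0.5)
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.set_xlabel(f"simulated {param}")
    ax.set_ylabel(f"recovered {param}")
    ax.set_title(
        f"{result.model_id}, noise={result.noise_param:g}, "
        f"r={rec[f'r_{param}']:.3f}"
    )
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def correlation_heatmap(rho, p=None, path=None):
    """Heatmap of a (Spearman) correlation matrix, p-values annotated."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = np.asarray(rho, dtype=float)
    labels = list(rho.columns)
    fig, ax = plt.subplots(figsize=(0.6 * len(labels) + 2,) * 2)
    im = ax.imshow(vals, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    for i in range(len(labels)):
        for j in range(len(labels)):
            if not np.isfinite(vals[i, j]):
                continue
            txt = f"{vals[i, j]:.2f}"
            if p is not None and i != j:
                txt += f"\n({np.asarray(p)[i, j]:.2g})"
            ax.text(j, i, txt, ha="center", va="center", fontsize=5)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
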