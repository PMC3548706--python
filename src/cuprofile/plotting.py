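"""Diagnostic heatmap of an optimized profile (requires matplotlib)."""

from __future__ import annotations

from .clustering import OptimizedProfile

__all__ = ["plot_profile_heatmap"]


def plot_profile_heatmap(opt: OptimizedProfile, path=None, ax=None):
    """Render the optimized interval matrix as a grayscale heatmap.

    Rows and columns follow the optimized orders; cell shade encodes the
    11 discretisation levels.  Returns the matplotlib Axes.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    data = opt.ordered_intervals()
    if ax is None:
        _, ax = plt.subplots(
            figsize=(0.45 * len(opt.col_order) + 2, 0.22 * len(opt.row_order) + 1.5)
        )
    ax.imshow(data.to_numpy(), cmap="Greys", vmin=0, vmax=10, aspect="auto")
    ax.set_xticks(range(len(opt.col_order)), opt.col_order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(opt.row_order)), opt.row_order, fontsize=6)
    ax.set_xlabel("seed protein")
    ax.set_ylabel("genus")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
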