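"""Diagnostic plots: kappa-error diagrams and PCoA scatters (SVG/PNG)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["kappa_error_diagram", "pcoa_scatter"]


def kappa_error_diagram(points, path: str, title: str = "Kappa-error diagram") -> None:
    """Scatter of tree-pair mean error (y) against Cohen's kappa (x)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(
        [p.kappa for p in points],
        [p.mean_pair_error for p in points],
        s=12, alpha=0.6, edgecolors="none",
    )
    ax.set_xlabel("Cohen's kappa (pairwise agreement)")
    ax.set_ylabel("Mean pair error")
    ax.set_xlim(-1.05, 1.05)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def pcoa_scatter(result, labels, path: str, title: str = "PCoA of decision space") -> None:
    """First two principal coordinates, colored by class."""
    labels = np.asarray(labels)
    coords = result.coordinates
    ratios = result.explained_variance_ratio
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls in np.unique(labels):
        m = labels == cls
        y = coords[m, 1] if coords.shape[1] > 1 else np.zeros(m.sum())
        ax.scatter(coords[m, 0], y, s=18, alpha=0.75, label=str(cls))
    ax.set_xlabel(f"PCo1 ({100 * ratios[0]:.1f}%)")
    if coords.shape[1] > 1:
        ax.set_ylabel(f"PCo2 ({100 * ratios[1]:.1f}%)")
    ax.legend(frameon=False)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
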