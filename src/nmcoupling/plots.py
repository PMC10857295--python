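"""Simple heatmap exports for FNC and NMC grids (matplotlib optional)."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def save_heatmap(mat, path, title: str = "", labels=None) -> Path:
    """Save a square matrix or NMC grid as a PNG heatmap.

    matplotlib is imported lazily so the analysis core has no hard
    plotting dependency.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = np.asarray(mat, dtype=float)
    vmax = np.nanmax(np.abs(mat)) or 1.0
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    fig.colorbar(im, ax=ax)
    if title:
        ax.set_title(title)
    if labels is not None and len(labels) <= 30:
        ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
        ax.set_yticks(range(len(labels)), labels, fontsize=6)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
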