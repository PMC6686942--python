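"""Optional track plots: log2(F/M) ratio per scaffold and the painting heat grid.

Matplotlib is imported lazily so the core pipeline has no plotting
dependency at import time.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .sexscan import RatioTrack
from .synteny_paint import NO_LABEL, PaintingMatrix, window_dominant_labels


def plot_ratio_track(ratio: RatioTrack, path: str | Path, min_length: int = 0) -> None:
    """Per-scaffold log2(F/M) window ratios, scaffolds ordered longest first.

    ``min_length`` reproduces the classic display filter (e.g. scaffolds
    > 1 Mb only); it affects plotting only, never calling.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = ratio.grid
    scaffolds = [s for s in grid.scaffolds if grid.scaffold_lengths[s] >= min_length]
    scaffolds.sort(key=lambda s: -grid.scaffold_lengths[s])
    fig, axes = plt.subplots(
        1, max(len(scaffolds), 1), figsize=(2 + 1.2 * len(scaffolds), 3),
        sharey=True, squeeze=False,
    )
    for ax, name in zip(axes[0], scaffolds):
        sl = grid.scaffold_slice(name)
        vals = ratio.log2_ratio[sl]
        pos = grid.window_starts()[sl] / 1e6
        ax.axhline(0, color="0.8", lw=0.8)
        ax.axhline(1, color="0.8", lw=0.8, ls="--")
        ax.plot(pos, vals, ".", ms=3)
        ax.set_title(name, fontsize=8)
        ax.set_xlabel("Mb", fontsize=7)
    axes[0][0].set_ylabel("log2(F/M)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_painting(matrix: PaintingMatrix, path: str | Path,
                  min_window_fraction: float = 0.5) -> None:
    """Heat-grid of dominant reference chromosome per window.

    One row per scaffold, one cell per window, colored by the dominant
    reference chromosome; windows with no synteny are drawn red.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import colors as mcolors
    from matplotlib.patches import Patch

    grid = matrix.grid
    dominant = window_dominant_labels(matrix, min_window_fraction)
    labels = list(matrix.labels)
    palette = plt.get_cmap("tab10")
    color_of = {lab: palette(i % 10) for i, lab in enumerate(labels)}
    color_of[NO_LABEL] = mcolors.to_rgba("red")

    max_windows = max(grid.n_windows_of(s) for s in grid.scaffolds)
    img = np.ones((len(grid.scaffolds), max_windows, 4))
    for i, name in enumerate(grid.scaffolds):
        sl = grid.scaffold_slice(name)
        for j, lab in enumerate(dominant[sl]):
            img[i, j] = color_of[lab]
        img[i, grid.n_windows_of(name):] = (1, 1, 1, 0)

    fig, ax = plt.subplots(figsize=(8, 0.5 * len(grid.scaffolds) + 1))
    ax.imshow(img, aspect="auto", interpolation="nearest")
    ax.set_yticks(range(len(grid.scaffolds)), grid.scaffolds, fontsize=7)
    ax.set_xlabel(f"{grid.window_size // 1000}-kb window index")
    handles = [Patch(color=color_of[l], label=l) for l in labels]
    handles.append(Patch(color=color_of[NO_LABEL], label="no synteny"))
    ax.legend(handles=handles, fontsize=6, loc="upper right", ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
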