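"""Simple renderers for aggregate profiles and single-read matrices."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .profile_agg import AggregateProfile  # noqa: E402
from .single_read import ReadMatrix  # noqa: E402


def plot_profiles(profiles: dict[str, AggregateProfile], out_path,
                  title: str | None = None):
    """Overlay labeled aggregate profiles (fraction vs offset) to a file."""
    fig, ax = plt.subplots(figsize=(7, 3.2))
    for label, prof in profiles.items():
        ax.plot(prof.offsets, np.clip(prof.frac, 0, None), lw=1.2,
                label=label)
    ax.set_xlabel("offset from motif center (bp)")
    ax.set_ylabel("methylated fraction")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def plot_read_matrix(matrix: ReadMatrix, out_path, title: str | None = None):
    """Raster of a single-read matrix: methylated dark, no-call light."""
    fig, ax = plt.subplots(figsize=(7, 4))
    img = matrix.cells.astype(float)
    img[img < 0] = np.nan  # no-call rendered as background
    ax.imshow(img, aspect="auto", interpolation="nearest", cmap="Greys",
              vmin=0, vmax=1,
              extent=(matrix.offsets[0], matrix.offsets[-1],
                      len(matrix), 0))
    ax.set_xlabel("offset from motif center (bp)")
    ax.set_ylabel("reads (sorted)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
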