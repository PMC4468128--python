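"""Minimal LOD-profile plotting helper."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_profile(profile, path, threshold: float | None = None):
    """Save a genome-wide LOD profile with chromosome panels side by side."""
    chroms = list(dict.fromkeys(profile.chrom))
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(3 * len(chroms), 3), sharey=True, squeeze=False
    )
    for ax, cid in zip(axes[0], chroms):
        sel = profile.chrom == cid
        ax.plot(profile.pos[sel], profile.lod[sel], lw=1.2)
        if threshold is not None:
            ax.axhline(threshold, ls="--", c="grey", lw=0.8)
        ax.set_title(str(cid))
        ax.set_xlabel("cM")
    axes[0][0].set_ylabel("LOD")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
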