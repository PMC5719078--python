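"""Diagnostic plots: consensus heatmaps and PAC/CDF curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .consensus import ConsensusResult, consensus_cdf


def consensus_heatmap(result: ConsensusResult, k: int, path: str | Path) -> None:
    """Consensus matrix at *k*, samples ordered by assignment."""
    order = np.argsort(result.assignments[k], kind="stable")
    M = result.matrices[k][np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(M, cmap="Blues", vmin=0, vmax=1, interpolation="nearest")
    ax.set_title(f"consensus matrix, k={k}")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.8, label="co-clustering frequency")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def consensus_cdf_plot(result: ConsensusResult, path: str | Path) -> None:
    """Empirical CDFs of consensus entries for every k, for manual k selection."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for k in sorted(result.matrices):
        cdf = consensus_cdf(result, k)
        ax.plot(cdf["consensus"], cdf["cdf"], label=f"k={k} (PAC {result.pac[k]:.2f})")
    ax.set_xlabel("consensus index")
    ax.set_ylabel("CDF")
    ax.legend(fontsize=7)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
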