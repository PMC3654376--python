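"""2-D visualization of coherence matrices and networks."""

from __future__ import annotations

import numpy as np

from .spectral import CoherenceResult

__all__ = ["plot_coherence_heatmap"]


def plot_coherence_heatmap(result: CoherenceResult, band: str, ax=None,
                           cmap: str = "RdYlBu_r"):
    """Heatmap of one band's parcel x parcel coherence.

    Parcels are ordered right hemisphere first, so intra-right pairs fill
    the upper-left quadrant; a separator line marks the hemisphere
    boundary.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    b = result.band_names.index(band)
    M = result.per_band[:, :, b]
    im = ax.imshow(M, vmin=0, vmax=1, cmap=cmap, interpolation="nearest")
    n_right = sum(1 for p in result.parcels if p.endswith("_R")
                  or p.endswith("right"))
    if 0 < n_right < len(result.parcels):
        ax.axhline(n_right - 0.5, color="k", lw=0.8)
        ax.axvline(n_right - 0.5, color="k", lw=0.8)
    step = max(1, len(result.parcels) // 20)
    ticks = np.arange(0, len(result.parcels), step)
    ax.set_xticks(ticks)
    ax.set_xticklabels([result.parcels[i] for i in ticks], rotation=90,
                       fontsize=6)
    ax.set_yticks(ticks)
    ax.set_yticklabels([result.parcels[i] for i in ticks], fontsize=6)
    ax.set_title(f"{band} coherence ({result.n_epochs} epochs)")
    ax.figure.colorbar(im, ax=ax, label="coherence")
    return ax
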