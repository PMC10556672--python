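"""Plain plotting helpers (violin of LD volumes, distance-vs-volume map)."""

from __future__ import annotations

import numpy as np


def violin_ld_volumes(metrics, ax=None, by="timepoint"):
    """Violin plot of per-cell total LD volume, grouped by ``by``.

    Volumes are shown on a cube-root scale, which keeps the small basal
    population visible next to the large starvation LDs.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    groups = list(dict.fromkeys(metrics[by]))
    data = [np.cbrt(metrics.loc[metrics[by] == g,
                                "total_ld_volume_um3"].to_numpy())
            for g in groups]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(groups) + 1), groups)
    ax.set_ylabel(r"total LD volume$^{1/3}$ ($\mu$m)")
    return ax


def distance_volume_map(volumes_um3, distances_um, ax=None):
    """Scatter of LD-plastid distance against cube-root LD volume."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(np.cbrt(volumes_um3), distances_um, s=8, alpha=0.5)
    ax.axhline(5.0, ls="--", c="grey", lw=1)
    ax.set_xlabel(r"LD volume$^{1/3}$ ($\mu$m)")
    ax.set_ylabel(r"LD-plastid distance ($\mu$m)")
    return ax
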