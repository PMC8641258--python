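"""QC scatter plot: log10 UMI count against nuclear fraction, by status."""

from __future__ import annotations

import numpy as np

STATUS_COLORS = {
    "cell": "#4477aa",
    "empty_droplet": "#ee6677",
    "damaged_cell": "#ccbb44",
    "unassigned": "#bbbbbb",
}


def qc_scatter(table, ax=None, cutoff: float | None = None):
    """Scatter of log10(UMI) vs NF colored by qc_status.

    Returns the matplotlib Axes; imports matplotlib lazily so headless
    counting runs never touch a display backend.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    sub = table[table["nuclear_fraction"].notna() & (table["umi_count"] > 0)]
    for status, color in STATUS_COLORS.items():
        grp = sub[sub["qc_status"] == status]
        if len(grp):
            ax.scatter(grp["nuclear_fraction"], np.log10(grp["umi_count"]),
                       s=6, alpha=0.5, color=color, label=status, linewidths=0)
    if cutoff is not None:
        ax.axvline(cutoff, color="black", linestyle="--", linewidth=1)
    ax.set_xlabel("nuclear fraction")
    ax.set_ylabel("log10 UMI count")
    ax.set_xlim(0, 1)
    ax.legend(frameon=False, markerscale=2)
    return ax
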