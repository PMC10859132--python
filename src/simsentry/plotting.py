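"""Optional rendering of the diagnostic data sets.

The CSV/DataFrame contracts in :mod:`simsentry.diagnostics` are normative;
these matplotlib wrappers are convenience layers and nothing tests their
pixels.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_scatter", "plot_zip"]


def plot_scatter(scatter: dict, ax=None):
    """SE estimate against point estimate, one marker set per dgm x method."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for (dgm, method), pts in scatter.items():
        ax.scatter(pts["estimate"], pts["se"], s=8, alpha=0.5, label=f"{dgm}/{method}")
    ax.set_xlabel("point estimate (log odds ratio)")
    ax.set_ylabel("standard error estimate")
    ax.legend(fontsize="small")
    return ax


def plot_zip(zip_rows: pd.DataFrame, theta: float = 0.0, ax=None):
    """Zip plot: CIs stacked by p-value rank, non-covering intervals in red."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for _, row in zip_rows.iterrows():
        color = "tab:blue" if row["covers"] else "tab:red"
        ax.plot(
            [row["ci_low"], row["ci_high"]],
            [row["rank_fraction"]] * 2,
            color=color,
            lw=0.5,
            alpha=0.7,
        )
    ax.axvline(theta, color="black", lw=1)
    ax.set_xlabel("95% confidence interval")
    ax.set_ylabel("rank fraction of p-value")
    return ax
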