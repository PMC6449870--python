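"""Optional figures (requires matplotlib)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def cluster_heatmap(profiles: pd.DataFrame, assignment, feature_order,
                    path: str) -> None:
    """Row-clustered, column-ordered heatmap of feature Z-scores."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = assignment.labels.sort_values().index
    data = profiles.loc[order, feature_order]
    fig, ax = plt.subplots(figsize=(8, 10))
    vmax = np.nanpercentile(np.abs(data.values), 98)
    im = ax.imshow(data.values, aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(feature_order)))
    ax.set_xticklabels(feature_order, rotation=90, fontsize=5)
    ax.set_yticks([])
    ax.set_ylabel(f"knockdowns (k={assignment.k} clusters)")
    fig.colorbar(im, ax=ax, label="mean feature Z score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def projection_scatter(coords: pd.DataFrame, samples: pd.DataFrame,
                       model, path: str) -> None:
    """Rotated embedding with the fitted time curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    day = samples.set_index("sample")["day"].reindex(coords.index)
    is_tc = day.notna()
    fig, ax = plt.subplots(figsize=(7, 6))
    ax.scatter(coords.loc[is_tc, "x"], coords.loc[is_tc, "y"],
               c=day[is_tc], cmap="viridis", label="time course", s=30)
    ax.scatter(coords.loc[~is_tc, "x"], coords.loc[~is_tc, "y"],
               c="black", marker="x", label="knockdowns", s=25)
    xs = np.linspace(*model.domain, 200)
    ax.plot(xs, model.curve(xs), "r-", lw=1.5, label="fitted time curve")
    ax.set_xlabel("x (pseudotime proxy)")
    ax.set_ylabel("y")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
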