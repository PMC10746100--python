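"""Optional matplotlib views of the fitted model and the decision rule.

Imported lazily so the core pipeline has no hard matplotlib dependency.
"""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_marginals(marginals, ax=None):
    """Predicted %BMIL (+-1.96 SE band) per diet across the score grid."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    g = marginals.grid
    for pred, se, label, color in (
        (marginals.pred_mhp, marginals.se_mhp, "MHP", "tab:blue"),
        (marginals.pred_lf, marginals.se_lf, "LF", "tab:red"),
    ):
        ax.plot(g, pred, color=color, label=label)
        ax.fill_between(g, pred - 1.96 * se, pred + 1.96 * se, color=color, alpha=0.2)
    ax.set_xlabel("total methylation score")
    ax.set_ylabel("predicted %BMIL")
    ax.legend(title="diet")
    return ax


def plot_decision(recs, alpha: float = 0.05, ax=None):
    """Z-test p-value against the total score; the horizontal line marks alpha."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    colors = {"MHP": "tab:blue", "LF": "tab:red", "either": "tab:gray"}
    for cat, sub in recs.groupby("category"):
        ax.scatter(sub["total"], sub["p"], s=12, color=colors.get(cat, "k"), label=cat)
    ax.axhline(alpha, color="k", linestyle="--", linewidth=0.8)
    ax.set_xlabel("total methylation score")
    ax.set_ylabel("Z-test p-value")
    ax.legend(title="recommendation")
    return ax


def plot_score_histogram(recs, bins: int = 20, ax=None):
    """Distribution of total scores, shaded by recommendation category."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    edges = np.histogram_bin_edges(recs["total"], bins=bins)
    colors = {"MHP": "tab:blue", "LF": "tab:red", "either": "tab:gray"}
    bottom = np.zeros(len(edges) - 1)
    for cat in ("either", "MHP", "LF"):
        counts, _ = np.histogram(recs.loc[recs["category"] == cat, "total"], bins=edges)
        ax.bar(
            edges[:-1], counts, width=np.diff(edges), align="edge",
            bottom=bottom, color=colors[cat], label=cat, edgecolor="white",
        )
        bottom += counts
    ax.set_xlabel("total methylation score")
    ax.set_ylabel("participants")
    ax.legend(title="recommendation")
    return ax
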