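"""Optional figure rendering: Bland-Altman plots, imputation convergence
traces, and prevalence comparisons with error bars.

All functions take an output path and write PNG or SVG (by extension);
they return the Matplotlib figure for further tweaking.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import validity  # noqa: E402


def bland_altman_plot(self_vals, meas_vals, out_path=None, weights=None, title=None):
    """Scatter of difference vs pair mean with the mean line (solid) and the
    1.96-SD limits of agreement (dashed)."""
    rep = validity.bland_altman(self_vals, meas_vals, weights=weights)
    a = np.asarray(self_vals, dtype=float)
    b = np.asarray(meas_vals, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter((a + b) / 2, a - b, s=8, alpha=0.4, edgecolors="none")
    ax.axhline(rep.mean_diff, color="black")
    for y in (rep.loa_lower, rep.loa_upper):
        ax.axhline(y, color="black", linestyle="--")
    ax.set_xlabel("mean of self-reported and measured")
    ax.set_ylabel("self-reported − measured")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def trace_plot(trace, out_path=None):
    """Mean and SD of the imputed values per iteration, one line per chain."""
    variables = sorted(trace["variable"].unique())
    fig, axes = plt.subplots(
        len(variables), 2, figsize=(8, 2.2 * len(variables)), squeeze=False
    )
    for i, var in enumerate(variables):
        sub = trace[trace["variable"] == var]
        for stat, ax in zip(("mean", "sd"), axes[i]):
            for _, chain in sub.groupby("chain"):
                ax.plot(chain["iteration"], chain[stat], lw=0.8)
            ax.set_title(f"{var} — {stat}", fontsize=9)
            ax.set_xlabel("iteration", fontsize=8)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def prevalence_bar_plot(table, out_path=None, se_suffix="_se"):
    """Grouped bars of prevalence per indicator and method, with one-SD
    error bars.  ``table`` needs an ``indicator`` column; every other
    column pair (<method>, <method>_se) becomes a bar group."""
    methods = [
        c for c in table.columns
        if c != "indicator" and not c.endswith(se_suffix)
    ]
    indicators_ = table["indicator"].tolist()
    x = np.arange(len(indicators_))
    width = 0.8 / max(len(methods), 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    for j, m in enumerate(methods):
        err = table[m + se_suffix] if m + se_suffix in table.columns else None
        ax.bar(x + j * width, table[m], width=width, label=m, yerr=err, capsize=2)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(indicators_, rotation=20, ha="right", fontsize=8)
    ax.set_ylabel("prevalence")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
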