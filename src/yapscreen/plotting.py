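"""Diagnostic plots for screens and fitted shape models."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_yap_diff_vs_cell_number(summaries: pd.DataFrame, k_sd: float = 2.0, ax=None):
    """Scatter of well-mean yap_diff against cell count.

    Control wells as blue circles, treatment wells as red crosses, with
    dashed lines at +/- k_sd SD of the control well means — the screen's
    hit threshold.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ctrl = summaries.loc[summaries["is_control"]]
    treat = summaries.loc[~summaries["is_control"]]
    ax.scatter(ctrl["n_cells"], ctrl["mean_yap_diff"], s=18,
               facecolors="none", edgecolors="tab:blue", label="control wells")
    ax.scatter(treat["n_cells"], treat["mean_yap_diff"], s=22, marker="x",
               color="tab:red", label="treatment wells")
    thr = k_sd * ctrl["mean_yap_diff"].std(ddof=1)
    for y in (thr, -thr):
        ax.axhline(y, ls="--", lw=0.8, color="gray")
    ax.set_xlabel("cells per well")
    ax.set_ylabel("mean YAP$_{diff}$ (log10)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_coefficients(results, ax=None):
    """Standardized betas of a fitted shape model as a bar chart."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    feats = list(results.feature_order)
    betas = [results.standardized_betas.get(f, np.nan) for f in feats]
    ax.bar(feats, betas, color=["tab:red" if b < 0 else "tab:blue" for b in betas])
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel(r"standardized $\beta$")
    ax.set_title(f"shape model (R$^2$={results.r_squared:.3f})")
    return ax
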