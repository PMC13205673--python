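"""Bland-Altman and Q-Q plots for migration difference data."""

from __future__ import annotations

import numpy as np

from .evaluate import BlandAltmanResult, qq_data


def plot_bland_altman(result: BlandAltmanResult, axis_label: str = "x", ax=None):
    """Bland-Altman plot: true migration on the abscissa, truth - measured on
    the ordinate, with the mean difference and limits of agreement drawn with
    their 95% confidence bands."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.abscissa, result.diffs, s=12, alpha=0.6, edgecolors="none")
    ax.axhline(result.mean_diff, color="tab:blue", ls=":", label=f"mean {result.mean_diff:.3f}")
    for lo in (result.loa_low, result.loa_high):
        ax.axhline(lo, color="tab:orange", ls=":")
    for ci in (result.ci_mean, result.ci_loa_low, result.ci_loa_high):
        ax.axhspan(ci[0], ci[1], color="grey", alpha=0.15)
    ax.set_xlabel(f"true {axis_label}-migration (mm)")
    ax.set_ylabel("truth - measured (mm)")
    ax.legend(loc="best", fontsize=8)
    return ax


def plot_qq(diffs, ax=None):
    """Q-Q plot of the differences against a fitted normal."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    theo, sample = qq_data(diffs)
    ax.scatter(theo, sample, s=10, alpha=0.7, edgecolors="none")
    lim = [min(theo.min(), sample.min()), max(theo.max(), sample.max())]
    ax.plot(lim, lim, color="k", lw=0.8)
    ax.set_xlabel("theoretical quantiles")
    ax.set_ylabel("ordered differences")
    return ax
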