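"""Matplotlib figures: L(d) envelope plots and response-function bars."""

from __future__ import annotations

import numpy as np

from .climate import ResponseFunctionResult
from .spatial import KFunctionResult

__all__ = ["plot_l_function", "plot_response_function"]


def plot_l_function(result: KFunctionResult, ax=None, title: str = ""):
    """Observed L(d) with the Monte Carlo envelope, if present."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(result.distances, result.l, color="crimson", lw=1.5, label="L(d)")
    if result.envelope_low is not None:
        ax.plot(result.distances, result.envelope_low, "k:", lw=1, label="envelope")
        ax.plot(result.distances, result.envelope_high, "k:", lw=1)
    ax.axhline(0.0, color="grey", lw=0.6)
    ax.set_xlabel("distance d (m)")
    ax.set_ylabel("L(d) (m)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_response_function(result: ResponseFunctionResult, ax=None, title: str = ""):
    """Bootstrap coefficient bars with the |mean/sd| = 1.96 significance cut."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    tab = result.coefficients
    x = np.arange(len(tab))
    colors = np.where(tab["significant"], "firebrick", "lightsteelblue")
    ax.bar(x, tab["mean_coef"], yerr=1.96 * tab["sd_coef"], color=colors,
           error_kw={"lw": 0.6}, width=0.8)
    ax.axhline(0.0, color="k", lw=0.6)
    ax.set_xticks(x)
    ax.set_xticklabels(tab.index, rotation=90, fontsize=7)
    ax.set_ylabel("standardized coefficient")
    label = f"R_V = {result.r_v:.2f}, r/s = {result.r_over_s:.2f} ({result.p_band})"
    ax.set_title(f"{title}  {label}".strip())
    return ax
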