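"""Recovery-curve plots in the style of FRAP figure panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .frap import MeanTrace, TwoStateFit


def plot_recovery(
    mean_trace: MeanTrace,
    fit: TwoStateFit | None = None,
    title: str = "",
    path: str | Path | None = None,
):
    """Mean recovery +/- SE with the fitted curve and the 130 s marker."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    t, g, se = mean_trace.t_s, mean_trace.g_mean, mean_trace.g_se
    ax.errorbar(t, g, yerr=None if np.all(np.isnan(se)) else se,
                fmt="o", ms=3, lw=1, capsize=2, label=f"mean of {mean_trace.n_cells} cells")
    if fit is not None and np.isfinite(fit.c_eq1):
        tt = np.linspace(t[0], t[-1], 200)
        ax.plot(tt, fit.predict(tt), "-", label="two-binding-state fit")
    ax.axvline(130.0, ls="--", lw=0.8, color="gray")
    ax.set_xlabel("time post-bleach (s)")
    ax.set_ylabel("recovery fraction g(t)")
    ax.set_ylim(bottom=min(0.0, float(np.nanmin(g))))
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
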