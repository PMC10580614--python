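"""Simple lag-response figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .inference import FitResult, single_lag_effect

__all__ = ["plot_lag_response"]


def plot_lag_response(fit: FitResult, title: str = "", scale: float = 10.0):
    """Percent increase (with 95% CI) per single lag day 0..6."""
    effs = [single_lag_effect(fit, l, scale=scale) for l in range(7)]
    lags = list(range(7))
    pct = [e.percent for e in effs]
    lo = [e.ci_low for e in effs]
    hi = [e.ci_high for e in effs]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.errorbar(
        lags, pct,
        yerr=[[p - l for p, l in zip(pct, lo)], [h - p for p, h in zip(pct, hi)]],
        fmt="o-", capsize=3,
    )
    ax.set_xlabel("lag (days)")
    ax.set_ylabel(f"% increase per {scale:g} µg/m³")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig
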