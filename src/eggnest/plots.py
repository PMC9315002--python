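"""Plot helpers for the two standard displays.

* per-category boxplots of PGLS partial residuals with compact letter
  labels (the multiple-comparison display), and
* per-group spline curves of C number against node depth (median with
  5th/95th-percentile envelope), optionally back-transformed from
  log10 for display.
"""

from __future__ import annotations

import numpy as np

from .nests import RISK_ORDER
from .pgls import PGLSResults

__all__ = ["plot_partial_residuals", "plot_trend_curves"]


def plot_partial_residuals(fit: PGLSResults, character: str, categories,
                           letters: dict[str, str] | None = None, ax=None):
    """Boxplots of the fitted model's partial residuals for one nest
    character, one box per category in risk order, letters on top."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.6 * len(set(categories)) + 1, 4))
    pr = fit.partial_residuals(character)
    cats = np.asarray(categories)
    levels = [lv for lv in RISK_ORDER.get(character, sorted(set(cats)))
              if lv in set(cats)]
    data = [pr[cats == lv] for lv in levels]
    ax.boxplot(data, tick_labels=levels)
    if letters:
        top = max(d.max() for d in data if len(d))
        for i, lv in enumerate(levels, start=1):
            ax.text(i, top * 1.02 if top > 0 else top * 0.98,
                    letters.get(lv, ""), ha="center", va="bottom")
    ax.set_xlabel(character)
    ax.set_ylabel("partial residual (log10 C)")
    return ax


def plot_trend_curves(curves: dict, ax=None, back_transform: bool = False,
                      colors: dict | None = None):
    """Median and 5th/95th-percentile spline curves per group, as
    produced by :func:`eggnest.trend.spline_trend`."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    tf = (lambda y: 10.0 ** y) if back_transform else (lambda y: y)
    for group, cur in curves.items():
        color = (colors or {}).get(group)
        qs = sorted(q for q in cur if q != "depth")
        mid = qs[len(qs) // 2]
        line, = ax.plot(cur["depth"], tf(cur[mid]), label=str(group),
                        color=color)
        for q in qs:
            if q != mid:
                ax.plot(cur["depth"], tf(cur[q]), linestyle="--",
                        linewidth=0.8, color=line.get_color())
    ax.set_xlabel("node depth")
    ax.set_ylabel("C number" if back_transform else "log10 C")
    ax.legend()
    return ax
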