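"""Quantile-regression trends of C number over evolutionary time.

Tips (extant species) and internal nodes (ancestral reconstructions) are
pooled into one table of log10 C values against node depth (summed branch
length from the root, i.e. elapsed evolutionary time), with a passerine
indicator and its interaction with depth. The conditional quantile
(default: the median) is fitted by minimising the check loss, with
bootstrap standard errors; locally fitted polynomial splines through
running quantiles visualise the non-linear trend per group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_interp_spline
from statsmodels.regression.quantile_regression import QuantReg

from .ancestral import AncestralEstimates
from .trees import Phylogeny

__all__ = ["TrendFit", "QuantileTrend", "pooled_trend_table", "spline_trend"]


@dataclass
class TrendFit:
    """Quantile-regression fit with bootstrap uncertainty."""

    tau: float
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    nobs: int
    n_boot: int
    objective: float          # sum of check losses at the solution

    def summary(self) -> str:
        lines = [f"Quantile regression (tau={self.tau}), n={self.nobs}, "
                 f"{self.n_boot} bootstrap replicates",
                 f"{'':<24}{'coef':>10}{'boot SE':>10}"
                 f"{'2.5%':>10}{'97.5%':>10}"]
        for k in self.params.index:
            lines.append(f"{k:<24}{self.params[k]:>10.4f}{self.bse[k]:>10.4f}"
                         f"{self.conf_int.loc[k, 'lower']:>10.4f}"
                         f"{self.conf_int.loc[k, 'upper']:>10.4f}")
        return "\n".join(lines)


def check_loss(resid: np.ndarray, tau: float) -> float:
    """Sum of the asymmetric absolute (check) loss."""
    r = np.asarray(resid, dtype=float)
    return float(np.sum(r * (tau - (r < 0))))


class QuantileTrend:
    """Trend model: value ~ depth (+ passerine + depth:passerine).

    Parameters
    ----------
    values, depths : aligned 1-d arrays (tips and nodes pooled)
    passerine : optional boolean array; when given, the model includes the
        passerine offset and its interaction with depth.
    """

    def __init__(self, values, depths, passerine=None):
        values = np.asarray(values, dtype=float)
        depths = np.asarray(depths, dtype=float)
        if values.shape != depths.shape or values.ndim != 1:
            raise ValueError("values and depths must be matching 1-d arrays")
        if len(values) <= 4:
            raise ValueError("need more than 4 observations")
        if not np.all(np.isfinite(depths)):
            raise ValueError("depths must be finite")
        if np.ptp(depths) == 0:
            raise ValueError("degenerate design: constant depth")
        cols = {"Intercept": np.ones_like(depths), "depth": depths}
        if passerine is not None:
            p = np.asarray(passerine).astype(float)
            cols["passerine"] = p
            cols["depth:passerine"] = depths * p
        self.exog = pd.DataFrame(cols)
        self.endog = values

    def _point_fit(self, y: np.ndarray, X: pd.DataFrame, tau: float) -> np.ndarray:
        with warnings.catch_warnings():
            # exact fits and degenerate bootstrap resamples trip harmless
            # iteration / sparsity warnings inside the IRLS solver
            warnings.simplefilter("ignore")
            res = QuantReg(y, X).fit(q=tau)
        return np.asarray(res.params)

    def fit(self, tau: float = 0.5, n_boot: int = 1000,
            seed: int | None = None) -> TrendFit:
        """Fit the tau-th conditional quantile; SEs and percentile CIs come
        from ``n_boot`` row-resampling bootstrap replicates (seeded)."""
        if not 0 < tau < 1:
            raise ValueError("tau must be in (0, 1)")
        if seed is None:
            raise ValueError("an explicit seed is required for the bootstrap")
        beta = self._point_fit(self.endog, self.exog, tau)
        rng = np.random.default_rng(seed)
        n = len(self.endog)
        boots = np.empty((n_boot, len(beta)))
        for b in range(n_boot):
            idx = rng.integers(n, size=n)
            boots[b] = self._point_fit(self.endog[idx],
                                       self.exog.iloc[idx], tau)
        names = list(self.exog.columns)
        resid = self.endog - self.exog.values @ beta
        ci = pd.DataFrame(
            {"lower": np.percentile(boots, 2.5, axis=0),
             "upper": np.percentile(boots, 97.5, axis=0)}, index=names)
        return TrendFit(tau=tau, params=pd.Series(beta, index=names),
                        bse=pd.Series(boots.std(axis=0, ddof=1), index=names),
                        conf_int=ci, nobs=n, n_boot=n_boot,
                        objective=check_loss(resid, tau))


def pooled_trend_table(tree: Phylogeny, estimates: AncestralEstimates,
                       tip_values: pd.Series,
                       passerine: pd.Series | None = None) -> pd.DataFrame:
    """Pool tips (observed values) and internal nodes (posterior medians)
    into one depth-indexed table for trend fitting.

    An internal node counts as passerine when all its descendant tips are
    passerine.
    """
    tip_depths = tree.tip_depths()
    rows = [{"value": float(tip_values[lab]), "depth": tip_depths[lab],
             "is_tip": True,
             "passerine": bool(passerine[lab]) if passerine is not None
             else False}
            for lab in tree.tip_labels]
    for nid, rec in estimates.table.iterrows():
        tips = estimates.mrca_tips[nid]
        rows.append({"value": float(rec["median"]), "depth": float(rec["depth"]),
                     "is_tip": False,
                     "passerine": bool(passerine[list(tips)].all())
                     if passerine is not None else False})
    return pd.DataFrame(rows)


def spline_trend(values, depths, group=None, quantiles=(0.05, 0.5, 0.95),
                 n_windows: int = 10, n_grid: int = 200) -> dict:
    """Polynomial-spline curves through running quantiles, per group.

    Observations are split (within each group) into ``n_windows``
    equal-count depth windows; in each window the requested quantiles of
    the values are taken at the median depth, and a cubic interpolating
    spline is drawn through them. Returns
    ``{group: {"depth": grid, q: curve-values}}``. Groups are fitted in
    isolation. Purely descriptive — no inference.
    """
    values = np.asarray(values, dtype=float)
    depths = np.asarray(depths, dtype=float)
    groups = (np.zeros(len(values), dtype=int) if group is None
              else np.asarray(group))
    out: dict = {}
    for g in pd.unique(groups):
        mask = groups == g
        v, d = values[mask], depths[mask]
        if len(v) < 10:
            raise ValueError(f"group {g!r} has fewer than 10 points")
        order = np.argsort(d)
        v, d = v[order], d[order]
        edges = np.array_split(np.arange(len(v)), min(n_windows, len(v) // 2))
        xs = np.array([np.median(d[w]) for w in edges])
        grid = np.linspace(xs[0], xs[-1], n_grid)
        curves = {"depth": grid}
        for q in quantiles:
            ys = np.array([np.quantile(v[w], q) for w in edges])
            k = 3 if len(xs) > 3 else max(1, len(xs) - 1)
            spl = make_interp_spline(xs, ys, k=k)
            curves[q] = spl(grid)
        out[g] = curves
    return out
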