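"""Phylogenetic generalised least squares with Pagel's lambda.

The response (log10 C number) is regressed on nest characters and clutch
size with a phylogenetic error structure: residuals are multivariate
normal with covariance ``sigma^2 * V(lambda)``, where ``V(1)`` is the
Brownian-motion covariance (shared root-to-MRCA path lengths) and
``lambda`` in [0, 1] scales the off-diagonal entries, measuring
phylogenetic signal. ``lambda`` is estimated by maximum likelihood
(profile likelihood, bounded scalar search), and models are compared by
AICc with ``k`` counting the regression coefficients plus ``sigma^2``
plus ``lambda``.

Multiple comparison among the levels of one nest character follows an
AICc model-selection approach: every set-partition of the levels defines
a candidate model with levels merged, and the lowest-AICc partition is
reported as a compact letter display (levels sharing a letter share a
group).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.optimize import minimize_scalar

from .nests import REFERENCE_LEVELS, RISK_ORDER
from .trees import Phylogeny

__all__ = ["PGLS", "PGLSResults", "lambda_covariance", "aicc",
           "build_design", "grouping_selection", "GroupingResult",
           "set_partitions"]


def lambda_covariance(V: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform: keep the diagonal of the Brownian
    covariance ``V``, multiply off-diagonals by ``lam``."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    V = np.asarray(V, dtype=float)
    out = lam * V
    np.fill_diagonal(out, np.diag(V))
    return out


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: ``-2 l + 2k + 2k(k+1)/(n-k-1)``."""
    if n <= k + 1:
        raise ValueError("AICc requires n > k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def build_design(data: pd.DataFrame, characters: Sequence[str] = (),
                 covariates: Sequence[str] = (),
                 reference: Mapping[str, str] | None = None,
                 merges: Mapping[str, Mapping[str, str]] | None = None,
                 interaction: tuple[str, str] | None = None) -> pd.DataFrame:
    """Treatment-coded design matrix with an intercept.

    ``characters`` are categorical columns dummy-coded against their
    reference (lowest-risk) level; ``covariates`` enter numerically.
    ``merges`` optionally maps a character's levels onto merged group
    labels before coding (used for grouping selection and for the
    basal/non-basal, non-tree/others aggregations). ``interaction`` adds
    products of the two named characters' dummies.
    """
    reference = dict(reference or {})
    X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    dummies: dict[str, pd.DataFrame] = {}
    for ch in characters:
        col = data[ch].astype(str)
        if merges and ch in merges:
            col = col.map(dict(merges[ch]))
            if col.isna().any():
                raise ValueError(f"merge map for {ch!r} misses some levels")
        levels = list(dict.fromkeys(
            [lv for lv in RISK_ORDER.get(ch, [])
             if lv in set(col)] + sorted(set(col))))
        ref = reference.get(ch, REFERENCE_LEVELS.get(ch, levels[0]))
        if ref not in levels:
            ref = levels[0]
        block = pd.DataFrame(index=data.index)
        for lv in levels:
            if lv != ref:
                block[f"{ch}[{lv}]"] = (col == lv).astype(float)
        dummies[ch] = block
        X = pd.concat([X, block], axis=1)
    if interaction is not None:
        a, b = interaction
        for ca in dummies[a].columns:
            for cb in dummies[b].columns:
                X[f"{ca}:{cb}"] = dummies[a][ca] * dummies[b][cb]
    for cov in covariates:
        X[cov] = pd.to_numeric(data[cov])
    return X


@dataclass
class PGLSResults:
    """Fitted PGLS model: coefficients, uncertainty, lambda, fit metrics."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    lam: float
    sigma2: float
    llf: float
    aicc: float
    nobs: int
    k_params: int
    df_resid: int
    resid: pd.Series = field(repr=False)
    fittedvalues: pd.Series = field(repr=False)
    cov_params: pd.DataFrame = field(repr=False)
    model: "PGLS" = field(repr=False)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame({"lower": self.params - q * self.bse,
                             "upper": self.params + q * self.bse})

    def partial_residuals(self, character: str) -> pd.Series:
        """Residuals plus the focal character's fitted contribution — the
        quantity boxplotted per nest-category group."""
        cols = [c for c in self.params.index
                if c.startswith(f"{character}[")]
        X = self.model.exog[cols]
        return self.resid + X.values @ self.params[cols].values

    def summary(self) -> str:
        lines = ["PGLS (Pagel's lambda, ML)",
                 f"n = {self.nobs}, k = {self.k_params}, "
                 f"lambda = {self.lam:.3f}, sigma2 = {self.sigma2:.4g}",
                 f"logLik = {self.llf:.3f}, AICc = {self.aicc:.3f}",
                 "-" * 76,
                 f"{'':<32}{'coef':>9}{'SE':>9}{'t':>9}{'p':>12}"]
        for name in self.params.index:
            lines.append(f"{name:<32}{self.params[name]:>9.3f}"
                         f"{self.bse[name]:>9.3f}{self.tvalues[name]:>9.2f}"
                         f"{self.pvalues[name]:>12.3g}")
        return "\n".join(lines)


class PGLS:
    """PGLS regression model on a phylogeny.

    Parameters
    ----------
    endog : Series indexed by species (or array)
    exog : DataFrame of regressors including an intercept column
    tree : Phylogeny whose tips cover the species
    """

    def __init__(self, endog, exog: pd.DataFrame, tree: Phylogeny):
        exog = pd.DataFrame(exog)
        endog = pd.Series(endog, index=exog.index, dtype=float)
        species = list(exog.index.astype(str))
        missing = set(species) - set(tree.tip_labels)
        if missing:
            raise ValueError(f"species absent from tree: {sorted(missing)[:5]}...")
        self.endog = endog
        self.exog = exog
        self.tree = tree
        self.species = species
        self._V = tree.vcv(species)
        X = exog.values
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient; drop empty "
                             "or aliased category combinations")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       tree: Phylogeny, characters: Sequence[str] = (),
                       covariates: Sequence[str] = (),
                       species_col: str | None = None,
                       **design_kwargs) -> "PGLS":
        """Build the model from a trait table. ``species_col`` (default:
        the index) aligns rows with tree tips."""
        if species_col is not None:
            data = data.set_index(species_col)
        data = data.copy()
        data.index = data.index.astype(str)
        X = build_design(data, characters, covariates, **design_kwargs)
        return cls(data[response], X, tree)

    # ------------------------------------------------------------- fitting
    def _profile(self, lam: float) -> tuple[float, np.ndarray, np.ndarray, float]:
        """Profile log-likelihood at lambda; returns (llf, beta, XtVi_chol
        pieces, sigma2_ml)."""
        V = lambda_covariance(self._V, lam)
        try:
            L = linalg.cholesky(V, lower=True)
        except np.linalg.LinAlgError:
            # near-duplicate tips (zero-length splits): tiny ridge
            ridge = 1e-10 * float(np.trace(V)) / len(V)
            L = linalg.cholesky(V + ridge * np.eye(len(V)), lower=True)
        y = linalg.solve_triangular(L, self.endog.values, lower=True)
        X = linalg.solve_triangular(L, self.exog.values, lower=True)
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        n = len(y)
        rss = float(resid @ resid)
        sigma2 = rss / n
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        llf = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
        return llf, beta, X, sigma2

    def loglik(self, lam: float) -> float:
        """Profile ML log-likelihood at a fixed lambda."""
        return self._profile(lam)[0]

    def fit(self, estimate_lambda: bool = True, lam: float = 1.0,
            xatol: float = 1e-6) -> PGLSResults:
        """Fit by ML. With ``estimate_lambda`` the profile likelihood is
        maximised over [0, 1] by bounded scalar search; otherwise
        ``lam`` is held fixed."""
        if estimate_lambda:
            res = minimize_scalar(lambda l: -self._profile(l)[0],
                                  bounds=(0.0, 1.0), method="bounded",
                                  options={"xatol": xatol})
            lam_hat = float(res.x)
            # boundary beats the interior optimum on flat profiles
            for cand in (0.0, 1.0):
                if self._profile(cand)[0] > self._profile(lam_hat)[0]:
                    lam_hat = cand
        else:
            lam_hat = float(lam)
        llf, beta, Xw, sigma2_ml = self._profile(lam_hat)
        n, p = Xw.shape
        df = n - p
        rss = sigma2_ml * n
        s2_resid = rss / df
        XtX_inv = np.linalg.inv(Xw.T @ Xw)
        cov = s2_resid * XtX_inv
        bse = np.sqrt(np.diag(cov))
        tvals = beta / bse
        pvals = 2 * stats.t.sf(np.abs(tvals), df)
        k = p + 1 + (1 if estimate_lambda else 0)
        names = list(self.exog.columns)
        fitted = self.exog.values @ beta
        return PGLSResults(
            params=pd.Series(beta, index=names),
            bse=pd.Series(bse, index=names),
            tvalues=pd.Series(tvals, index=names),
            pvalues=pd.Series(pvals, index=names),
            lam=lam_hat, sigma2=sigma2_ml, llf=llf,
            aicc=aicc(llf, k, n), nobs=n, k_params=k, df_resid=df,
            resid=pd.Series(self.endog.values - fitted, index=self.exog.index),
            fittedvalues=pd.Series(fitted, index=self.exog.index),
            cov_params=pd.DataFrame(cov, index=names, columns=names),
            model=self)


# ------------------------------------------------- AICc grouping selection

def set_partitions(items: Sequence) -> Iterator[list[list]]:
    """All set-partitions of ``items`` (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


@dataclass
class GroupingResult:
    character: str
    best_partition: tuple[tuple[str, ...], ...]
    letters: dict[str, str]
    table: pd.DataFrame          # one row per partition with its AICc
    best_fit: PGLSResults = field(repr=False)


def grouping_selection(data: pd.DataFrame, response: str, character: str,
                       tree: Phylogeny, covariates: Sequence[str] = (),
                       species_col: str | None = None) -> GroupingResult:
    """AICc multiple comparison over all level groupings of one character.

    Every set-partition of the character's observed levels defines a PGLS
    model with the levels merged; the lowest-AICc partition wins and is
    rendered as a compact letter display (same letter = same group,
    letters ordered by increasing fitted group effect).
    """
    if species_col is not None:
        data = data.set_index(species_col)
    data = data.copy()
    data.index = data.index.astype(str)
    levels = [lv for lv in RISK_ORDER.get(character, [])
              if lv in set(data[character])]
    levels += sorted(set(data[character]) - set(levels))
    if len(levels) > 6:
        raise ValueError("grouping selection supports at most 6 levels")
    rows, fits = [], []
    for part in set_partitions(levels):
        merge = {lv: "+".join(sorted(grp)) for grp in part for lv in grp}
        model = PGLS.from_dataframe(
            data, response, tree, characters=[character],
            covariates=covariates, merges={character: merge})
        fit = model.fit()
        rows.append({"partition": tuple(tuple(sorted(g)) for g in part),
                     "n_groups": len(part), "aicc": fit.aicc,
                     "loglik": fit.llf, "lambda": fit.lam})
        fits.append((part, merge, fit))
    table = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    best_part, best_merge, best_fit = min(
        fits, key=lambda t: t[2].aicc)
    # order groups by fitted effect (reference group has effect 0)
    effects = {}
    for grp in best_part:
        name = f"{character}[{'+'.join(sorted(grp))}]"
        effects[tuple(grp)] = best_fit.params.get(name, 0.0)
    ordered = sorted(effects, key=effects.get)
    letters = {}
    for letter, grp in zip("abcdefgh", ordered):
        for lv in grp:
            letters[lv] = letter
    return GroupingResult(character=character,
                          best_partition=tuple(tuple(sorted(g))
                                               for g in best_part),
                          letters=letters, table=table, best_fit=best_fit)
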