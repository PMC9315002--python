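"""Brownian-motion ancestral state reconstruction for log10 C.

Under a non-directional random-walk (Brownian motion) model, tip values
and ancestral (internal-node) values are jointly multivariate normal with
covariances given by shared root-to-MRCA path lengths. Two estimators are
provided:

* a closed-form GLS reconstruction (conditional means of the internal
  nodes given the tips, with the root value estimated by GLS and the
  diffusion rate sigma^2 by ML) — deterministic, and the oracle against
  which the sampler is checked;
* a Bayesian MCMC reconstruction sampling (root, sigma^2) with an
  exponential prior on sigma^2 and drawing internal-node states from
  their exact conditional normal at each retained iteration, reporting
  per-node posterior mean/median/SD and an across-run convergence check.

Each internal node is identified by the set of tip labels it is the most
recent common ancestor of, so estimates can be matched across trees that
do not share their internal-node labelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .trees import Phylogeny

__all__ = ["AsrConfig", "AncestralEstimates", "BrownianASR"]


@dataclass
class AsrConfig:
    """Sampler settings. The full-scale convention is 500,000 iterations,
    200,000 burn-in, sampling every 1000, exponential prior mean 0.001 on
    the diffusion rate (for trees in units where rates are of that order);
    defaults here are desk-sized with a prior mean matched to unit-depth
    trees."""

    iterations: int = 20_000
    burn_in: int = 5_000
    thinning: int = 10
    prior_mean: float = 0.1
    seed: int | None = None
    proposal_scale: float = 0.8
    n_runs: int = 2
    convergence_tol: float = 0.05   # across-run SD of node means / tip SD

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("an explicit seed is required")
        if self.burn_in >= self.iterations:
            raise ValueError("burn-in must be smaller than iterations")


@dataclass
class AncestralEstimates:
    """Per-internal-node estimates of the ancestral trait value.

    ``table`` has one row per internal node: ``depth``, ``mean``,
    ``median``, ``sd`` and ``mrca_size``; ``mrca_tips[node_id]`` is the
    frozenset of descendant tip labels identifying the node.
    """

    table: pd.DataFrame
    mrca_tips: dict[int, frozenset[str]] = field(repr=False)
    method: str = "gls"
    sigma2: float | None = None
    root_value: float | None = None
    converged: bool | None = None
    convergence_stat: float | None = None

    def value_for(self, tips: frozenset[str]) -> pd.Series:
        for nid, s in self.mrca_tips.items():
            if s == tips:
                return self.table.loc[nid]
        raise KeyError("no internal node with that tip set")


class BrownianASR:
    """Ancestral reconstruction model for one continuous trait on a tree."""

    def __init__(self, tree: Phylogeny, tip_values: pd.Series):
        tip_values = pd.Series(tip_values, dtype=float)
        missing = set(tree.tip_labels) - set(tip_values.index.astype(str))
        if missing:
            raise ValueError(f"missing tip values: {sorted(missing)[:5]}...")
        self.tree = tree
        self.labels = tree.tip_labels
        self.x = tip_values.loc[self.labels].values
        self._prepare()

    def _prepare(self) -> None:
        """Joint BM covariance of tips and internal nodes, and the pieces
        of the conditional normal of nodes given tips."""
        tree = self.tree.tree
        depths = self.tree.node_depths()
        tipsets: dict = {}
        internal, internal_sets = [], []
        tip_index = {lab: i for i, lab in enumerate(self.labels)}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                tipsets[node] = frozenset([node.taxon.label])
            else:
                tipsets[node] = frozenset().union(*(tipsets[c]
                                                    for c in node.child_nodes()))
                internal.append(node)
                internal_sets.append(tipsets[node])
        n, m = len(self.labels), len(internal)
        V_tt = self.tree.vcv(self.labels)
        V_nt = np.zeros((m, n))
        V_nn = np.zeros((m, m))
        # MRCA(a, b) depth = depth of the smallest tip set containing both
        node_of = {s: k for k, s in enumerate(internal_sets)}
        for k, node in enumerate(internal):
            V_nn[k, k] = depths[node]
            anc = node.parent_node
            # covariance with any other node/tip = depth of common ancestor
        # walk pairs via ancestor chains (trees here are modest: O(m^2))
        anc_chain: dict = {}
        for node in tree.preorder_node_iter():
            anc_chain[node] = ([node] if node.parent_node is None
                               else anc_chain[node.parent_node] + [node])
        leaves = {lab: None for lab in self.labels}
        for leaf in tree.leaf_node_iter():
            leaves[leaf.taxon.label] = leaf
        def mrca_depth(a, b):
            ca = anc_chain[a]
            cb = set(id(x) for x in anc_chain[b])
            last = ca[0]
            for x in ca:
                if id(x) in cb:
                    last = x
                else:
                    break
            return depths[last]
        for k, node in enumerate(internal):
            for i, lab in enumerate(self.labels):
                V_nt[k, i] = mrca_depth(node, leaves[lab])
            for k2 in range(k + 1, m):
                V_nn[k, k2] = V_nn[k2, k] = mrca_depth(node, internal[k2])
        self.node_depth = np.array([depths[nd] for nd in internal])
        self.mrca_tips = {k: s for k, s in enumerate(internal_sets)}
        ridge = 1e-12 * np.trace(V_tt) / n
        self._Vtt_chol = linalg.cho_factor(V_tt + ridge * np.eye(n), lower=True)
        Vtt_inv_Vtn = linalg.cho_solve(self._Vtt_chol, V_nt.T)
        self._W = Vtt_inv_Vtn.T                       # m x n conditional weights
        C0 = V_nn - V_nt @ Vtt_inv_Vtn
        C0 = (C0 + C0.T) / 2
        w, U = np.linalg.eigh(C0)
        self._C0_sqrt = U * np.sqrt(np.clip(w, 0, None))
        self._cond_sd_unit = np.sqrt(np.clip(np.diag(C0), 0, None))
        ones = np.ones(n)
        Vi_x = linalg.cho_solve(self._Vtt_chol, self.x)
        Vi_1 = linalg.cho_solve(self._Vtt_chol, ones)
        self._a = float(self.x @ Vi_x)
        self._b = float(ones @ Vi_x)
        self._c = float(ones @ Vi_1)
        self._logdetV = 2.0 * float(
            np.sum(np.log(np.diag(self._Vtt_chol[0]))))
        self.n = n

    # ---------------------------------------------------------------- GLS
    def fit_gls(self) -> AncestralEstimates:
        """Closed-form conditional-mean reconstruction with GLS root and
        ML diffusion rate."""
        mu = self._b / self._c
        q = self._a - 2 * self._b * mu + self._c * mu ** 2
        sigma2 = q / self.n
        means = mu + self._W @ (self.x - mu)
        sds = np.sqrt(sigma2) * self._cond_sd_unit
        table = pd.DataFrame({"depth": self.node_depth, "mean": means,
                              "median": means, "sd": sds,
                              "mrca_size": [len(self.mrca_tips[k])
                                            for k in range(len(means))]})
        table.index.name = "node"
        return AncestralEstimates(table=table, mrca_tips=self.mrca_tips,
                                  method="gls", sigma2=float(sigma2),
                                  root_value=float(mu))

    # --------------------------------------------------------------- MCMC
    def _loglik(self, mu: float, sigma2: float) -> float:
        q = self._a - 2 * self._b * mu + self._c * mu ** 2
        return -0.5 * (self.n * np.log(2 * np.pi * sigma2)
                       + self._logdetV + q / sigma2)

    def _run_chain(self, config: AsrConfig, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        mu = self._b / self._c
        sigma2 = max((self._a - self._b ** 2 / self._c) / self.n, 1e-12)
        scale = config.proposal_scale
        ll = self._loglik(mu, sigma2)
        draws = []
        acc = cnt = 0
        m = len(self.node_depth)
        for it in range(config.iterations):
            # MH on sigma2 (lognormal multiplier, exponential prior)
            mult = np.exp(scale * rng.normal())
            s2_new = sigma2 * mult
            ll_new = self._loglik(mu, s2_new)
            log_alpha = (ll_new - ll - (s2_new - sigma2) / config.prior_mean
                         + np.log(mult))
            if np.log(rng.uniform()) < log_alpha:
                sigma2, ll = s2_new, ll_new
                acc += 1
            cnt += 1
            if it < config.burn_in and (it + 1) % 100 == 0:
                scale = float(np.clip(scale * np.exp(0.5 * (acc / cnt - 0.35)),
                                      1e-3, 5.0))
                acc = cnt = 0
            # Gibbs on the root (flat prior): N(b/c, sigma2/c)
            mu = self._b / self._c + rng.normal() * np.sqrt(sigma2 / self._c)
            ll = self._loglik(mu, sigma2)
            if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
                nodes = (mu + self._W @ (self.x - mu)
                         + np.sqrt(sigma2) * (self._C0_sqrt @ rng.normal(size=m)))
                draws.append(np.concatenate([[mu, sigma2], nodes]))
        return np.asarray(draws)

    def fit_mcmc(self, config: AsrConfig) -> AncestralEstimates:
        """Posterior reconstruction; runs ``config.n_runs`` chains from
        seeds ``seed, seed+1, ...`` and flags non-convergence when the
        across-run SD of node posterior means exceeds
        ``convergence_tol * SD(tip values)``."""
        runs = [self._run_chain(config, config.seed + i)
                for i in range(config.n_runs)]
        pooled = np.vstack([run[:, 2:] for run in runs])
        means = pooled.mean(axis=0)
        run_means = np.stack([run[:, 2:].mean(axis=0) for run in runs])
        spread = float(run_means.std(axis=0).max()) if config.n_runs > 1 else 0.0
        tip_sd = float(np.std(self.x)) or 1.0
        converged = spread <= config.convergence_tol * tip_sd
        all_params = np.vstack(runs)
        table = pd.DataFrame({
            "depth": self.node_depth,
            "mean": means,
            "median": np.median(pooled, axis=0),
            "sd": pooled.std(axis=0, ddof=1),
            "mrca_size": [len(self.mrca_tips[k]) for k in range(pooled.shape[1])],
        })
        table.index.name = "node"
        return AncestralEstimates(
            table=table, mrca_tips=self.mrca_tips, method="mcmc",
            sigma2=float(all_params[:, 1].mean()),
            root_value=float(all_params[:, 0].mean()),
            converged=bool(converged), convergence_stat=spread / tip_sd)
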