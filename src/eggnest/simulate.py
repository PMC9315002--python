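"""Synthetic studies with known ground truth.

Generates every ingredient of the egg-nest analysis so each pipeline stage
can be tested end to end without external downloads: ultrametric Yule
trees; nest characters evolving as continuous-time Markov chains
(including the 4-state dependent model for paired binary traits);
log10 C responses with Pagel's-lambda phylogenetic signal plus additive
nest-category and clutch-size effects on the scale of the fitted models
(e.g. dome +0.136, clutch +0.017 per egg on log10 C); and egg geometries
with allometric mass-size-thickness structure.

Every generator takes an explicit seed; there is no module-level
randomness.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .nests import RISK_ORDER
from .trees import Phylogeny

__all__ = ["SimulationConfig", "simulate_tree", "simulate_continuous",
           "simulate_discrete", "simulate_geometry", "simulate_study",
           "paired_trait_q", "DEFAULT_EFFECTS"]

#: additive effects on log10 C, one per non-reference nest category level
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "attachment": {"lateral/horizontal": 0.052, "pensile": 0.111},
    "site": {"tree": 0.050, "non-tree vegetation": 0.081},
    "structure": {"cavity": 0.066, "cup": 0.070, "dome": 0.136},
}
DEFAULT_CLUTCH_EFFECT = 0.017     # per egg, log10 C
DEFAULT_INTERCEPT = 4.10          # log10 C at reference levels, clutch 0
DEFAULT_SIGMA2 = 0.025            # BM rate of log10 C on a unit-depth tree


@dataclass
class SimulationConfig:
    """Study-level generator settings (defaults sized for test runs;
    ``n_tips=1350`` mirrors the full-data scale)."""

    n_tips: int = 200
    birth_rate: float = 1.0
    seed: int = 0
    lambda_signal: float = 1.0
    sigma2: float = DEFAULT_SIGMA2
    intercept: float = DEFAULT_INTERCEPT
    effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_EFFECTS.items()})
    clutch_effect: float = DEFAULT_CLUTCH_EFFECT
    clutch_mean: float = 2.5          # clutch ~ 1 + Poisson(mean)
    category_rate: float = 3.0        # Mk rate between adjacent risk levels
    passerine_fraction: float = 0.5


def _rng(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("an explicit seed is required")
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def simulate_tree(n_tips: int, seed, birth_rate: float = 1.0,
                  death_rate: float = 0.0, scale_depth: float | None = 1.0
                  ) -> Phylogeny:
    """Ultrametric birth-death (default Yule) tree with ``n_tips`` extant
    tips labelled ``s0001``..., optionally rescaled to a fixed root-to-tip
    depth."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = _rng(seed)
    pyrng = random.Random(int(rng.integers(2 ** 31)))
    from dendropy.simulate import treesim
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=death_rate,
        num_extant_tips=n_tips, rng=pyrng)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"s{i + 1:04d}"
    # the process stops at the n-th speciation, so the youngest pair of
    # terminal branches has zero length; floor to keep covariances
    # nonsingular (then restore ultrametricity by extending all tips)
    phylo = Phylogeny(tree)
    floor = 1e-6 * phylo.max_depth()
    for leaf in tree.leaf_node_iter():
        if (leaf.edge.length or 0.0) < floor:
            leaf.edge.length = floor
    phylo = Phylogeny(tree)
    max_d = phylo.max_depth()
    depths = phylo.tip_depths()
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += max_d - depths[leaf.taxon.label]
    if scale_depth is not None:
        factor = scale_depth / phylo.max_depth()
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
    return Phylogeny(tree)


def simulate_continuous(tree: Phylogeny, seed, lambda_signal: float = 1.0,
                        sigma2: float = DEFAULT_SIGMA2, root: float = 0.0,
                        X: pd.DataFrame | None = None,
                        beta: np.ndarray | None = None
                        ) -> tuple[pd.Series, dict]:
    """Tip values of a trait with Pagel's-lambda covariance plus fixed
    effects: ``y = X beta + b + e`` with ``b`` Brownian motion of rate
    ``sigma2 * lambda`` simulated node by node and ``e`` independent
    normal with variance ``sigma2 * (1 - lambda) * depth_i``, giving
    residual covariance ``sigma2 * V(lambda)`` exactly.

    Returns the tip series (sorted label order) and the true values of the
    Brownian component at internal nodes (plus the root trend), keyed by
    the frozenset of descendant tip labels — the ground truth for
    ancestral-reconstruction tests (exact when ``lambda = 1``).
    """
    if not 0.0 <= lambda_signal <= 1.0:
        raise ValueError("lambda_signal must lie in [0, 1]")
    rng = _rng(seed)
    bm_rate = sigma2 * lambda_signal
    node_val: dict[dendropy.Node, float] = {}
    node_states: dict[frozenset[str], float] = {}
    tipsets: dict[dendropy.Node, frozenset[str]] = {}
    tip_b: dict[str, float] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            node_val[node] = root
        else:
            bl = node.edge.length or 0.0
            node_val[node] = node_val[node.parent_node] + \
                rng.normal(0.0, np.sqrt(bm_rate * bl))
        if node.is_leaf():
            tip_b[node.taxon.label] = node_val[node]
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = frozenset([node.taxon.label])
        else:
            tipsets[node] = frozenset().union(*(tipsets[c]
                                                for c in node.child_nodes()))
            node_states[tipsets[node]] = node_val[node]
    labels = tree.tip_labels
    depths = tree.tip_depths()
    e = rng.normal(0.0, np.sqrt(sigma2 * (1 - lambda_signal)
                                * np.array([depths[l] for l in labels])))
    y = np.array([tip_b[l] for l in labels]) + e
    if X is not None:
        y = y + np.asarray(X.loc[labels]).astype(float) @ np.asarray(beta)
    return pd.Series(y, index=labels, name="value"), node_states


def simulate_discrete(tree: Phylogeny, Q: np.ndarray, root_state: int, seed,
                      labels: list | None = None
                      ) -> tuple[pd.Series, list[tuple]]:
    """Exact forward simulation of a continuous-time Markov chain along the
    tree (Gillespie per branch). Returns tip states (as ``labels`` entries
    if given, else integers) and the full event history as
    ``(tip_set, time_along_branch, from_state, to_state)`` tuples."""
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    if Q.shape != (k, k) or np.any(Q - np.diag(np.diag(Q)) < 0):
        raise ValueError("Q must be square with nonnegative off-diagonals")
    rng = _rng(seed)
    states: dict[dendropy.Node, int] = {}
    history: list[tuple] = []
    tipsets: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = frozenset([node.taxon.label])
        else:
            tipsets[node] = frozenset().union(*(tipsets[c]
                                                for c in node.child_nodes()))
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = int(root_state)
            continue
        s = states[node.parent_node]
        t, bl = 0.0, node.edge.length or 0.0
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= bl:
                break
            probs = np.clip(Q[s], 0.0, None)
            probs[s] = 0.0
            new = int(rng.choice(k, p=probs / probs.sum()))
            history.append((tipsets[node], t, s, new))
            s = new
        states[node] = s
    tips = {n.taxon.label: states[n] for n in tree.tree.leaf_node_iter()}
    out = pd.Series(tips).sort_index()
    if labels is not None:
        out = out.map(dict(enumerate(labels)))
    return out, history


def paired_trait_q(base_rate: float = 10.0, elevated: str | None = None,
                   factor: float = 10.0) -> np.ndarray:
    """4-state generator for a pair of binary traits: all single-trait
    transition rates equal ``base_rate``; optionally one dependent-model
    rate (e.g. ``"q24"``, trait-1 gain while trait 2 is in state 1) is
    multiplied by ``factor``. ``elevated=None`` gives an exactly
    independent process."""
    from .coevolution import DEPENDENT_PARAMS, rate_matrix
    rates = {k: base_rate for k in DEPENDENT_PARAMS}
    if elevated is not None:
        rates[elevated] = base_rate * factor
    return rate_matrix(rates, "dependent")


def _ordered_mk_q(n_levels: int, rate: float) -> np.ndarray:
    """Stepwise Markov generator between adjacent risk levels."""
    Q = np.zeros((n_levels, n_levels))
    for i in range(n_levels - 1):
        Q[i, i + 1] = rate
        Q[i + 1, i] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def simulate_geometry(n: int, seed, size_mean_mm: float = 40.0,
                      size_sd_log: float = 0.35, noise_sd: float = 0.04,
                      elongation: float = 1.35, thickness_ratio: float = 0.009,
                      density: float = 1031.0) -> pd.DataFrame:
    """Egg geometries from a latent size with lognormal allometric noise.

    Breadth ``A`` tracks the latent size, length ``B = elongation * A``,
    shell thickness ``t = thickness_ratio * A`` and mass follows the
    spheroid volume times whole-egg density — each with multiplicative
    lognormal noise of scale ``noise_sd``. The thin-shell constraint
    ``t/A < 0.05`` is enforced by construction.
    """
    rng = _rng(seed)
    size = size_mean_mm * np.exp(rng.normal(0, size_sd_log, n))
    A = size * np.exp(rng.normal(0, noise_sd, n))
    B = elongation * A * np.exp(rng.normal(0, noise_sd, n))
    t = thickness_ratio * A * np.exp(rng.normal(0, noise_sd, n))
    t = np.minimum(t, 0.049 * A)
    vol_m3 = np.pi / 6 * (A / 1000.0) ** 2 * (B / 1000.0)
    mass_g = density * vol_m3 * 1000.0 * np.exp(rng.normal(0, noise_sd, n))
    return pd.DataFrame({
        "species": [f"s{i + 1:04d}" for i in range(n)],
        "A_mm": A, "B_mm": B, "thickness_mm": t, "mass_g": mass_g,
        "ellipticity": rng.uniform(-0.05, 0.15, n),
        "asymmetry": rng.uniform(0.0, 0.2, n),
    }).set_index("species")


def _passerine_flags(tree: Phylogeny, fraction: float,
                     rng: np.random.Generator) -> pd.Series:
    """Mark one clade of roughly the requested tip fraction as 'passerine'."""
    target = fraction * tree.n_tips
    best, best_err = None, np.inf
    tipsets: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = frozenset([node.taxon.label])
        else:
            tipsets[node] = frozenset().union(*(tipsets[c]
                                                for c in node.child_nodes()))
            err = abs(len(tipsets[node]) - target)
            if node.parent_node is not None and err < best_err:
                best, best_err = tipsets[node], err
    flags = pd.Series(False, index=tree.tip_labels)
    if best:
        flags[list(best)] = True
    return flags


def simulate_study(config: SimulationConfig
                   ) -> tuple[Phylogeny, pd.DataFrame, dict]:
    """Generate a complete synthetic study: tree, trait table and truth.

    The trait table has one row per species with the nest characters,
    clutch size, passerine flag and the response ``log10_C`` generated as
    intercept + category effects + clutch effect + phylogenetic noise.
    The returned ``truth`` dict records the generating coefficients,
    lambda, sigma2 and the true ancestral values of the phylogenetic
    component.
    """
    rng = _rng(config.seed)
    tree = simulate_tree(config.n_tips, rng, birth_rate=config.birth_rate)
    labels = tree.tip_labels
    data = pd.DataFrame(index=pd.Index(labels, name="species"))
    X_cols, beta = {}, []
    for ch, effects in config.effects.items():
        levels = RISK_ORDER[ch]
        Q = _ordered_mk_q(len(levels), config.category_rate)
        # root category from the chain's stationary law (uniform for the
        # symmetric stepwise chain) so all levels occur at realistic rates
        root_state = int(rng.integers(len(levels)))
        states, _ = simulate_discrete(tree, Q, root_state, rng, labels=levels)
        data[ch] = states
        for lv, eff in effects.items():
            X_cols[f"{ch}[{lv}]"] = (states == lv).astype(float)
            beta.append(eff)
    clutch = 1 + rng.poisson(config.clutch_mean, len(labels))
    data["clutch_size"] = clutch
    X_cols["clutch_size"] = pd.Series(clutch.astype(float), index=labels)
    beta.append(config.clutch_effect)
    X = pd.DataFrame(X_cols, index=labels)
    y, node_states = simulate_continuous(
        tree, rng, lambda_signal=config.lambda_signal, sigma2=config.sigma2,
        root=config.intercept, X=X, beta=np.array(beta))
    data["log10_C"] = y
    data["passerine"] = _passerine_flags(tree, config.passerine_fraction, rng)
    truth = {"effects": {c: dict(v) for c, v in config.effects.items()},
             "clutch_effect": config.clutch_effect,
             "intercept": config.intercept,
             "lambda": config.lambda_signal, "sigma2": config.sigma2,
             "ancestral": node_states}
    return tree, data, truth
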