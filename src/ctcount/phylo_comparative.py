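"""Phylogenetic signal and correlated evolution.

Species-level traits (mean pollen number, ovule number, P:O and its
variance) may covary with phylogeny; this module provides the three
standard tools used to quantify that:

* **Pagel's λ** for continuous traits by maximum likelihood under a
  Brownian-motion (BM) model: the tip covariance is the shared
  root-to-MRCA path length, off-diagonals scaled by λ ∈ [0, 1] (λ = 0:
  no signal, traits independent of phylogeny; λ = 1: full BM).
* A **symmetric two-state Markov model** (equal rates q01 = q10 = q)
  for a binary trait (e.g. rewarding vs deceptive), with the likelihood
  computed by Felsenstein's pruning algorithm, optionally with a joint
  λ branch-scale transform.
* **PGLS** regression, where λ applies to the covariance of the model's
  residual errors; λ = 0 reduces exactly to ordinary least squares.

Likelihoods are full ML (not REML); the λ search is a bounded scalar
optimisation on [0, 1] with profile (analytic) MLEs of the BM rate and
root mean at each λ.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Phylogeny",
    "read_newick",
    "bm_cov",
    "lambda_transform",
    "LambdaFit",
    "fit_lambda_continuous",
    "fit_discrete_sym",
    "PGLSFit",
    "pgls",
    "simulate_bm",
    "random_tree",
]

log = logging.getLogger(__name__)

LAMBDA_GRID_POINTS = 1001
ULTRAMETRIC_RTOL = 1e-6


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths, tips in deterministic order."""

    tree: dendropy.Tree
    tips: list[str]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def tip_depths(self) -> np.ndarray:
        depth = _node_depths(self.tree)
        leaf = {lf.taxon.label: depth[lf] for lf in self.tree.leaf_node_iter()}
        return np.array([leaf[t] for t in self.tips])


def _node_depths(tree: dendropy.Tree) -> dict:
    depth = {}
    for node in tree.preorder_node_iter():
        el = node.edge.length
        if el is None:
            el = 0.0
        if el < 0:
            raise ValueError("negative branch length")
        depth[node] = (depth[node.parent_node] if node.parent_node else 0.0) + el
    return depth


def read_newick(text_or_path: str) -> Phylogeny:
    """Parse a newick tree (string or file path) with branch lengths.

    Tips are enumerated in the order they appear in the newick string.
    Deviations from ultrametricity beyond a relative 1e-6 are warned
    about but not rejected.
    """
    if "(" in text_or_path:
        src = dict(data=text_or_path, schema="newick")
    else:
        src = dict(path=text_or_path, schema="newick")
    try:
        tree = dendropy.Tree.get(**src, suppress_internal_node_taxa=True)
    except Exception as e:  # dendropy raises several parser error types
        raise ValueError(f"malformed newick: {e}") from e
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(tips)) != len(tips):
        raise ValueError("duplicate tip labels")
    for lf in tree.leaf_node_iter():
        if lf.edge.length is None:
            raise ValueError(f"missing branch length above tip {lf.taxon.label!r}")
    phy = Phylogeny(tree, tips)
    depths = phy.tip_depths()
    span = depths.max()
    if span > 0 and (depths.max() - depths.min()) / span > ULTRAMETRIC_RTOL:
        log.warning("tree is not ultrametric (tip depths %.6g..%.6g)",
                    depths.min(), depths.max())
    return phy


def bm_cov(phy: Phylogeny) -> np.ndarray:
    """BM tip covariance: shared root-to-MRCA path length per tip pair."""
    depth = _node_depths(phy.tree)
    n = phy.n_tips
    order = {t: i for i, t in enumerate(phy.tips)}
    C = np.zeros((n, n))
    # accumulate each internal edge's length on all tip pairs below it
    for node in phy.tree.preorder_node_iter():
        idx = [order[lf.taxon.label] for lf in node.leaf_iter()]
        d = depth[node]
        if node.parent_node is None:
            continue
        parent_d = depth[node.parent_node]
        block = np.ix_(idx, idx)
        C[block] += d - parent_d
    return C


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal covariance entries by λ (diagonal unchanged)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    out = lam * np.asarray(C, dtype=np.float64)
    np.fill_diagonal(out, np.diag(C))
    return out


# ---------------------------------------------------------------------------
# continuous traits: Pagel's lambda
# ---------------------------------------------------------------------------

def _mvn_profile_loglik(y: np.ndarray, V: np.ndarray) -> tuple[float, float, float]:
    """Profile ML log-likelihood of y ~ N(mu*1, sigma2*V).

    Returns (logL, mu_hat, sigma2_hat) with the analytic MLEs plugged in.
    """
    n = len(y)
    L = np.linalg.cholesky(V)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ones = np.ones(n)
    a = np.linalg.solve(L, y)
    b = np.linalg.solve(L, ones)
    mu = float(b @ a) / float(b @ b)
    r = a - mu * b
    sigma2 = float(r @ r) / n
    if sigma2 <= 0:
        return -np.inf, mu, 0.0
    logl = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return logl, mu, sigma2


@dataclass
class LambdaFit:
    """ML estimate of Pagel's λ for one continuous trait."""

    lam: float
    loglik: float
    loglik_lambda0: float
    loglik_lambda1: float
    mu: float       # ancestral (root) mean
    sigma2: float   # BM rate
    flagged: Optional[str] = None


def fit_lambda_continuous(phy: Phylogeny, traits) -> LambdaFit:
    """Maximum-likelihood Pagel's λ (bounded to [0, 1]) for tip values.

    ``traits`` is a mapping/Series keyed by tip label or an array in tip
    order.  σ² and the root mean are profiled analytically at each λ;
    the bounded scalar search is verified against a 1001-point λ grid.
    """
    y = _align_traits(phy, traits)
    if phy.n_tips < 3:
        raise ValueError("need at least 3 tips to estimate lambda")
    if np.allclose(y, y[0]):
        raise ValueError("zero trait variance: lambda is unidentifiable")
    C = bm_cov(phy)

    def nll(lam: float) -> float:
        return -_mvn_profile_loglik(y, lambda_transform(C, lam))[0]

    res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    # coarse grid guard against local optima of the profile
    grid = np.linspace(0.0, 1.0, LAMBDA_GRID_POINTS)
    grid_vals = np.array([nll(g) for g in grid])
    g_best = grid[int(np.argmin(grid_vals))]
    candidates = [(nll(res.x), float(res.x)), (grid_vals.min(), float(g_best)),
                  (nll(0.0), 0.0), (nll(1.0), 1.0)]
    best_nll, best_lam = min(candidates)
    logl, mu, sigma2 = _mvn_profile_loglik(y, lambda_transform(C, best_lam))
    return LambdaFit(best_lam, logl, -candidates[2][0], -candidates[3][0], mu, sigma2)


def _align_traits(phy: Phylogeny, traits) -> np.ndarray:
    if isinstance(traits, (dict, pd.Series)):
        missing = [t for t in phy.tips if t not in traits]
        if missing:
            raise ValueError(f"traits missing for tips: {missing}")
        y = np.array([float(traits[t]) for t in phy.tips])
    else:
        y = np.asarray(traits, dtype=np.float64)
        if len(y) != phy.n_tips:
            raise ValueError(f"expected {phy.n_tips} trait values, got {len(y)}")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite trait values")
    return y


# ---------------------------------------------------------------------------
# discrete trait: symmetric 2-state Markov model
# ---------------------------------------------------------------------------

def _prune_loglik_sym(phy: Phylogeny, states: np.ndarray, q: float,
                      lam: float = 1.0) -> float:
    """Pruning log-likelihood of a 2-state symmetric model (rate q).

    ``lam`` rescales internal branches (Pagel's λ on a discrete trait);
    terminal branches keep the portion that preserves tip depths.
    """
    tip_state = dict(zip(phy.tips, states))
    depth = _node_depths(phy.tree)

    def plen(node) -> float:
        el = node.edge.length or 0.0
        if lam == 1.0:
            return el
        if node.is_leaf():
            # lambda transform preserves the diagonal: tip depth unchanged,
            # shared (internal) path scaled by lambda
            root_to_parent = depth[node.parent_node] if node.parent_node else 0.0
            return el + (1.0 - lam) * root_to_parent
        return lam * el

    def pmat(t: float) -> np.ndarray:
        e = math.exp(-2.0 * q * t)
        same = 0.5 * (1.0 + e)
        diff = 0.5 * (1.0 - e)
        return np.array([[same, diff], [diff, same]])

    def partial(node) -> np.ndarray:
        if node.is_leaf():
            s = int(tip_state[node.taxon.label])
            vec = np.zeros(2)
            vec[s] = 1.0
            return vec
        out = np.ones(2)
        for ch in node.child_nodes():
            out = out * (pmat(plen(ch)) @ partial(ch))
        return out

    root_partial = partial(phy.tree.seed_node)
    like = float(0.5 * root_partial.sum())  # stationary root prior (1/2, 1/2)
    return math.log(like) if like > 0 else -np.inf


def fit_discrete_sym(phy: Phylogeny, states, fit_lambda: bool = False):
    """ML fit of the symmetric (equal-rates) 2-state Markov model.

    Returns ``(q_hat, loglik, lambda_hat)``; ``lambda_hat`` is None unless
    ``fit_lambda`` is set, in which case the branch-scale transform is
    optimised jointly with the rate.
    """
    y = _align_traits(phy, np.asarray(states, dtype=float)).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("states must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("single-state trait: rate is unidentifiable")
    depth_scale = float(np.mean(phy.tip_depths()))

    if not fit_lambda:
        def nll(logq):
            return -_prune_loglik_sym(phy, y, math.exp(logq))
        res = optimize.minimize_scalar(nll, bounds=(math.log(1e-8 / depth_scale),
                                                    math.log(1e3 / depth_scale)),
                                       method="bounded", options={"xatol": 1e-10})
        return math.exp(res.x), -res.fun, None

    def nll2(params):
        logq, lam = params
        lam = min(max(lam, 0.0), 1.0)
        return -_prune_loglik_sym(phy, y, math.exp(logq), lam)

    res = optimize.minimize(nll2, x0=[math.log(1.0 / depth_scale), 0.5],
                            bounds=[(math.log(1e-8 / depth_scale),
                                     math.log(1e3 / depth_scale)), (0.0, 1.0)],
                            method="L-BFGS-B")
    return math.exp(res.x[0]), -res.fun, float(res.x[1])


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclass
class PGLSFit:
    """GLS regression with λ-transformed BM residual covariance."""

    coef: pd.DataFrame  # estimate, se, t, p per coefficient
    lam: float
    loglik: float
    sigma2: float
    n: int


def pgls(phy: Phylogeny, response, predictors, lam: Optional[float] = None,
         names: Optional[Sequence[str]] = None) -> PGLSFit:
    """Phylogenetic generalised least squares.

    ``predictors`` is an (n, p) array / DataFrame aligned to tip order
    (or a mapping per column keyed by tip); an intercept is prepended.
    With ``lam=None`` the residual λ is estimated by ML on [0, 1]; with
    ``lam=0`` the fit equals OLS exactly.
    """
    y = _align_traits(phy, response)
    n = phy.n_tips
    if isinstance(predictors, pd.DataFrame):
        X = np.column_stack([_align_traits(phy, predictors[c]) for c in predictors])
        names = names or list(predictors.columns)
    else:
        X = np.asarray(predictors, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != n:
            raise ValueError(f"predictors have {X.shape[0]} rows, tree has {n} tips")
    X = np.column_stack([np.ones(n), X])
    names = ["intercept"] + list(names or [f"x{i}" for i in range(1, X.shape[1])])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    C = bm_cov(phy)

    def fit_at(lmb: float):
        V = lambda_transform(C, lmb)
        L = np.linalg.cholesky(V)
        Xi = np.linalg.solve(L, X)
        yi = np.linalg.solve(L, y)
        beta, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
        resid = yi - Xi @ beta
        sigma2 = float(resid @ resid) / n
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        logl = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n) \
            if sigma2 > 0 else -np.inf
        return beta, sigma2, logl, Xi

    if lam is None:
        res = optimize.minimize_scalar(lambda l: -fit_at(l)[2], bounds=(0.0, 1.0),
                                       method="bounded", options={"xatol": 1e-8})
        cand = [(-fit_at(l)[2], l) for l in (float(res.x), 0.0, 1.0)]
        lam = min(cand)[1]
    beta, sigma2, logl, Xi = fit_at(lam)
    p = X.shape[1]
    df = n - p
    s2_unbiased = sigma2 * n / df if df > 0 else np.nan
    cov_beta = s2_unbiased * np.linalg.inv(Xi.T @ Xi)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    coef = pd.DataFrame({"estimate": beta, "se": se, "t": tvals, "p": pvals},
                        index=names)
    return PGLSFit(coef, float(lam), float(logl), float(sigma2), n)


# ---------------------------------------------------------------------------
# simulation helpers (parameter-recovery tests and calibration)
# ---------------------------------------------------------------------------

def random_tree(n_tips: int, seed: int = 0) -> Phylogeny:
    """Random ultrametric coalescent tree rescaled to unit total depth."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    # Kingman coalescent: merge a uniform random pair at exponential times
    nodes = [f"t{i}" for i in range(n_tips)]
    heights = [0.0] * n_tips
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = nodes[i], nodes[j]
        ha, hb = heights[i], heights[j]
        merged = f"({a}:{t - ha:.10g},{b}:{t - hb:.10g})"
        nodes[i], heights[i] = merged, t
        del nodes[j], heights[j]
    # rescale to unit depth
    phy = read_newick(nodes[0] + ";")
    depth = phy.tip_depths().max()
    for e in phy.tree.preorder_edge_iter():
        if e.length is not None:
            e.length /= depth
    return phy


def simulate_bm(phy: Phylogeny, sigma2: float = 1.0, mu: float = 0.0,
                lam: float = 1.0, seed: int = 0) -> np.ndarray:
    """Simulate tip values under λ-transformed BM (for recovery tests)."""
    C = lambda_transform(bm_cov(phy), lam) * sigma2
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(phy.n_tips))
    return mu + L @ rng.normal(size=phy.n_tips)
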