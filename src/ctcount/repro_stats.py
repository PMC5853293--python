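"""Permutation and summary statistics for per-flower count tables.

The inferential layer mirrors a classical distance-based analysis of
count data: Euclidean distance matrices, a permutational (non-parametric)
ANOVA with adonis-style sequential pseudo-F statistics (McArdle &
Anderson partitioning) including interaction terms, Bonferroni-corrected
pairwise post hoc comparisons, an exact two-sample
Mann-Whitney-Wilcoxon test for comparing per-species variances between
pollination strategies, a simple-regression F test, and the per-species /
per-strategy summary tables (means, SE, variances, N-weighted strategy
means, P:O).

On univariate data with Euclidean distances the PERMANOVA pseudo-F is
identical to the classical one-way ANOVA F; permutation p-values use
``(#{F_perm >= F_obs} + 1) / (n_perm + 1)`` with free permutation of raw
observations.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "euclidean_dm",
    "PermanovaResult",
    "permanova",
    "permanova_posthoc",
    "grouping_letters",
    "MWWResult",
    "mww_exact",
    "ols_f",
    "GroupSummary",
    "table1_summary",
    "weighted_strategy_means",
]

log = logging.getLogger(__name__)

DEFAULT_N_PERM = 9999
#: exact MWW enumeration is used while C(n1+n2, n1) stays below this
MWW_EXACT_LIMIT = 10 ** 6


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

def euclidean_dm(values) -> np.ndarray:
    """Euclidean distance matrix of per-sample scalars or vectors."""
    x = np.asarray(values, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (n >= 2) x p array of sample values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite sample values")
    return squareform(pdist(x, metric="euclidean"))


def _check_dm(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10) or np.any(np.diag(d) != 0) or np.any(d < 0):
        raise ValueError("not a valid distance matrix (symmetry/zero diagonal/non-negativity)")
    return d


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _dummy(factor: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    levels = pd.unique(factor)
    return np.column_stack([(factor == lv).astype(float) for lv in levels[1:]]) \
        if len(levels) > 1 else np.empty((len(factor), 0))


def _term_columns(term: str, design: pd.DataFrame) -> np.ndarray:
    if ":" in term:
        a, b = term.split(":")
        da, db = _dummy(design[a].to_numpy()), _dummy(design[b].to_numpy())
        cols = [da[:, i] * db[:, j] for i in range(da.shape[1]) for j in range(db.shape[1])]
        return np.column_stack(cols) if cols else np.empty((len(design), 0))
    return _dummy(design[term].to_numpy())


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal-projection (hat) matrix and rank of a design matrix."""
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


@dataclass
class PermanovaResult:
    """Sequential (Type-I) PERMANOVA table."""

    table: pd.DataFrame  # rows: terms..., Residual, Total
    n_permutations: int
    seed: Optional[int]
    undefined: bool = False
    flags: list = field(default_factory=list)

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def permanova(
    d: np.ndarray,
    design,
    terms: Optional[Sequence[str]] = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: Optional[int] = None,
) -> PermanovaResult:
    """Distance-based permutational ANOVA with sequential SS.

    Parameters
    ----------
    d
        n x n distance matrix.
    design
        DataFrame (or mapping) of factor columns, length n.
    terms
        Model terms in order; ``"a:b"`` denotes an interaction.  Defaults
        to the design columns in order.
    n_perm, seed
        Number of free permutations of the observations and RNG seed.

    Sum-of-squares partitioning follows the Gower-centred inner-product
    matrix: ``SS(model) = tr(H G)`` with H the design's hat matrix, terms
    added sequentially; ``pseudo-F = (SS_t/df_t) / (SS_res/df_res)``.
    """
    d = _check_dm(d)
    n = d.shape[0]
    design = pd.DataFrame(design)
    if len(design) != n:
        raise ValueError(f"design has {len(design)} rows, distance matrix has {n}")
    if terms is None:
        terms = list(design.columns)
    for t in terms:
        for name in t.split(":"):
            if name not in design.columns:
                raise ValueError(f"unknown factor {name!r} in term {t!r}")
            if design[name].nunique() < 2:
                raise ValueError(f"factor {name!r} has fewer than 2 levels")
            counts = design[name].value_counts()
            if (counts == 1).any():
                log.warning("factor %r has singleton level(s): %s",
                            name, list(counts.index[counts == 1]))

    # Gower-centred matrix G; SS_total = tr(G)
    A = -0.5 * d ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    ss_total = float(np.trace(G))
    if ss_total <= 1e-12 * n:
        log.warning("all observations identical: total SS is zero, result undefined")
        tbl = pd.DataFrame(index=[*terms, "Residual", "Total"],
                           columns=["df", "SS", "F", "R2", "p"], dtype=float)
        tbl.loc["Total", ["df", "SS"]] = [n - 1, 0.0]
        return PermanovaResult(tbl, n_perm, seed, undefined=True, flags=["zero total SS"])

    # sequential hat matrices
    ones = np.ones((n, 1))
    X = ones
    prev_hat, prev_rank = _hat(X)
    h_diffs, dfs = [], []
    for t in terms:
        X = np.hstack([X, _term_columns(t, design)])
        H, rank = _hat(X)
        h_diffs.append(H - prev_hat)
        dfs.append(rank - prev_rank)
        prev_hat, prev_rank = H, rank
    df_res = n - prev_rank
    if df_res <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    h_res = np.eye(n) - prev_hat

    eps = 1e-12 * ss_total  # float-noise floor for perfectly fitted groups

    def _stats(Gm: np.ndarray):
        ss = np.array([float(np.sum(hd * Gm)) for hd in h_diffs])
        ss_res = float(np.sum(h_res * Gm))
        if ss_res < eps:
            ss_res = 0.0
        with np.errstate(divide="ignore"):
            F = (ss / np.asarray(dfs)) / np.where(ss_res > 0, ss_res / df_res, 0.0)
        return ss, ss_res, F

    ss_obs, ss_res_obs, f_obs = _stats(G)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    chunk = max(1, min(n_perm, int(2e7 // max(n * n, 1))))
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        perms = np.argsort(rng.random((c, n)), axis=1)
        Gp = G[perms[:, :, None], perms[:, None, :]]  # (c, n, n)
        ss_p = np.stack([np.einsum("pij,ij->p", Gp, hd) for hd in h_diffs])
        ss_res_p = np.einsum("pij,ij->p", Gp, h_res)
        ss_res_p[ss_res_p < eps] = 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            F_p = (ss_p / np.asarray(dfs)[:, None]) / (ss_res_p / df_res)
        F_p[np.isnan(F_p)] = np.inf  # 0/0: perfect fit both ways
        exceed += (F_p >= f_obs[:, None] * (1 - 1e-12)).sum(axis=1)
        done += c
    pvals = (exceed + 1.0) / (n_perm + 1.0)

    tbl = pd.DataFrame({
        "df": [*dfs, df_res, n - 1],
        "SS": [*ss_obs, ss_res_obs, ss_total],
        "F": [*f_obs, np.nan, np.nan],
        "R2": [*(ss_obs / ss_total), ss_res_obs / ss_total, 1.0],
        "p": [*pvals, np.nan, np.nan],
    }, index=[*terms, "Residual", "Total"])
    return PermanovaResult(tbl, n_perm, seed)


def permanova_posthoc(
    d: np.ndarray,
    factor,
    n_perm: int = DEFAULT_N_PERM,
    seed: Optional[int] = None,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """All pairwise one-way PERMANOVAs with Bonferroni correction.

    Returns one row per level pair with the pair's pseudo-F, raw p and
    ``p_adj = min(1, p * n_pairs)``.
    """
    if correction != "bonferroni":
        raise ValueError(f"unsupported correction {correction!r}")
    d = _check_dm(d)
    factor = np.asarray(factor)
    levels = list(pd.unique(factor))
    if len(levels) < 3:
        log.warning("fewer than 3 levels: the plain test suffices")
    pairs = list(itertools.combinations(levels, 2))
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in pairs:
        sel = np.flatnonzero((factor == a) | (factor == b))
        sub = d[np.ix_(sel, sel)]
        res = permanova(sub, pd.DataFrame({"g": factor[sel]}), ["g"],
                        n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
        row = res.table.loc["g"]
        rows.append(dict(level_a=a, level_b=b, F=row["F"], R2=row["R2"],
                         p=row["p"], p_adj=min(1.0, row["p"] * len(pairs))))
    return pd.DataFrame(rows)


def grouping_letters(pairwise: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Compact letter display from an adjusted pairwise table.

    Levels that are not significantly different share at least one
    letter; the assignment is a deterministic greedy clique cover of the
    non-significance graph.
    """
    levels = sorted(set(pairwise["level_a"]) | set(pairwise["level_b"]), key=str)
    ns = {frozenset((r.level_a, r.level_b)) for r in pairwise.itertuples()
          if r.p_adj > alpha}
    groups: list[set] = []
    for lv in levels:
        placed = False
        for g in groups:
            if all(frozenset((lv, o)) in ns for o in g):
                g.add(lv)
                placed = True
        if not placed:
            groups.append({lv})
    letters = {lv: "" for lv in levels}
    for g, ch in zip(groups, "abcdefghijklmnopqrstuvwxyz"):
        for lv in sorted(g, key=str):
            letters[lv] += ch
    return letters


# ---------------------------------------------------------------------------
# exact Mann-Whitney-Wilcoxon
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MWWResult:
    """Two-sample MWW test under the smaller-is-extreme W convention."""

    w: float  # min(U1, U2)
    p: float
    n1: int
    n2: int
    u1: float
    u2: float
    method: str  # "exact" | "normal"


def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U: counts of arrangements per U value.

    Classical recurrence ``N(u; m, n) = N(u - n; m - 1, n) + N(u; m, n - 1)``
    over the number of x's (m) and y's (n).
    """
    umax = n1 * n2
    # dp[m, u] for current n; start at n = 0 where U is always 0
    dp = np.zeros((n1 + 1, umax + 1), dtype=np.float64)
    dp[:, 0] = 1.0
    for n in range(1, n2 + 1):
        new = np.zeros_like(dp)
        new[0, 0] = 1.0
        for m in range(1, n1 + 1):
            new[m] = dp[m]
            new[m, n:] += new[m - 1, :-n] if n > 0 else new[m - 1]
        dp = new
    counts = dp[n1]
    assert abs(counts.sum() - math.comb(n1 + n2, n1)) < 1e-6
    return counts


def mww_exact(x, y) -> MWWResult:
    """Exact two-sided two-sample Mann-Whitney-Wilcoxon test.

    ``W = min(U1, U2)`` (0 <= W <= n1*n2); the exact two-sided p doubles
    the smaller tail probability (capped at 1) by complete enumeration of
    the null U distribution.  With ties, or when C(n1+n2, n1) exceeds
    10^6, a normal approximation with tie correction and continuity
    correction is used and flagged in ``method``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    w = min(u1, u2)
    has_ties = len(np.unique(combined)) < n1 + n2
    if not has_ties and math.comb(n1 + n2, n1) <= MWW_EXACT_LIMIT:
        counts = _u_null_counts(n1, n2)
        total = counts.sum()
        iu = int(round(u1))
        lower = counts[: iu + 1].sum() / total
        upper = counts[iu:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return MWWResult(float(w), float(p), n1, n2, float(u1), float(u2), "exact")
    # normal approximation with tie correction
    log.warning("MWW falling back to normal approximation (ties or large samples)")
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return MWWResult(float(w), 1.0, n1, n2, float(u1), float(u2), "normal")
    z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * stats.norm.sf(z))
    return MWWResult(float(w), float(p), n1, n2, float(u1), float(u2), "normal")


# ---------------------------------------------------------------------------
# simple regression F test
# ---------------------------------------------------------------------------

def ols_f(x, y) -> tuple[float, int, int, float, float]:
    """Simple linear regression F test: ``(F, df1, df2, p, R2)``."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("x is constant: slope is unidentifiable")
    xc, yc = x - x.mean(), y - y.mean()
    ss_total = float(yc @ yc)
    beta = float(xc @ yc) / float(xc @ xc)
    ss_reg = beta ** 2 * float(xc @ xc)
    ss_res = ss_total - ss_reg
    df1, df2 = 1, n - 2
    if ss_res <= 0:  # perfectly collinear
        return math.inf, df1, df2, 0.0, 1.0
    F = (ss_reg / df1) / (ss_res / df2)
    p = float(stats.f.sf(F, df1, df2))
    r2 = ss_reg / ss_total if ss_total > 0 else np.nan
    return float(F), df1, df2, p, float(r2)


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

@dataclass
class GroupSummary:
    """Per-species and per-strategy summary of a per-flower count table."""

    species: pd.DataFrame
    strategy: pd.DataFrame
    po_variance_ratio: float  # mean per-species P:O variance, rewarding / deceptive


def table1_summary(records: pd.DataFrame) -> GroupSummary:
    """Summarise FlowerRecord rows per species and per strategy.

    Per species: mean, SE (= sample sd / sqrt(N)), variance and N for
    pollen, ovule and P:O counts.  Per strategy: N-weighted means of the
    species means (identical to the pooled per-flower mean when weights
    are the species Ns) with the pooled per-flower SE, plus the ratio of
    mean per-species P:O variances (rewarding / deceptive).
    """
    req = {"species", "strategy", "pollen", "ovules"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if records["strategy"].isna().any():
        raise ValueError("missing strategy labels")
    rec = records.copy()
    if "po" not in rec.columns or rec["po"].isna().any():
        rec["po"] = rec["pollen"] / rec["ovules"]

    def _summary(g: pd.DataFrame) -> pd.Series:
        out = {}
        for var in ("pollen", "ovules", "po"):
            v = g[var].astype(float)
            n = int(v.count())
            sd = float(v.std(ddof=1)) if n > 1 else np.nan
            out[f"{var}_mean"] = float(v.mean())
            out[f"{var}_se"] = sd / math.sqrt(n) if n > 1 else np.nan
            out[f"{var}_var"] = float(v.var(ddof=1)) if n > 1 else np.nan
            out[f"{var}_n"] = n
        out["strategy"] = g["strategy"].iloc[0]
        return pd.Series(out)

    species = rec.groupby("species", sort=True).apply(_summary, include_groups=False)

    strat_rows = {}
    for strat, g in rec.groupby("strategy", sort=True):
        sp = species[species["strategy"] == strat]
        row = {}
        for var in ("pollen", "ovules", "po"):
            wmean = float(np.sum(sp[f"{var}_mean"] * sp[f"{var}_n"]) / sp[f"{var}_n"].sum())
            pooled = g[var].astype(float)
            row[f"{var}_weighted_mean"] = wmean
            row[f"{var}_pooled_se"] = float(pooled.std(ddof=1) / math.sqrt(pooled.count()))
            row[f"{var}_n"] = int(pooled.count())
        strat_rows[strat] = row
    strategy = pd.DataFrame(strat_rows).T

    ratio = np.nan
    by = species.groupby("strategy")["po_var"].mean()
    if {"rewarding", "deceptive"} <= set(by.index):
        ratio = float(by["rewarding"] / by["deceptive"])
    return GroupSummary(species, strategy, ratio)


def weighted_strategy_means(summary: pd.DataFrame, mean_col: str, n_col: str,
                            strategy_col: str = "strategy") -> dict:
    """N-weighted strategy means from a per-species summary table.

    This reproduces group means directly from printed per-species means
    and sample sizes: ``sum(mean_i * N_i) / sum(N_i)`` per strategy.
    """
    out = {}
    for strat, g in summary.groupby(strategy_col):
        out[str(strat)] = float(np.sum(g[mean_col] * g[n_col]) / g[n_col].sum())
    return out
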