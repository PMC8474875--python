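"""Statistics behind the results figures: Fisher's exact and rank-sum
tests, shift-preference analysis, PCA, PERMANOVA, logistic ROC/AUC and
hypergeometric over-representation analysis."""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import IsomiRKey
from .de import bh_adjust
from .survival import CLASS_HARMFUL, CLASS_PROTECTIVE, percentage


def fisher_exact(table, side: str = "two-sided") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table [[a, b], [c, d]].

    The conditional hypergeometric p is computed in exact integer
    arithmetic; the two-sided rule is minimum-likelihood (sum of outcomes
    at most as probable as the observed one). Returns the sample odds
    ratio ad/bc and the p-value.
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    total = a + b + c + d
    if total == 0:
        raise ValueError("empty table")
    if side not in {"two-sided", "greater", "less"}:
        raise ValueError(f"unknown side {side!r}")
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - total), min(row1, col1)
    # integer hypergeometric weights share the denominator C(total, col1),
    # so the selection rule can be applied without floating-point ties
    weights = {x: math.comb(row1, x) * math.comb(total - row1, col1 - x)
               for x in range(lo, hi + 1)}
    w_obs = weights[a]
    if side == "greater":
        num = sum(w for x, w in weights.items() if x >= a)
    elif side == "less":
        num = sum(w for x, w in weights.items() if x <= a)
    else:
        num = sum(w for w in weights.values() if w <= w_obs)
    p = num / math.comb(total, col1)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return odds, min(float(p), 1.0)


def wilcoxon_ranksum(x, y) -> tuple[float, float]:
    """Two-sided rank-sum (Mann-Whitney) test with midrank ties.

    Exact by full enumeration over group assignments when the number of
    combinations is small; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    nx_, ny_ = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled, method="average")
    u = ranks[:nx_].sum() - nx_ * (nx_ + 1) / 2.0

    n_comb = math.comb(nx_ + ny_, nx_)
    if n_comb <= 200_000:
        mu = nx_ * ny_ / 2.0
        obs_dev = abs(u - mu)
        count = 0
        idx = range(nx_ + ny_)
        for combo in combinations(idx, nx_):
            u_star = ranks[list(combo)].sum() - nx_ * (nx_ + 1) / 2.0
            if abs(u_star - mu) >= obs_dev - 1e-12:
                count += 1
        return float(u), count / n_comb
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(u), float(res.pvalue)


def shift_preference(keys_with_classes: list[tuple[IsomiRKey, str]]) -> pd.DataFrame:
    """Per-class counts of positive/negative shifts with a Fisher test.

    Archetypes (shift 0) are excluded. Each class's positive/negative
    split is tested against the split of all remaining (nonzero-shift)
    keys by a two-sided Fisher's exact test.
    """
    shifted = [(k, c) for k, c in keys_with_classes if k.shift != 0]
    rows = []
    for cls in (CLASS_PROTECTIVE, CLASS_HARMFUL):
        n_pos = sum(1 for k, c in shifted if c == cls and k.shift > 0)
        n_neg = sum(1 for k, c in shifted if c == cls and k.shift < 0)
        r_pos = sum(1 for k, c in shifted if c != cls and k.shift > 0)
        r_neg = sum(1 for k, c in shifted if c != cls and k.shift < 0)
        total = n_pos + n_neg
        if total and (r_pos + r_neg):
            _, p = fisher_exact([[n_pos, n_neg], [r_pos, r_neg]])
        else:
            p = math.nan
        rows.append(
            {
                "class": cls,
                "n_pos": n_pos,
                "n_neg": n_neg,
                "frac_pos": n_pos / total if total else math.nan,
                "fisher_p": p,
            }
        )
    return pd.DataFrame(rows, columns=["class", "n_pos", "n_neg", "frac_pos", "fisher_p"])


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    explained: np.ndarray  # variance fractions
    components: np.ndarray  # components x features


def pca(grid: np.ndarray) -> PCAResult:
    """Column-centered SVD principal components of a samples x features grid."""
    X = np.asarray(grid, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("constant grid: no variance to decompose")
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = u * s
    explained = s**2 / np.sum(s**2)
    return PCAResult(scores=scores, explained=explained, components=vt)


def permanova(
    distances: np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutational MANOVA pseudo-F and permutation p on a distance matrix.

    p = (1 + #{F* >= F}) / (1 + n_perm).
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    labels = np.asarray(labels)
    n = len(labels)
    groups, counts = np.unique(labels, return_counts=True)
    a = len(groups)
    if a < 2:
        raise ValueError("need at least 2 groups")
    D2 = D**2

    def pseudo_f(lab: np.ndarray) -> float:
        ss_total = D2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for g in groups:
            idx = np.flatnonzero(lab == g)
            if len(idx) < 2:
                continue
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_among = ss_total - ss_within
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(labels)) >= f_obs:
            hits += 1
    return float(f_obs), (1 + hits) / (1 + n_perm)


def auc_rank(scores, labels) -> float:
    """AUC via the rank statistic: U / (n1 * n0) with midrank ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both labels must be present")
    ranks = stats.rankdata(scores, method="average")
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class LogisticROC:
    auc: float
    coef: np.ndarray
    converged: bool
    fpr: np.ndarray
    tpr: np.ndarray
    fitted: np.ndarray


def logistic_roc(scores: np.ndarray, labels, max_iter: int = 50) -> LogisticROC:
    """Unpenalized IRLS logistic fit on score columns; ROC/AUC on the fit.

    Under complete separation the likelihood has no finite maximizer; the
    fit is flagged unconverged and the AUC is still computed from the
    (divergent but rank-stable) linear predictor.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    A = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(A.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = A @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = A.T @ (y - mu)
        hess = A.T @ (A * w[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            converged = True
            break
        if np.max(np.abs(beta)) > 1e6:
            break
    eta = A @ beta
    auc = auc_rank(eta, y.astype(int))

    order = np.argsort(-eta, kind="stable")
    ys = y[order]
    tp = np.concatenate([[0.0], np.cumsum(ys)])
    fp = np.concatenate([[0.0], np.cumsum(1 - ys)])
    tpr = tp / max(ys.sum(), 1)
    fpr = fp / max((1 - ys).sum(), 1)
    return LogisticROC(auc=auc, coef=beta, converged=converged, fpr=fpr, tpr=tpr,
                       fitted=1.0 / (1.0 + np.exp(-eta)))


def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def ora(
    query: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in gene sets.

    p is the upper tail P(X >= k) with N = |universe|, K = |set ∩
    universe|, n = |query|; BH-adjusted, sorted by p.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    n = len(query)
    big_n = len(universe)
    rows = []
    for name, genes in gene_sets.items():
        in_universe = genes & universe
        big_k = len(in_universe)
        k = len(query & in_universe)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n)) if big_k else 1.0
        rows.append({"set": name, "k": k, "K": big_k, "n": n, "N": big_n, "p": p})
    df = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    if len(df):
        df["adj_p"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    return df


def de_class_crosstab(class_keys: list[str], de: pd.DataFrame) -> dict:
    """Cross-tabulate one survival class against DE directions.

    Reports counts of up/down/ns features and the integer percentages as
    printed in the summary tables.
    """
    n = len(class_keys)
    directions = [de.loc[k, "direction"] if k in de.index else "ns" for k in class_keys]
    n_up = sum(1 for d in directions if d == "up")
    n_down = sum(1 for d in directions if d == "down")
    return {
        "n": n,
        "n_up": n_up,
        "n_down": n_down,
        "n_ns": n - n_up - n_down,
        "up_pct": percentage(n_up, n),
        "down_pct": percentage(n_down, n),
    }
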