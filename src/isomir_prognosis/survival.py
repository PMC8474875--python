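"""Per-isomiR multivariate Cox proportional-hazards screening.

The Cox partial likelihood is maximized by Newton-Raphson with the Efron
tie correction (Breslow available), step-halving on likelihood decrease,
and convergence on relative log-likelihood change < 1e-9. Each feature is
tested in a multivariate model together with the clinical confounders;
the feature coefficient is gated on its Wald p-value, with the
likelihood-ratio p against the confounders-only null reported alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import IsomiRKey

log = logging.getLogger(__name__)

CLASS_PROTECTIVE = "protective"
CLASS_HARMFUL = "harmful"
CLASS_NS = "nonsignificant"


class CoxError(ValueError):
    pass


class ConvergenceError(CoxError):
    """Monotone likelihood / flat likelihood: no finite maximizer found."""


@dataclass
class CoxResult:
    key: IsomiRKey | None
    beta: float
    se: float
    wald_z: float
    wald_p: float
    lrt_p: float
    n_used: int
    n_events: int
    label: str = CLASS_NS

    @property
    def hr(self) -> float:
        return math.exp(self.beta)


def _cox_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray,
                ties: str = "efron") -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, gradient and Hessian.

    Assumes rows sorted by ascending time. Risk set at an event time t is
    {j : time_j >= t}.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # guard overflow; PL is invariant to a constant shift
    w = np.exp(eta)
    wX = w[:, None] * X
    wXX = np.einsum("i,ij,ik->ijk", w, X, X)

    # suffix sums over the risk set (time sorted ascending)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    # extreme trial betas during the line search can underflow the suffix
    # sums; the non-finite likelihood is handled by step-halving upstream
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        while i < n:
            j = i
            while j < n and time[j] == time[i]:
                j += 1
            dead = [k for k in range(i, j) if event[k] == 1]
            d = len(dead)
            if d > 0:
                s0r, s1r, s2r = S0[i], S1[i], S2[i]
                if s0r <= 0:  # underflow at extreme beta: signal the line search
                    return -np.inf, grad, hess
                ll += eta[dead].sum()
                grad += X[dead].sum(axis=0)
                if ties == "efron" and d > 1:
                    s0d = w[dead].sum()
                    s1d = wX[dead].sum(axis=0)
                    s2d = wXX[dead].sum(axis=0)
                    for l in range(d):
                        f = l / d
                        s0 = s0r - f * s0d
                        s1 = s1r - f * s1d
                        s2 = s2r - f * s2d
                        ll -= math.log(s0)
                        grad -= s1 / s0
                        hess -= s2 / s0 - np.outer(s1, s1) / s0**2
                else:  # breslow, or a single death where the two coincide
                    ll -= d * math.log(s0r)
                    grad -= d * s1r / s0r
                    hess -= d * (s2r / s0r - np.outer(s1r, s1r) / s0r**2)
            i = j
    return ll, grad, hess


def cox_fit(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit a Cox model; returns (beta, covariance, log-likelihood)."""
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if X.ndim != 2:
        raise CoxError("X must be 2-D")
    if event.sum() < 2:
        raise CoxError("need at least 2 events")
    if np.any(np.ptp(X, axis=0) == 0):
        raise CoxError("constant covariate: flat likelihood")

    order = np.argsort(time, kind="stable")
    X, time, event = X[order], time[order], event[order]

    # standardize internally for numerical stability; back-transform at the end
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Z = (X - mu) / sd

    beta = np.zeros(X.shape[1])
    ll, grad, hess = _cox_loglik(beta, Z, time, event, ties)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        new_beta = beta + step
        new_ll, new_grad, new_hess = _cox_loglik(new_beta, Z, time, event, ties)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll) and halvings < 30:
            step = step / 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _cox_loglik(new_beta, Z, time, event, ties)
            halvings += 1
        converged = abs(new_ll - ll) < tol * (abs(ll) + 1.0)
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if converged:
            break
    else:
        raise ConvergenceError("Newton-Raphson did not converge (monotone likelihood?)")
    # a standardized log-hazard beyond ~15 means the event order is (near-)
    # perfectly separated by a covariate: no finite maximizer
    if np.any(np.abs(beta) > 15):
        raise ConvergenceError("diverging coefficient: monotone likelihood")

    cov_z = np.linalg.inv(-hess)
    beta_x = beta / sd
    cov_x = cov_z / np.outer(sd, sd)
    return beta_x, cov_x, ll


def cox_loglik_at(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                  beta: np.ndarray, ties: str = "efron") -> float:
    """Log partial likelihood at a fixed beta (no fitting)."""
    order = np.argsort(np.asarray(time, dtype=float), kind="stable")
    X = np.asarray(X, dtype=float)[order]
    t = np.asarray(time, dtype=float)[order]
    e = np.asarray(event, dtype=int)[order]
    ll, _, _ = _cox_loglik(np.asarray(beta, dtype=float), X, t, e, ties)
    return ll


def load_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV into the screening layout.

    Requires columns: sample, time, event, age_at_index, cigarettes_per_day,
    ajcc_pathologic_t. The T stage is encoded as an integer score T1=1..T4=4;
    sub-stages (e.g. T1a) collapse to the major stage.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time", "event", "age_at_index", "cigarettes_per_day", "ajcc_pathologic_t"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns {sorted(missing)}")
    df = df.set_index("sample")
    df["t_stage"] = df["ajcc_pathologic_t"].map(encode_t_stage)
    return df


def encode_t_stage(value) -> float:
    if pd.isna(value):
        return np.nan
    s = str(value).strip().upper()
    if s.startswith("T") and len(s) >= 2 and s[1] in "1234":
        return int(s[1])
    try:
        v = int(float(s))
    except ValueError:
        return np.nan
    return v if 1 <= v <= 4 else np.nan


def epv_filter(
    counts: pd.DataFrame,
    clinical: pd.DataFrame,
    dead_fraction: float = 0.5,
) -> tuple[list[str], pd.Series]:
    """Keep keys expressed (read_count > 0) in enough dead samples.

    The threshold is ceil(dead_fraction * number of dead samples); at a
    threshold of zero, any key expressed anywhere is kept. Returns the
    kept labels and the per-key dead-sample coverage.
    """
    if not 0 <= dead_fraction <= 1:
        raise ValueError("dead_fraction must be in [0, 1]")
    dead = clinical.index[clinical["event"] == 1]
    dead = [s for s in dead if s in counts.columns]
    if len(dead) == 0:
        raise ValueError("no dead samples in the expression matrix")
    coverage = (counts[dead] > 0).sum(axis=1)
    threshold = math.ceil(dead_fraction * len(dead))
    if threshold <= 0:
        kept = coverage.index[(counts > 0).any(axis=1)]
    else:
        kept = coverage.index[coverage >= threshold]
    return list(kept), coverage


CONFOUNDERS = ["age_at_index", "cigarettes_per_day", "t_stage"]


def fit_cox(
    expression: pd.Series,
    clinical: pd.DataFrame,
    covariates: list[str] | None = None,
    ties: str = "efron",
    transform: str = "log2p1",
) -> CoxResult:
    """Multivariate Cox fit for one feature plus clinical confounders.

    Expression enters as log2(x+1) by default (``transform='raw'`` for the
    untransformed scale). Samples missing any covariate are dropped
    (complete case). The LRT p compares against the confounders-only null.
    """
    if covariates is None:
        covariates = CONFOUNDERS
    common = [s for s in clinical.index if s in expression.index]
    expr = expression.loc[common].astype(float)
    if transform == "log2p1":
        expr = np.log2(expr + 1.0)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")

    design = pd.DataFrame({"expr": expr})
    for c in covariates:
        design[c] = clinical.loc[common, c].astype(float)
    design["time"] = clinical.loc[common, "time"].astype(float)
    design["event"] = clinical.loc[common, "event"].astype(int)
    design = design.dropna()

    cols = ["expr"] + covariates
    X = design[cols].to_numpy()
    time = design["time"].to_numpy()
    event = design["event"].to_numpy()

    beta, cov, ll = cox_fit(X, time, event, ties=ties)
    se = math.sqrt(cov[0, 0])
    z = beta[0] / se
    wald_p = 2.0 * stats.norm.sf(abs(z))

    if covariates:
        _, _, ll0 = cox_fit(design[covariates].to_numpy(), time, event, ties=ties)
    else:
        ll0 = cox_loglik_at(X, time, event, np.zeros(X.shape[1]), ties)
    lrt = max(2.0 * (ll - ll0), 0.0)
    lrt_p = stats.chi2.sf(lrt, df=1)

    return CoxResult(
        key=None,
        beta=float(beta[0]),
        se=se,
        wald_z=float(z),
        wald_p=float(wald_p),
        lrt_p=float(lrt_p),
        n_used=len(design),
        n_events=int(event.sum()),
    )


def classify(results: list[CoxResult], alpha: float = 0.05) -> list[CoxResult]:
    """Label each result protective (beta<0), harmful (beta>0) at p<alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    for r in results:
        if r.wald_p < alpha and r.beta < 0:
            r.label = CLASS_PROTECTIVE
        elif r.wald_p < alpha and r.beta > 0:
            r.label = CLASS_HARMFUL
        else:
            r.label = CLASS_NS
    return results


def screen(
    matrix_rpm: pd.DataFrame,
    counts: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
    dead_fraction: float = 0.5,
    ties: str = "efron",
    transform: str = "log2p1",
) -> pd.DataFrame:
    """Run the full survival screen over an isomiR matrix.

    Only tumor samples present in the clinical table enter the models.
    Features failing the EPV filter or whose fit does not converge are
    excluded (the latter logged).
    """
    kept, coverage = epv_filter(counts, clinical, dead_fraction)
    results: list[CoxResult] = []
    for label in kept:
        expr = matrix_rpm.loc[label]
        try:
            res = fit_cox(expr, clinical, ties=ties, transform=transform)
        except CoxError as exc:
            log.info("skipping %s: %s", label, exc)
            continue
        res.key = IsomiRKey.parse(label)
        results.append(res)
    classify(results, alpha)
    return results_table(results, coverage)


def results_table(results: list[CoxResult], coverage: pd.Series | None = None) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "key": r.key.label if r.key else "",
                "shift": r.key.shift if r.key else np.nan,
                "beta": r.beta,
                "hr": r.hr,
                "ln_hr": r.beta,
                "se": r.se,
                "wald_z": r.wald_z,
                "wald_p": r.wald_p,
                "lrt_p": r.lrt_p,
                "n_used": r.n_used,
                "n_events": r.n_events,
                "class": r.label,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["key", "shift", "beta", "hr", "ln_hr", "se", "wald_z", "wald_p",
                 "lrt_p", "n_used", "n_events", "class"],
    )
    if coverage is not None and len(df):
        df["dead_coverage"] = df["key"].map(coverage).values
    return df


def screen_summary(table: pd.DataFrame) -> dict:
    """Summarize a screen: counts of classes and the isomiR share.

    Percentages are rounded to the nearest integer, as printed in the
    report tables.
    """
    sig = table[table["class"] != CLASS_NS]
    n = len(sig)
    n_isomir = int((sig["shift"] != 0).sum())
    return {
        "n_influential": n,
        "n_protective": int((sig["class"] == CLASS_PROTECTIVE).sum()),
        "n_harmful": int((sig["class"] == CLASS_HARMFUL).sum()),
        "n_isomir": n_isomir,
        "n_archetype": n - n_isomir,
        "isomir_pct": percentage(n_isomir, n),
    }


def percentage(k: int, n: int) -> int:
    """Integer percentage k/n as printed in summaries (round half up)."""
    if n == 0:
        return 0
    return int(math.floor(100.0 * k / n + 0.5))
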