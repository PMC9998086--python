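"""Cox screening, risk-score signature and Kaplan-Meier comparison.

The prognostic pipeline: (1) univariate Cox proportional-hazards screen of
every gene, retaining genes with Benjamini-Hochberg q < 0.1; (2) a
deterministic feature-reduction step keeping the top-k screened genes by
univariate |z| (default k = 6, the size of a six-gene signature); (3) one
multivariate Cox fit over the kept genes giving coefficients beta_i, and a
per-sample risk score sum_i x_i * beta_i; (4) a median split of the risk
score into low/high groups (scores exactly at the median go to "low"),
compared by Kaplan-Meier curves and the two-group log-rank test.

Cox fits maximise the partial likelihood by Newton-Raphson with the
Breslow approximation for tied event times; standard errors come from the
inverse observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import adjust_bh

__all__ = [
    "SurvivalData",
    "CoxFit",
    "RiskModel",
    "cox_fit",
    "univariate_screen",
    "select_signature",
    "build_risk_model",
    "km_estimate",
    "km_logrank",
    "median_split",
]

_MAX_ITER = 60
_GRAD_TOL = 1e-8
_BETA_BOUND = 20.0


@dataclass
class SurvivalData:
    """Right-censored survival outcomes per sample."""

    time: np.ndarray
    event: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if (self.time <= 0).any():
            raise ValueError("survival times must be > 0")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0/1")
        if self.time.shape != self.event.shape:
            raise ValueError("time/event length mismatch")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(len(self.time))]

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class CoxFit:
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    loglik: float
    converged: bool
    separation: bool
    n_iter: int
    covariates: list[str] = field(default_factory=list)


def _breslow_loglik(beta, X, time, event):
    """(loglik, gradient, information) of the Breslow partial likelihood."""
    order = np.argsort(-time, kind="stable")  # decreasing time
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)

    # running sums over the risk set (all with time >= t, i.e. prefix in sorted order)
    S0 = np.cumsum(w)
    S1 = np.cumsum(w[:, None] * Xs, axis=0)
    S2 = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)

    # group tied times: risk set for an event time t is the prefix up to the
    # LAST index with that time
    ll = 0.0
    grad = np.zeros(X.shape[1])
    info = np.zeros((X.shape[1], X.shape[1]))
    i = 0
    n = len(ts)
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        ev = es[i : j + 1].astype(bool)
        d = int(ev.sum())
        if d > 0:
            xi = Xs[i : j + 1][ev]
            s0, s1, s2 = S0[j], S1[j], S2[j]
            ll += float(eta[i : j + 1][ev].sum()) - d * np.log(s0)
            xbar = s1 / s0
            grad += xi.sum(axis=0) - d * xbar
            info += d * (s2 / s0 - np.outer(xbar, xbar))
        i = j + 1
    return ll, grad, info


def cox_fit(
    X: np.ndarray | pd.DataFrame,
    surv: SurvivalData,
    max_iter: int = _MAX_ITER,
    tol: float = _GRAD_TOL,
) -> CoxFit:
    """Newton-Raphson Cox proportional-hazards fit (Breslow ties).

    Non-convergence and separation (|beta| exceeding a bound) are flagged on
    the result, never silently dropped.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else []
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not names:
        names = [f"x{i}" for i in range(X.shape[1])]
    if len(X) != len(surv):
        raise ValueError("covariate rows must match survival samples")
    if surv.event.sum() < 1:
        raise ValueError("need at least one event")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant covariate: partial likelihood is flat")

    beta = np.zeros(X.shape[1])
    ll, grad, info = _breslow_loglik(beta, X, surv.time, surv.event)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving keeps the likelihood non-decreasing
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, info_new = _breslow_loglik(cand, X, surv.time, surv.event)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.linalg.norm(grad) < tol:
            converged = True
            break
    separation = bool(np.any(np.abs(beta) > _BETA_BOUND))
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return CoxFit(beta, se, z, p, float(ll), converged, separation, it, names)


def univariate_screen(
    expr: pd.DataFrame, surv: SurvivalData, q: float = 0.1
) -> pd.DataFrame:
    """One univariate Cox fit per gene (rows of ``expr``); keep BH q < ``q``.

    Genes whose fit fails to converge or shows separation are excluded with
    a warning and carry ``flagged=True`` in the returned table.
    """
    rows = []
    for gene in expr.index:
        x = expr.loc[gene].to_numpy(float)
        if np.std(x) == 0:
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, True))
            continue
        fit = cox_fit(x[:, None], surv)
        flagged = not fit.converged or fit.separation
        rows.append((gene, fit.beta[0], fit.se[0], fit.z[0], fit.p[0], flagged))
    res = pd.DataFrame(rows, columns=["gene_id", "beta", "se", "z", "pvalue", "flagged"])
    n_flagged = int(res["flagged"].sum())
    if n_flagged:
        warnings.warn(f"{n_flagged} gene fit(s) flagged and excluded from the screen")
    p = res["pvalue"].where(~res["flagged"], np.nan).to_numpy()
    res["qvalue"] = adjust_bh(p)
    res["selected"] = (res["qvalue"] < q) & ~res["flagged"]
    return res


def select_signature(screen: pd.DataFrame, k: int = 6) -> list[str]:
    """Deterministic feature reduction: top-k selected genes by |z|."""
    sel = screen[screen["selected"]].copy()
    sel["absz"] = sel["z"].abs()
    sel = sel.sort_values(["absz", "gene_id"], ascending=[False, True])
    return sel["gene_id"].head(k).tolist()


@dataclass
class RiskModel:
    gene_ids: list[str]
    beta: np.ndarray
    threshold: float  # median training risk score

    def risk_scores(self, expr: pd.DataFrame) -> pd.Series:
        """risk = sum_i x_i * beta_i over signature genes."""
        X = expr.loc[self.gene_ids].to_numpy(float).T
        return pd.Series(X @ self.beta, index=expr.columns, name="risk_score")


def build_risk_model(
    expr: pd.DataFrame, surv: SurvivalData, genes: list[str]
) -> RiskModel:
    """Multivariate Cox over the signature genes; median-split threshold."""
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    X = expr.loc[genes].to_numpy(float).T
    fit = cox_fit(pd.DataFrame(X, columns=genes), surv)
    if not fit.converged:
        raise RuntimeError(
            f"multivariate Cox did not converge in {fit.n_iter} iterations "
            f"(|grad| state at beta={fit.beta})"
        )
    scores = X @ fit.beta
    if np.allclose(scores, scores[0]):
        raise ValueError("degenerate risk scores (all equal); median split undefined")
    return RiskModel(list(genes), fit.beta, float(np.median(scores)))


def median_split(scores: pd.Series, threshold: float | None = None) -> pd.Series:
    """'low' for scores <= threshold (median by default), 'high' above."""
    t = float(scores.median()) if threshold is None else threshold
    return pd.Series(
        np.where(scores.to_numpy(float) > t, "high", "low"),
        index=scores.index,
        name="risk_group",
    )


def km_estimate(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns event-time rows with n_at_risk, n_events and S(t); S is
    right-continuous, non-increasing, S(0) = 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    rows = [(0.0, len(t), 0, 1.0)]
    s = 1.0
    for ut in np.unique(t[e == 1]):
        at_risk = int((t >= ut).sum())
        d = int(((t == ut) & (e == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append((float(ut), at_risk, d, s))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def km_logrank(
    groups: pd.Series | np.ndarray, surv: SurvivalData
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Two-group log-rank test with KM curves per group.

    Returns ({group: KM table}, chi-square, p).  With no events anywhere the
    statistic is undefined; p = 1 is returned with a warning.
    """
    g = np.asarray(groups)
    labels = sorted(pd.unique(g).tolist())
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {labels}")
    in0 = g == labels[0]
    if in0.all() or (~in0).all():
        raise ValueError("both groups must be non-empty")
    curves = {
        lab: km_estimate(surv.time[g == lab], surv.event[g == lab]) for lab in labels
    }
    t, e = surv.time, surv.event
    event_times = np.unique(t[e == 1])
    if len(event_times) == 0:
        warnings.warn("no events in either group; log-rank p set to 1")
        return curves, 0.0, 1.0
    obs = exp = var = 0.0
    for ut in event_times:
        at_risk = t >= ut
        n = int(at_risk.sum())
        n1 = int((at_risk & in0).sum())
        d = int(((t == ut) & (e == 1)).sum())
        d1 = int(((t == ut) & (e == 1) & in0).sum())
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return curves, 0.0, 1.0
    chi2 = (obs - exp) ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return curves, float(chi2), p
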