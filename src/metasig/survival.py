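"""Risk-score survival analysis: Cox fit, median split, KM, log-rank, HR.

The risk score of a patient is the linear predictor of a multivariate
proportional-hazards fit on the miRNA panel; patients above the median
score form the high-risk group.  Group separation is summarized by the
Kaplan–Meier curves, the two-group log-rank test, and the hazard ratio
from a univariate Cox fit on the group indicator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalCohort",
    "CoxFit",
    "RiskModel",
    "cox_fit",
    "risk_groups",
    "km_estimate",
    "logrank_test",
    "hazard_ratio",
]

_BETA_CAP = 15.0  # |beta| beyond this is treated as monotone likelihood


@dataclass
class SurvivalCohort:
    """Per-patient follow-up and miRNA panel values.

    ``panel`` is a patients x miRNAs DataFrame aligned with ``time`` and
    ``event``; rows with missing panel values must be filtered upstream.
    """

    patient_id: np.ndarray
    time: np.ndarray
    event: np.ndarray
    panel: pd.DataFrame

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if np.any(self.time <= 0):
            raise ValueError("follow-up times must be positive")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event must be 0 (censored) or 1 (death)")
        if self.panel.isna().any().any():
            raise ValueError("panel contains missing values")
        n = len(self.time)
        if len(self.event) != n or len(self.panel) != n or len(self.patient_id) != n:
            raise ValueError("misaligned cohort arrays")

    @property
    def n(self) -> int:
        return len(self.time)

    @classmethod
    def from_tsv(cls, path: str | Path, panel: Sequence[str] | None = None) -> "SurvivalCohort":
        """Load from TSV with columns patient_id, time, event, then panel miRNAs."""
        df = pd.read_csv(path, sep="\t")
        cols = [c for c in df.columns if c not in ("patient_id", "time", "event")]
        if panel is not None:
            missing = set(panel) - set(cols)
            if missing:
                raise ValueError(f"panel miRNAs absent from file: {sorted(missing)}")
            cols = list(panel)
        return cls(
            patient_id=df["patient_id"].to_numpy(),
            time=df["time"].to_numpy(dtype=float),
            event=df["event"].to_numpy(dtype=int),
            panel=df[cols].reset_index(drop=True),
        )

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame({"patient_id": self.patient_id, "time": self.time, "event": self.event})
        out = pd.concat([out, self.panel.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CoxFit:
    betas: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    separation: bool
    n_events: int


def _cox_loglik_grad_hess(
    beta: np.ndarray, times: np.ndarray, events: np.ndarray, X: np.ndarray, ties: str
):
    """Breslow/Efron partial log-likelihood with gradient and Hessian.

    Arrays must be sorted by ascending time.
    """
    n, p = X.shape
    lp = X @ beta
    lp -= lp.max()  # guard overflow; constant shift cancels in the ratios
    w = np.exp(lp)
    # reverse cumulative sums over the risk sets
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    S2 = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        ev = np.arange(i, j)[events[i:j] == 1]
        d = len(ev)
        if d:
            xsum = X[ev].sum(axis=0)
            ll += lp[ev].sum()
            if ties == "breslow" or d == 1:
                ll -= d * math.log(S0[i])
                grad += xsum - d * S1[i] / S0[i]
                hess -= d * (S2[i] / S0[i] - np.outer(S1[i], S1[i]) / S0[i] ** 2)
            else:  # efron
                wd = w[ev].sum()
                s1d = (w[ev, None] * X[ev]).sum(axis=0)
                s2d = (w[ev, None, None] * (X[ev, :, None] * X[ev, None, :])).sum(axis=0)
                for l in range(d):
                    f = l / d
                    s0l = S0[i] - f * wd
                    s1l = S1[i] - f * s1d
                    s2l = S2[i] - f * s2d
                    ll -= math.log(s0l)
                    grad += -s1l / s0l
                    hess -= s2l / s0l - np.outer(s1l, s1l) / s0l**2
                grad += xsum
        i = j
    return ll, grad, hess


def cox_fit(
    times,
    events,
    X,
    ties: str = "breslow",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxFit:
    """Newton–Raphson maximization of the Cox partial likelihood.

    Iterates until the gradient norm falls below ``tol``.  A monotone
    likelihood (perfect separation) is detected when a coefficient walks
    past ±15; the coefficient is capped and the fit flagged.  Columns
    with zero variance contribute beta = 0 (no information).
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != times.size:
        X = X.T
    n, p = X.shape
    if p < 1:
        raise ValueError("need at least one covariate")
    n_events = int(events.sum())
    if n_events == 0:
        raise ValueError("no observed events")

    order = np.argsort(times, kind="mergesort")
    ts, es, Xs = times[order], events[order], X[order]

    informative = Xs.std(axis=0) > 0
    beta = np.zeros(p)
    separation = False
    converged = False
    ll = -np.inf
    if informative.any():
        Xi = Xs[:, informative]
        b = np.zeros(informative.sum())
        ll, grad, hess = _cox_loglik_grad_hess(b, ts, es, Xi, ties)
        for _ in range(max_iter):
            if np.linalg.norm(grad) < tol:
                converged = True
                break
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                step = grad
            # step halving; tolerate float-noise-level decreases so full
            # Newton steps are accepted near the optimum
            ll_floor = ll - 1e-9 * (1.0 + abs(ll))
            new_b = b + step
            new_ll, new_grad, new_hess = _cox_loglik_grad_hess(new_b, ts, es, Xi, ties)
            halvings = 0
            while new_ll < ll_floor and halvings < 30:
                step /= 2.0
                new_b = b + step
                new_ll, new_grad, new_hess = _cox_loglik_grad_hess(new_b, ts, es, Xi, ties)
                halvings += 1
            b, ll, grad, hess = new_b, new_ll, new_grad, new_hess
            if np.any(np.abs(b) > _BETA_CAP):
                separation = True
                b = np.clip(b, -_BETA_CAP, _BETA_CAP)
                ll, grad, hess = _cox_loglik_grad_hess(b, ts, es, Xi, ties)
                break
        else:
            converged = np.linalg.norm(grad) < tol
        if np.linalg.norm(grad) < tol:
            converged = True
        beta[informative] = b
        se = np.full(p, np.inf)
        try:
            cov = np.linalg.inv(-hess)
            d = np.diag(cov)
            se[informative] = np.sqrt(np.where(d > 0, d, np.inf))
        except np.linalg.LinAlgError:
            pass
    else:
        # all covariates constant: no information, beta = 0 by definition
        converged = True
        se = np.full(p, np.inf)
        ll, _, _ = _cox_loglik_grad_hess(np.zeros(1), ts, es, np.zeros((n, 1)), ties)
    return CoxFit(
        betas=beta, se=se, loglik=float(ll), converged=bool(converged),
        separation=separation, n_events=n_events,
    )


@dataclass(frozen=True)
class RiskModel:
    betas: np.ndarray
    risk_score: np.ndarray
    threshold: float
    group: np.ndarray  # "high"/"low" per patient


def risk_groups(cohort: SurvivalCohort, betas, split: str = "median") -> RiskModel:
    """Dichotomize patients by their risk score.

    Score is the linear predictor over the panel; patients strictly
    above the median go to the high-risk group, ties at the median to
    the low-risk group (deterministic).
    """
    if split != "median":
        raise ValueError("only the median split is supported")
    betas = np.asarray(betas, dtype=float)
    scores = cohort.panel.to_numpy(dtype=float) @ betas
    if np.all(scores == scores[0]):
        raise ValueError("all risk scores identical; no split possible")
    threshold = float(np.median(scores))
    group = np.where(scores > threshold, "high", "low")
    return RiskModel(betas=betas, risk_score=scores, threshold=threshold, group=group)


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan–Meier product-limit estimate.

    Returns a step table with a row at t = 0 (survival 1) and one row
    per distinct event time: time, n_at_risk, n_events, survival.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty group")
    order = np.argsort(times, kind="mergesort")
    ts, es = times[order], events[order]
    rows = [(0.0, len(ts), 0, 1.0)]
    s = 1.0
    i = 0
    n = len(ts)
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        d = int(es[i:j].sum())
        at_risk = n - i
        if d:
            s *= 1.0 - d / at_risk
            rows.append((float(ts[i]), at_risk, d, s))
        i = j
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test.

    Uses the hypergeometric variance at each distinct event time; the
    statistic is referred to chi-square with 1 df.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError("log-rank test needs exactly two non-empty groups")
    if events.sum() == 0:
        raise ValueError("no events observed")
    g1 = group == labels[0]
    order = np.argsort(times, kind="mergesort")
    ts, es, g1s = times[order], events[order], g1[order]
    n = len(ts)
    obs_minus_exp = 0.0
    var = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        d = int(es[i:j].sum())
        if d:
            at_risk = n - i
            n1 = int(g1s[i:].sum())
            d1 = int(es[i:j][g1s[i:j]].sum())
            e1 = d * n1 / at_risk
            obs_minus_exp += d1 - e1
            if at_risk > 1:
                var += d * (n1 / at_risk) * (1 - n1 / at_risk) * (at_risk - d) / (at_risk - 1)
        i = j
    if var == 0:
        return 0.0, 1.0
    chi2 = obs_minus_exp**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def hazard_ratio(
    times, events, group, high_label: str = "high", ties: str = "breslow"
) -> tuple[float, tuple[float, float]]:
    """Hazard ratio of high- vs low-risk group with Wald 95% CI."""
    group = np.asarray(group)
    x = (group == high_label).astype(float)
    if x.std() == 0:
        raise ValueError("group indicator is constant")
    fit = cox_fit(times, events, x[:, None], ties=ties)
    beta, se = float(fit.betas[0]), float(fit.se[0])
    z = stats.norm.ppf(0.975)
    return math.exp(beta), (math.exp(beta - z * se), math.exp(beta + z * se))
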