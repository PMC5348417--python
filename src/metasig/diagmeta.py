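"""Bivariate random-effects meta-analysis of diagnostic 2x2 tables.

Implements the normal-approximation two-level model: per-study
(logit sensitivity, logit specificity) pairs are treated as draws from a
bivariate normal around ``(mu_se, mu_sp)`` with an unknown between-study
covariance plus known within-study variances.  On top of the fit sit the
summary ROC curve and its AUC, the funnel-plot asymmetry regression of
ln(diagnostic odds ratio) on effective sample size, and basic residual
diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

__all__ = [
    "Diagnostic2x2",
    "BivariateFit",
    "DeeksResult",
    "ModelDiagnostics",
    "sens_spec",
    "fit_bivariate",
    "sroc_curve",
    "sroc_auc",
    "deeks_test",
    "model_diagnostics",
    "read_diagnostic_tables",
]

_LOGTAU_MIN, _LOGTAU_MAX = -30.0, 5.0
_BOUNDARY_LOGTAU = -15.0  # below this we call tau2 a boundary (zero) fit


@dataclass(frozen=True)
class Diagnostic2x2:
    """TP/FP/FN/TN counts of one diagnostic accuracy study."""

    study_id: str
    tp: int
    fp: int
    fn: int
    tn: int
    sample_source: str | None = None
    method: str | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tp + self.fn < 1:
            raise ValueError("need at least one diseased subject (tp + fn >= 1)")
        if self.tn + self.fp < 1:
            raise ValueError("need at least one non-diseased subject (tn + fp >= 1)")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp


class SensSpec(NamedTuple):
    se: float
    sp: float
    var_logit_se: float
    var_logit_sp: float


def sens_spec(table: Diagnostic2x2, continuity: float = 0.5) -> SensSpec:
    """Sensitivity, specificity and logit-scale within-study variances.

    The continuity amount is added to all four cells only when the study
    has any zero cell (Haldane–Anscombe convention).
    """
    if continuity < 0:
        raise ValueError("continuity must be >= 0")
    tp, fp, fn, tn = (float(x) for x in (table.tp, table.fp, table.fn, table.tn))
    if min(tp, fp, fn, tn) == 0:
        tp += continuity
        fp += continuity
        fn += continuity
        tn += continuity
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    return SensSpec(se, sp, 1.0 / tp + 1.0 / fn, 1.0 / tn + 1.0 / fp)


@dataclass(frozen=True)
class BivariateFit:
    """Maximum-likelihood fit of the bivariate random-effects model.

    ``tau_cov`` is the between-study covariance of (logit se, logit sp);
    it is typically negative for a threshold-like trade-off.
    """

    mu_se: float
    mu_sp: float
    tau2_se: float
    tau2_sp: float
    tau_cov: float
    pooled_se: float
    pooled_sp: float
    ci_se: tuple[float, float]
    ci_sp: tuple[float, float]
    loglik: float
    converged: bool
    boundary: bool
    n_studies: int

    def __post_init__(self) -> None:
        if self.tau2_se < 0 or self.tau2_sp < 0:
            raise ValueError("between-study variances must be non-negative")
        if abs(self.tau_cov) > math.sqrt(self.tau2_se * self.tau2_sp) + 1e-12:
            raise ValueError("covariance violates positive semi-definiteness")


def _logit_data(
    studies: Sequence[Diagnostic2x2], continuity: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-study (logit se, logit sp) and within-study variances, (n,2) each."""
    y = np.empty((len(studies), 2))
    v = np.empty((len(studies), 2))
    for i, s in enumerate(studies):
        se, sp, vse, vsp = sens_spec(s, continuity)
        y[i] = (logit(se), logit(sp))
        v[i] = (vse, vsp)
    return y, v


def _nll(params: np.ndarray, y: np.ndarray, v: np.ndarray) -> float:
    mu1, mu2, lt1, lt2, z = params
    lt1 = np.clip(lt1, _LOGTAU_MIN, _LOGTAU_MAX)
    lt2 = np.clip(lt2, _LOGTAU_MIN, _LOGTAU_MAX)
    t1, t2 = math.exp(lt1), math.exp(lt2)
    rho = math.tanh(z)
    cov = rho * math.sqrt(t1 * t2)
    v11 = t1 + v[:, 0]
    v22 = t2 + v[:, 1]
    det = v11 * v22 - cov * cov
    if np.any(det <= 0):
        return 1e12
    r1 = y[:, 0] - mu1
    r2 = y[:, 1] - mu2
    quad = (r1 * r1 * v22 - 2.0 * r1 * r2 * cov + r2 * r2 * v11) / det
    return float(0.5 * np.sum(np.log(det) + quad) + y.shape[0] * math.log(2 * math.pi))


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


def fit_bivariate(
    studies: Sequence[Diagnostic2x2], continuity: float = 0.5
) -> BivariateFit:
    """ML fit of the bivariate normal-approximation model.

    The covariance is parameterized through log-variances and an
    arctanh-correlation, so every iterate is positive-definite.  A
    Nelder–Mead search from a method-of-moments start is polished with
    L-BFGS-B; non-convergence and variance-boundary fits are flagged.
    """
    if len(studies) < 2:
        raise ValueError("need at least two studies")
    y, v = _logit_data(studies, continuity)

    # method-of-moments start
    mu0 = y.mean(axis=0)
    resvar = np.maximum(y.var(axis=0, ddof=1) - v.mean(axis=0), 1e-4)
    x0 = np.array([mu0[0], mu0[1], math.log(resvar[0]), math.log(resvar[1]), 0.0])

    nm = optimize.minimize(
        _nll, x0, args=(y, v), method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12},
    )
    bounds = [(None, None), (None, None), (_LOGTAU_MIN, _LOGTAU_MAX),
              (_LOGTAU_MIN, _LOGTAU_MAX), (-10.0, 10.0)]
    lb = optimize.minimize(_nll, nm.x, args=(y, v), method="L-BFGS-B", bounds=bounds)
    best = lb if lb.fun <= nm.fun else nm

    mu1, mu2, lt1, lt2, z = best.x
    lt1 = float(np.clip(lt1, _LOGTAU_MIN, _LOGTAU_MAX))
    lt2 = float(np.clip(lt2, _LOGTAU_MIN, _LOGTAU_MAX))
    boundary = lt1 < _BOUNDARY_LOGTAU or lt2 < _BOUNDARY_LOGTAU
    t1 = 0.0 if lt1 < _BOUNDARY_LOGTAU else math.exp(lt1)
    t2 = 0.0 if lt2 < _BOUNDARY_LOGTAU else math.exp(lt2)
    cov = math.tanh(z) * math.sqrt(t1 * t2)

    # Wald CIs for the pooled proportions via the numeric Hessian of the nll
    se_mu = np.full(2, np.nan)
    try:
        H = _numeric_hessian(lambda p: _nll(p, y, v), best.x)
        cov_params = np.linalg.pinv(H)
        d = np.diag(cov_params)[:2]
        se_mu = np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        pass
    zcrit = stats.norm.ppf(0.975)

    def ci(mu: float, s: float) -> tuple[float, float]:
        if not np.isfinite(s):
            return (float("nan"), float("nan"))
        return (float(expit(mu - zcrit * s)), float(expit(mu + zcrit * s)))

    return BivariateFit(
        mu_se=float(mu1),
        mu_sp=float(mu2),
        tau2_se=t1,
        tau2_sp=t2,
        tau_cov=cov,
        pooled_se=float(expit(mu1)),
        pooled_sp=float(expit(mu2)),
        ci_se=ci(mu1, se_mu[0]),
        ci_sp=ci(mu2, se_mu[1]),
        loglik=-float(best.fun),
        converged=bool(best.success or np.isfinite(best.fun)),
        boundary=boundary,
        n_studies=len(studies),
    )


def _sroc_tpr(fit: BivariateFit, fpr: np.ndarray) -> np.ndarray:
    """Conditional-expectation summary ROC: E[logit se | logit sp = -logit f].

    With ``tau_cov`` the covariance of (logit se, logit sp), conditioning
    on logit(sp) = -logit(fpr) gives
    ``logit TPR = mu_se - (tau_cov / tau2_sp) * (logit(fpr) + mu_sp)``.
    A zero ``tau2_sp`` degenerates to the horizontal line at pooled se.
    """
    if fit.tau2_sp <= 0:
        return np.full_like(fpr, fit.pooled_se, dtype=float)
    slope = -fit.tau_cov / fit.tau2_sp
    return expit(fit.mu_se + slope * (logit(fpr) + fit.mu_sp))


def sroc_curve(fit: BivariateFit, n_points: int = 2001) -> pd.DataFrame:
    """Grid of (FPR, TPR) points along the summary ROC curve."""
    fpr = np.linspace(0.0005, 0.9995, n_points)
    return pd.DataFrame({"fpr": fpr, "tpr": _sroc_tpr(fit, fpr)})


def sroc_auc(
    fit: BivariateFit,
    n_points: int = 2001,
    fpr_range: str | tuple[float, float] = "full",
    studies: Sequence[Diagnostic2x2] | None = None,
    continuity: float = 0.5,
) -> float:
    """Area under the summary ROC curve by trapezoidal integration.

    ``fpr_range="full"`` integrates over [0, 1]: the interior uses a
    uniform grid of ``n_points`` on [0.0005, 0.9995] and the endpoints
    take the analytic limits of the curve.  ``"observed"`` integrates
    (unnormalized) over the observed per-study FPR range and requires
    ``studies``.  The result is clamped to [0, 1].
    """
    if fpr_range == "full":
        fpr = np.linspace(0.0005, 0.9995, n_points)
        tpr = _sroc_tpr(fit, fpr)
        slope = 0.0 if fit.tau2_sp <= 0 else -fit.tau_cov / fit.tau2_sp
        if slope > 0:
            t0, t1 = 0.0, 1.0
        elif slope < 0:
            t0, t1 = 1.0, 0.0
        else:
            t0 = t1 = tpr[0]
        fpr = np.concatenate(([0.0], fpr, [1.0]))
        tpr = np.concatenate(([t0], tpr, [t1]))
    elif fpr_range == "observed":
        if studies is None:
            raise ValueError("observed-range AUC needs the study tables")
        fprs = [1.0 - sens_spec(s, continuity).sp for s in studies]
        lo, hi = min(fprs), max(fprs)
        if hi <= lo:
            return 0.0
        fpr = np.linspace(lo, hi, n_points)
        tpr = _sroc_tpr(fit, fpr)
    else:
        lo, hi = fpr_range  # explicit (lo, hi) tuple
        fpr = np.linspace(lo, hi, n_points)
        tpr = _sroc_tpr(fit, fpr)
    auc = float(np.trapezoid(tpr, fpr))
    return min(1.0, max(0.0, auc))


@dataclass(frozen=True)
class DeeksResult:
    slope: float
    slope_se: float
    intercept: float
    t_statistic: float
    p_value: float
    n_studies: int
    ess: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def deeks_test(studies: Sequence[Diagnostic2x2], continuity: float = 0.5) -> DeeksResult:
    """Funnel-plot asymmetry regression of ln(DOR) on 1/sqrt(ESS).

    Weighted least squares with ESS weights, where
    ``ESS = 4 * n1 * n0 / (n1 + n0)`` uses the raw arm sizes and the
    diagnostic odds ratio uses continuity-corrected cells.  Two-sided
    t-test on the slope with n - 2 df; a zero-residual constant response
    is reported as slope 0 with p = 1 by convention.
    """
    if len(studies) < 3:
        raise ValueError("Deeks' test needs at least 3 studies")
    ess = np.array([4.0 * s.n_cases * s.n_controls / (s.n_cases + s.n_controls) for s in studies])
    ldor = np.empty(len(studies))
    for i, s in enumerate(studies):
        tp, fp, fn, tn = (float(x) for x in (s.tp, s.fp, s.fn, s.tn))
        if min(tp, fp, fn, tn) == 0:
            tp += continuity
            fp += continuity
            fn += continuity
            tn += continuity
        ldor[i] = math.log((tp * tn) / (fp * fn))
    x = 1.0 / np.sqrt(ess)
    w = ess
    if np.ptp(x) < 1e-12:
        raise ValueError("all effective sample sizes identical; asymmetry slope undefined")
    X = np.column_stack([np.ones_like(x), x])
    WX = X * w[:, None]
    beta = np.linalg.solve(X.T @ WX, WX.T @ ldor)
    resid = ldor - X @ beta
    df = len(studies) - 2
    s2 = float(resid @ (w * resid)) / df
    if s2 < 1e-14:  # degenerate perfect fit
        slope = float(beta[1])
        p = 1.0 if abs(slope) < 1e-12 else 0.0
        return DeeksResult(slope, 0.0, float(beta[0]), 0.0 if p == 1.0 else math.inf,
                           p, len(studies), tuple(ess.tolist()))
    cov = s2 * np.linalg.inv(X.T @ WX)
    slope_se = math.sqrt(cov[1, 1])
    t = float(beta[1]) / slope_se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return DeeksResult(float(beta[1]), slope_se, float(beta[0]), t, p,
                       len(studies), tuple(ess.tolist()))


@dataclass(frozen=True)
class ModelDiagnostics:
    chi2: float
    df: int
    chi2_per_df: float
    residual_skew: float
    residual_kurtosis: float
    max_abs_residual: float
    max_residual_study: str


def model_diagnostics(
    fit: BivariateFit, studies: Sequence[Diagnostic2x2], continuity: float = 0.5
) -> ModelDiagnostics:
    """Pearson-type goodness of fit against the fitted bivariate model.

    Each study's residual pair is whitened by its total (between +
    within) covariance; the chi-square statistic is the sum of squared
    whitened residuals with ``2n - 5`` degrees of freedom.  Skewness and
    excess kurtosis of the pooled whitened residuals summarize
    bivariate normality.
    """
    y, v = _logit_data(studies, continuity)
    mu = np.array([fit.mu_se, fit.mu_sp])
    Sigma = np.array([[fit.tau2_se, fit.tau_cov], [fit.tau_cov, fit.tau2_sp]])
    zs = []
    per_study = np.empty(len(studies))
    for i in range(len(studies)):
        V = Sigma + np.diag(v[i])
        L = np.linalg.cholesky(V)
        z = np.linalg.solve(L, y[i] - mu)
        zs.append(z)
        per_study[i] = np.abs(z).max()
    zs_flat = np.concatenate(zs)
    chi2 = float(np.sum(zs_flat**2))
    df = max(2 * len(studies) - 5, 1)
    imax = int(per_study.argmax())
    if np.allclose(zs_flat, 0.0):
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(zs_flat))
        kurt = float(stats.kurtosis(zs_flat))
    return ModelDiagnostics(
        chi2=chi2,
        df=df,
        chi2_per_df=chi2 / df,
        residual_skew=skew,
        residual_kurtosis=kurt,
        max_abs_residual=float(per_study[imax]),
        max_residual_study=studies[imax].study_id,
    )


def read_diagnostic_tables(path) -> list[Diagnostic2x2]:
    """Read studies from a TSV with columns study_id, tp, fp, fn, tn."""
    df = pd.read_csv(path, sep="\t", dtype={"study_id": str})
    return [
        Diagnostic2x2(
            study_id=str(row.study_id),
            tp=int(row.tp), fp=int(row.fp), fn=int(row.fn), tn=int(row.tn),
        )
        for row in df.itertuples()
    ]
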