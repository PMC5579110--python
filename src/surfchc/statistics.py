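"""Ensemble analysis of coarsening growth rates.

In the coarsening regime the characteristic length follows R_bar ~ t^alpha;
alpha is estimated per realization by ordinary least squares of ln R_bar
against ln t over a fit window.  Ensembles are summarized by mean, sample
standard deviation (n-1) and coefficient of variation, and the distribution
of alpha across realizations is fitted by a lognormal via maximum
likelihood on the logs, with a Kolmogorov-Smirnov test at the 5% level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .observables import TimeSeries

__all__ = ["GrowthFit", "EnsembleResult", "LognormalFit", "FIT_WINDOWS",
           "fit_growth_rate", "ensemble_stats", "fit_lognormal",
           "ensemble_envelope"]

# Default fit windows per study case (start, end), dimensionless time.
FIT_WINDOWS = {
    "sphere_default": (0.1, 10.0),
    "sphere_chc_degenerate": (0.1, 0.8),
    "dumbbell_ch_early": (0.02, 0.2),
    "dumbbell_ch_late": (1.0, 10.0),
    "dumbbell_chc": (0.1, 10.0),
}

MIN_WINDOW_SAMPLES = 10


@dataclass(frozen=True)
class GrowthFit:
    alpha: float
    window: tuple[float, float]
    residual: float        # rms residual of the log-log fit
    n_samples: int


@dataclass(frozen=True)
class EnsembleResult:
    alphas: tuple
    mean: float
    sd: float
    cv: float


@dataclass(frozen=True)
class LognormalFit:
    mu: float              # log-mean
    sigma_pdf: float       # log standard deviation (MLE, n denominator)
    ks_statistic: float
    ks_pvalue: float
    reject_at_5pct: bool

    @property
    def mean(self) -> float:
        """Mean of the fitted lognormal, exp(mu + sigma_pdf^2 / 2)."""
        return float(np.exp(self.mu + 0.5 * self.sigma_pdf**2))


def fit_growth_rate(series: TimeSeries,
                    window: tuple[float, float]) -> GrowthFit:
    """OLS slope of ln R_bar vs ln t over t in [t_lo, t_hi]."""
    t_lo, t_hi = window
    if not t_lo < t_hi:
        raise ValueError("window must satisfy t_lo < t_hi")
    t = np.asarray(series.t)
    r = np.asarray(series.r_bar)
    sel = (t >= t_lo) & (t <= t_hi) & np.isfinite(r)
    if np.any(t[sel] <= 0) or np.any(r[sel] <= 0):
        raise ValueError("growth fit requires positive t and R_bar")
    if sel.sum() < MIN_WINDOW_SAMPLES:
        raise ValueError(
            f"fit window contains {int(sel.sum())} samples; "
            f"at least {MIN_WINDOW_SAMPLES} required")
    x = np.log(t[sel])
    y = np.log(r[sel])
    slope, intercept = np.polyfit(x, y, 1)
    resid = float(np.sqrt(np.mean((y - slope * x - intercept) ** 2)))
    return GrowthFit(alpha=float(slope), window=(t_lo, t_hi),
                     residual=resid, n_samples=int(sel.sum()))


def ensemble_stats(alphas) -> EnsembleResult:
    """Sample mean, sd (n-1 denominator) and coefficient of variation."""
    a = np.asarray(list(alphas), dtype=float)
    if a.size == 0:
        raise ValueError("empty ensemble")
    mean = float(np.mean(a))
    sd = float(np.std(a, ddof=1)) if a.size > 1 else float("nan")
    cv = sd / mean if a.size > 1 else float("nan")
    return EnsembleResult(alphas=tuple(a), mean=mean, sd=sd, cv=cv)


def fit_lognormal(alphas, lilliefors: bool = False) -> LognormalFit:
    """MLE lognormal fit with a KS test of the sample against the fit.

    ``lilliefors=True`` replaces the parametric KS p-value by the
    Lilliefors test for normality of the logs (stricter, accounting for
    estimated parameters).
    """
    a = np.asarray(list(alphas), dtype=float)
    if a.size == 0 or np.any(a <= 0):
        raise ValueError("lognormal fit requires strictly positive samples")
    logs = np.log(a)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs, ddof=0))
    if sigma == 0:
        return LognormalFit(mu=mu, sigma_pdf=0.0, ks_statistic=np.nan,
                            ks_pvalue=np.nan, reject_at_5pct=False)
    ks = sps.kstest(a, sps.lognorm(s=sigma, scale=np.exp(mu)).cdf)
    stat, pval = float(ks.statistic), float(ks.pvalue)
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf
        stat, pval = (float(v) for v in _lf(logs, dist="norm"))
    return LognormalFit(mu=mu, sigma_pdf=sigma, ks_statistic=stat,
                        ks_pvalue=pval, reject_at_5pct=bool(pval < 0.05))


def ensemble_envelope(series_list) -> dict:
    """Pointwise min / mean / max of R_bar across realizations."""
    if not series_list:
        raise ValueError("empty ensemble")
    t0 = np.asarray(series_list[0].t)
    rs = []
    for s in series_list:
        if len(s.t) != len(t0) or not np.allclose(s.t, t0, rtol=1e-10):
            raise ValueError("realizations must share the time grid")
        rs.append(np.asarray(s.r_bar))
    R = np.vstack(rs)
    return {"t": t0, "min": np.nanmin(R, axis=0),
            "mean": np.nanmean(R, axis=0), "max": np.nanmax(R, axis=0)}
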