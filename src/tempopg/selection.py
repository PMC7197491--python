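"""Selection-coefficient inference from allele-frequency time series.

Under additive (genic) selection with no frequency dependence, the logit
of the focal-allele frequency declines linearly in time,

    zeta_t = ln[(1 - p_t)/p_t] = zeta_0 - mu_s * t,

so the negative slope of an ordinary least-squares regression of the
estimated zeta_t on generation estimates the mean per-generation
selection coefficient mu_s.  This module provides that estimator, its
closed-form sampling variance, the cruder two-point alternative, an
estimator for the among-generation variance sigma_s^2 of a fluctuating
selection coefficient, and survey-design calculators built on the same
variance formulas.

All estimators require every frequency estimate used to lie strictly
inside (0, 1); sites touching a boundary are dropped (regression) or
raise (single-site calculators) — pseudo-count smoothing would bias the
slope and is deliberately not offered.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_data import FreqSeries, harmonic_mean_n

__all__ = [
    "SelectionFit",
    "TwoPointResult",
    "SigmaS2Estimate",
    "DesignResult",
    "zeta",
    "fit_mu_s",
    "predicted_var_s",
    "two_point_s",
    "sparse_design",
    "interval_s_estimates",
    "estimate_sigma_s2",
    "detection_design",
    "round_sig",
]


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


def zeta(p):
    """Logit-scale transform zeta = ln[(1-p)/p].

    Antisymmetric about p = 0.5 (zeta(p) = -zeta(1-p)); undefined at the
    frequency boundaries.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("zeta is only defined for frequencies in (0, 1)")
    out = np.log((1.0 - p) / p)
    return float(out) if out.ndim == 0 else out


def _zeta_panel(p: np.ndarray):
    """Vectorized logit with a per-row validity mask (no exception)."""
    ok = np.all((p > 0.0) & (p < 1.0), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.log((1.0 - p) / p)
    return z, ok


@dataclass
class SelectionFit:
    """Regression estimate of the mean selection coefficient at one site."""

    s_hat: float
    se_ols: float
    se_pred: float
    T: int  # number of unit intervals spanned by the series
    n: float  # harmonic-mean sample size
    p0_hat: float
    zeta_series: np.ndarray | None = None
    dropped: bool = False


@dataclass
class TwoPointResult:
    """Endpoint-only estimate of s and its cost relative to a full survey.

    ``ratio_vs_full`` is the variance inflation of the two-point estimate
    over the full regression; ``min_se_gain`` = sqrt(T/6) is the floor on
    the SE improvement a full survey buys.
    """

    s_hat2: float
    var2: float
    ratio_vs_full: float
    min_se_gain: float
    T: int


@dataclass
class SigmaS2Estimate:
    """Decomposition sigma_s^2 = Var(s_hat) - Var(e) at one site.

    ``var_s_hat`` is the variance of the tau = T/2 non-overlapping
    interval estimates of s; ``var_e`` the closed-form average sampling
    variance of single-interval estimates.  A negative difference is
    returned as-is with ``negative_flag`` set, never clipped.
    """

    sigma_s2_hat: float
    var_s_hat: float
    var_e: float
    tau: int
    phi_series: np.ndarray
    negative_flag: bool


@dataclass
class DesignResult:
    """Output of a survey-design calculation; inputs echoed."""

    kind: str
    inputs: dict
    critical_T3n: float | None = None
    critical_T: float | None = None
    critical_T_rounded: float | None = None
    inflation_se: float | None = None
    extras: dict = field(default_factory=dict)


def predicted_var_s(T: int, n: float, p0: float, sigma_s2: float = 0.0) -> float:
    """Expected sampling variance of the regression estimate of mu_s.

        var(s_hat) = [6/((T-1)(T+1))] * [1/(T*n*p0*(1-p0)) + sigma_s2]

    ``T`` counts the equally spaced sampling points entering the
    regression; with that convention the leading term is exactly the OLS
    slope variance under binomial sampling noise (delta-method scale
    1/(2*n*p*q) per logit estimate for diploids).
    """
    if T < 2:
        raise ValueError("T must be at least 2")
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be inside (0, 1)")
    if sigma_s2 < 0:
        raise ValueError("sigma_s2 must be non-negative")
    return (6.0 / ((T - 1.0) * (T + 1.0))) * (
        1.0 / (T * n * p0 * (1.0 - p0)) + sigma_s2
    )


def _ols_slope_panel(t: np.ndarray, z: np.ndarray):
    """Closed-form OLS slope and residual-based slope SE, row-wise."""
    tbar = t.mean()
    tc = t - tbar
    S = np.sum(tc**2)
    slope = z @ tc / S
    fitted = z.mean(axis=-1, keepdims=True) + np.outer(slope, tc).reshape(z.shape)
    dof = t.size - 2
    if dof > 0:
        resid_var = np.sum((z - fitted) ** 2, axis=-1) / dof
        se = np.sqrt(resid_var / S)
    else:
        se = np.zeros(z.shape[:-1])
    return slope, se


def fit_mu_s(fs: FreqSeries, site: int = 0) -> SelectionFit:
    """OLS regression of the logit frequency on generation at one site.

    Returns ``s_hat = -slope`` (positive when the focal allele is
    favored), the residual-based SE, and the closed-form predicted SE.
    Any boundary frequency estimate makes the fit undefined
    (``dropped=True``).
    """
    p = fs.p_hat[site]
    t = fs.generations.astype(float)
    if t.size < 3:
        raise ValueError("regression requires at least 3 sampling points")
    n_h = harmonic_mean_n(fs.parent.sample_sizes[site])
    z, ok = _zeta_panel(p[None, :])
    if not ok[0]:
        return SelectionFit(
            s_hat=np.nan, se_ols=np.nan, se_pred=np.nan,
            T=t.size - 1, n=n_h, p0_hat=float(p[0]), dropped=True,
        )
    slope, se = _ols_slope_panel(t, z)
    se_pred = math.sqrt(predicted_var_s(t.size, n_h, float(p[0]), 0.0))
    return SelectionFit(
        s_hat=float(-slope[0]), se_ols=float(se[0]), se_pred=se_pred,
        T=t.size - 1, n=n_h, p0_hat=float(p[0]), zeta_series=z[0],
    )


def fit_mu_s_panel(fs: FreqSeries):
    """Vectorized per-site regression estimates of mu_s.

    Returns ``(s_hat, defined_mask)`` over all sites; boundary-touching
    sites are NaN with mask False.  The sampling variance of the mean of
    the defined estimates is the single-site variance divided by the
    number of sites pooled.
    """
    t = fs.generations.astype(float)
    z, ok = _zeta_panel(fs.p_hat)
    z = np.where(ok[:, None], z, 0.0)
    slope, _ = _ols_slope_panel(t, z)
    s = np.where(ok, -slope, np.nan)
    return s, ok


def two_point_s(fs: FreqSeries, site: int = 0) -> TwoPointResult:
    """Selection estimate from the first and last samples only."""
    p = fs.p_hat[site]
    t = fs.generations
    T = int(t[-1] - t[0])
    p0, pT = float(p[0]), float(p[-1])
    z0, zT = zeta(p0), zeta(pT)
    ns = fs.parent.sample_sizes[site][[0, -1]]
    n_h = harmonic_mean_n(ns)
    pq0, pqT = p0 * (1 - p0), pT * (1 - pT)
    var2 = (1.0 / (T**2 * n_h)) * (1.0 / pq0 + 1.0 / pqT)
    ratio = (T / 6.0) * (1.0 + pq0 / pqT)
    return TwoPointResult(
        s_hat2=(z0 - zT) / T, var2=float(var2), ratio_vs_full=float(ratio),
        min_se_gain=math.sqrt(T / 6.0), T=T,
    )


def sparse_design(
    T_prime: int, D: int, T_full: int, n: float = 100.0, p0: float = 0.5
) -> DesignResult:
    """SE inflation of a sparse survey (T' samples D generations apart).

    The sparse variance is the full-survey formula evaluated at T' with
    the slope taken per true generation (leading term divided by D^2);
    the inflation is relative to a dense survey of T_full samples.
    """
    if T_prime < 2 or D < 1:
        raise ValueError("T_prime must be >= 2 and D >= 1")
    var_sparse = predicted_var_s(T_prime, n, p0) / D**2
    var_full = predicted_var_s(T_full, n, p0)
    infl = math.sqrt(var_sparse / var_full)
    return DesignResult(
        kind="sparse_design",
        inputs={"T_prime": T_prime, "D": D, "T_full": T_full, "n": n, "p0": p0},
        inflation_se=infl,
        extras={"var_sparse": var_sparse, "var_full": var_full},
    )


def interval_s_estimates(fs: FreqSeries, site: int = 0) -> np.ndarray:
    """Per-interval selection estimates s_i = zeta_i - zeta_{i+1}.

    Intervals with a boundary frequency at either endpoint are NaN.
    """
    p = fs.p_hat[site]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.log((1.0 - p) / p)
    s = z[:-1] - z[1:]
    bad = ~(np.isfinite(z[:-1]) & np.isfinite(z[1:]))
    s = np.where(bad, np.nan, s)
    return s


def _sigma_s2_panel(p: np.ndarray, n: np.ndarray, ploidy: int):
    """Vectorized sigma_s^2 decomposition over rows of a frequency panel.

    Expects an even number of intervals; returns (var_s, var_e, sigma2,
    ok_mask) with NaN where a row touches a frequency boundary.
    """
    Tn = p.shape[-1] - 1  # intervals
    if Tn % 2 or Tn < 4:
        raise ValueError("an even number of intervals T >= 4 is required")
    z, ok = _zeta_panel(p)
    zs = np.where(ok[:, None], z, 0.5)  # placeholder; masked later
    # variance of the tau = T/2 non-overlapping single-generation
    # intervals (0,1),(2,3),...
    tau = Tn // 2
    idx = 2 * np.arange(tau)
    s_i = zs[:, idx] - zs[:, idx + 1]
    var_s = np.var(s_i, axis=-1, ddof=1)
    # closed-form average sampling variance from phi_t = 1/(ploidy*n_t*p*q)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = 1.0 / (ploidy * n * p * (1.0 - p))
    phi_m = np.where(ok[:, None], phi, np.nan)
    inner = phi_m[:, 1:Tn].sum(axis=-1)
    var_e = (phi_m[:, 0] + phi_m[:, Tn] + (2.0 * Tn / (Tn - 1.0)) * inner) / Tn
    sigma2 = np.where(ok, var_s - var_e, np.nan)
    var_s = np.where(ok, var_s, np.nan)
    return var_s, var_e, sigma2, ok, phi_m


def estimate_sigma_s2(fs: FreqSeries, site: int = 0) -> SigmaS2Estimate:
    """Among-generation variance of the selection coefficient at one site.

    ``Var(s_hat)`` comes from the non-overlapping interval estimates
    (0,1),(2,3),...,(T-2,T-1); ``Var(e)`` is the closed-form average
    sampling variance using all T single-generation estimates and their
    shared-sample covariances.  Odd T drops the final sample with a
    warning.  The difference may be negative (flagged, not clipped).
    """
    p = fs.p_hat[site][None, :]
    n = fs.parent.sample_sizes[site][None, :]
    Tn = p.shape[-1] - 1
    if Tn % 2:
        warnings.warn(
            f"odd number of intervals T={Tn}; dropping the final sample",
            stacklevel=2,
        )
        p, n, Tn = p[:, :-1], n[:, :-1], Tn - 1
    if Tn < 4:
        raise ValueError("sigma_s^2 estimation requires T >= 4 intervals")
    var_s, var_e, sigma2, ok, phi = _sigma_s2_panel(p, n, fs.parent.ploidy)
    if not ok[0]:
        raise ValueError(
            "sigma_s^2 estimate undefined: a frequency estimate is 0 or 1"
        )
    return SigmaS2Estimate(
        sigma_s2_hat=float(sigma2[0]), var_s_hat=float(var_s[0]),
        var_e=float(var_e[0]), tau=Tn // 2, phi_series=phi[0],
        negative_flag=bool(sigma2[0] < 0),
    )


def detection_design(mu_s: float, p0: float = 0.5, n: float = 100.0) -> DesignResult:
    """Survey size needed to detect a mean selection coefficient mu_s.

    Sets the two-sided 5% detection condition 24/[T^3 n p0(1-p0)] <
    mu_s^2 (from the minimum sampling variance 6/[T^3 n p0(1-p0)]), and
    reports the critical T^3*n product and the implied duration T for the
    given n, both raw and rounded to two significant figures.
    """
    if mu_s <= 0:
        raise ValueError("mu_s must be positive")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be inside (0, 1)")
    if n < 1:
        raise ValueError("n must be at least 1")
    t3n = 24.0 / (p0 * (1.0 - p0) * mu_s**2)
    T = (t3n / n) ** (1.0 / 3.0)
    return DesignResult(
        kind="detect_s",
        inputs={"mu_s": mu_s, "p0": p0, "n": n},
        critical_T3n=t3n, critical_T=T, critical_T_rounded=round_sig(T, 2),
    )
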