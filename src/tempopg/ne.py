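"""Temporal method-of-moments estimation of effective population size.

Drift moves a neutral allele frequency by a variance p(1-p)/(2*Ne) per
generation (diploids).  The squared frequency change between two samples
t generations apart, standardized by pbar(1-pbar) and corrected for the
binomial noise of sampling n individuals at each time point,

    phi = F_hat - 1/(2*n_j) - 1/(2*n_k),
    F_hat = (p_hat_j - p_hat_k)^2 / [pbar(1-pbar)],

has expectation ~ t/(2*Ne) for t << 2*Ne.  Averaging phi across L
independent sites *before* taking the ratio gives the moment estimator

    Ne_hat = t / (2 * phi_bar),

whose closed-form sampling variance and CV drive the design calculators
here.  Sites fixed at both samples carry no information (F_hat is 0/0)
and are excluded; a non-positive phi_bar — expected whenever the drift
signal is below the sampling-noise floor — yields a flagged undefined
estimate rather than a negative Ne.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import FreqSeries, harmonic_mean_n

__all__ = [
    "NeEstimate",
    "MultiIntervalNe",
    "f_hat",
    "phi",
    "estimate_ne",
    "predicted_var_ne",
    "predicted_cv_ne",
    "design_tn",
    "multi_interval_ne",
]


@dataclass
class NeEstimate:
    """Method-of-moments Ne from one pair of temporal samples."""

    ne_hat: float  # NaN when undefined (phi_bar <= 0)
    phi_bar: float
    t: float  # generations between the two samples (includes interval D)
    L: int  # sites actually used
    n_harmonic: float
    predicted_var: float
    predicted_cv: float
    dropped_sites: int
    defined: bool
    warnings: list[str] = field(default_factory=list)


@dataclass
class MultiIntervalNe:
    """Per-subinterval Ne estimates under a multi-sample scheme.

    The expected sampling SDs of the pooled estimates under the three
    canonical six-sample schemes (endpoints / halves / thirds) scale
    roughly as 1.0 : 1.4 : 1.7, and the halves/thirds pooled means are
    biased low relative to the endpoints estimate.
    """

    scheme: str
    estimates: list[NeEstimate]
    pooled_mean: float
    n_defined: int


def f_hat(p_j, p_k):
    """Standardized squared frequency change (p_j-p_k)^2/[pbar(1-pbar)].

    Symmetric in its arguments; undefined (NaN) when the mean frequency
    is 0 or 1, i.e. the site is fixed in both samples.
    """
    p_j = np.asarray(p_j, dtype=float)
    p_k = np.asarray(p_k, dtype=float)
    pbar = 0.5 * (p_j + p_k)
    denom = pbar * (1.0 - pbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, (p_j - p_k) ** 2 / denom, np.nan)
    return float(out) if out.ndim == 0 else out


def phi(fhat, n_j, n_k, ploidy: int = 2):
    """Drift signal: F_hat minus the two binomial-sampling corrections."""
    corr = 1.0 / (ploidy * np.asarray(n_j, float)) + 1.0 / (
        ploidy * np.asarray(n_k, float)
    )
    out = np.asarray(fhat, float) - corr
    return float(out) if out.ndim == 0 else out


def _phi_panel(p, n, ploidy, j, k):
    """Per-site phi values between sampling-point columns j and k."""
    fh = f_hat(p[..., j], p[..., k])
    ph = phi(fh, n[..., j], n[..., k], ploidy)
    return ph, np.isfinite(fh)


def estimate_ne(fs: FreqSeries, time_j: int = 0, time_k: int = -1) -> NeEstimate:
    """Two-sample moment estimate of Ne from sampling points j and k.

    ``time_j``/``time_k`` index the sampling points.  phi is averaged
    across usable sites before the ratio (never per-site Ne values).
    The elapsed time multiplies the metadata interval length D, so the
    returned Ne is on the true-generation scale.
    """
    tc = fs.parent
    j = int(np.arange(tc.generations.size)[time_j])
    k = int(np.arange(tc.generations.size)[time_k])
    if tc.generations[k] <= tc.generations[j]:
        raise ValueError("time_k must be later than time_j")
    t = float(tc.generations[k] - tc.generations[j]) * tc.interval
    ph, ok = _phi_panel(fs.p_hat, tc.sample_sizes, tc.ploidy, j, k)
    L = int(ok.sum())
    dropped = ph.size - L
    if L < 1:
        raise ValueError("no usable sites: all fixed at both sampling points")
    phi_bar = float(np.mean(ph[ok]))
    n_h = harmonic_mean_n(tc.sample_sizes[:, [j, k]])
    notes = []
    if phi_bar <= 0:
        notes.append(
            "mean drift signal phi_bar <= 0: drift is below the "
            "sampling-noise floor; Ne is undefined"
        )
        return NeEstimate(
            ne_hat=np.nan, phi_bar=phi_bar, t=t, L=L, n_harmonic=n_h,
            predicted_var=np.nan, predicted_cv=np.nan,
            dropped_sites=dropped, defined=False, warnings=notes,
        )
    ne = t / (2.0 * phi_bar)
    var = predicted_var_ne(ne, L, t, n_h)
    return NeEstimate(
        ne_hat=ne, phi_bar=phi_bar, t=t, L=L, n_harmonic=n_h,
        predicted_var=var, predicted_cv=np.sqrt(var) / ne,
        dropped_sites=dropped, defined=True, warnings=notes,
    )


def predicted_var_ne(
    Ne: float, L: int, t: float, n_harmonic: float,
    N_census: float | None = None, full: bool = False,
) -> float:
    """Expected sampling variance of the moment estimate of Ne.

    Reduced form (default): (2/L) * (2*Ne^2/(t*n))^2 — valid when the
    per-sample noise term dominates, i.e. t*n << 2*Ne.  The full form
    keeps the drift and census-sampling terms:
    (8*Ne^4/L) * [1/(2*Ne)^2 + 1/(t*N*n) + 1/(t*n)^2].
    """
    if min(Ne, L, t, n_harmonic) <= 0:
        raise ValueError("all arguments must be positive")
    tn = t * n_harmonic
    if full:
        if N_census is None or N_census <= 0:
            raise ValueError("full=True requires a positive N_census")
        return (8.0 * Ne**4 / L) * (
            1.0 / (2.0 * Ne) ** 2 + 1.0 / (tn * N_census) + 1.0 / tn**2
        )
    return (2.0 / L) * (2.0 * Ne**2 / tn) ** 2


def predicted_cv_ne(Ne: float, L: int, t: float, n_harmonic: float) -> float:
    """CV of the Ne estimate under the reduced variance form."""
    return float(np.sqrt(predicted_var_ne(Ne, L, t, n_harmonic)) / Ne)


def design_tn(Ne: float, L: float, cv_target: float = 0.1) -> dict:
    """Critical product t*n needed to reach a target CV for Ne.

    Inverts the CV formula: t*n > 2*Ne*sqrt(2/L)/cv_target.  Also
    reports the field's rounded rule of thumb for cv_target = 0.1,
    0.035*t*n*sqrt(L) > Ne, i.e. t*n > Ne/(0.035*sqrt(L)).
    """
    if min(Ne, L, cv_target) <= 0:
        raise ValueError("all arguments must be positive")
    exact = 2.0 * Ne * np.sqrt(2.0 / L) / cv_target
    thumb = Ne / (0.035 * np.sqrt(L))
    return {
        "critical_tn": float(exact),
        "rule_of_thumb_tn": float(thumb),
        "inputs": {"Ne": Ne, "L": L, "cv_target": cv_target},
    }


_SCHEMES = {
    "endpoints": None,  # (first, last), any layout
    "halves": [(0, 2), (3, 5)],
    "thirds": [(0, 1), (2, 3), (4, 5)],
}


def multi_interval_ne(fs: FreqSeries, scheme: str = "endpoints") -> MultiIntervalNe:
    """Ne from sub-interval analyses of a six-sample survey.

    ``endpoints`` contrasts the first and last samples (works for any
    number of samples, reducing to :func:`estimate_ne`); ``halves``
    performs two two-generation analyses on samples (0,2) and (3,5);
    ``thirds`` three single-generation analyses on (0,1), (2,3), (4,5).
    The pooled value is the plain mean of the defined estimates.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    n_samples = fs.generations.size
    if scheme == "endpoints":
        pairs = [(0, n_samples - 1)]
    else:
        if n_samples < 6:
            raise ValueError(f"scheme {scheme!r} requires 6 sampling points")
        pairs = _SCHEMES[scheme]
    ests = [estimate_ne(fs, j, k) for j, k in pairs]
    vals = [e.ne_hat for e in ests if e.defined]
    pooled = float(np.mean(vals)) if vals else np.nan
    return MultiIntervalNe(
        scheme=scheme, estimates=ests, pooled_mean=pooled, n_defined=len(vals)
    )
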