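"""Tests of whether allele-frequency time series are consistent with drift.

Under pure genetic drift the true per-interval frequency changes at a
neutral site are uncorrelated.  Three covariance statistics probe this:

* **scheme 1** — within one site, pair every change with the change two
  intervals later (maximal use of the data; expectation slightly negative
  because sampling points are reused),
* **scheme 2** — within one site, fully disjoint pairings (unbiased, but
  a survey of the same length yields fewer pairs),
* **genome-wide** — across L sites, the covariance of the changes in two
  non-overlapping time intervals.

The genome-wide statistic applied to *standardized* changes (each change
divided by its binomial-sampling SD) has null expectation 0 and variance
1/L, giving a simple two-sided z test with 5% critical value 1.96/sqrt(L).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .core_data import DeltaSeries, harmonic_mean_n

__all__ = [
    "DriftCovResult",
    "NullCovDistribution",
    "InsufficientDataError",
    "cov_scheme1",
    "cov_scheme2",
    "cov_genomewide",
    "standardized_cov_test",
    "scheme1_expected_bias",
    "expected_cov_se",
    "null_cov_pdf",
]


class InsufficientDataError(ValueError):
    """Too few sampling points or sites for the requested statistic."""


@dataclass
class DriftCovResult:
    """A covariance-of-changes estimate with its null calibration.

    ``estimate`` is the unbiased m/(m-1) sample covariance; ``z`` is the
    estimate standardized by its expected null SE (after subtracting the
    closed-form neutral expectation where one exists), and ``p_value`` the
    two-sided normal tail probability.
    """

    scheme: str
    estimate: float
    m: int
    L: int
    expected_se: float
    expected_bias: float | None
    z: float
    p_value: float
    reject: bool | None = None
    alpha: float | None = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class NullCovDistribution:
    """Null sampling distribution of v = L * cov(standardized changes).

    ``student_like`` is the heavy-tailed small-L form (variance L-1, exact
    to four moments under the null); ``gaussian`` is the large-L normal
    limit with variance L.
    """

    L: int
    form: str = "student_like"

    @property
    def variance(self) -> float:
        return float(self.L - 1 if self.form == "student_like" else self.L)

    def pdf(self, v):
        return null_cov_pdf(v, self.L, self.form)


def _cov_unbiased(x: np.ndarray, y: np.ndarray) -> float:
    """Unbiased sample covariance m*(mean(xy) - mean(x)mean(y))/(m-1)."""
    m = x.size
    return float(m * (np.mean(x * y) - x.mean() * y.mean()) / (m - 1))


def scheme1_expected_bias(p0: float, T: int, Ne: float, exact: bool = False) -> float:
    """Neutral expectation of the scheme-1 covariance (slightly negative).

    The exact form sums the per-generation heterozygosity decay
    lambda^i with lambda = 1 - 1/(2*Ne) over the interior intervals; the
    approximate form replaces the sum by T-4 (valid for Ne >> T).
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be strictly inside (0, 1)")
    if T < 3:
        raise ValueError("T must be at least 3")
    if Ne <= 0:
        raise ValueError("Ne must be positive")
    pq = p0 * (1.0 - p0)
    denom = 2.0 * (T - 3) * (T - 2) * Ne
    if exact:
        lam = 1.0 - 1.0 / (2.0 * Ne)
        i = np.arange(2, T - 2)  # i = 2 .. T-3
        return float(-pq * np.sum(lam**i) / denom)
    return float(-pq * (T - 4) / denom)


def expected_cov_se(scheme: str, pq_bar: float, n: float, L: int, m: int) -> float:
    """Closed-form null SE of a covariance-of-changes statistic.

    ``m`` is the number of paired comparisons (scheme 1: m = T-2,
    scheme 2: m = (T+1)/4); it is ignored for the genome-wide scheme,
    which behaves like a disjoint two-interval comparison (m = 2).
    """
    if pq_bar <= 0 or n <= 0 or L < 1:
        raise ValueError("pq_bar, n must be positive and L >= 1")
    if scheme == "genomewide":
        return float(pq_bar / (n * np.sqrt(L)))
    if m < 2:
        raise ValueError("at least m = 2 paired comparisons are required")
    if scheme == "scheme2":
        return float(pq_bar / (n * np.sqrt(L * (m - 1))))
    if scheme == "scheme1":
        return float(pq_bar / (n * np.sqrt(L * (m - 1) / 2.0)))
    raise ValueError(f"unknown scheme {scheme!r}")


def _site_pq_and_n(ds: DeltaSeries, site: int):
    fs = ds.parent
    p0 = fs.p_hat[site, 0]
    n_h = harmonic_mean_n(fs.parent.sample_sizes[site])
    return p0 * (1.0 - p0), n_h


def _finish_site_result(scheme, est, m, pq, n_h, bias):
    se = expected_cov_se(scheme, pq, n_h, 1, m) if pq > 0 else np.nan
    center = bias if bias is not None else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (est - center) / se
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return se, z, p


def cov_scheme1(ds: DeltaSeries, site: int = 0, Ne: float | None = None) -> DriftCovResult:
    """Scheme-1 covariance at one site: pairs (D_t, D_{t+2}), t = 0..T-3.

    When ``Ne`` is supplied the small negative neutral expectation is
    evaluated and subtracted before standardizing.
    """
    d = ds.deltas[site]
    T = d.size
    if T < 5:
        raise InsufficientDataError(
            f"scheme 1 requires T >= 5 intervals (m >= 3 pairs), got T={T}"
        )
    m = T - 2
    x, y = d[: T - 2], d[2:T]
    est = _cov_unbiased(x, y)
    pq, n_h = _site_pq_and_n(ds, site)
    bias = None
    if Ne is not None:
        p0 = ds.parent.p_hat[site, 0]
        bias = scheme1_expected_bias(p0, T, Ne, exact=True) if 0 < p0 < 1 else None
    se, z, p = _finish_site_result("scheme1", est, m, pq, n_h, bias)
    return DriftCovResult(
        scheme="scheme1", estimate=est, m=m, L=1, expected_se=se,
        expected_bias=bias, z=z, p_value=p,
    )


def cov_scheme2(ds: DeltaSeries, site: int = 0) -> DriftCovResult:
    """Scheme-2 covariance at one site: disjoint pairs (D_{4i}, D_{4i+2}).

    When the number of sampling points T+1 is not divisible by 4 the
    maximal prefix is used and a warning is recorded.
    """
    d = ds.deltas[site]
    T = d.size
    m = (T + 1) // 4
    if m < 2:
        raise InsufficientDataError(
            f"scheme 2 requires T >= 7 intervals (m >= 2 disjoint pairs), got T={T}"
        )
    notes = []
    if (T + 1) % 4 != 0:
        msg = (
            f"T+1 = {T + 1} sampling points not divisible by 4; "
            f"using the first {m} disjoint pairs"
        )
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
    i = 4 * np.arange(m)
    est = _cov_unbiased(d[i], d[i + 2])
    pq, n_h = _site_pq_and_n(ds, site)
    se, z, p = _finish_site_result("scheme2", est, m, pq, n_h, None)
    return DriftCovResult(
        scheme="scheme2", estimate=est, m=m, L=1, expected_se=se,
        expected_bias=0.0, z=z, p_value=p, warnings=notes,
    )


def _check_disjoint(interval_j, interval_k):
    j0, j1 = interval_j
    k0, k1 = interval_k
    if j0 >= j1 or k0 >= k1:
        raise ValueError("intervals must be ordered (t0, t1) with t0 < t1")
    if {j0, j1} & {k0, k1}:
        raise ValueError(
            f"intervals {interval_j} and {interval_k} share a sampling "
            f"time point; the covariance test requires disjoint samples"
        )
    return j0, j1, k0, k1


def cov_genomewide(ds: DeltaSeries, interval_j, interval_k) -> DriftCovResult:
    """Across-site covariance of the changes in two disjoint intervals."""
    j0, j1, k0, k1 = _check_disjoint(interval_j, interval_k)
    p = ds.parent.p_hat
    L = p.shape[0]
    if L < 2:
        raise InsufficientDataError("genome-wide covariance requires L >= 2 sites")
    dj = p[:, j1] - p[:, j0]
    dk = p[:, k1] - p[:, k0]
    est = _cov_unbiased(dj, dk)
    pq = float(np.mean(p[:, j0] * (1.0 - p[:, j0])))
    n_h = harmonic_mean_n(ds.parent.parent.sample_sizes)
    se = expected_cov_se("genomewide", pq, n_h, L, 2) if pq > 0 else np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        z = est / se
    pval = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return DriftCovResult(
        scheme="genomewide", estimate=est, m=2, L=L, expected_se=se,
        expected_bias=0.0, z=z, p_value=pval,
    )


def _standardized_changes(p, n, ploidy, t0, t1):
    """Vectorized standardized change between sampling points t0 and t1.

    Returns (std_change, defined_mask); the change is divided by the
    two-sample binomial SD evaluated at the interval-mean frequency.
    """
    d = p[..., t1] - p[..., t0]
    pbar = 0.5 * (p[..., t0] + p[..., t1])
    var = pbar * (1.0 - pbar) * (
        1.0 / (ploidy * n[..., t0]) + 1.0 / (ploidy * n[..., t1])
    )
    ok = var > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(ok, d / np.sqrt(var), np.nan), ok


def standardized_cov_test(
    ds: DeltaSeries,
    interval_j,
    interval_k,
    alpha: float = 0.05,
    effective_L: int | None = None,
) -> DriftCovResult:
    """Genome-wide drift test on standardized changes of two intervals.

    The statistic is the across-site sample covariance of the two
    standardized changes; under neutrality it has expectation 0 and
    variance 1/L, so ``z = estimate * sqrt(L)`` is compared with the
    standard normal.  Sites whose standardization is undefined (interval
    mean frequency 0 or 1) are dropped and L reduced; ``effective_L``
    overrides the degrees of freedom when sites are linked.
    """
    j0, j1, k0, k1 = _check_disjoint(interval_j, interval_k)
    fs = ds.parent
    p, n, c = fs.p_hat, fs.parent.sample_sizes, fs.parent.ploidy
    sj, okj = _standardized_changes(p, n, c, j0, j1)
    sk, okk = _standardized_changes(p, n, c, k0, k1)
    keep = okj & okk
    L_used = int(keep.sum())
    if L_used < 2:
        raise InsufficientDataError(
            f"only {L_used} sites have defined standardized changes"
        )
    notes = []
    dropped = p.shape[0] - L_used
    if dropped:
        notes.append(f"dropped {dropped} sites with undefined standardization")
    est = _cov_unbiased(sj[keep], sk[keep])
    L_eff = int(effective_L) if effective_L is not None else L_used
    se = 1.0 / np.sqrt(L_eff)
    z = est / se
    pval = float(2.0 * stats.norm.sf(abs(z)))
    return DriftCovResult(
        scheme="genomewide", estimate=est, m=2, L=L_eff, expected_se=se,
        expected_bias=0.0, z=z, p_value=pval, reject=bool(pval < alpha),
        alpha=alpha, warnings=notes,
    )


def null_cov_pdf(v, L: int, form: str = "student_like"):
    """Null density of the standardized covariance v = L * cov(x', y').

    ``gaussian``: N(0, L).  ``student_like``: the four-moment-exact
    small-L form, a symmetric heavy-tailed density with variance L-1,
    evaluated in log space via log-gamma for numerical stability.
    """
    if L < 2:
        raise ValueError("L must be at least 2")
    v = np.asarray(v, dtype=float)
    if form == "gaussian":
        return stats.norm.pdf(v, scale=np.sqrt(L))
    if form != "student_like":
        raise ValueError(f"unknown form {form!r}")
    a = (L + 4) / 2.0
    log_norm = (
        special.gammaln(a)
        - special.gammaln((L + 3) / 2.0)
        - 0.5 * np.log(np.pi * (L**2 - 1.0))
    )
    return np.exp(log_norm - a * np.log1p(v**2 / (L**2 - 1.0)))
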