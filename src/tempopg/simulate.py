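"""Wright-Fisher simulation of allele-frequency time series.

Each generation applies a deterministic additive (genic) selection update

    p* = p (1 + s_t) / (1 + p s_t),

followed by drift as binomial sampling of ploidy*Ne gene copies at p*.
Under this haploid/genic form the logit frequency declines by exactly
ln(1 + s) per generation, so the regression estimator recovers ln(1 + s)
on noiseless trajectories.  A fluctuating selection coefficient is drawn
each generation from a Gaussian with mean mu_s and variance sigma_s2
(no autocorrelation), truncated at -0.99 to keep fitness positive;
truncation events are counted and should be a negligible fraction of
draws.  Individual sampling draws binomial(ploidy*n, p_true) copies at
each retained time point.

:func:`run_experiment` packages the validation studies used to calibrate
the estimators in this package (regression-slope bias and SD, the
sigma_s^2 estimator, the moment Ne estimator and its multi-interval
variants, and the null behavior of the standardized covariance test) at
replication counts sized for a single CPU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ne as ne_mod
from .core_data import TemporalCounts
from .drift_test import _cov_unbiased, _standardized_changes
from .selection import _ols_slope_panel, _sigma_s2_panel, _zeta_panel, predicted_var_s

__all__ = ["WFConfig", "Trajectory", "simulate_trajectory", "sample_series",
           "simulate_panel", "run_experiment", "EXPERIMENTS"]

_S_TRUNC = -0.99


@dataclass(frozen=True)
class WFConfig:
    """Configuration of a Wright-Fisher simulation run.

    ``T`` is the number of generations evolved; time points 0..T are
    retained every ``sample_every`` (=D) generations.  ``p0_range``
    switches the initial frequency from the fixed ``p0`` to a uniform
    draw per site.  A seed is mandatory: every run is reproducible.
    """

    ne: float
    p0: float
    T: int
    n: int
    mu_s: float = 0.0
    sigma_s2: float = 0.0
    L: int = 1
    ploidy: int = 2
    seed: int | None = None
    sample_every: int = 1
    p0_range: tuple[float, float] | None = None

    def __post_init__(self):
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must be inside (0, 1)")
        if self.sigma_s2 < 0:
            raise ValueError("sigma_s2 must be non-negative")
        if self.T < 1 or self.L < 1 or self.n < 1 or self.ne < 1:
            raise ValueError("T, L, n, ne must be positive")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        if self.seed is None:
            raise ValueError("a seed is required for any stochastic run")


@dataclass
class Trajectory:
    """True allele-frequency path and the realized selection coefficients."""

    true_p: np.ndarray  # length T+1
    applied_s: np.ndarray  # length T
    n_truncated: int = 0


def _draw_s(rng, mu_s, sigma_s2, size):
    """Per-generation selection coefficients; Gaussian when fluctuating."""
    if sigma_s2 == 0.0:
        return np.full(size, mu_s), 0
    s = rng.normal(mu_s, np.sqrt(sigma_s2), size=size)
    n_trunc = int(np.sum(s < _S_TRUNC))
    if n_trunc:
        s = np.maximum(s, _S_TRUNC)
    return s, n_trunc


def _step(rng, p, copies, s):
    """One generation: genic selection then binomial drift."""
    if np.isscalar(s) and s == 0.0:
        pstar = p
    else:
        pstar = p * (1.0 + s) / (1.0 + p * s)
    return rng.binomial(copies, pstar) / copies


def simulate_trajectory(cfg: WFConfig) -> Trajectory:
    """Single-site true-frequency path over cfg.T generations."""
    rng = np.random.default_rng(cfg.seed)
    copies = int(cfg.ploidy * cfg.ne)
    p = np.empty(cfg.T + 1)
    p[0] = cfg.p0
    s, n_trunc = _draw_s(rng, cfg.mu_s, cfg.sigma_s2, cfg.T)
    for t in range(cfg.T):
        p[t + 1] = _step(rng, p[t], copies, s[t])
    return Trajectory(true_p=p, applied_s=s, n_truncated=n_trunc)


def _sample_times(cfg: WFConfig) -> np.ndarray:
    return np.arange(0, cfg.T + 1, cfg.sample_every)


def sample_series(tr: Trajectory, cfg: WFConfig) -> TemporalCounts:
    """Binomially sample n individuals at each retained time point."""
    rng = np.random.default_rng(None if cfg.seed is None else cfg.seed + 1)
    times = _sample_times(cfg)
    draws = cfg.ploidy * cfg.n
    counts = rng.binomial(draws, tr.true_p[times])
    return TemporalCounts(
        site_ids=["site_0"],
        generations=np.arange(times.size),
        counts=counts[None, :],
        sample_sizes=np.full((1, times.size), cfg.n),
        ploidy=cfg.ploidy,
        interval=float(cfg.sample_every),
    )


def _panel_freqs(rng, cfg: WFConfig, L: int):
    """Vectorized panel: true p at each retained time, sampled counts.

    Sites evolve independently; all draws come from one seeded stream in
    (generation, site-block) order, so a fixed (config, seed) reproduces
    byte-identical output.
    Returns (true_p[L, K], counts[L, K]) over the K retained times.
    """
    if cfg.p0_range is not None:
        a, b = cfg.p0_range
        p = rng.uniform(a, b, size=L)
    else:
        p = np.full(L, cfg.p0)
    copies = int(cfg.ploidy * cfg.ne)
    times = _sample_times(cfg)
    retained = set(times.tolist())
    true_p = np.empty((L, times.size))
    n_trunc = 0
    k = 0
    for t in range(cfg.T + 1):
        if t in retained:
            true_p[:, k] = p
            k += 1
        if t < cfg.T:
            if cfg.sigma_s2 > 0:
                s, nt = _draw_s(rng, cfg.mu_s, cfg.sigma_s2, L)
                n_trunc += nt
            else:
                s = cfg.mu_s
            p = _step(rng, p, copies, s)
    counts = rng.binomial(cfg.ploidy * cfg.n, true_p)
    return true_p, counts, n_trunc


def simulate_panel(cfg: WFConfig) -> TemporalCounts:
    """L independent sites simulated, sampled and assembled into counts."""
    rng = np.random.default_rng(cfg.seed)
    _, counts, n_trunc = _panel_freqs(rng, cfg, cfg.L)
    if n_trunc and n_trunc > 1e-6 * cfg.L * cfg.T:
        warnings.warn(
            f"{n_trunc} fluctuating-selection draws were truncated at "
            f"{_S_TRUNC}; sigma_s2 may be too large for a valid run",
            stacklevel=2,
        )
    K = counts.shape[1]
    return TemporalCounts(
        site_ids=[f"site_{i}" for i in range(cfg.L)],
        generations=np.arange(K),
        counts=counts,
        sample_sizes=np.full((cfg.L, K), cfg.n),
        ploidy=cfg.ploidy,
        interval=float(cfg.sample_every),
    )


# ---------------------------------------------------------------------------
# Experiment harness
# ---------------------------------------------------------------------------

def _chunks(total, size):
    done = 0
    while done < total:
        yield min(size, total - done)
        done += size


def _study_cov_null(rng, reps, *, L=10_000, ne=1e6, n=100,
                    p0_range=(0.1, 0.9), chunk=200):
    """Null calibration of the standardized covariance-of-change test.

    Four neutral sampling points form two disjoint unit intervals; per
    replicate the across-site covariance of standardized changes is
    scored against the 5% and 1% critical values 1.96/sqrt(L) and
    2.58/sqrt(L).
    """
    ests = []
    for r in _chunks(reps, chunk):
        p0 = rng.uniform(*p0_range, size=(r, L))
        copies = int(2 * ne)
        p = [p0]
        for _ in range(3):
            p.append(rng.binomial(copies, p[-1]) / copies)
        ptrue = np.stack(p, axis=-1)  # (r, L, 4)
        phat = rng.binomial(2 * n, ptrue) / (2.0 * n)
        narr = np.full(ptrue.shape, n)
        sj, okj = _standardized_changes(phat, narr, 2, 0, 1)
        sk, okk = _standardized_changes(phat, narr, 2, 2, 3)
        for i in range(r):
            keep = okj[i] & okk[i]
            ests.append((_cov_unbiased(sj[i][keep], sk[i][keep]), int(keep.sum())))
    cov = np.array([e[0] for e in ests])
    Ls = np.array([e[1] for e in ests])
    rej05 = np.abs(cov) > 1.96 / np.sqrt(Ls)
    rej01 = np.abs(cov) > 2.58 / np.sqrt(Ls)
    rows = [
        ("type1_error_05", rej05.mean(), rej05.std(ddof=1) / np.sqrt(reps)),
        ("type1_error_01", rej01.mean(), rej01.std(ddof=1) / np.sqrt(reps)),
        ("mean_cov", cov.mean(), cov.std(ddof=1) / np.sqrt(reps)),
        ("var_cov_times_L", cov.var(ddof=1) * Ls.mean(), np.nan),
    ]
    return pd.DataFrame(
        [{"study": "cov_null", "ne": ne, "L": L, "n": n, "reps": reps,
          "statistic": k, "value": v, "mc_se": se} for k, v, se in rows]
    )


_FIG2_SD_CONDITIONS = [
    (1e6, s, p0, T)
    for s in (1e-3, 1e-2) for p0 in (0.1, 0.5) for T in (10, 30)
]


def _fig2_run(rng, reps, ne, s, p0, T_samples, n):
    """Replicated selection+drift trajectories, regression fit per rep.

    ``T_samples`` sequential samples are taken one generation apart; the
    closed-form variance formula is exact on that sample count.
    """
    copies = int(2 * ne)
    p = np.full(reps, p0)
    phat = np.empty((reps, T_samples))
    for t in range(T_samples):
        phat[:, t] = rng.binomial(2 * n, p) / (2.0 * n)
        if t < T_samples - 1:
            p = _step(rng, p, copies, s)
    z, ok = _zeta_panel(phat)
    z = np.where(ok[:, None], z, 0.0)
    slope, _ = _ols_slope_panel(np.arange(T_samples, dtype=float), z)
    return np.where(ok, -slope, np.nan), ok


def _study_fig2(rng, reps, conditions, n=100, study="fig2_sd"):
    rows = []
    for ne, s, p0, T in conditions:
        s_hat, ok = _fig2_run(rng, reps, ne, s, p0, T, n)
        v = s_hat[ok]
        pred_sd = np.sqrt(predicted_var_s(T, n, p0, 0.0))
        mean, sd = v.mean(), v.std(ddof=1)
        base = {"study": study, "ne": ne, "s": s, "p0": p0, "T": T,
                "n": n, "reps": reps}
        for k, val, se in [
            ("mean_s_hat", mean, sd / np.sqrt(v.size)),
            ("sd_s_hat", sd, sd / np.sqrt(2 * (v.size - 1))),
            ("predicted_sd", pred_sd, np.nan),
            ("log1p_s", np.log1p(s), np.nan),
            ("frac_dropped", 1.0 - ok.mean(), np.nan),
        ]:
            rows.append({**base, "statistic": k, "value": val, "mc_se": se})
    return pd.DataFrame(rows)


def _study_fig2_sd(rng, reps, *, conditions=None, n=100):
    """Sampling SD of the regression slope vs its closed-form prediction."""
    return _study_fig2(rng, reps, conditions or _FIG2_SD_CONDITIONS, n, "fig2_sd")


_FIG2_BIAS_CONDITIONS = [
    # (ne, s, p0, T): strong-signal regime Ne*s*p0 > 1, then the
    # drift-dominated regime Ne*s*p0 < 1 where downward bias sets in.
    (1e6, 1e-2, 0.2, 21),
    (1e6, 1e-3, 0.5, 21),
    (1e4, 1e-4, 0.1, 41),
]


def _study_fig2_bias(rng, reps, *, conditions=None, n=100):
    """Mean of the regression estimate across selection regimes."""
    return _study_fig2(rng, reps, conditions or _FIG2_BIAS_CONDITIONS, n,
                       "fig2_bias")


def _study_fig3_svar(rng, reps, *, ne=1e8, sigma_s2=1e-3, mu_s=0.0,
                     p0=0.5, T=100, n=1000):
    """Recovery of the among-generation selection variance sigma_s^2.

    Quasi-neutral fluctuating selection over T single-generation
    intervals with essentially no drift (large Ne); per replicate the
    variance decomposition is applied to the sampled series.
    """
    copies = int(2 * ne)
    p = np.full(reps, p0)
    phat = np.empty((reps, T + 1))
    n_trunc = 0
    for t in range(T + 1):
        phat[:, t] = rng.binomial(2 * n, p) / (2.0 * n)
        if t < T:
            s, nt = _draw_s(rng, mu_s, sigma_s2, reps)
            n_trunc += nt
            p = _step(rng, p, copies, s)
    narr = np.full(phat.shape, n)
    _, _, sig2, ok, _ = _sigma_s2_panel(phat, narr, 2)
    v = sig2[ok]
    mean, sd = v.mean(), v.std(ddof=1)
    base = {"study": "fig3_svar", "ne": ne, "sigma_s2": sigma_s2, "p0": p0,
            "T": T, "n": n, "reps": reps}
    rows = [
        ("mean_sigma_s2_hat", mean, sd / np.sqrt(v.size)),
        ("sd_sigma_s2_hat", sd, np.nan),
        ("cv_sigma_s2_hat", sd / mean if mean > 0 else np.inf, np.nan),
        ("frac_negative", float((v < 0).mean()), np.nan),
        ("n_truncated_draws", float(n_trunc), np.nan),
    ]
    return pd.DataFrame([{**base, "statistic": k, "value": val, "mc_se": se}
                         for k, val, se in rows])


def _ne_panel_reps(rng, reps, ne, T, n, L, p0_range, chunk=50):
    """Neutral panels sampled at all T+1 points; returns p_hat (reps, L, T+1)."""
    out = np.empty((reps, L, T + 1))
    copies = int(2 * ne)
    done = 0
    for r in _chunks(reps, chunk):
        p = rng.uniform(*p0_range, size=(r, L))
        block = np.empty((r, L, T + 1))
        block[:, :, 0] = p
        for t in range(T):
            p = rng.binomial(copies, p) / copies
            block[:, :, t + 1] = p
        out[done:done + r] = rng.binomial(2 * n, block) / (2.0 * n)
        done += r
    return out


def _pooled_ne(phat, n, t_pairs, interval_len):
    """Mean-of-subinterval moment Ne estimates per replicate (NaN if none)."""
    reps = phat.shape[0]
    est = np.full((reps, len(t_pairs)), np.nan)
    for c, (j, k) in enumerate(t_pairs):
        fh = ne_mod.f_hat(phat[:, :, j], phat[:, :, k])
        ph = ne_mod.phi(fh, n, n, 2)
        phi_bar = np.nanmean(ph, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            est[:, c] = np.where(phi_bar > 0,
                                 interval_len * (k - j) / (2.0 * phi_bar),
                                 np.nan)
    return est.mean(axis=1)


def _study_ne_validation(rng, reps, *, ne=1e3, t=5, n=500, L=10_000,
                         p0_range=(0.1, 0.9)):
    """Bias and sampling variance of the two-sample moment Ne estimate."""
    phat = _ne_panel_reps(rng, reps, ne, t, n, L, p0_range)
    est = _pooled_ne(phat[:, :, [0, -1]], n, [(0, 1)], t)
    v = est[np.isfinite(est)]
    mean, var = v.mean(), v.var(ddof=1)
    pred_red = ne_mod.predicted_var_ne(ne, L, t, n)
    pred_full = ne_mod.predicted_var_ne(ne, L, t, n, N_census=ne, full=True)
    base = {"study": "ne_validation", "ne": ne, "t": t, "n": n, "L": L,
            "reps": reps}
    rows = [
        ("mean_ne_hat", mean, v.std(ddof=1) / np.sqrt(v.size)),
        ("var_ne_hat", var, var * np.sqrt(2.0 / (v.size - 1))),
        ("predicted_var_reduced", pred_red, np.nan),
        ("predicted_var_full", pred_full, np.nan),
        ("frac_undefined", 1.0 - v.size / reps, np.nan),
    ]
    return pd.DataFrame([{**base, "statistic": k, "value": val, "mc_se": se}
                         for k, val, se in rows])


def _study_ne_multi_interval(rng, reps, *, ne=1e3, n=500, L=10_000,
                             p0_range=(0.1, 0.9)):
    """SD scaling of endpoint/halves/thirds Ne schemes on six samples."""
    phat = _ne_panel_reps(rng, reps, ne, 5, n, L, p0_range)
    schemes = {
        "endpoints": [(0, 5)],
        "halves": [(0, 2), (3, 5)],
        "thirds": [(0, 1), (2, 3), (4, 5)],
    }
    rows = []
    base = {"study": "ne_multi_interval", "ne": ne, "t": 5, "n": n, "L": L,
            "reps": reps}
    sds = {}
    for name, pairs in schemes.items():
        est = _pooled_ne(phat, n, pairs, 1.0)
        v = est[np.isfinite(est)]
        sds[name] = v.std(ddof=1)
        for k, val, se in [
            (f"mean_ne_{name}", v.mean(), v.std(ddof=1) / np.sqrt(v.size)),
            (f"sd_ne_{name}", sds[name],
             sds[name] / np.sqrt(2 * (v.size - 1))),
            (f"frac_undefined_{name}", 1.0 - v.size / reps, np.nan),
        ]:
            rows.append({**base, "statistic": k, "value": val, "mc_se": se})
    for name in ("halves", "thirds"):
        rows.append({**base, "statistic": f"sd_ratio_{name}",
                     "value": sds[name] / sds["endpoints"], "mc_se": np.nan})
    return pd.DataFrame(rows)


EXPERIMENTS = {
    "cov_null": (_study_cov_null, 2000),
    "fig2_sd": (_study_fig2_sd, 10_000),
    "fig2_bias": (_study_fig2_bias, 10_000),
    "fig3_svar": (_study_fig3_svar, 10_000),
    "ne_validation": (_study_ne_validation, 300),
    "ne_multi_interval": (_study_ne_multi_interval, 400),
}


def run_experiment(study: str, reps: int | None = None,
                   seed: int | None = None, **overrides) -> pd.DataFrame:
    """Run a canned validation study and return a tidy summary table.

    Columns: the study's condition parameters, ``statistic``, ``value``
    and the Monte-Carlo standard error ``mc_se`` where meaningful.
    """
    if study not in EXPERIMENTS:
        raise ValueError(
            f"unknown study {study!r}; available: {sorted(EXPERIMENTS)}"
        )
    if seed is None:
        raise ValueError("a seed is required for any stochastic run")
    fn, default_reps = EXPERIMENTS[study]
    rng = np.random.default_rng(seed)
    return fn(rng, reps or default_reps, **overrides)
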