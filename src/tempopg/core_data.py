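"""Allele-frequency time-series containers and TSV input/output.

The universal input for every analysis in this package is a panel of L
biallelic sites observed at T+1 sampling points.  At each point the copy
number of a declared *focal* allele and the number of sampled individuals
are recorded.  Frequencies of the complementary allele are implicit; no
reorientation is performed, so the sign of downstream selection estimates
is under the user's control.

Sampling points are indexed by consecutive integer generations 0..T.  A
survey whose samples are actually D generations apart carries D as the
``interval`` metadata scalar; closed-form estimators are then rescaled
(s/D, sigma_s^2/D^2, Ne*D) by their callers rather than by this module.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TemporalCounts",
    "FreqSeries",
    "DeltaSeries",
    "TemporalDataError",
    "read_counts",
    "write_counts",
    "to_frequencies",
    "deltas",
    "harmonic_mean_n",
]

_HEADER = ("site_id", "generation", "count", "n")


class TemporalDataError(ValueError):
    """Malformed or internally inconsistent temporal count data."""


@dataclass
class TemporalCounts:
    """Focal-allele copy counts and sample sizes for L sites at T+1 times.

    Attributes
    ----------
    site_ids : list of str
        Identifiers of the L sites.
    generations : ndarray of int, shape (T+1,)
        Strictly increasing sampling-point indices starting at 0.
    counts : ndarray of int, shape (L, T+1)
        Observed copies of the focal allele; 0 <= count <= ploidy*n.
    sample_sizes : ndarray of int, shape (L, T+1)
        Individuals genotyped per site per time point.
    ploidy : int
        1 (haploid) or 2 (diploid).
    interval : float
        Number of real generations per unit step between sampling points
        (the survey spacing D); carried as metadata only.
    """

    site_ids: list[str]
    generations: np.ndarray
    counts: np.ndarray
    sample_sizes: np.ndarray
    ploidy: int = 2
    interval: float = 1.0

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=int)
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=np.int64))
        self.sample_sizes = np.atleast_2d(
            np.asarray(self.sample_sizes, dtype=np.int64)
        )
        if self.ploidy not in (1, 2):
            raise TemporalDataError(f"ploidy must be 1 or 2, got {self.ploidy}")
        if self.generations.ndim != 1 or self.generations.size < 2:
            raise TemporalDataError("at least 2 sampling points are required")
        if self.generations[0] != 0:
            raise TemporalDataError("generation indices must start at 0")
        if np.any(np.diff(self.generations) <= 0):
            raise TemporalDataError("generations must be strictly increasing")
        L, P = self.counts.shape
        if len(self.site_ids) != L:
            raise TemporalDataError("site_ids length does not match counts")
        if self.sample_sizes.shape != (L, P):
            raise TemporalDataError("sample_sizes shape does not match counts")
        if P != self.generations.size:
            raise TemporalDataError("counts columns do not match generations")
        if np.any(self.sample_sizes < 1):
            raise TemporalDataError("sample sizes must be positive")
        if np.any(self.counts < 0):
            raise TemporalDataError("counts must be non-negative")
        bad = self.counts > self.ploidy * self.sample_sizes
        if np.any(bad):
            i, t = np.argwhere(bad)[0]
            raise TemporalDataError(
                f"count exceeds ploidy*n at site {self.site_ids[i]!r}, "
                f"generation {self.generations[t]}"
            )

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_intervals(self) -> int:
        """Number of unit intervals T (sampling points minus one)."""
        return self.generations.size - 1


@dataclass
class FreqSeries:
    """Estimated focal-allele frequencies p_hat = count/(ploidy*n)."""

    p_hat: np.ndarray
    parent: TemporalCounts

    @property
    def generations(self) -> np.ndarray:
        return self.parent.generations

    @property
    def n_sites(self) -> int:
        return self.p_hat.shape[0]


@dataclass
class DeltaSeries:
    """Per-interval frequency changes and their standardized versions.

    ``deltas[i, t]`` is p_hat[i, t+1] - p_hat[i, t].  ``std_deltas``
    divides each change by the binomial-sampling standard deviation
    sqrt(pbar*(1-pbar)*(1/(c*n_t) + 1/(c*n_{t+1}))) with c the ploidy and
    pbar the mean of the interval's two frequency estimates (for constant
    diploid n this is the familiar sqrt(pbar(1-pbar)/n)).  Intervals whose
    mean frequency is 0 or 1 have no defined standardization and are NaN;
    their (site, interval) indices are listed in ``dropped``.
    """

    deltas: np.ndarray
    std_deltas: np.ndarray
    dropped: np.ndarray  # (k, 2) array of (site, interval) indices
    parent: FreqSeries = field(repr=False)


def to_frequencies(tc: TemporalCounts) -> FreqSeries:
    """Derive allele-frequency estimates from counts."""
    p = tc.counts / (tc.ploidy * tc.sample_sizes)
    return FreqSeries(p_hat=p, parent=tc)


def deltas(fs: FreqSeries) -> DeltaSeries:
    """Adjacent-sample frequency changes, raw and standardized."""
    p = fs.p_hat
    d = np.diff(p, axis=1)
    pbar = 0.5 * (p[:, 1:] + p[:, :-1])
    n = fs.parent.sample_sizes
    c = fs.parent.ploidy
    var = pbar * (1.0 - pbar) * (1.0 / (c * n[:, :-1]) + 1.0 / (c * n[:, 1:]))
    with np.errstate(divide="ignore", invalid="ignore"):
        std = np.where(var > 0, d / np.sqrt(var), np.nan)
    dropped = np.argwhere(var <= 0)
    return DeltaSeries(deltas=d, std_deltas=std, dropped=dropped, parent=fs)


def harmonic_mean_n(sample_sizes: np.ndarray, warn_threshold: float = 0.10):
    """Harmonic-mean sample size, warning when sizes vary by > threshold.

    Closed-form standard-error formulas assume one constant n; when the
    panel's sample sizes differ by more than ``warn_threshold`` (relative
    range) a warning is emitted and the harmonic mean is used.
    """
    ns = np.asarray(sample_sizes, dtype=float)
    lo, hi = ns.min(), ns.max()
    if lo > 0 and (hi - lo) / lo > warn_threshold:
        warnings.warn(
            f"sample sizes vary by more than {warn_threshold:.0%} "
            f"(min={lo:.0f}, max={hi:.0f}); using the harmonic mean",
            stacklevel=2,
        )
    return ns.size / np.sum(1.0 / ns)


# ---------------------------------------------------------------------------
# TSV dialect: '#' comments, '##key=value' metadata, tab-separated header
# site_id / generation / count / n, one row per site per time point.
# ---------------------------------------------------------------------------

def read_counts(path) -> TemporalCounts:
    """Read a tab-separated allele-count time series.

    Rows sharing a site_id are collated; every site must be observed at
    exactly the same set of generations (missing cells are unsupported).
    """
    ploidy, interval = 2, 1.0
    rows: dict[str, dict[int, tuple[int, int]]] = {}
    order: list[str] = []
    header_seen = False
    opener = open(path, "r", encoding="utf-8") if not hasattr(path, "read") else None
    fh = opener if opener is not None else path
    try:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                if key == "ploidy":
                    ploidy = int(value)
                elif key == "interval":
                    interval = float(value)
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(fields) != _HEADER:
                    raise TemporalDataError(
                        f"line {lineno}: malformed header {fields!r}; "
                        f"expected {list(_HEADER)}"
                    )
                header_seen = True
                continue
            if len(fields) != 4:
                raise TemporalDataError(
                    f"line {lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            sid, gen_s, count_s, n_s = fields
            try:
                gen, count, n = int(gen_s), int(count_s), int(n_s)
            except ValueError as exc:
                raise TemporalDataError(f"line {lineno}: {exc}") from None
            if sid not in rows:
                rows[sid] = {}
                order.append(sid)
            if gen in rows[sid]:
                raise TemporalDataError(
                    f"line {lineno}: duplicate entry for site {sid!r}, "
                    f"generation {gen}"
                )
            rows[sid][gen] = (count, n)
    finally:
        if opener is not None:
            opener.close()
    if not header_seen:
        raise TemporalDataError("missing header line")
    if not rows:
        raise TemporalDataError("no data rows")
    gens = sorted(rows[order[0]])
    for sid in order:
        if sorted(rows[sid]) != gens:
            raise TemporalDataError(
                f"site {sid!r} is not observed at the same generations as "
                f"the rest of the panel"
            )
    counts = np.array([[rows[sid][g][0] for g in gens] for sid in order])
    ns = np.array([[rows[sid][g][1] for g in gens] for sid in order])
    return TemporalCounts(
        site_ids=order,
        generations=np.array(gens),
        counts=counts,
        sample_sizes=ns,
        ploidy=ploidy,
        interval=interval,
    )


def write_counts(tc: TemporalCounts, path) -> None:
    """Write ``tc`` in the same TSV dialect that :func:`read_counts` accepts."""
    buf = io.StringIO()
    buf.write(f"##ploidy={tc.ploidy}\n")
    ivl = tc.interval
    buf.write(f"##interval={ivl:g}\n")
    buf.write("\t".join(_HEADER) + "\n")
    for i, sid in enumerate(tc.site_ids):
        for t, g in enumerate(tc.generations):
            buf.write(
                f"{sid}\t{g}\t{tc.counts[i, t]}\t{tc.sample_sizes[i, t]}\n"
            )
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
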