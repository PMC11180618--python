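"""Group statistics: Mann–Whitney comparison and ROUT outlier removal.

Waveform metrics are strongly non-normal across waves and horns, so
groups (stages, genotypes, treatments) are compared with the two-tailed
Mann–Whitney rank test. Before testing, each group is cleaned with the
ROUT procedure (robust regression + outlier removal) at a maximum
desired false discovery rate Q (default 1%); for a single sample the
robustly fitted "model" is the median, the robust scale is the RSDR
estimated from the 68.27th percentile of absolute residuals, and the
FDR step is a Benjamini–Hochberg-style test over residual p-values.

The exact Mann–Whitney p is computed by enumerating the U distribution
(a dynamic program) whenever ``n_a * n_b <= 400`` and the data carry no
ties; otherwise the normal approximation with tie and continuity
corrections is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median as _median

import numpy as np
from scipy import special

from .errors import ValidationError

EXACT_PRODUCT_CUTOFF = 400


@dataclass(frozen=True)
class RoutParams:
    """ROUT tuning: Q = maximum desired false discovery rate."""

    q: float = 0.01
    max_iterations: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.q < 0.5:
            raise ValidationError(f"Q must lie in (0, 0.5), got {self.q}")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")


@dataclass
class MannWhitneyResult:
    """U statistic of the first sample, two-tailed p, and provenance."""

    u: float
    p: float
    method: str  # "exact" | "normal"
    degenerate: bool = False


def _rankdata(x: np.ndarray) -> np.ndarray:
    """Midranks of a 1D array (average rank for ties), 1-based."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _exact_u_cdf(u: int, m: int, n: int) -> float:
    """P(U <= u) under the null by enumerating the U distribution.

    ``N(u; m, n) = N(u - n; m - 1, n) + N(u; m, n - 1)`` counts the rank
    arrangements of m + n untied values giving Mann–Whitney statistic u.
    """
    total_u = m * n
    counts = np.zeros((m + 1, n + 1, total_u + 1))
    counts[0, :, 0] = 1.0
    counts[:, 0, 0] = 1.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            shifted = np.zeros(total_u + 1)
            shifted[j:] = counts[i - 1, j, : total_u + 1 - j]
            counts[i, j] = shifted + counts[i, j - 1]
    dist = counts[m, n]
    return float(dist[: u + 1].sum() / dist.sum())


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-tailed Mann–Whitney test between two samples.

    Exact enumeration when ``n_a * n_b <= 400`` and no ties; otherwise
    the normal approximation with tie and continuity corrections. When
    every value in both groups is identical the test is degenerate and
    ``p = 1`` is reported with a flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("samples must be finite")

    m, n = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _rankdata(pooled)
    u_a = float(ranks[:m].sum() - m * (m + 1) / 2)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(u=u_a, p=1.0, method="normal", degenerate=True)

    if not has_ties and m * n <= EXACT_PRODUCT_CUTOFF:
        u_small = int(round(min(u_a, m * n - u_a)))
        p = min(1.0, 2.0 * _exact_u_cdf(u_small, m, n))
        return MannWhitneyResult(u=u_a, p=p, method="exact")

    big_n = m + n
    mu = m * n / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (big_n * (big_n - 1))
    sigma2 = (m * n / 12.0) * ((big_n + 1) - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(u=u_a, p=1.0, method="normal", degenerate=True)
    sigma = np.sqrt(sigma2)
    if has_ties:
        # tie-corrected normal approximation with continuity correction
        z = max((abs(u_a - mu) - 0.5) / sigma, 0.0)
        p = min(1.0, float(special.erfc(z / np.sqrt(2.0))))
        return MannWhitneyResult(u=u_a, p=p, method="normal")
    # untied ranks: Edgeworth expansion with the exact excess kurtosis of U
    # (the platykurtic U distribution makes the plain normal tail too light)
    g2 = -1.2 * (m * m + n * n + m * n + m + n) / (m * n * (big_n + 1))
    z = (min(u_a, m * n - u_a) - mu + 0.5) / sigma
    phi = np.exp(-z * z / 2.0) / np.sqrt(2.0 * np.pi)
    cdf = special.ndtr(z) - g2 / 24.0 * (z**3 - 3.0 * z) * phi
    p = min(1.0, max(0.0, 2.0 * float(cdf)))
    return MannWhitneyResult(u=u_a, p=p, method="normal")


@dataclass
class RoutResult:
    """Outlier flags (aligned with the input) and the cleaned sample."""

    outlier: np.ndarray
    cleaned: np.ndarray
    rsdr: float | None = None


def rout_outliers(x, params: RoutParams | None = None) -> RoutResult:
    """Univariate ROUT outlier detection at FDR Q.

    Iteratively: centre = median, robust scale RSDR = 68.27th percentile
    of absolute residuals times ``n / (n - 1)``; residual t-scores get
    two-tailed p-values (Student t, ``n - 1`` df) which enter a
    Benjamini–Hochberg step at rate Q; flagged points are removed and
    the fit repeated until stable. Samples below n = 5 and degenerate
    (all-equal) samples are returned unchanged.
    """
    params = params or RoutParams()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("rout_outliers expects a 1D sample")
    if not np.all(np.isfinite(x)):
        raise ValidationError("sample must be finite")

    outlier = np.zeros(x.size, dtype=bool)
    if x.size < 5:
        return RoutResult(outlier=outlier, cleaned=x.copy())

    rsdr = None
    for _ in range(params.max_iterations):
        keep = ~outlier
        kept = x[keep]
        n = kept.size
        if n < 5:
            break
        resid = kept - np.median(kept)
        sdr = np.percentile(np.abs(resid), 68.27)
        if sdr <= 0:
            break
        rsdr = sdr * n / (n - 1)
        t = np.abs(resid) / rsdr
        pvals = 2.0 * special.stdtr(n - 1, -t)

        order = np.argsort(pvals)
        ranked = pvals[order]
        bh = ranked <= params.q * (np.arange(1, n + 1) / n)
        if not bh.any():
            break
        k = int(np.flatnonzero(bh).max()) + 1
        new_flags = np.zeros(n, dtype=bool)
        new_flags[order[:k]] = True
        outlier[np.flatnonzero(keep)[new_flags]] = True

    return RoutResult(outlier=outlier, cleaned=x[~outlier], rsdr=rsdr)


def compare_conditions(
    metrics_a: dict[str, list],
    metrics_b: dict[str, list],
    metric_names: list[str] | None = None,
    rout: RoutParams | None = None,
    alpha: float = 0.05,
) -> dict[str, dict]:
    """Per-metric group comparison report.

    Each group is ROUT-cleaned independently, then compared with the
    two-tailed Mann–Whitney test; a metric is flagged significant when
    ``p < alpha``. Input dicts map metric name -> list of values (one
    per wave/horn).
    """
    rout = rout or RoutParams()
    names = metric_names or sorted(set(metrics_a) & set(metrics_b))
    report: dict[str, dict] = {}
    for name in names:
        if name not in metrics_a or name not in metrics_b:
            raise ValidationError(f"unknown metric name: {name!r}")
        a = np.asarray([v for v in metrics_a[name] if v is not None], dtype=float)
        b = np.asarray([v for v in metrics_b[name] if v is not None], dtype=float)
        if metric_names is None and a.size == 0 and b.size == 0:
            continue  # metric absent from both groups (e.g. no periods marked)
        ra, rb = rout_outliers(a, rout), rout_outliers(b, rout)
        if ra.cleaned.size == 0 or rb.cleaned.size == 0:
            raise ValidationError(
                f"metric {name!r}: a group is empty after outlier removal"
            )
        mw = mann_whitney(ra.cleaned, rb.cleaned)
        report[name] = {
            "n_a": int(ra.cleaned.size),
            "n_b": int(rb.cleaned.size),
            "median_a": float(np.median(ra.cleaned)),
            "median_b": float(np.median(rb.cleaned)),
            "outliers_removed_a": [float(v) for v in a[ra.outlier]],
            "outliers_removed_b": [float(v) for v in b[rb.outlier]],
            "u": mw.u,
            "p": mw.p,
            "method": mw.method,
            "significant": bool(mw.p < alpha and not mw.degenerate),
        }
    return report


def metrics_table(metrics: list) -> dict[str, list]:
    """Collect a list of WaveMetrics into a metric-name -> values dict."""
    out: dict[str, list] = {}
    for field in ("amplitude_um", "period_s", "frequency_hz",
                  "velocity_um_s", "wavelength_um"):
        out[field] = [getattr(m, field) for m in metrics
                      if getattr(m, field) is not None]
    return out
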