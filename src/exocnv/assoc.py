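"""Case-control association of adjusted local PCs and scan diagnostics.

Each region's adjusted first principal component is tested against the
0/1 phenotype with a univariate logistic regression; the scan-wide Wald
chi-square statistics feed the genomic-control inflation factor

    lambda = median(chi2) / median(chi2_1)   (median chi2_1 ~= 0.4549),

with quantile-quantile and GC-content tables as the companion
diagnostics.  lambda ~= 1 indicates calibrated tests; lambda > 1, inflation
from uncorrected technical structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LogisticFit",
    "AssociationResult",
    "InflationReport",
    "fit_logistic",
    "scan",
    "compute_lambda",
    "qq_table",
    "gc_significance_table",
    "CHI2_1_MEDIAN",
]

# median of the chi-square distribution with 1 df, fixed to 12 significant
# digits so lambda is bit-stable across platforms
CHI2_1_MEDIAN = 0.454936423120

_SEPARATION_BETA = 15.0


@dataclass
class LogisticFit:
    beta: float
    se: float
    p_value: float
    converged: bool
    estimable: bool
    n_iterations: int = 0

    @property
    def wald_chi2(self) -> float:
        if not self.estimable:
            return math.nan
        return (self.beta / self.se) ** 2


@dataclass
class AssociationResult:
    region_id: str
    H: int
    beta: float
    se: float
    wald_chi2: float
    p_value: float
    rank: int | None = None  # 1 = most significant; None when non-estimable
    gc_fraction: float | None = None
    estimable: bool = True


@dataclass
class InflationReport:
    H: int
    lambda_gc: float
    n_regions: int


def fit_logistic(x: np.ndarray, y: np.ndarray, max_iter: int = 25,
                 tol: float = 1e-10) -> LogisticFit:
    """Maximum-likelihood fit of ``logit P(y=1) = b0 + b1 x`` by IRLS.

    Returns the slope, its standard error and the two-sided Wald p-value.
    A zero-variance predictor, or complete separation (diverging |b1| with
    non-decreasing likelihood), yields ``estimable=False`` with a missing
    p-value.

    Raises if ``y`` contains a single class — the model is then undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if not np.all(np.isfinite(x)):
        raise ValueError("predictor contains non-finite values")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))) or classes.size < 2:
        raise ValueError("y must contain both classes 0 and 1")
    if np.ptp(x) == 0.0:
        return LogisticFit(math.nan, math.nan, math.nan, False, False)

    # fit on the standardized predictor so the complete-separation bound is
    # scale-free; slope and SE are mapped back afterwards (z and p invariant)
    x_sd = float(x.std())
    xs = (x - x.mean()) / x_sd
    X = np.column_stack([np.ones_like(xs), xs])
    beta = np.zeros(2)
    ll_old = -math.inf
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        # Newton step: (X' W X) d = X'(y - mu)
        xtwx = X.T @ (X * w[:, None])
        grad = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(xtwx, grad)
        except np.linalg.LinAlgError:
            return LogisticFit(math.nan, math.nan, math.nan, False, False)
        beta = beta + delta
        eta = X @ beta
        # numerically safe Bernoulli log-likelihood at the updated beta
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if abs(beta[1]) > _SEPARATION_BETA and ll >= ll_old:
            return LogisticFit(math.nan, math.nan, math.nan, False, False)
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    xtwx = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        return LogisticFit(math.nan, math.nan, math.nan, False, False)
    se = math.sqrt(cov[1, 1])
    if not math.isfinite(se) or se == 0.0 or abs(beta[1]) > _SEPARATION_BETA:
        return LogisticFit(math.nan, math.nan, math.nan, False, False)
    chi2 = (beta[1] / se) ** 2
    p = float(stats.chi2.sf(chi2, 1))
    p = max(p, np.nextafter(0.0, 1.0))
    # back to the original predictor scale
    return LogisticFit(float(beta[1]) / x_sd, se / x_sd, p, converged, True, iterations)


def scan(adjusted_pcs, phenotypes: np.ndarray, H: int,
         gc_fractions: dict[str, float] | None = None,
         min_regions_for_lambda: int = 10):
    """Per-region logistic association of adjusted PCs with phenotype.

    ``adjusted_pcs`` is an iterable of :class:`~exocnv.pca.AdjustedPC` (or
    ``(region_id, vector)`` pairs).  Ranks are assigned by ascending
    p-value with ties broken by region_id, so the scan is independent of
    input order.  Non-estimable regions are excluded from both the ranking
    and the inflation factor.

    Returns ``(results, InflationReport)``.
    """
    phenotypes = np.asarray(phenotypes, dtype=float)
    gc_fractions = gc_fractions or {}
    results: list[AssociationResult] = []
    for item in adjusted_pcs:
        if hasattr(item, "region_id"):
            region_id, vector = item.region_id, item.vector
        else:
            region_id, vector = item
        fit = fit_logistic(np.asarray(vector, dtype=float), phenotypes)
        results.append(
            AssociationResult(
                region_id=region_id,
                H=H,
                beta=fit.beta,
                se=fit.se,
                wald_chi2=fit.wald_chi2,
                p_value=fit.p_value,
                gc_fraction=gc_fractions.get(region_id),
                estimable=fit.estimable,
            )
        )
    if not results:
        raise ValueError("empty region set")
    estimable = [r for r in results if r.estimable]
    if not estimable:
        raise ValueError("all regions non-estimable; nothing to rank")
    for rank, res in enumerate(
        sorted(estimable, key=lambda r: (r.p_value, r.region_id)), start=1
    ):
        res.rank = rank
    lam = compute_lambda(
        [r.wald_chi2 for r in estimable], min_statistics=min_regions_for_lambda
    )
    return results, InflationReport(H, lam, len(estimable))


def compute_lambda(wald_chi2, min_statistics: int = 10) -> float:
    """Genomic-control inflation factor from Wald chi-square statistics."""
    stats_arr = np.asarray(list(wald_chi2), dtype=float)
    stats_arr = stats_arr[np.isfinite(stats_arr)]
    if stats_arr.size < min_statistics:
        raise ValueError(
            f"need at least {min_statistics} finite statistics for a stable median, "
            f"got {stats_arr.size}"
        )
    if np.any(stats_arr < 0):
        raise ValueError("chi-square statistics must be non-negative")
    return float(np.median(stats_arr)) / CHI2_1_MEDIAN


def qq_table(p_values) -> np.ndarray:
    """Observed vs expected -log10(p) quantiles for a QQ plot.

    Row i pairs the i-th smallest p-value with the uniform-order-statistic
    expectation -log10((i - 0.5) / n); rows are sorted by expected value
    descending, so the most extreme quantile comes first.  Zero p-values
    are clamped to the smallest positive float.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros((0, 2))
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.maximum(np.sort(p), np.nextafter(0.0, 1.0))
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p)
    return np.column_stack([expected, observed])


def gc_significance_table(results, bin_width: float = 0.05,
                          p_threshold: float = 1e-4):
    """GC-content bias diagnostic for a scan.

    Returns ``(points, bins)``: ``points`` pairs each region's gc_fraction
    with its -log10 p (rows with missing GC dropped); ``bins`` aggregates,
    per GC bin of ``bin_width``, the fraction of regions with
    ``p < p_threshold`` — technical GC bias shows up as small-p enrichment
    concentrated in particular GC bands, which PC correction should remove.

    ``bins`` rows are ``(bin_low, n_regions, frac_significant)``.
    """
    rows = [
        (r.gc_fraction, -math.log10(max(r.p_value, np.nextafter(0.0, 1.0))), r.p_value)
        for r in results
        if r.estimable and r.gc_fraction is not None
    ]
    if not rows:
        return np.zeros((0, 2)), np.zeros((0, 3))
    points = np.array([(gc, nlp) for gc, nlp, _ in rows])
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    idx = np.clip(np.digitize(points[:, 0], edges) - 1, 0, len(edges) - 2)
    sig = np.array([p < p_threshold for _, _, p in rows])
    bins = []
    for b in range(len(edges) - 1):
        mask = idx == b
        n = int(mask.sum())
        if n == 0:
            continue
        bins.append((edges[b], n, float(sig[mask].mean())))
    return points, np.array(bins)


def write_scan_tsv(results, regions_by_id, path, header_lines=()) -> None:
    """Scan TSV: region_id, chrom, start, end, H, beta, se, chi2, p, rank, gc."""
    def fmt(v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return "NA"
        return repr(float(v)) if isinstance(v, float) else str(v)

    with open(path, "w") as out:
        for line in header_lines:
            out.write(f"# {line}\n")
        out.write("region_id\tchrom\tstart\tend\tH\tbeta\tse\tchi2\tp\trank\tgc_fraction\n")
        for r in results:
            reg = regions_by_id.get(r.region_id)
            chrom, start, end = (reg.chrom, reg.start, reg.end) if reg else ("NA",) * 3
            out.write("\t".join([
                r.region_id, str(chrom), str(start), str(end), str(r.H),
                fmt(r.beta), fmt(r.se), fmt(r.wald_chi2), fmt(r.p_value),
                fmt(r.rank), fmt(r.gc_fraction),
            ]) + "\n")


def write_inflation_tsv(reports, path, header_lines=()) -> None:
    with open(path, "w") as out:
        for line in header_lines:
            out.write(f"# {line}\n")
        out.write("H\tlambda\tn_regions\n")
        for rep in reports:
            out.write(f"{rep.H}\t{repr(float(rep.lambda_gc))}\t{rep.n_regions}\n")


def write_table_tsv(table, columns, path, header_lines=()) -> None:
    """Generic two/three-column numeric table (QQ, GC diagnostics)."""
    with open(path, "w") as out:
        for line in header_lines:
            out.write(f"# {line}\n")
        out.write("\t".join(columns) + "\n")
        for row in np.atleast_2d(table):
            if len(row):
                out.write("\t".join(repr(float(v)) for v in row) + "\n")
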