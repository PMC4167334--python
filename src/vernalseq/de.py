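"""No-replicate negative-binomial differential expression and variance stabilization.

A pooled-library time course has one sequencing library per time point,
so condition-specific variance cannot be estimated.  The workaround used
here treats *all* libraries of a tissue as replicates of one condition
("blind" mode): per-gene method-of-moments dispersions are fitted with a
parametric mean-dispersion curve alpha(mu) = a0 + a1/mu, and each pair
of time points is compared with an exact conditional NB test on the
total count.  Because blind dispersion absorbs real signal into the
variance estimate, the resulting p-values are conservative — by design,
given the absence of replication.

The same fitted curve yields a closed-form variance-stabilizing
transformation (the integral of 1/sqrt(v(mu))), calibrated to log2-like
units, which downstream clustering consumes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .grids import TimeGrid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CountMatrix:
    """Genes x samples integer counts plus per-sample metadata.

    ``counts`` is a DataFrame indexed by unique gene ids with one column
    per sample; ``samples`` a DataFrame indexed by sample name with at
    least genotype, tissue, time_days and phase columns, row-aligned
    with the count columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dup[:5])}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts are not allowed")
        missing = [c for c in self.counts.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing from sample sheet: {missing}")
        object.__setattr__(
            self, "samples", self.samples.loc[list(self.counts.columns)]
        )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios library size factors.

    For each gene expressed in every sample, the ratio of its count to
    its across-sample geometric mean is formed; a sample's factor is the
    median of those ratios.  Raises if no gene is positive in all
    samples.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "size-factor estimation failed: no gene has positive counts in "
            "every sample"
        )
    log_mat = np.log(mat[all_pos])
    log_geo = log_mat.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_mat - log_geo, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


@dataclass(frozen=True)
class DispersionFit:
    """Blind-mode dispersion estimates and the parametric fit.

    ``per_gene_alpha`` holds the clipped method-of-moments dispersion
    per gene; ``a0``/``a1`` parameterize alpha(mu) = a0 + a1/mu.
    """

    per_gene_alpha: pd.Series
    a0: float
    a1: float
    mode: str = "blind"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a0) and np.isfinite(self.a1)):
            raise ValueError("fitted dispersion parameters must be finite")
        if self.a0 < 0 or self.a1 < 0:
            raise ValueError("fitted alpha(mu) must be non-negative")

    def alpha(self, mu):
        """Fitted dispersion at mean ``mu`` (vectorized)."""
        mu = np.asarray(mu, dtype=float)
        with np.errstate(divide="ignore"):
            out = self.a0 + np.where(mu > 0, self.a1 / np.maximum(mu, 1e-300), np.inf)
        return out if out.ndim else float(out)


def estimate_dispersion_blind(
    counts: pd.DataFrame | CountMatrix, sf: pd.Series | np.ndarray
) -> DispersionFit:
    """Fit the mean-dispersion curve treating all samples as one condition.

    Per gene, with normalized counts ``k/s``: ``mu_hat`` is their mean,
    ``v_hat`` their sample variance, and the raw dispersion is
    ``(v_hat - mu_hat * xi) / mu_hat**2`` with ``xi`` the mean reciprocal
    size factor (the shot-noise correction).  (a0, a1) are fitted to the
    raw values against 1/mu_hat by iteratively reweighted least squares
    with gamma-family weights 1/fitted^2; per-gene stored dispersions are
    clipped at zero.

    Genuinely regulated genes inflate the blind variance far beyond the
    technical mean-dispersion trend, so the curve is anchored to the
    unregulated majority by robust fitting: a median (L1) regression of
    the chi-square-median-corrected dispersions against 1/mu, iterated
    with outlier trimming (genes whose observed variance exceeds the
    99.9th percentile of its sampling distribution under the current
    robust fit are excluded), followed by one gamma-weighted IRLS pass
    on the final kept set for an unbiased (a0, a1).  Falls back to the
    robust L1 parameters, then to the median clipped dispersion (a1=0),
    if a fit degenerates; fallbacks are logged.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    sf = np.asarray(sf, dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("blind dispersion estimation needs at least 2 samples")
    norm = counts.to_numpy(dtype=float) / sf[None, :]
    mu_hat = norm.mean(axis=1)
    v_hat = norm.var(axis=1, ddof=1)
    xi = float(np.mean(1.0 / sf))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = (v_hat - mu_hat * xi) / mu_hat**2
    ok = mu_hat > 0
    per_gene = np.where(ok, np.clip(alpha_raw, 0.0, None), np.nan)

    mu_ok = mu_hat[ok]
    x = 1.0 / mu_ok
    y = alpha_raw[ok]
    v_ok = v_hat[ok]

    # Variance-ratio threshold for dropping regulated genes from the fit:
    # under the fitted model v_hat ~ v_fit * chi2_k / k with k = n - 1.
    k_df = counts.shape[1] - 1
    r_max = stats.chi2.ppf(0.999, k_df) / k_df
    # Median-unbiased dispersions (median of chi2_k/k corrects the skew
    # of the variance estimate) feed the robust L1 trend fit.
    m_k = stats.chi2.ppf(0.5, k_df) / k_df
    y_med = (v_ok / m_k - mu_ok * xi) / mu_ok**2

    robust = _l1_fit(x, y_med)
    keep = np.ones(len(x), dtype=bool)
    if robust is not None:
        keep_prev = None
        for _ in range(10):
            a0_r, a1_r = robust
            v_fit = mu_ok * xi + (a0_r + a1_r / mu_ok) * mu_ok**2
            keep = v_ok <= r_max * v_fit
            if keep.sum() < 2:
                keep = np.ones(len(x), dtype=bool)
                break
            if keep_prev is not None and np.array_equal(keep, keep_prev):
                break
            new_robust = _l1_fit(x[keep], y_med[keep])
            if new_robust is None:
                break
            robust = new_robust
            keep_prev = keep

    a0, a1 = _irls_gamma(x[keep], y[keep])
    if a0 is None and robust is not None:
        logger.warning("gamma IRLS dispersion fit failed; using robust L1 fit")
        a0, a1 = robust
    if a0 is None:
        med = float(np.nanmedian(per_gene))
        logger.warning(
            "parametric dispersion fit failed; falling back to median "
            "per-gene dispersion a0=%.4g, a1=0", med
        )
        a0, a1 = (med if np.isfinite(med) else 0.0), 0.0
    return DispersionFit(
        per_gene_alpha=pd.Series(per_gene, index=counts.index, name="alpha"),
        a0=float(a0),
        a1=float(a1),
    )


def _l1_fit(x: np.ndarray, y: np.ndarray):
    """Median (L1) regression of y ~ a0 + a1*x, clipped at zero.

    Robust to a minority of genes whose variance is inflated by real
    regulation; returns None on failure.
    """
    if len(x) < 2:
        return None
    import statsmodels.api as sm

    X = np.column_stack([np.ones_like(x), x])
    try:
        res = sm.QuantReg(y, X).fit(q=0.5, max_iter=2000)
        a0, a1 = float(res.params[0]), float(res.params[1])
    except Exception:
        return None
    if not (np.isfinite(a0) and np.isfinite(a1)):
        return None
    return max(a0, 0.0), max(a1, 0.0)


def _irls_gamma(x: np.ndarray, y: np.ndarray, n_iter: int = 20):
    """IRLS for y ~ a0 + a1*x with gamma-family weights 1/fitted^2.

    Responses are the raw (possibly negative) moment dispersions; using
    them untruncated keeps the fit unbiased at small sample counts.
    Returns (a0, a1) clipped at zero, or (None, None) on failure.
    """
    if len(x) < 2:
        return None, None
    X = np.column_stack([np.ones_like(x), x])
    try:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        for _ in range(n_iter):
            fitted = np.clip(X @ beta, 1e-8, None)
            w = 1.0 / fitted
            beta_new, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
            if not np.all(np.isfinite(beta_new)):
                return None, None
            if np.allclose(beta_new, beta, rtol=1e-8, atol=1e-12):
                beta = beta_new
                break
            beta = beta_new
    except np.linalg.LinAlgError:
        return None, None
    a0, a1 = float(beta[0]), float(beta[1])
    if not (np.isfinite(a0) and np.isfinite(a1)):
        return None, None
    return max(a0, 0.0), max(a1, 0.0)


def _nb_logpmf(k: np.ndarray, mean: float, alpha: float) -> np.ndarray:
    """log PMF with variance mean + alpha*mean^2 (Poisson when alpha<=0)."""
    if mean <= 0:
        # degenerate at zero
        return np.where(np.asarray(k) == 0, 0.0, -np.inf)
    if alpha <= 0:
        return stats.poisson.logpmf(k, mean)
    n = 1.0 / alpha
    p = n / (n + mean)
    return stats.nbinom.logpmf(k, n, p)


def nb_exact_test(k_a: int, k_b: int, s_a: float, s_b: float, alpha_fn) -> float:
    """Exact conditional NB test for two libraries without replicates.

    Conditions on the total ``k_a + k_b``: under the null both counts
    share the pooled normalized mean ``q = (k_a/s_a + k_b/s_b)/2``, and
    the p-value sums the probabilities of all splits of the total that
    are no more likely than the observed one.  ``alpha_fn`` maps a mean
    to a fitted dispersion.  Returns p in (0, 1]; an all-zero pair
    returns 1 by convention.
    """
    if k_a < 0 or k_b < 0:
        raise ValueError("counts must be non-negative")
    if s_a <= 0 or s_b <= 0:
        raise ValueError("size factors must be positive")
    total = int(k_a) + int(k_b)
    if total == 0:
        return 1.0
    q = (k_a / s_a + k_b / s_b) / 2.0
    alpha = float(alpha_fn(q))
    a = np.arange(total + 1)
    lp = _nb_logpmf(a, q * s_a, alpha) + _nb_logpmf(total - a, q * s_b, alpha)
    lp_obs = lp[int(k_a)]
    keep = lp <= lp_obs + 1e-8
    p = float(np.exp(logsumexp(lp[keep]) - logsumexp(lp)))
    return min(max(p, 0.0), 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# variance-stabilizing transformation


def vst_raw(mu, a0: float, a1: float):
    """Uncalibrated VST: the closed form of integral dmu / sqrt(v(mu)).

    With v(mu) = (1 + a1) mu + a0 mu^2 this is
    (2/sqrt(a0)) * asinh(sqrt(a0 * mu / (1 + a1))); the a0 = 0 Poisson
    limit is 2 * sqrt(mu / (1 + a1)).
    """
    mu = np.asarray(mu, dtype=float)
    if a0 < 0 or a1 < 0:
        raise ValueError("dispersion parameters must be non-negative")
    if a0 == 0:
        return 2.0 * np.sqrt(mu / (1.0 + a1))
    return (2.0 / np.sqrt(a0)) * np.arcsinh(np.sqrt(a0 * mu / (1.0 + a1)))


def vst_values(mu, a0: float, a1: float):
    """Calibrated VST of normalized means: log2-like units.

    The raw transform is scaled and shifted so that for large mu a
    doubling adds exactly 1 and the value approaches log2(mu):
    A = sqrt(a0)/ln 2, B = -2*log2(2*sqrt(a0/(1+a1))).  At a0 = 0 no
    log2-like calibration exists; the uncalibrated Poisson limit is
    returned and a warning logged.
    """
    if a0 == 0:
        logger.warning("a0 = 0: returning uncalibrated Poisson-limit VST")
        return vst_raw(mu, a0, a1)
    A = np.sqrt(a0) / np.log(2.0)
    B = -2.0 * np.log2(2.0 * np.sqrt(a0 / (1.0 + a1)))
    return A * vst_raw(mu, a0, a1) + B


def vst(
    counts: pd.DataFrame | CountMatrix,
    sf: pd.Series | np.ndarray,
    fit: DispersionFit,
) -> pd.DataFrame:
    """Variance-stabilized expression matrix from counts and the dispersion fit.

    Applies the calibrated closed-form transform to size-factor
    normalized counts; strictly increasing in the count within a sample.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    sf = np.asarray(sf, dtype=float)
    norm = counts.to_numpy(dtype=float) / sf[None, :]
    vals = vst_values(norm, fit.a0, fit.a1)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# pairwise testing across the time grid


@dataclass(frozen=True)
class DEResult:
    """One pairwise time-point comparison.

    ``table`` has one row per tested gene: baseMeanA, baseMeanB,
    log2FoldChange (+-inf sentinel when one side is zero), pval, padj
    and the significance flag at the configured level.
    """

    time_a: float
    time_b: float
    alpha_level: float
    table: pd.DataFrame

    @property
    def significant_genes(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


def pairwise_de(
    cm: CountMatrix,
    grid: TimeGrid,
    alpha: float = 0.05,
    fit: DispersionFit | None = None,
    sf: pd.Series | None = None,
):
    """Exact NB tests for every unordered pair of time points.

    Technical-replicate columns sharing a time point are summed (their
    size factors add).  Genes with zero counts at every sample are
    dropped before testing and logged.  Returns ``(results, union,
    info)``: one :class:`DEResult` per pair (C(n, 2) comparisons), the
    union of genes significant in at least one comparison, and a dict
    with the dispersion fit and dropped-gene count.
    """
    samples = cm.samples
    if not np.isin(samples["time_days"].unique(), grid.times_array).all():
        raise ValueError("sample sheet contains times not on the grid")
    cols_by_time: dict[float, list[str]] = {}
    for t in grid.times:
        cols = list(samples.index[samples["time_days"] == t])
        if not cols:
            raise ValueError(f"no sample for grid time {t:g}")
        cols_by_time[t] = cols

    counts = cm.counts
    nonzero = counts.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("dropping %d genes with zero counts in all samples", n_dropped)
    counts = counts.loc[nonzero]

    if sf is None:
        sf = size_factors(counts)
    if fit is None:
        fit = estimate_dispersion_blind(counts, sf)

    # aggregate technical replicates: counts and size factors both sum
    agg_counts = {}
    agg_sf = {}
    for t, cols in cols_by_time.items():
        agg_counts[t] = counts[cols].sum(axis=1).to_numpy()
        agg_sf[t] = float(sf[cols].sum())

    results = []
    union: set[str] = set()
    genes = counts.index
    for t_a, t_b in itertools.combinations(grid.times, 2):
        k_a, k_b = agg_counts[t_a], agg_counts[t_b]
        s_a, s_b = agg_sf[t_a], agg_sf[t_b]
        pvals = np.array(
            [nb_exact_test(int(ka), int(kb), s_a, s_b, fit.alpha)
             for ka, kb in zip(k_a, k_b)]
        )
        padj = bh_adjust(pvals)
        base_a = k_a / s_a
        base_b = k_b / s_b
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = np.log2(base_b) - np.log2(base_a)
        lfc = np.where((k_a == 0) & (k_b == 0), 0.0, lfc)
        table = pd.DataFrame(
            {
                "baseMeanA": base_a,
                "baseMeanB": base_b,
                "log2FoldChange": lfc,
                "pval": pvals,
                "padj": padj,
                "significant": padj < alpha,
            },
            index=genes,
        )
        res = DEResult(time_a=t_a, time_b=t_b, alpha_level=alpha, table=table)
        union |= res.significant_genes
        results.append(res)
    info = {"fit": fit, "size_factors": sf, "n_dropped": n_dropped, "alpha": alpha}
    return results, union, info
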