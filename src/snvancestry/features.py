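"""Ancestry-informative SNV selection.

Each SNV is scanned with a Pearson chi-square test of independence between
population label and genotype category (0/1/2).  Because informative sites
in large cohorts reach p-values far below the smallest positive double
(the operating regime is thresholds like 7.5e-49), all p-values are
computed and compared on the log10 scale via the chi-square log survival
function; they are never exponentiated.

The scan is exposed both as module functions operating on
:class:`~snvancestry.containers.GenotypeMatrix` and as the scikit-learn
transformer :class:`ChiSquareSNVSelector`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .containers import (
    AlleleFrequencyTable,
    GenotypeMatrix,
    ValidationError,
    VariantKey,
)

LOG10 = np.log(10.0)

#: default continental p-value threshold (selected by cross-validated
#: accuracy on the aggregate-frequency training regime)
DEFAULT_P_THRESHOLD = 7.5e-49


@dataclass
class FeatureScanResult:
    """Per-variant chi-square scan output (log10 p-values, -inf-safe)."""

    variants: list[VariantKey]
    statistics: np.ndarray
    log10_pvalues: np.ndarray
    dof: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.variants)
        for arr in (self.statistics, self.log10_pvalues, self.dof):
            if len(arr) != n:
                raise ValidationError("scan result arrays disagree in length")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "ref": [v.ref for v in self.variants],
                "alt": [v.alt for v in self.variants],
                "statistic": self.statistics,
                "dof": self.dof,
                "log10_p": self.log10_pvalues,
            }
        )


def _chi_square_columns(X: np.ndarray, y: np.ndarray):
    """Vectorised per-column Pearson chi-square of genotype vs label.

    Contingency rows are populations, columns the genotype categories
    {0,1,2} actually present for that variant (all-zero count columns are
    dropped; dof = (rows-1)(kept_cols-1)).  Returns (stat, log10_p, dof).
    """
    classes, y_idx = np.unique(y, return_inverse=True)
    P = len(classes)
    if P < 2:
        raise ValidationError("chi-square scan needs >= 2 populations")
    n, m = X.shape
    counts = np.zeros((P, 3, m))
    for g in (0, 1, 2):
        mask = X == g
        for p in range(P):
            counts[p, g] = mask[y_idx == p].sum(axis=0)
    col_tot = counts.sum(axis=0)  # 3 x m
    row_tot = counts.sum(axis=1)  # P x m (constant per pop)
    N = float(n)
    kept = (col_tot > 0).sum(axis=0)  # genotype categories present per variant
    expected = row_tot[:, None, :] * col_tot[None, :, :] / N
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    stat = contrib.sum(axis=(0, 1))
    dof = (P - 1) * np.maximum(kept - 1, 0)
    log10_p = np.zeros(m)
    testable = dof > 0
    # log-scale tail: survives statistics whose p underflows double precision
    log10_p[testable] = _chi2_log10_sf(stat[testable], dof[testable])
    stat[~testable] = 0.0  # single genotype category: nothing to test
    return stat, log10_p, dof


def _chi2_log10_sf(stat: np.ndarray, dof: np.ndarray) -> np.ndarray:
    """log10 of the chi-square survival function, finite for any statistic.

    scipy's logsf itself underflows to -inf once the tail drops below the
    smallest subnormal double (statistics beyond ~1490 at 1 dof); those
    entries are replaced by the standard asymptotic expansion of the upper
    incomplete gamma function,
    Q(a, x) ~ x^(a-1) e^-x / Gamma(a) * sum_k Gamma(a) / (Gamma(a-k) x^k),
    with a = dof/2 and x = stat/2.
    """
    from scipy.special import gammaln

    stat = np.asarray(stat, dtype=float)
    dof = np.asarray(dof, dtype=float)
    out = stats.chi2.logsf(stat, dof) / LOG10
    bad = ~np.isfinite(out) & (stat > 0)
    if bad.any():
        a = dof[bad] / 2.0
        x = stat[bad] / 2.0
        series = np.ones_like(x)
        term = np.ones_like(x)
        for k in range(1, 12):
            term = term * (a - k) / x
            series = series + term
        log_q = (a - 1.0) * np.log(x) - x - gammaln(a) + np.log(
            np.maximum(series, np.finfo(float).tiny)
        )
        out[bad] = log_q / LOG10
    return out


def chi_square_scan(
    matrix: GenotypeMatrix, labels: dict[str, str] | None = None
) -> FeatureScanResult:
    """Scan every SNV for association with population label.

    ``labels`` defaults to the matrix's own label map; every sample must be
    labelled.  Variants with a single genotype category get statistic 0 and
    p-value 1 (log10 p = 0).
    """
    if labels is not None:
        missing = [s for s in matrix.samples if s not in labels]
        if missing:
            raise ValidationError(f"labels missing for samples: {missing[:5]}")
        y = np.array([labels[s] for s in matrix.samples])
    else:
        y = matrix.label_array()
    stat, log10_p, dof = _chi_square_columns(matrix.values, y)
    return FeatureScanResult(
        variants=list(matrix.variants),
        statistics=stat,
        log10_pvalues=log10_p,
        dof=dof,
    )


def filter_by_pvalue(
    scan: FeatureScanResult, threshold: float = DEFAULT_P_THRESHOLD
) -> list[VariantKey]:
    """Variants whose p-value <= threshold, order preserved.

    The comparison happens in log10 space so thresholds like 7.5e-49 work
    even though the p-values themselves underflow as plain doubles.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValidationError("threshold must lie in (0, 1]")
    log10_t = np.log10(threshold)
    keep = scan.log10_pvalues <= log10_t
    return [v for v, k in zip(scan.variants, keep) if k]


def min_carrier_filter(
    matrix: GenotypeMatrix, min_carriers: int = 2
) -> GenotypeMatrix:
    """Drop variants carried (genotype > 0) by fewer than ``min_carriers`` samples.

    This is the in-matrix analogue of restricting a kinship analysis to
    variants shared by at least two individuals.
    """
    if min_carriers < 1:
        raise ValidationError("min_carriers must be >= 1")
    carriers = (matrix.values > 0).sum(axis=0)
    return matrix.select_variants(carriers >= min_carriers)


def gnomad_prefilter(
    aft: AlleleFrequencyTable,
    min_freq: float = 0.001,
    callrate_mask: np.ndarray | None = None,
) -> AlleleFrequencyTable:
    """Frequency prefilter on an aggregate AF table.

    Keeps variants whose maximum non-missing population frequency is
    strictly greater than ``min_freq`` (default 0.1%) and, when given, that
    pass a per-variant boolean call-rate mask.  Biallelic-SNV-only is
    structural (the variant key admits nothing else).
    """
    freqs = np.where(aft.missing, -np.inf, aft.freqs)
    keep = freqs.max(axis=0) > min_freq
    if callrate_mask is not None:
        callrate_mask = np.asarray(callrate_mask, dtype=bool)
        if callrate_mask.shape != (aft.n_variants,):
            raise ValidationError("callrate_mask length must equal n_variants")
        keep &= callrate_mask
    return aft.select_variants(keep)


class ChiSquareSNVSelector(SelectorMixin, BaseEstimator):
    """scikit-learn transformer keeping SNVs with chi-square p <= p_threshold.

    Parameters
    ----------
    p_threshold : float, default 7.5e-49
        Retention threshold on the per-variant p-value; comparison is done
        in log10 space.

    Attributes
    ----------
    statistics_ : ndarray of shape (n_features,)
        Pearson chi-square statistic per variant.
    log10_pvalues_ : ndarray of shape (n_features,)
        log10 p-values (0 for untestable variants, i.e. p = 1).
    dof_ : ndarray of shape (n_features,)
        Degrees of freedom per variant.
    """

    def __init__(self, p_threshold: float = DEFAULT_P_THRESHOLD):
        self.p_threshold = p_threshold

    def fit(self, X, y):
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValidationError("p_threshold must lie in (0, 1]")
        X = validate_data(self, X, dtype=np.int64, ensure_2d=True)
        y = np.asarray(y)
        self.statistics_, self.log10_pvalues_, self.dof_ = _chi_square_columns(X, y)
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.log10_pvalues_ <= np.log10(self.p_threshold)
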