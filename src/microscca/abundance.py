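"""Metagenomic feature-table normalization, filtering and Tweedie diagnostics.

Shotgun metagenomic feature tables (KEGG-ortholog gene families or
species) are compositional: per-sample totals reflect library size, not
community size.  The normalization used here divides every count by the
geometric mean of the sample's positive counts -- a hybrid of Aitchison's
centered log-ratio and RPKM that corrects library magnitude and, for gene
families, gene length (per kilobase) in one step.  Dividing by the
geometric mean rather than the total keeps the transform equivariant
under per-sample rescaling while leaving values on a nonnegative scale a
Tweedie model can describe.

Tables are oriented features x samples, matching the on-disk TSV layout;
the sklearn-style transformers in this module follow the sklearn
convention (samples x features) instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .tweedie import TweedieFit, tweedie_zero_probability

__all__ = [
    "FeatureTable",
    "geometric_mean_positive",
    "modified_rpkm",
    "normalize_geometric_mean",
    "prevalence_filter",
    "estimate_taylor_power",
    "zero_diagnostic",
    "GeometricMeanNormalizer",
    "PrevalenceFilter",
]


@dataclass
class FeatureTable:
    """Nonnegative feature x sample abundance table.

    Parameters
    ----------
    values : pandas.DataFrame
        Features in rows, samples in columns; nonnegative, finite.
    lengths : pandas.Series, optional
        Per-feature length in bases (gene-family tables); positive,
        indexed like ``values``.  Species tables carry no lengths.
    normalization : str or None
        ``None`` for raw counts, else ``"modified_rpkm"`` or
        ``"geometric_mean_only"``.
    """

    values: pd.DataFrame
    lengths: pd.Series | None = None
    normalization: str | None = None

    def __post_init__(self):
        v = self.values
        if not np.isfinite(v.to_numpy()).all() or (v.to_numpy() < 0).any():
            raise ValueError("feature table must be nonnegative and finite")
        if v.index.has_duplicates or v.columns.has_duplicates:
            raise ValueError("feature and sample identifiers must be unique")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(v.index)
            if self.lengths.isna().any() or (self.lengths <= 0).any():
                raise ValueError("lengths must be positive and cover every feature")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def geometric_mean_positive(x) -> float:
    """Geometric mean of the strictly positive entries of ``x``.

    Zeros are excluded from the mean rather than pseudocounted, which
    preserves scale equivariance: ``g(k*x) = k*g(x)``.

    Raises
    ------
    ValueError
        If ``x`` has no positive entry (an unusable, all-zero sample).
    """
    x = np.asarray(x, dtype=float)
    pos = x[x > 0]
    if pos.size == 0:
        raise ValueError("all-zero vector: geometric mean undefined for this sample")
    return float(np.exp(np.mean(np.log(pos))))


def _sample_geometric_means(values: np.ndarray) -> np.ndarray:
    """Per-column geometric mean of positive entries (columns = samples)."""
    with np.errstate(divide="ignore"):
        logs = np.where(values > 0, np.log(np.where(values > 0, values, 1.0)), 0.0)
    npos = (values > 0).sum(axis=0)
    if np.any(npos == 0):
        bad = np.flatnonzero(npos == 0)
        raise ValueError(f"sample(s) at positions {bad.tolist()} contain only zeros")
    return np.exp(logs.sum(axis=0) / npos)


def modified_rpkm(table: FeatureTable) -> FeatureTable:
    """Length- and compositionality-corrected abundances for gene families.

    ``value[i, j] = count[i, j] / ((length[i] / 1000) * g[j])`` where
    ``g[j]`` is the geometric mean of sample ``j``'s positive counts.
    Zeros map to zeros; the result is invariant to rescaling a sample's
    counts by any positive constant.
    """
    if table.lengths is None:
        raise ValueError(
            "feature lengths are required for modified RPKM; use "
            "normalize_geometric_mean for length-free (species) tables"
        )
    counts = table.values.to_numpy(dtype=float)
    g = _sample_geometric_means(counts)
    kb = table.lengths.to_numpy(dtype=float) / 1000.0
    out = counts / (kb[:, None] * g[None, :])
    values = pd.DataFrame(out, index=table.feature_ids, columns=table.sample_ids)
    return FeatureTable(values, lengths=table.lengths, normalization="modified_rpkm")


def normalize_geometric_mean(table: FeatureTable) -> FeatureTable:
    """Divide each sample by its positive-entry geometric mean (species tables)."""
    counts = table.values.to_numpy(dtype=float)
    g = _sample_geometric_means(counts)
    values = pd.DataFrame(
        counts / g[None, :], index=table.feature_ids, columns=table.sample_ids
    )
    return FeatureTable(values, lengths=table.lengths, normalization="geometric_mean_only")


def prevalence_filter(table: FeatureTable, min_prevalence: float = 0.10) -> FeatureTable:
    """Retain features present (value > 0) in at least ``min_prevalence``
    of samples; the boundary is inclusive. Feature order is preserved."""
    if not (0.0 < min_prevalence <= 1.0):
        raise ValueError("min_prevalence must lie in (0, 1]")
    prev = (table.values.to_numpy() > 0).mean(axis=1)
    keep = prev >= min_prevalence
    if not keep.any():
        warnings.warn("prevalence filter removed every feature", stacklevel=2)
    values = table.values.loc[keep]
    lengths = table.lengths.loc[keep] if table.lengths is not None else None
    return FeatureTable(values, lengths=lengths, normalization=table.normalization)


def estimate_taylor_power(table: FeatureTable) -> TweedieFit:
    """Fit ``Var(Y) = phi * mu**p`` by OLS of log variance on log mean.

    Each feature contributes one (mean, variance) point across samples;
    features with zero mean or zero variance are excluded (not imputed).
    The slope estimates the Tweedie power ``p`` and ``exp`` of the
    intercept the dispersion ``phi``.
    """
    v = table.values.to_numpy(dtype=float)
    means = v.mean(axis=1)
    varis = v.var(axis=1, ddof=1)
    ok = (means > 0) & (varis > 0)
    if ok.sum() < 3:
        raise ValueError(
            f"need >= 3 features with positive mean and variance, got {int(ok.sum())}"
        )
    x = np.log(means[ok])
    y = np.log(varis[ok])
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    ise, sse = res.bse
    return TweedieFit(
        p=float(slope),
        phi=float(np.exp(intercept)),
        slope_se=float(sse),
        intercept_se=float(ise),
        n_features_used=int(ok.sum()),
    )


def zero_diagnostic(table: FeatureTable, fit: TweedieFit) -> pd.DataFrame:
    """Observed vs Tweedie-expected zero proportion per feature.

    Under a well-specified fit the two agree along the diagonal.  The
    expected proportion is ``P(Y=0)`` at the feature's mean with the
    table-level ``(p, phi)``; requires ``1 < p < 2``.
    """
    means = table.values.mean(axis=1)
    if (means <= 0).any():
        raise ValueError("all-zero features must be prevalence-filtered first")
    expected = tweedie_zero_probability(means.to_numpy(), fit.phi, fit.p)
    observed = (table.values == 0).mean(axis=1)
    return pd.DataFrame(
        {"expected_zero": expected, "observed_zero": observed}, index=table.feature_ids
    )


class GeometricMeanNormalizer(BaseEstimator, TransformerMixin):
    """Sklearn transformer for the per-sample geometric-mean normalization.

    Operates on samples x features arrays (sklearn orientation).  When
    ``lengths`` is given, counts are additionally divided by feature
    length per kilobase (modified RPKM); otherwise only the sample
    geometric mean is removed.  Stateless: ``fit`` only validates.
    """

    def __init__(self, lengths=None):
        self.lengths = lengths

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.lengths is not None and len(np.asarray(self.lengths)) != X.shape[1]:
            raise ValueError("lengths must have one entry per feature column")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = np.asarray(X, dtype=float)
        g = _sample_geometric_means(X.T)
        out = X / g[:, None]
        if self.lengths is not None:
            out = out / (np.asarray(self.lengths, dtype=float) / 1000.0)[None, :]
        return out


class PrevalenceFilter(BaseEstimator, TransformerMixin):
    """Column filter keeping features nonzero in >= ``min_prevalence`` of rows."""

    def __init__(self, min_prevalence: float = 0.10):
        self.min_prevalence = min_prevalence

    def fit(self, X, y=None):
        if not (0.0 < self.min_prevalence <= 1.0):
            raise ValueError("min_prevalence must lie in (0, 1]")
        X = np.asarray(X, dtype=float)
        self.support_ = (X > 0).mean(axis=0) >= self.min_prevalence
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X)[:, self.support_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_
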