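"""Covariate, ancestry and twin-relatedness adjustment of both views.

Before canonical correlation, abundances and coded genotypes are each
residualized against the same nuisance structure: fixed effects for age
at sampling, BMI, shipment batch and ancestry principal components, and
a random intercept per twin pair that absorbs the correlation of a
person with their own co-twin.  Abundances use a Tweedie generalized
linear mixed model with log link fit by penalized quasi-likelihood
(PQL); the power ``p`` comes from the table-level Taylor-law fit and the
dispersion is re-estimated per feature.  Genotype columns use a Gaussian
linear mixed model.  With all-distinct family labels both paths reduce
exactly to plain GLM/LM residuals, so the pipeline applies unchanged to
cohorts of unrelated individuals.

Pearson residuals are returned for the abundance side (variance-
standardized, suitable for correlation analysis); raw conditional
residuals for the genotype side.  All residual columns are centered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .abundance import FeatureTable
from .genotype import CodedGenotypeMatrix
from .lmm import FamilyBlocks, fit_lmm, lmm_residuals_many

__all__ = [
    "ResidualMatrix",
    "validate_covariates",
    "build_design",
    "tweedie_glmm_residuals",
    "gaussian_lmm_residuals",
    "MixedModelResidualizer",
]

_REQUIRED = ("age", "bmi", "shipment", "family_id")


@dataclass
class ResidualMatrix:
    """Centered residuals, samples x features.

    ``source`` tags the origin (``"abundance"`` or ``"genotype"``);
    ``groups`` carries the coded-column -> locus map for the genotype
    side; ``excluded`` lists features dropped for non-convergence.
    """

    values: pd.DataFrame
    source: str
    groups: pd.Series | None = None
    excluded: list = field(default_factory=list)

    def __post_init__(self):
        v = self.values.to_numpy()
        if not np.isfinite(v).all():
            raise ValueError("residuals must be finite")
        col_means = v.mean(axis=0)
        if v.size and np.abs(col_means).max() > 1e-8:
            raise ValueError("residual columns must be centered")


def validate_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, missingness, and family sizes (<= 2)."""
    missing = [c for c in _REQUIRED if c not in cov.columns]
    if missing:
        raise ValueError(f"covariate table lacks columns: {missing}")
    if cov[list(_REQUIRED)].isna().any().any():
        raise ValueError("covariates contain missing values")
    if cov.index.has_duplicates:
        raise ValueError("one row per sample required")
    if (cov.groupby("family_id").size() > 2).any():
        raise ValueError("every family_id may have at most two members")
    return cov


def build_design(cov: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect design: intercept + age + BMI + shipment dummies + PCs.

    Shipment uses treatment (drop-first) dummy coding; a single shipment
    level contributes no dummies.  Ancestry PC columns are any columns
    named ``PC<number>``.  Column names are stable across calls.
    """
    cov = validate_covariates(cov)
    parts = [pd.Series(1.0, index=cov.index, name="intercept")]
    for col in ("age", "bmi"):
        vals = cov[col].astype(float)
        if vals.nunique() == 1:
            warnings.warn(f"covariate {col!r} is constant", stacklevel=2)
        parts.append(vals.rename(col))
    ship = cov["shipment"].astype(str)
    levels = sorted(ship.unique())
    for lev in levels[1:]:
        parts.append((ship == lev).astype(float).rename(f"shipment[{lev}]"))
    pc_cols = [c for c in cov.columns if c.startswith("PC") and c[2:].isdigit()]
    pc_cols = sorted(pc_cols, key=lambda c: int(c[2:]))
    for c in pc_cols:
        parts.append(cov[c].astype(float).rename(c))
    return pd.concat(parts, axis=1)


def _pql_feature(y, X, blocks, p, max_iter=8, tol=1e-6):
    """One Tweedie PQL fit; returns (mu, n_iter, converged)."""
    y = np.asarray(y, dtype=float)
    mu = (y + y.mean()) / 2.0
    mu = np.maximum(mu, 1e-8)
    eta = np.log(mu)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = eta + (y - mu) / mu
        w = mu ** (2.0 - p)
        res = fit_lmm(z, X, blocks, weights=w)
        eta_new = np.clip(res["fitted"], -30.0, 30.0)
        delta = np.max(np.abs(eta_new - eta)) / (np.max(np.abs(eta)) + 1.0)
        eta = eta_new
        mu = np.exp(eta)
        if delta < tol:
            converged = True
            break
    return mu, it, converged


def _glm_fallback(y, design: pd.DataFrame, cov: pd.DataFrame, p: float):
    """Tweedie GLM with fixed family intercepts (mixed-fit fallback)."""
    fam = pd.get_dummies(cov["family_id"].astype(str), prefix="fam", drop_first=True)
    X = pd.concat([design, fam.astype(float).set_index(design.index)], axis=1)
    model = sm.GLM(y, X.to_numpy(), family=sm.families.Tweedie(var_power=p))
    return np.asarray(model.fit(maxiter=100, tol=1e-8).mu)


def tweedie_glmm_residuals(
    table: FeatureTable,
    cov: pd.DataFrame,
    p: float,
    residual_type: str = "pearson",
    max_iter: int = 8,
) -> ResidualMatrix:
    """Per-feature Tweedie mixed-model residuals (samples x features).

    Fixed effects from :func:`build_design`, random intercept per
    ``family_id``, log link, power ``p`` fixed table-wide (from the
    Taylor-law fit) with dispersion re-estimated per feature.  Features
    whose mixed fit fails fall back to fixed family intercepts; features
    failing both are dropped and recorded in ``excluded``.
    """
    if not (1.0 < p < 2.0):
        raise ValueError(f"power p={p} must lie in (1, 2)")
    if residual_type not in ("pearson", "response"):
        raise ValueError("residual_type must be 'pearson' or 'response'")
    cov = validate_covariates(cov).loc[table.sample_ids]
    design = build_design(cov)
    X = design.to_numpy(dtype=float)
    q = X.shape[1]
    blocks = _blocks_for(cov)
    Y = table.values.to_numpy(dtype=float).T  # samples x features
    if (Y.sum(axis=0) == 0).any():
        raise ValueError("all-zero features must be prevalence-filtered first")
    cols, kept, excluded = [], [], []
    for j, fid in enumerate(table.feature_ids):
        y = Y[:, j]
        mu = None
        try:
            mu, _, _ = _pql_feature(y, X, blocks, p, max_iter=max_iter)
            if not np.isfinite(mu).all():
                raise FloatingPointError("non-finite PQL fit")
        except Exception:
            try:
                mu = _glm_fallback(y, design, cov, p)
            except Exception:
                mu = None
        if mu is None or not np.isfinite(mu).all() or np.any(mu <= 0):
            excluded.append(str(fid))
            warnings.warn(f"feature {fid!r} dropped: residual fit failed", stacklevel=2)
            continue
        if residual_type == "pearson":
            r = (y - mu) / np.sqrt(mu**p)
            phi_j = float((r**2).sum() / max(len(y) - q, 1))
            r = r / np.sqrt(max(phi_j, 1e-300))
        else:
            r = y - mu
        cols.append(r - r.mean())
        kept.append(fid)
    values = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((table.n_samples, 0)),
        index=table.sample_ids,
        columns=kept,
    )
    return ResidualMatrix(values, source="abundance", excluded=excluded)


def gaussian_lmm_residuals(
    coded: CodedGenotypeMatrix, cov: pd.DataFrame
) -> ResidualMatrix:
    """Gaussian mixed-model residuals of every coded genotype column.

    Same fixed effects as the abundance side, random intercept per
    family; conditional residuals are exactly orthogonal to the fixed-
    effect design.  The column -> locus group map is carried through.
    """
    cov = validate_covariates(cov).loc[coded.columns.index]
    X = build_design(cov).to_numpy(dtype=float)
    blocks = _blocks_for(cov)
    resid = lmm_residuals_many(coded.columns.to_numpy(dtype=float), X, blocks)
    values = pd.DataFrame(
        resid, index=coded.columns.index, columns=coded.columns.columns
    )
    return ResidualMatrix(values, source="genotype", groups=coded.groups)


def _blocks_for(cov: pd.DataFrame) -> FamilyBlocks:
    return FamilyBlocks(cov["family_id"].to_numpy())


class MixedModelResidualizer(BaseEstimator, TransformerMixin):
    """Sklearn-style residualizer for either view.

    Parameters
    ----------
    kind : {"gaussian", "tweedie"}
        Gaussian LMM (genotype columns) or Tweedie PQL (abundances).
    power : float
        Tweedie power, used when ``kind="tweedie"``.
    residual_type : {"pearson", "response"}
        Abundance residual flavor.

    ``fit`` requires ``covariates=`` (a validated covariate frame
    aligned to the rows of ``X``).  ``transform`` returns the residual
    matrix for the fitted data; this is a per-dataset adjustment, not a
    mapping to out-of-sample rows.
    """

    def __init__(self, kind: str = "gaussian", power: float = 1.6,
                 residual_type: str = "pearson", max_iter: int = 8):
        self.kind = kind
        self.power = power
        self.residual_type = residual_type
        self.max_iter = max_iter

    def fit(self, X, y=None, covariates: pd.DataFrame | None = None):
        if covariates is None:
            raise ValueError("covariates= is required")
        X = self._frame(X, covariates.index)
        if self.kind == "gaussian":
            cov = validate_covariates(covariates).loc[X.index]
            D = build_design(cov).to_numpy(dtype=float)
            resid = lmm_residuals_many(
                X.to_numpy(dtype=float), D, _blocks_for(cov)
            )
            self.residuals_ = pd.DataFrame(resid, index=X.index, columns=X.columns)
            self.excluded_ = []
        elif self.kind == "tweedie":
            table = FeatureTable(X.T)
            rm = tweedie_glmm_residuals(
                table, covariates, self.power,
                residual_type=self.residual_type, max_iter=self.max_iter,
            )
            self.residuals_ = rm.values
            self.excluded_ = rm.excluded
        else:
            raise ValueError("kind must be 'gaussian' or 'tweedie'")
        return self

    def transform(self, X):
        # per-dataset adjustment: X must be the fitted data; returned
        # residuals are those computed in fit
        check_is_fitted(self, "residuals_")
        if np.asarray(X).shape[0] != self.residuals_.shape[0]:
            raise ValueError("residualization does not extend to new samples")
        return self.residuals_.to_numpy()

    @staticmethod
    def _frame(X, index):
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(
            X, index=index, columns=[f"f{j}" for j in range(X.shape[1])]
        )
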