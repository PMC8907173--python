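"""Genotype filtering, additive/dominance coding and ancestry PCs.

The QC chain mirrors common GWAS practice (plink-style flags): drop loci
with any missing call, drop rare alleles (MAF < 0.10), drop loci out of
Hardy-Weinberg equilibrium (1-df chi-square, alpha = 0.001), and prune
one member of each pair in high linkage disequilibrium (r^2 > 0.8,
sliding window of 50 loci advancing by 10).  The filter order
missing -> MAF -> HWE -> LD is fixed; each filter is idempotent.

Each surviving locus is expanded to two orthogonal predictor columns:
an additive code {1, 0, -1} counting alleles and a dominance code
{-1, 1, -1} carrying the heterozygote effect.  Genotype calls 0/1/2 map
to (1,-1), (0,1), (-1,-1).  The two columns of a locus form one group
for group-lasso selection downstream, so a variant is selected or
dropped as a whole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GenotypeMatrix",
    "CodedGenotypeMatrix",
    "filter_missing",
    "filter_maf",
    "filter_hwe",
    "ld_prune",
    "code_additive_dominance",
    "decode_additive_dominance",
    "hwe_chi_square",
    "ancestry_pcs",
    "GenotypeQC",
    "AdditiveDominanceEncoder",
    "AncestryPCA",
]

# call value -> (additive, dominance)
_ADD_CODE = {0: 1.0, 1: 0.0, 2: -1.0}
_DOM_CODE = {0: -1.0, 1: 1.0, 2: -1.0}


@dataclass
class GenotypeMatrix:
    """Samples x loci matrix of minor-allele counts {0, 1, 2, NaN}.

    ``loci`` carries per-locus metadata indexed by locus identifier with
    at least ``chrom`` and ``pos`` columns; positions must be
    nondecreasing within each chromosome.
    """

    calls: pd.DataFrame
    loci: pd.DataFrame

    def __post_init__(self):
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype calls must be 0, 1, 2 or missing")
        if not self.calls.columns.equals(self.loci.index):
            raise ValueError("loci metadata must align with call columns")
        for _, sub in self.loci.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError("locus positions must be nondecreasing per chromosome")

    @property
    def sample_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def subset(self, keep) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.loc[:, keep], self.loci.loc[keep])


@dataclass
class CodedGenotypeMatrix:
    """Additive/dominance design: samples x (2 * n_loci) real columns.

    ``groups`` maps each column name to its locus identifier; every
    locus owns exactly one additive and one dominance column (named
    ``<locus>:add`` and ``<locus>:dom``).
    """

    columns: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        if not self.columns.columns.equals(self.groups.index):
            raise ValueError("group map must align with coded columns")
        counts = self.groups.value_counts()
        if (counts != 2).any():
            raise ValueError("every locus must own exactly two coded columns")

    @property
    def locus_ids(self) -> pd.Index:
        return pd.Index(pd.unique(self.groups))

    def group_index(self) -> np.ndarray:
        """Integer group label per column, in column order."""
        return pd.factorize(self.groups)[0]


def filter_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Drop every locus with at least one missing call (plink ``--geno 0``)."""
    keep = g.calls.notna().all(axis=0)
    return g.subset(keep[keep].index)


def _maf(calls: np.ndarray) -> np.ndarray:
    f = calls.sum(axis=0) / (2.0 * calls.shape[0])
    return np.minimum(f, 1.0 - f)


def filter_maf(g: GenotypeMatrix, min_maf: float = 0.10) -> GenotypeMatrix:
    """Keep loci with minor allele frequency >= ``min_maf`` (inclusive)."""
    _require_complete(g)
    keep = _maf(g.calls.to_numpy(dtype=float)) >= min_maf
    return g.subset(g.calls.columns[keep])


def hwe_chi_square(n0: int, n1: int, n2: int) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit of genotype counts against the
    Hardy-Weinberg expectations from the sample allele frequency.

    Returns ``(chi2, p)``; ``(nan, 0.0)`` when any expected count is
    zero (monomorphic or degenerate locus, treated as failing).
    """
    n = n0 + n1 + n2
    f = (n1 + 2 * n2) / (2.0 * n)
    exp = np.array([(1 - f) ** 2 * n, 2 * f * (1 - f) * n, f**2 * n])
    if np.any(exp == 0):
        return float("nan"), 0.0
    obs = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def filter_hwe(g: GenotypeMatrix, alpha: float = 0.001) -> GenotypeMatrix:
    """Drop loci whose HWE chi-square p-value falls below ``alpha``."""
    _require_complete(g)
    calls = g.calls.to_numpy(dtype=float)
    n = calls.shape[0]
    n2 = (calls == 2).sum(axis=0)
    n1 = (calls == 1).sum(axis=0)
    n0 = n - n1 - n2
    f = (n1 + 2 * n2) / (2.0 * n)
    exp0 = (1 - f) ** 2 * n
    exp1 = 2 * f * (1 - f) * n
    exp2 = f**2 * n
    degenerate = (exp0 == 0) | (exp1 == 0) | (exp2 == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (
            (n0 - exp0) ** 2 / exp0
            + (n1 - exp1) ** 2 / exp1
            + (n2 - exp2) ** 2 / exp2
        )
    pvals = stats.chi2.sf(chi2, df=1)
    keep = ~degenerate & (pvals >= alpha)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} loci with zero expected HWE counts dropped",
            stacklevel=2,
        )
    return g.subset(g.calls.columns[keep])


def ld_prune(
    g: GenotypeMatrix,
    window: int = 50,
    step: int = 10,
    r2_max: float = 0.8,
) -> GenotypeMatrix:
    """Sliding-window LD pruning of allele-count correlations.

    Within each window of ``window`` loci (advancing by ``step``, per
    chromosome), pairs with squared Pearson correlation > ``r2_max`` are
    broken by removing the member with the lower MAF (tie: the later
    position).  No surviving within-window pair exceeds the threshold.
    """
    _require_complete(g)
    calls = g.calls.to_numpy(dtype=float)
    mafs = _maf(calls)
    col_pos = {c: i for i, c in enumerate(g.calls.columns)}
    removed: set[int] = set()
    for _, sub in g.loci.groupby("chrom", sort=False):
        idx = np.array([col_pos[c] for c in sub.index])
        start = 0
        while True:
            win = idx[start : start + window]
            if len(win) > 1:
                _prune_window(calls, win, mafs, r2_max, removed)
            if start + window >= len(idx):
                break
            start += step
    keep = [c for c in g.calls.columns if col_pos[c] not in removed]
    return g.subset(keep)


def _prune_window(calls, win, mafs, r2_max, removed):
    active = [i for i in win if i not in removed]
    while len(active) > 1:
        block = calls[:, active]
        sd = block.std(axis=0)
        ok = sd > 0
        r = np.zeros((len(active), len(active)))
        if ok.any():
            sub = np.corrcoef(block[:, ok], rowvar=False)
            r[np.ix_(ok, ok)] = np.atleast_2d(sub)
        np.fill_diagonal(r, 0.0)
        r2 = r**2
        if np.nanmax(r2) <= r2_max:
            break
        a, b = np.unravel_index(np.nanargmax(r2), r2.shape)
        ia, ib = active[a], active[b]
        # drop the lower-MAF member; on ties, the later column position
        if (mafs[ia], -ia) < (mafs[ib], -ib):
            drop = ia
        else:
            drop = ib
        removed.add(drop)
        active.remove(drop)


def code_additive_dominance(g: GenotypeMatrix) -> CodedGenotypeMatrix:
    """Expand calls to additive {1,0,-1} and dominance {-1,1,-1} columns.

    The codes are orthogonal whenever genotype frequencies sit at the
    1/4 : 1/2 : 1/4 balance; the coding is bijective per call value, so
    ``decode_additive_dominance`` recovers calls exactly.
    """
    _require_complete(g)
    calls = g.calls.to_numpy(dtype=float).astype(int)
    add = np.select([calls == 0, calls == 1, calls == 2], [1.0, 0.0, -1.0])
    dom = np.select([calls == 0, calls == 1, calls == 2], [-1.0, 1.0, -1.0])
    n_loci = calls.shape[1]
    cols = np.empty((calls.shape[0], 2 * n_loci))
    cols[:, 0::2] = add
    cols[:, 1::2] = dom
    names, group = [], []
    for locus in g.calls.columns:
        names.extend([f"{locus}:add", f"{locus}:dom"])
        group.extend([locus, locus])
    columns = pd.DataFrame(cols, index=g.sample_ids, columns=names)
    return CodedGenotypeMatrix(columns, pd.Series(group, index=names, name="locus"))


def decode_additive_dominance(coded: CodedGenotypeMatrix) -> pd.DataFrame:
    """Invert the coding: (1,-1) -> 0, (0,1) -> 1, (-1,-1) -> 2."""
    add = coded.columns.iloc[:, 0::2].to_numpy()
    calls = np.select([add == 1.0, add == 0.0, add == -1.0], [0, 1, 2])
    loci = [coded.groups.iloc[i] for i in range(0, coded.columns.shape[1], 2)]
    return pd.DataFrame(calls, index=coded.columns.index, columns=loci)


def ancestry_pcs(
    g: GenotypeMatrix, k: int = 10, family_ids: pd.Series | None = None
) -> pd.DataFrame:
    """Ancestry principal-component scores for every sample.

    To avoid twin pairs dominating the rotation, PCA loadings are fit on
    one representative per family (the lowest-sorting sample identifier)
    after centering and scaling the additive dosages by the
    representatives' statistics; all samples -- including held-out
    co-twins -- are then scored on those loadings.  Identical genotype
    rows (MZ twins) receive identical scores.
    """
    _require_complete(g)
    if k == 0:
        return pd.DataFrame(index=g.sample_ids)
    if k > g.n_loci:
        raise ValueError(f"k={k} exceeds the {g.n_loci} retained loci")
    if family_ids is None:
        reps = list(g.sample_ids)
    else:
        fam = pd.Series(family_ids).reindex(g.sample_ids)
        reps = [sorted(members.index)[0] for _, members in fam.groupby(fam)]
    train = g.calls.loc[reps].to_numpy(dtype=float)
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit((train - mean) / sd)
    scores = pca.transform((g.calls.to_numpy(dtype=float) - mean) / sd)
    return pd.DataFrame(
        scores, index=g.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )


def _require_complete(g: GenotypeMatrix):
    if g.calls.isna().any().any():
        raise ValueError("missing calls present; apply filter_missing first")


class GenotypeQC(BaseEstimator, TransformerMixin):
    """Missing -> MAF -> HWE -> LD filter chain as a column selector.

    ``positions`` (and optionally ``chromosomes``) give the genomic
    order used by the LD window; both default to the column order on a
    single chromosome.  ``fit`` learns the retained-locus mask on an
    (n_samples, n_loci) call matrix; ``transform`` subsets columns.
    """

    def __init__(
        self,
        min_maf: float = 0.10,
        hwe_alpha: float = 0.001,
        ld_window: int = 50,
        ld_step: int = 10,
        ld_r2: float = 0.8,
        positions=None,
        chromosomes=None,
    ):
        self.min_maf = min_maf
        self.hwe_alpha = hwe_alpha
        self.ld_window = ld_window
        self.ld_step = ld_step
        self.ld_r2 = ld_r2
        self.positions = positions
        self.chromosomes = chromosomes

    def fit(self, X, y=None):
        g = self._as_genotype_matrix(X)
        g = filter_missing(g)
        g = filter_maf(g, self.min_maf)
        g = filter_hwe(g, self.hwe_alpha)
        g = ld_prune(g, self.ld_window, self.ld_step, self.ld_r2)
        all_ids = self._locus_ids(X)
        self.support_ = np.isin(all_ids, g.calls.columns.to_numpy())
        self.n_features_in_ = len(all_ids)
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X, dtype=float)[:, self.support_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_

    def _locus_ids(self, X):
        if isinstance(X, pd.DataFrame):
            return X.columns.to_numpy()
        return np.array([f"locus{i}" for i in range(np.asarray(X).shape[1])])

    def _as_genotype_matrix(self, X) -> GenotypeMatrix:
        calls = (
            X.astype(float)
            if isinstance(X, pd.DataFrame)
            else pd.DataFrame(np.asarray(X, dtype=float), columns=self._locus_ids(X))
        )
        n_loci = calls.shape[1]
        pos = self.positions if self.positions is not None else np.arange(n_loci)
        chrom = self.chromosomes if self.chromosomes is not None else np.repeat("1", n_loci)
        loci = pd.DataFrame({"chrom": chrom, "pos": pos}, index=calls.columns)
        return GenotypeMatrix(calls, loci)


class AdditiveDominanceEncoder(BaseEstimator, TransformerMixin):
    """Stateless transformer expanding 0/1/2 calls to paired columns."""

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        calls = np.asarray(X, dtype=float).astype(int)
        out = np.empty((calls.shape[0], 2 * calls.shape[1]))
        out[:, 0::2] = np.select([calls == 0, calls == 1, calls == 2], [1.0, 0.0, -1.0])
        out[:, 1::2] = np.select([calls == 0, calls == 1, calls == 2], [-1.0, 1.0, -1.0])
        return out

    def group_index(self) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        return np.repeat(np.arange(self.n_features_in_), 2)


class AncestryPCA(BaseEstimator, TransformerMixin):
    """PCA scores from additive dosages, loadings fit family-aware.

    ``families`` (one label per row, passed to ``fit``) selects one
    representative per family for the rotation; scores are produced for
    all rows.
    """

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, X, y=None, families=None):
        X = self._frame(X)
        if families is not None:
            fam = pd.Series(families, index=X.index)
            reps = [sorted(members.index)[0] for _, members in fam.groupby(fam)]
        else:
            reps = list(X.index)
        train = X.loc[reps].to_numpy(dtype=float)
        self.mean_ = train.mean(axis=0)
        sd = train.std(axis=0)
        sd[sd == 0] = 1.0
        self.scale_ = sd
        self.pca_ = PCA(n_components=self.n_components, svd_solver="full")
        self.pca_.fit((train - self.mean_) / self.scale_)
        self.scores_ = pd.DataFrame(
            self.pca_.transform((X.to_numpy(dtype=float) - self.mean_) / self.scale_),
            index=X.index,
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "scores_")
        X = self._frame(X).to_numpy(dtype=float)
        return self.pca_.transform((X - self.mean_) / self.scale_)

    @staticmethod
    def _frame(X):
        if isinstance(X, pd.DataFrame):
            return X.astype(float)
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(
            X,
            index=[f"s{i}" for i in range(X.shape[0])],
            columns=[f"locus{j}" for j in range(X.shape[1])],
        )
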