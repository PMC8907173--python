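"""Sparse canonical correlation analysis with group-lasso and elastic-net
penalties.

The model seeks paired weight vectors (beta over coded genotype columns,
alpha over microbial features) minimizing

    || X beta - Y alpha ||_2^2  +  lambda1 * pen1(beta)  +  lambda2 * pen2(alpha)
    subject to  ||X beta||_2 = ||Y alpha||_2 = 1,

where ``pen1`` is a group lasso over the additive/dominance column pair
of each variant (a variant is selected whole or not at all) and ``pen2``
is an elastic net (correlated features are selected together).  The fit
alternates penalized regressions -- beta on X with target Y alpha, then
alpha on Y with target X beta -- rescaling the active variate to unit
norm after each half-step.  Additional components are extracted after
matrix deflation: every column is replaced by its residual against the
component's canonical variate, so later components describe structure
orthogonal to what was already found.

Because penalization biases the weight magnitudes unevenly across
features, weights are interpreted as zero / nonzero only (selection);
after selection, a classical CCA refit on the reduced column sets gives
the reported canonical correlation.

:class:`SparseCCA` wraps the whole procedure (cross-validated penalty
tuning, per-component fit, refit, deflation) as a scikit-learn style
estimator; the module functions expose each step separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PenaltyGrid",
    "CanonicalComponent",
    "SccaModel",
    "group_lasso_step",
    "elastic_net_step",
    "group_lasso_max_penalty",
    "elastic_net_max_penalty",
    "build_penalty_grid",
    "build_sparsity_grid",
    "scca_fit",
    "tune_penalties",
    "deflate",
    "final_cca",
    "run_scca",
    "selection_summary",
    "selection_overlap",
    "SparseCCA",
]


@dataclass(frozen=True)
class PenaltyGrid:
    """Candidate penalty pairs and the elastic-net mixing.

    ``mode="penalty"``: pairs are absolute (lambda1, lambda2) values.
    ``mode="sparsity"``: pairs are (k_groups, k_features) bounds; at each
    half-step the penalty level is found by bisection so that at most
    that many groups/features stay active -- the bound-form
    parameterization of penalized matrix decomposition, which keeps the
    alternation stable when the matrices have far more columns than
    samples.  Every bound still maps to a data-derived lambda at which
    the exact penalized regression is solved.
    """

    pairs: tuple
    elastic_net_mixing: float = 0.5
    mode: str = "penalty"

    def __post_init__(self):
        if len(self.pairs) == 0:
            raise ValueError("penalty grid must contain at least one pair")
        if not (0.0 < self.elastic_net_mixing <= 1.0):
            raise ValueError("elastic_net_mixing must lie in (0, 1]")
        if self.mode not in ("penalty", "sparsity"):
            raise ValueError("mode must be 'penalty' or 'sparsity'")
        for l1, l2 in self.pairs:
            if l1 < 0 or l2 < 0:
                raise ValueError("penalties must be nonnegative")
            if self.mode == "sparsity" and (l1 < 1 or l2 < 1):
                raise ValueError("sparsity bounds must be >= 1")


@dataclass
class CanonicalComponent:
    """One canonical pair: sparse weights, selections, correlation."""

    beta: pd.Series
    alpha: pd.Series
    selected_snps: list
    selected_features: list
    canonical_correlation: float
    n_iterations: int
    converged: bool
    status: str = "ok"
    objective_trace: np.ndarray | None = None
    penalties: tuple | None = None  # realized (lambda1, lambda2)

    @property
    def is_empty(self) -> bool:
        return self.status == "collapsed"


@dataclass
class SccaModel:
    """Ordered components with their tuning and deflation records."""

    components: list = field(default_factory=list)
    selection_components: list = field(default_factory=list)
    penalty_pairs_chosen: list = field(default_factory=list)
    cv_tables: list = field(default_factory=list)
    deflation_history: list = field(default_factory=list)
    status: str = "ok"


# ---------------------------------------------------------------------------
# penalized regression steps


def _group_norms(b: np.ndarray, groups: np.ndarray) -> np.ndarray:
    return np.sqrt(np.bincount(groups, weights=b * b))


def _spectral_norm_sq(X: np.ndarray, n_iter: int = 30) -> float:
    """Squared spectral norm by power iteration (deterministic start)."""
    v = np.ones(X.shape[1]) / np.sqrt(X.shape[1])
    s = 0.0
    for _ in range(n_iter):
        u = X @ v
        v = X.T @ u
        s = np.linalg.norm(v)
        if s == 0:
            return 0.0
        v /= s
    return float(s)


def group_lasso_max_penalty(X, z, groups) -> float:
    """Smallest lambda1 at which the group-lasso solution is all-zero:
    ``max_g ||X_g' z|| / (n sqrt(p_g))``."""
    X = np.asarray(X, dtype=float)
    z = np.asarray(z, dtype=float)
    groups = np.asarray(groups)
    c = X.T @ z
    norms = _group_norms(c, groups)
    sizes = np.bincount(groups)
    return float(np.max(norms / np.sqrt(sizes)) / X.shape[0])


def elastic_net_max_penalty(Y, z, mixing: float = 0.5) -> float:
    """Smallest lambda2 zeroing the elastic net: ``max|Y'z| / (n * mixing)``."""
    Y = np.asarray(Y, dtype=float)
    z = np.asarray(z, dtype=float)
    return float(np.max(np.abs(Y.T @ z)) / (Y.shape[0] * mixing))


def group_lasso_step(
    X,
    groups,
    z,
    lam1: float,
    *,
    tol: float = 1e-9,
    max_iter: int = 2000,
    lipschitz: float | None = None,
    warm: np.ndarray | None = None,
) -> np.ndarray:
    """Solve the group-lasso regression of ``z`` on centered ``X``:

        min_b  1/(2n) ||z - X b||^2  +  lam1 * sum_g sqrt(p_g) ||b_g||_2

    by monotone FISTA (accelerated proximal gradient with function-value
    restart).  Within a group, coefficients are jointly zero or jointly
    free.  ``lam1 = 0`` returns the (minimum-norm) least-squares fit.
    """
    if lam1 < 0:
        raise ValueError("lam1 must be >= 0")
    X = np.asarray(X, dtype=float)
    z = np.asarray(z, dtype=float)
    groups = np.asarray(groups)
    n, p = X.shape
    if lam1 == 0.0:
        return np.linalg.lstsq(X, z, rcond=None)[0]
    sqrt_pg = np.sqrt(np.bincount(groups))
    L = lipschitz if lipschitz is not None else _spectral_norm_sq(X) / n
    if L == 0:
        return np.zeros(p)
    thresh = lam1 * sqrt_pg / L

    def prox(v):
        norms = _group_norms(v, groups)
        scale = np.where(norms > 0, np.maximum(0.0, 1.0 - thresh / np.maximum(norms, 1e-300)), 0.0)
        return v * scale[groups]

    def objective(b, Xb):
        pen = lam1 * float(sqrt_pg @ _group_norms(b, groups))
        return 0.5 * np.sum((z - Xb) ** 2) / n + pen

    b = np.zeros(p) if warm is None else warm.astype(float).copy()
    y = b.copy()
    t = 1.0
    Xb = X @ b
    obj = objective(b, Xb)
    for _ in range(max_iter):
        Xy = X @ y
        grad = X.T @ (Xy - z) / n
        b_new = prox(y - grad / L)
        Xb_new = X @ b_new
        obj_new = objective(b_new, Xb_new)
        if obj_new > obj:  # restart momentum, plain proximal step
            y = b.copy()
            t = 1.0
            grad = X.T @ (Xb - z) / n
            b_new = prox(y - grad / L)
            Xb_new = X @ b_new
            obj_new = objective(b_new, Xb_new)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = b_new + ((t - 1.0) / t_new) * (b_new - b)
        done = abs(obj - obj_new) <= tol * max(1.0, abs(obj))
        b, Xb, obj, t = b_new, Xb_new, obj_new, t_new
        if done:
            break
    return b


def elastic_net_step(
    Y,
    z,
    lam2: float,
    mixing: float = 0.5,
    *,
    tol: float = 1e-8,
    max_iter: int = 5000,
    enet: ElasticNet | None = None,
) -> np.ndarray:
    """Solve the elastic-net regression of ``z`` on centered ``Y``:

        min_a  1/(2n) ||z - Y a||^2 + lam2*mixing*||a||_1
               + lam2*(1-mixing)/2 * ||a||_2^2

    via scikit-learn's coordinate descent.  ``lam2 = 0`` returns the
    (minimum-norm) least-squares fit.
    """
    if lam2 < 0:
        raise ValueError("lam2 must be >= 0")
    Y = np.asarray(Y, dtype=float)
    z = np.asarray(z, dtype=float)
    if lam2 == 0.0:
        return np.linalg.lstsq(Y, z, rcond=None)[0]
    if enet is None:
        enet = ElasticNet(
            alpha=lam2, l1_ratio=mixing, fit_intercept=False,
            tol=tol, max_iter=max_iter,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enet.fit(Y, z)
    return enet.coef_.copy()


# ---------------------------------------------------------------------------
# sparsity-bound (bisection) solvers with safe screening


def _group_lasso_bounded(X, group_idx, z, k, *, n_bisect=9):
    """Group lasso with at most ``k`` active groups.

    Bisects lambda1 between 0 and the analytic maximum; each trial
    solves the exact penalized problem on a screened candidate set (top
    groups by marginal norm plus previous actives) with a full KKT
    verification, so the restricted solution equals the full one.
    Returns ``(beta, lambda1)`` for the largest active count <= k.
    """
    n, p = X.shape
    c = X.T @ z
    sizes = np.bincount(group_idx)
    sqrt_pg = np.sqrt(sizes)
    marg = _group_norms(c, group_idx) / sqrt_pg / n
    order = np.argsort(marg)[::-1]
    lam_max = marg[order[0]]
    if lam_max == 0:
        return np.zeros(p), 0.0
    n_cand = min(len(order), max(4 * k, 60))
    cand_groups = set(order[:n_cand].tolist())

    def solve(lam, warm_b):
        groups_in = sorted(
            cand_groups
            | ({int(g) for g in np.unique(group_idx[warm_b != 0])} if warm_b is not None else set())
        )
        for _ in range(4):
            mask = np.isin(group_idx, groups_in)
            sub_idx = pd.factorize(group_idx[mask])[0]
            Xs = X[:, mask]
            warm_s = warm_b[mask] if warm_b is not None else None
            bs = group_lasso_step(Xs, sub_idx, z, lam, warm=warm_s)
            full = np.zeros(p)
            full[mask] = bs
            # KKT check on the complement
            grad = X.T @ (Xs @ bs - z) / n
            viol = _group_norms(grad, group_idx) / sqrt_pg
            viol[np.asarray(groups_in)] = 0.0
            bad = np.flatnonzero(viol > lam * (1 + 1e-6))
            if bad.size == 0:
                return full
            groups_in = sorted(set(groups_in) | set(bad.tolist()))
        return full

    lo, hi = 0.0, lam_max
    best = (np.zeros(p), lam_max, 0)
    warm = None
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        b = solve(mid, warm)
        warm = b
        ng = len(np.unique(group_idx[b != 0]))
        if ng > k:
            lo = mid
        else:
            if ng >= best[2]:
                best = (b.copy(), mid, ng)
            hi = mid
            if ng == k:
                break
    return best[0], best[1]


def _elastic_net_bounded(Y, z, k, mixing, *, n_bisect=9):
    """Elastic net with at most ``k`` active features (bisection on
    lambda2, screened solve with KKT verification)."""
    n, p = Y.shape
    c = np.abs(Y.T @ z) / (n * mixing)
    order = np.argsort(c)[::-1]
    lam_max = c[order[0]]
    if lam_max == 0:
        return np.zeros(p), 0.0
    n_cand = min(p, max(4 * k, 120))
    cand = set(order[:n_cand].tolist())

    def solve(lam, warm_a):
        cols = sorted(
            cand | ({int(j) for j in np.flatnonzero(warm_a)} if warm_a is not None else set())
        )
        for _ in range(4):
            Ys = Y[:, cols]
            a_s = elastic_net_step(Ys, z, lam, mixing)
            full = np.zeros(p)
            full[cols] = a_s
            grad = np.abs(Y.T @ (Ys @ a_s - z)) / n
            grad[np.asarray(cols)] = 0.0
            bad = np.flatnonzero(grad > lam * mixing * (1 + 1e-6))
            if bad.size == 0:
                return full
            cols = sorted(set(cols) | set(bad.tolist()))
        return full

    lo, hi = 0.0, lam_max
    best = (np.zeros(p), lam_max, 0)
    warm = None
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        a = solve(mid, warm)
        warm = a
        nf = int((a != 0).sum())
        if nf > k:
            lo = mid
        else:
            if nf >= best[2]:
                best = (a.copy(), mid, nf)
            hi = mid
            if nf == k:
                break
    return best[0], best[1]


# ---------------------------------------------------------------------------
# alternating fit


def _init_alpha(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Leading singular vector of Y'X on the Y side (deterministic)."""
    M = Y.T @ X
    if min(M.shape) == 0:
        raise ValueError("empty matrix")
    if min(M.shape) <= 200:
        u, _, _ = np.linalg.svd(M, full_matrices=False)
        return u[:, 0]
    # deterministic power iteration on M M' for large problems
    u = np.ones(M.shape[0]) / np.sqrt(M.shape[0])
    for _ in range(100):
        w = M @ (M.T @ u)
        nw = np.linalg.norm(w)
        if nw == 0:
            return u
        w /= nw
        if np.linalg.norm(w - u) < 1e-10:
            u = w
            break
        u = w
    return u


def _init_candidates(X: np.ndarray, Y: np.ndarray) -> list:
    """Deterministic starting direction for the alternation.

    In the classical regime (more samples than total columns) the
    leading singular vector of Y'X is the natural start: the alternation
    then behaves like power iteration on the CCA operator.  When the
    columns outnumber the samples that direction is noise-dominated, so
    the start is instead the leading principal axis of Y: the model
    under test is that associated variants and abundances share a common
    latent factor, and such a factor is a dominant axis of shared
    variation in the abundance view.
    """
    if Y.shape[1] == 1:
        return [np.ones(1)]
    n = Y.shape[0]
    if n > X.shape[1] + Y.shape[1]:
        return [_init_alpha(X, Y)]
    _, _, Vt = np.linalg.svd(Y, full_matrices=False)
    return [Vt[0]]


def _empty_component(x_cols, y_cols, status="collapsed") -> CanonicalComponent:
    return CanonicalComponent(
        beta=pd.Series(0.0, index=x_cols),
        alpha=pd.Series(0.0, index=y_cols),
        selected_snps=[],
        selected_features=[],
        canonical_correlation=0.0,
        n_iterations=0,
        converged=False,
        status=status,
    )


def _labels(obj, n, prefix):
    if isinstance(obj, pd.DataFrame):
        return obj.columns
    return pd.Index([f"{prefix}{i}" for i in range(n)])


def _as_array(obj):
    return obj.to_numpy(dtype=float) if isinstance(obj, pd.DataFrame) else np.asarray(obj, dtype=float)


def scca_fit(
    Xres,
    Yres,
    groups,
    lam1: float | None = None,
    lam2: float | None = None,
    *,
    sparsity: tuple | None = None,
    mixing: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 200,
    damping: float | None = None,
    seed: int | None = None,
) -> CanonicalComponent:
    """One sparse canonical component by block alternation.

    Iterates the group-lasso step (beta given the Y-variate) and the
    elastic-net step (alpha given the X-variate), rescaling the active
    variate to unit norm after each half-step.  The reported
    ``canonical_correlation`` is the Pearson correlation of the two
    variates.  If either weight vector shrinks to exactly zero the
    component is returned empty with ``status="collapsed"``.

    Penalties are given either as absolute ``(lam1, lam2)`` values
    (stopping on the relative change of the penalized objective), or as
    ``sparsity=(k_groups, k_features)`` bounds: each half-step then
    bisects its penalty so at most that many groups/features stay
    active, stopping when both supports stabilize.  In bound mode the
    Y-variate target is damped (weight ``damping`` on the new variate,
    default 0.5) to curb the two-sided co-adaptation that pure
    alternation exhibits when both views have far more columns than
    samples.  The realized penalties are reported on the component.

    ``groups`` assigns each X column to its variant; the two columns of
    a variant are selected jointly.  ``seed`` is accepted for interface
    stability; the initialization (best of the leading singular vector
    of Y'X and the top principal axes of Y) is deterministic.
    """
    X = _as_array(Xres)
    Y = _as_array(Yres)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must share their sample order")
    if X.shape[0] < 10:
        raise ValueError("at least 10 samples required")
    if sparsity is None and (lam1 is None or lam2 is None):
        raise ValueError("give either (lam1, lam2) or sparsity=(k1, k2)")
    x_cols = _labels(Xres, X.shape[1], "x")
    y_cols = _labels(Yres, Y.shape[1], "y")
    group_idx = pd.factorize(np.asarray(groups))[0]
    sqrt_pg = np.sqrt(np.bincount(group_idx))
    n = X.shape[0]
    L = _spectral_norm_sq(X) / n
    gamma = damping if damping is not None else (0.5 if sparsity is not None else 1.0)

    def objective(beta, alpha, u, v, l1, l2):
        pen = l1 * float(sqrt_pg @ _group_norms(beta, group_idx))
        pen += l2 * (
            mixing * np.abs(alpha).sum() + 0.5 * (1 - mixing) * float(alpha @ alpha)
        )
        return float(np.sum((u - v) ** 2)) + pen

    def alternate(alpha0, n_iter):
        """Run the block alternation from alpha0; None on collapse."""
        v = Y @ alpha0
        nv = np.linalg.norm(v)
        if nv == 0:
            return None
        alpha = alpha0 / nv
        v = v / nv
        beta = np.zeros(X.shape[1])
        trace = []
        obj_prev = np.inf
        prev_support = None
        converged = False
        it = 0
        u = v
        l1, l2 = (lam1 or 0.0), (lam2 or 0.0)
        for it in range(1, n_iter + 1):
            if sparsity is not None:
                beta, l1 = _group_lasso_bounded(X, group_idx, v, sparsity[0])
            else:
                beta = group_lasso_step(X, group_idx, v, l1, lipschitz=L, warm=beta)
            u = X @ beta
            nu = np.linalg.norm(u)
            if nu == 0:
                return None
            beta = beta / nu
            u = u / nu
            if sparsity is not None:
                alpha, l2 = _elastic_net_bounded(Y, u, sparsity[1], mixing)
            else:
                alpha = elastic_net_step(Y, u, l2, mixing)
            v_new = Y @ alpha
            nv = np.linalg.norm(v_new)
            if nv == 0:
                return None
            alpha = alpha / nv
            v_new = v_new / nv
            v = gamma * v_new + (1.0 - gamma) * v
            v = v / np.linalg.norm(v)
            obj = objective(beta, alpha, u, v_new, l1, l2)
            trace.append(obj)
            if sparsity is not None:
                support = (
                    frozenset(np.flatnonzero(beta != 0).tolist()),
                    frozenset(np.flatnonzero(alpha != 0).tolist()),
                )
                if support == prev_support and it >= 2:
                    converged = True
                    break
                prev_support = support
            else:
                if np.isfinite(obj_prev) and abs(obj_prev - obj) <= tol * max(
                    1.0, abs(obj_prev)
                ):
                    converged = True
                    break
                obj_prev = obj
        return beta, alpha, u, Y @ alpha / np.linalg.norm(Y @ alpha), trace, it, converged, (l1, l2)

    # probe every starting direction briefly, continue the best one
    candidates = _init_candidates(X, Y)
    best_idx, best_obj = None, np.inf
    for c, alpha0 in enumerate(candidates):
        probe = alternate(alpha0, n_iter=min(2, max_iter))
        if probe is not None and probe[4][-1] < best_obj:
            best_idx, best_obj = c, probe[4][-1]
    if best_idx is None:
        return _empty_component(x_cols, y_cols)
    result = alternate(candidates[best_idx], n_iter=max_iter)
    if result is None:
        return _empty_component(x_cols, y_cols)
    beta, alpha, u, v, trace, it, converged, realized = result

    corr = float(np.corrcoef(u, v)[0, 1]) if u.std() > 0 and v.std() > 0 else 0.0
    beta_s = pd.Series(beta, index=x_cols)
    alpha_s = pd.Series(alpha, index=y_cols)
    glabels = np.asarray(groups)
    sel_groups = pd.unique(glabels[beta != 0.0]).tolist()
    sel_feats = [y_cols[j] for j in np.flatnonzero(alpha != 0.0)]
    return CanonicalComponent(
        beta=beta_s,
        alpha=alpha_s,
        selected_snps=sel_groups,
        selected_features=sel_feats,
        canonical_correlation=corr,
        n_iterations=it,
        converged=converged,
        objective_trace=np.asarray(trace),
        penalties=realized,
    )


# ---------------------------------------------------------------------------
# tuning, deflation, refit


def build_penalty_grid(
    Xres,
    Yres,
    groups,
    mixing: float = 0.5,
    n_lam1: int = 3,
    n_lam2: int = 4,
    lam1_span: tuple = (0.2, 0.6),
    lam2_span: tuple = (0.08, 0.5),
) -> PenaltyGrid:
    """Default 12-pair grid: {3 lambda1} x {4 lambda2}, log-spaced
    within a fraction span of each side's analytic maximum penalty.

    The spans default to the sparse regime (20-60% of the group-lasso
    maximum, 8-50% of the elastic-net maximum): with far more columns
    than samples, weak penalties let either view fit any target variate
    almost perfectly, so cross-validated correlation no longer
    distinguishes signal from overfit noise.  The maxima are computed
    against the deterministic initialization variates, since the exact
    alternation fixed point is unknown before fitting.
    """
    X = _as_array(Xres)
    Y = _as_array(Yres)
    group_idx = pd.factorize(np.asarray(groups))[0]
    alpha0 = _init_alpha(X, Y)
    v0 = Y @ alpha0
    nv = np.linalg.norm(v0)
    if nv == 0:
        raise ValueError("degenerate Y matrix")
    v0 = v0 / nv
    lam1_max = group_lasso_max_penalty(X, v0, group_idx)
    # a moderately penalized X-side fit gives a realistic variate for
    # the Y-side maximum (lam1=0 would interpolate v0 when p > n)
    beta0 = group_lasso_step(X, group_idx, v0, 0.5 * lam1_max)
    u0 = X @ beta0
    nu = np.linalg.norm(u0)
    u0 = u0 / nu if nu > 0 else v0
    lam2_max = elastic_net_max_penalty(Y, u0, mixing)
    lam1s = lam1_max * np.geomspace(*lam1_span, n_lam1)
    lam2s = lam2_max * np.geomspace(*lam2_span, n_lam2)
    pairs = tuple((float(l1), float(l2)) for l1 in lam1s for l2 in lam2s)
    return PenaltyGrid(pairs=pairs, elastic_net_mixing=mixing)


def build_sparsity_grid(
    k_groups=(5, 10, 20), k_features=(10, 20, 40, 80), mixing: float = 0.5
) -> PenaltyGrid:
    """Default 12-pair sparsity ladder: {3 group bounds} x {4 feature
    bounds}, doubling from very sparse to moderate.  Each bound maps to
    a data-derived penalty by bisection inside the fit; cross-validation
    picks the pair, so the ladder only needs to bracket the plausible
    effect sparsity."""
    pairs = tuple((int(k1), int(k2)) for k1 in k_groups for k2 in k_features)
    return PenaltyGrid(pairs=pairs, elastic_net_mixing=mixing, mode="sparsity")


def tune_penalties(
    Xres,
    Yres,
    groups,
    grid: PenaltyGrid | None = None,
    folds: int = 5,
    seed: int | None = 0,
    *,
    max_iter: int = 60,
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Choose the penalty pair maximizing mean held-out correlation.

    Samples are split into ``folds`` folds; for each grid pair the model
    is fit on the training folds and ``corr(X_test beta, Y_test alpha)``
    is recorded (0 for collapsed fits or zero-variance variates).  Ties
    on the mean go to the sparser pair (larger lambda1 + lambda2 in
    penalty mode, smaller k1 + k2 in sparsity mode).
    """
    X = _as_array(Xres)
    Y = _as_array(Yres)
    if grid is None:
        grid = build_sparsity_grid()
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    records = np.zeros((len(grid.pairs), folds))
    for f, (tr, te) in enumerate(kf.split(X)):
        for g, (l1, l2) in enumerate(grid.pairs):
            kwargs = (
                {"sparsity": (l1, l2)}
                if grid.mode == "sparsity"
                else {"lam1": l1, "lam2": l2}
            )
            try:
                comp = scca_fit(
                    X[tr], Y[tr], groups,
                    mixing=grid.elastic_net_mixing, max_iter=max_iter, seed=seed,
                    **kwargs,
                )
            except ValueError:
                records[g, f] = 0.0
                continue
            if comp.is_empty:
                records[g, f] = 0.0
                continue
            u = X[te] @ comp.beta.to_numpy()
            v = Y[te] @ comp.alpha.to_numpy()
            if u.std() == 0 or v.std() == 0:
                records[g, f] = 0.0
            else:
                records[g, f] = float(np.corrcoef(u, v)[0, 1])
    mean = records.mean(axis=1)
    best = mean.max()
    ties = [g for g in range(len(grid.pairs)) if mean[g] >= best - 1e-12]
    if grid.mode == "sparsity":
        chosen = min(ties, key=lambda g: sum(grid.pairs[g]))
    else:
        chosen = max(ties, key=lambda g: sum(grid.pairs[g]))
    names = ["k_groups", "k_features"] if grid.mode == "sparsity" else ["lam1", "lam2"]
    table = pd.DataFrame(
        records,
        index=pd.MultiIndex.from_tuples(grid.pairs, names=names),
        columns=[f"fold{f}" for f in range(folds)],
    )
    table["mean"] = mean
    return grid.pairs[chosen], table


def deflate(Xres, Yres, comp: CanonicalComponent, mode: str = "own"):
    """Residualize each matrix against a component's canonical variate.

    ``mode="own"`` regresses X columns on ``u = X beta`` and Y columns on
    ``v = Y alpha`` (Witten-style); ``mode="cross"`` swaps the variates.
    Output columns are re-centered; they are exactly orthogonal to the
    variate regressed out.
    """
    if comp.is_empty:
        raise ValueError("cannot deflate with an empty component")
    X = _as_array(Xres)
    Y = _as_array(Yres)
    u = X @ comp.beta.to_numpy()
    v = Y @ comp.alpha.to_numpy()
    if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
        raise ValueError("zero-norm canonical variate")
    if mode == "own":
        zx, zy = u, v
    elif mode == "cross":
        zx, zy = v, u
    else:
        raise ValueError("mode must be 'own' or 'cross'")
    Xd = X - np.outer(zx, zx @ X) / (zx @ zx)
    Yd = Y - np.outer(zy, zy @ Y) / (zy @ zy)
    Xd -= Xd.mean(axis=0, keepdims=True)
    Yd -= Yd.mean(axis=0, keepdims=True)
    if isinstance(Xres, pd.DataFrame):
        Xd = pd.DataFrame(Xd, index=Xres.index, columns=Xres.columns)
    if isinstance(Yres, pd.DataFrame):
        Yd = pd.DataFrame(Yd, index=Yres.index, columns=Yres.columns)
    return Xd, Yd


def _cca_first_pair(X: np.ndarray, Y: np.ndarray, ridge: float = 0.0):
    """First canonical pair by whitening + SVD; ridge is relative to the
    mean diagonal of each covariance block."""
    n = X.shape[0]
    Cxx = X.T @ X / n
    Cyy = Y.T @ Y / n
    Cxy = X.T @ Y / n
    if ridge > 0:
        Cxx = Cxx + ridge * np.mean(np.diag(Cxx)) * np.eye(Cxx.shape[0])
        Cyy = Cyy + ridge * np.mean(np.diag(Cyy)) * np.eye(Cyy.shape[0])
    Wx = _inv_sqrt(Cxx)
    Wy = _inv_sqrt(Cyy)
    K = Wx @ Cxy @ Wy
    u, s, vt = np.linalg.svd(K)
    a = Wx @ u[:, 0]
    b = Wy @ vt[0]
    ua, vb = X @ a, Y @ b
    if np.linalg.norm(ua) > 0:
        a = a / np.linalg.norm(ua)
    if np.linalg.norm(vb) > 0:
        b = b / np.linalg.norm(vb)
    corr = float(np.clip(s[0], -1.0, 1.0))
    # orient so the correlation is reported positive with aligned variates
    if np.dot(X @ a, Y @ b) < 0:
        b = -b
    return a, b, corr


def _inv_sqrt(C: np.ndarray) -> np.ndarray:
    vals, vecs = linalg.eigh(C)
    floor = max(vals.max(), 0.0) * 1e-12 + 1e-300
    inv = np.where(vals > floor, 1.0 / np.sqrt(np.maximum(vals, floor)), 0.0)
    return (vecs * inv) @ vecs.T


def final_cca(
    Xres,
    Yres,
    selected_snps,
    selected_features,
    groups,
    ridge: float = 1e-3,
) -> CanonicalComponent:
    """Classical CCA refit restricted to the selected column sets.

    ``selected_snps`` are variant (group) labels: both coded columns of
    each selected variant enter the refit.  When either selected block
    has at least as many columns as samples, the covariance blocks are
    ridge-stabilized with relative shrinkage ``ridge`` on the diagonal.
    Refined weights are embedded in full-length vectors (zeros off the
    selected support).
    """
    if len(selected_snps) == 0 or len(selected_features) == 0:
        raise ValueError("selections must be nonempty")
    X = _as_array(Xres)
    Y = _as_array(Yres)
    x_cols = _labels(Xres, X.shape[1], "x")
    y_cols = _labels(Yres, Y.shape[1], "y")
    glabels = np.asarray(groups)
    xmask = np.isin(glabels, np.asarray(selected_snps, dtype=glabels.dtype))
    ymask = np.asarray(y_cols.isin(selected_features))
    Xs, Ys = X[:, xmask], Y[:, ymask]
    n = X.shape[0]
    eps = ridge if max(Xs.shape[1], Ys.shape[1]) >= n else 0.0
    a, b, corr = _cca_first_pair(Xs, Ys, ridge=eps)
    beta = np.zeros(X.shape[1])
    beta[xmask] = a
    alpha = np.zeros(Y.shape[1])
    alpha[ymask] = b
    return CanonicalComponent(
        beta=pd.Series(beta, index=x_cols),
        alpha=pd.Series(alpha, index=y_cols),
        selected_snps=list(selected_snps),
        selected_features=list(selected_features),
        canonical_correlation=corr,
        n_iterations=1,
        converged=True,
        status="refit",
    )


def run_scca(
    Xres,
    Yres,
    groups,
    grid: PenaltyGrid | None = None,
    n_components: int = 2,
    *,
    folds: int = 5,
    seed: int | None = 0,
    mixing: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 4,
    cv_max_iter: int = 3,
    ridge: float = 1e-3,
    deflation_mode: str = "own",
) -> SccaModel:
    """Full pipeline: tune -> fit -> CCA refit -> deflate, per component.

    The default grid is the 12-pair sparsity ladder; penalties are tuned
    per component on the (deflated) matrices.  An empty (collapsed)
    component truncates the sequence with ``status="truncated"``.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    model = SccaModel()
    Xc, Yc = Xres, Yres
    for _ in range(n_components):
        try:
            grid_c = grid if grid is not None else build_sparsity_grid(mixing=mixing)
            (l1, l2), cv_table = tune_penalties(
                Xc, Yc, groups, grid_c, folds=folds, seed=seed, max_iter=cv_max_iter
            )
        except ValueError:
            model.status = "truncated"
            break
        kwargs = (
            {"sparsity": (l1, l2)}
            if grid_c.mode == "sparsity"
            else {"lam1": l1, "lam2": l2}
        )
        comp = scca_fit(
            Xc, Yc, groups,
            mixing=grid_c.elastic_net_mixing, tol=tol, max_iter=max_iter, seed=seed,
            **kwargs,
        )
        if comp.is_empty:
            model.status = "truncated"
            break
        refined = final_cca(
            Xc, Yc, comp.selected_snps, comp.selected_features, groups, ridge=ridge
        )
        model.selection_components.append(comp)
        model.components.append(refined)
        model.penalty_pairs_chosen.append((l1, l2))
        model.cv_tables.append(cv_table)
        model.deflation_history.append(
            {"component": len(model.components), "mode": deflation_mode}
        )
        Xc, Yc = deflate(Xc, Yc, refined, mode=deflation_mode)
    return model


def selection_summary(components, n_total_features: int, side: str = "features") -> dict:
    """Union of per-component selections via inclusion-exclusion.

    For two components with selected sets A and B this reports
    ``|A|, |B|, |A & B|`` and ``|A u B| = |A| + |B| - |A & B|``, plus
    each count as a percentage of ``n_total_features`` (printed to two
    decimals as percentages, e.g. 74.04 for 485/655).
    """
    attr = "selected_features" if side == "features" else "selected_snps"
    sets = [set(getattr(c, attr)) for c in components]
    union = set().union(*sets) if sets else set()
    pairwise = {
        (i + 1, j + 1): len(sets[i] & sets[j])
        for i in range(len(sets))
        for j in range(i + 1, len(sets))
    }
    def pct(k):
        return round(100.0 * k / n_total_features, 2) if n_total_features else float("nan")
    return {
        "per_component": [len(s) for s in sets],
        "per_component_pct": [pct(len(s)) for s in sets],
        "pairwise_overlap": pairwise,
        "union": len(union),
        "union_pct": pct(len(union)),
    }


def selection_overlap(a, b) -> float:
    """|a & b| / |a| -- the fraction of run ``a``'s selections found in ``b``."""
    a, b = set(a), set(b)
    if not a:
        return 0.0
    return len(a & b) / len(a)


class SparseCCA(BaseEstimator):
    """Scikit-learn style estimator for the full sparse-CCA pipeline.

    Parameters
    ----------
    n_components : int
        Canonical components to extract (deflating between them).
    penalty_grid : PenaltyGrid, optional
        Explicit (lambda1, lambda2) candidates; default is the 12-pair
        log-spaced grid rebuilt per component.
    mixing : float
        Elastic-net l1 fraction in (0, 1].
    cv : int
        Cross-validation folds for penalty tuning.
    ridge : float
        Relative diagonal shrinkage of the refit covariance blocks when
        a selected block is sample-deficient.
    deflation : {"own", "cross"}
        Whether each matrix is deflated against its own variate.
    random_state : int
        Seed for the CV fold shuffle (the fit itself is deterministic).

    Attributes
    ----------
    model_ : SccaModel
    x_weights_, y_weights_ : ndarray, (n_x_cols, k) / (n_y_cols, k)
        Refit weights per component.  Magnitudes are selection-only:
        interpret entries as zero vs nonzero.
    correlations_ : ndarray of refit canonical correlations.
    selected_snps_, selected_features_ : list of per-component lists.
    """

    def __init__(
        self,
        n_components: int = 2,
        penalty_grid: PenaltyGrid | None = None,
        mixing: float = 0.5,
        cv: int = 5,
        tol: float = 1e-6,
        max_iter: int = 4,
        cv_max_iter: int = 3,
        ridge: float = 1e-3,
        deflation: str = "own",
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.penalty_grid = penalty_grid
        self.mixing = mixing
        self.cv = cv
        self.tol = tol
        self.max_iter = max_iter
        self.cv_max_iter = cv_max_iter
        self.ridge = ridge
        self.deflation = deflation
        self.random_state = random_state

    def fit(self, X, Y=None, groups=None):
        if Y is None:
            raise ValueError("SparseCCA.fit requires both views: fit(X, Y)")
        if groups is None:
            groups = np.arange(_as_array(X).shape[1])
        self.model_ = run_scca(
            X, Y, groups,
            grid=self.penalty_grid,
            n_components=self.n_components,
            folds=self.cv,
            seed=self.random_state,
            mixing=self.mixing,
            tol=self.tol,
            max_iter=self.max_iter,
            cv_max_iter=self.cv_max_iter,
            ridge=self.ridge,
            deflation_mode=self.deflation,
        )
        comps = self.model_.components
        if comps:
            self.x_weights_ = np.column_stack([c.beta.to_numpy() for c in comps])
            self.y_weights_ = np.column_stack([c.alpha.to_numpy() for c in comps])
        else:
            self.x_weights_ = np.zeros((_as_array(X).shape[1], 0))
            self.y_weights_ = np.zeros((_as_array(Y).shape[1], 0))
        self.correlations_ = np.array([c.canonical_correlation for c in comps])
        self.selected_snps_ = [c.selected_snps for c in comps]
        self.selected_features_ = [c.selected_features for c in comps]
        return self

    def transform(self, X, Y=None):
        """Canonical variates (X scores, and Y scores when Y is given)."""
        check_is_fitted(self, "model_")
        xs = _as_array(X) @ self.x_weights_
        if Y is None:
            return xs
        return xs, _as_array(Y) @ self.y_weights_
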