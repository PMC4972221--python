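"""Multivariate engine for community ordination and constrained analysis.

Community matrices are analysed on the Hellinger scale (square root of
within-site relative abundances), so Euclidean distances between rows are
meaningful for species count data. On that scale the module provides

* unconstrained ordination — :class:`NMDS` (Kruskal stress-1, SMACOF with
  isotonic regression) and :func:`pca`;
* hypothesis tests on distance matrices — :func:`permanova` (Anderson's
  pseudo-F with label permutation);
* spatial predictors — :class:`PCNM` (principal coordinates of a truncated
  neighbour matrix);
* constrained ordination — :class:`PartialRDA` (redundancy analysis with an
  optional conditioning block), :func:`variation_partitioning`,
  :func:`forward_select` and :func:`collinearity_filter`.

Estimators follow scikit-learn conventions (``fit``, fitted attributes with a
trailing underscore, ``get_params``/``set_params``); the module-level
functions are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA as _SKPCA
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "hellinger",
    "HellingerTransformer",
    "pca",
    "NMDS",
    "nmds",
    "permanova",
    "PermanovaResult",
    "PCNM",
    "pcnm",
    "PartialRDA",
    "partial_rda",
    "rda",
    "variation_partitioning",
    "VarpartResult",
    "forward_select",
    "collinearity_filter",
    "adjusted_r2",
    "OrdinationResult",
]


# --------------------------------------------------------------------------
# transforms


def hellinger(abundance):
    """Hellinger transform: y'_ij = sqrt(x_ij / sum_j x_ij).

    Rows with zero total are rejected by name. Each output row has unit sum
    of squares.
    """
    df = isinstance(abundance, pd.DataFrame)
    X = np.asarray(abundance, dtype=float)
    if np.any(X < 0):
        raise ValueError("abundances must be non-negative")
    totals = X.sum(axis=1)
    bad = np.where(totals <= 0)[0]
    if bad.size:
        names = (
            list(abundance.index[bad]) if df else bad.tolist()
        )
        raise ValueError(f"zero-total rows cannot be Hellinger-transformed: {names}")
    Y = np.sqrt(X / totals[:, None])
    assert np.allclose((Y**2).sum(axis=1), 1.0)
    if df:
        return pd.DataFrame(Y, index=abundance.index, columns=abundance.columns)
    return Y


class HellingerTransformer(BaseEstimator):
    """Stateless sklearn-style wrapper around :func:`hellinger`."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return hellinger(X)

    def fit_transform(self, X, y=None):
        return self.transform(X)


# --------------------------------------------------------------------------
# result containers


@dataclass
class OrdinationResult:
    """Scores and diagnostics shared by the ordination operations."""

    scores: pd.DataFrame
    eigenvalues: np.ndarray | None = None
    proportion_explained: np.ndarray | None = None
    loadings: pd.DataFrame | None = None
    stress: float | None = None
    converged: bool | None = None
    r2: float | None = None
    adj_r2: float | None = None
    p_value: float | None = None
    axis_p_values: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    df_among: int
    df_within: int
    degenerate: bool = False


@dataclass
class VarpartResult:
    """Adjusted-R2 decomposition over 2-3 predictor blocks.

    ``fractions`` maps fraction labels (unique blocks by name, then joint
    combinations) to adjusted R2; negatives are reported as computed, with a
    floored view in ``fractions_truncated``. ``p_values`` covers the testable
    unique fractions.
    """

    fractions: dict[str, float]
    fractions_truncated: dict[str, float]
    residual: float
    total_adj_r2: float
    p_values: dict[str, float]


# --------------------------------------------------------------------------
# PCA


def pca(X, center: bool = True, scale: bool = False, n_components: int | None = None):
    """Principal components of a data matrix.

    With ``scale=True`` the analysis runs on the correlation matrix; constant
    columns are then an error (zero variance cannot be standardized).
    """
    df = isinstance(X, pd.DataFrame)
    cols = list(X.columns) if df else None
    idx = X.index if df else None
    A = np.asarray(X, dtype=float)
    if A.ndim != 2 or A.shape[0] < 2 or A.shape[1] < 1:
        raise ValueError("PCA needs >= 2 rows and >= 1 column")
    if np.any(~np.isfinite(A)):
        raise ValueError("PCA input contains missing values")
    mean = A.mean(axis=0) if center else np.zeros(A.shape[1])
    A = A - mean
    if scale:
        sd = A.std(axis=0, ddof=1)
        if np.any(sd == 0):
            which = [cols[i] if cols else i for i in np.where(sd == 0)[0]]
            raise ValueError(f"constant columns cannot be scaled: {which}")
        A = A / sd
    k = min(A.shape) if n_components is None else n_components
    model = _SKPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(A)
    axes = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=idx, columns=axes),
        eigenvalues=model.explained_variance_.copy(),
        proportion_explained=model.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(model.components_.T, index=cols, columns=axes),
        extras={"mean": mean, "model": model},
    )


# --------------------------------------------------------------------------
# NMDS


def _stress1(dist, disp):
    return float(np.sqrt(np.sum((dist - disp) ** 2) / np.sum(dist**2)))


class NMDS(BaseEstimator):
    """Nonmetric multidimensional scaling minimizing Kruskal stress-1.

    SMACOF iterations alternate an isotonic-regression fit of the disparities
    (monotone in the observed dissimilarities; ties averaged) with a Guttman
    transform of the configuration. Disparities are rescaled each iteration to
    the norm of the configuration distances, which guards against collapse.
    The best of ``n_starts`` initializations is kept; start 0 uses classical
    scaling (PCoA) of the input, the rest are random.

    Attributes
    ----------
    embedding_ : (n, k) configuration, centered and rotated to principal axes
    stress_ : final Kruskal stress-1 of the best start
    stress_history_ : per-iteration stress of the best start
    converged_ : True if any start reached the tolerance before max_iter
    """

    def __init__(self, n_components=2, n_starts=20, max_iter=300, tol=1e-7, seed=None):
        self.n_components = n_components
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self, D, y=None):
        D = np.asarray(D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("D must be a square distance matrix")
        if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
            raise ValueError("D must be symmetric with a zero diagonal")
        n, k = D.shape[0], self.n_components
        d_obs = squareform(D, checks=False)
        rng = np.random.default_rng(self.seed)
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

        best = None
        any_converged = False
        for start in range(self.n_starts):
            if start == 0:
                X = _pcoa_config(D, k)
            else:
                X = rng.normal(size=(n, k))
            history = []
            prev = np.inf
            converged = False
            for _ in range(self.max_iter):
                dist = pdist(X)
                dist = np.maximum(dist, 1e-12)
                disp = iso.fit(d_obs, dist).predict(d_obs)
                disp *= np.sqrt(np.sum(dist**2) / max(np.sum(disp**2), 1e-300))
                stress = _stress1(dist, disp)
                history.append(stress)
                if prev - stress < self.tol:
                    converged = True
                    break
                prev = stress
                # Guttman transform
                ratio = squareform(disp / dist, checks=False)
                B = -ratio
                np.fill_diagonal(B, ratio.sum(axis=1))
                X = B @ X / n
            any_converged = any_converged or converged
            if best is None or history[-1] < best[0]:
                best = (history[-1], X, history, converged)

        stress, X, history, _ = best
        X = X - X.mean(axis=0)
        # rotate to principal axes for a reproducible orientation
        _, _, Vt = np.linalg.svd(X, full_matrices=False)
        X = X @ Vt.T
        # deterministic sign convention: largest-|value| coordinate positive
        for j in range(X.shape[1]):
            i = np.argmax(np.abs(X[:, j]))
            if X[i, j] < 0:
                X[:, j] = -X[:, j]
        self.embedding_ = X
        self.stress_ = stress
        self.stress_history_ = np.asarray(history)
        self.converged_ = any_converged
        return self

    def fit_transform(self, D, y=None):
        return self.fit(D).embedding_


def _pcoa_config(D, k):
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def nmds(D, k: int = 2, n_starts: int = 20, max_iter: int = 300, tol: float = 1e-7,
         seed=None) -> OrdinationResult:
    """Functional wrapper over :class:`NMDS`."""
    model = NMDS(n_components=k, n_starts=n_starts, max_iter=max_iter, tol=tol, seed=seed)
    model.fit(D)
    idx = D.index if isinstance(D, pd.DataFrame) else None
    axes = [f"NMDS{i + 1}" for i in range(k)]
    return OrdinationResult(
        scores=pd.DataFrame(model.embedding_, index=idx, columns=axes),
        stress=model.stress_,
        converged=model.converged_,
        extras={"stress_history": model.stress_history_},
    )


# --------------------------------------------------------------------------
# PERMANOVA


def _permanova_ss(D2, labels, uniq):
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.where(labels == g)[0]
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return ss_total, ss_within


def permanova(D, groups, n_perm: int = 999, seed=None, strata=None) -> PermanovaResult:
    """Permutational multivariate ANOVA (Anderson's pseudo-F) on a distance matrix.

    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)`` with free permutation of
    row labels, optionally restricted within ``strata``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    D = np.asarray(D, dtype=float)
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    counts = np.array([(labels == g).sum() for g in uniq])
    if np.any(counts < 2):
        raise ValueError("every group needs at least two members")
    n, a = D.shape[0], uniq.size
    D2 = D**2
    ss_total, ss_within = _permanova_ss(D2, labels, uniq)
    df_among, df_within = a - 1, n - a
    if ss_total <= 1e-12:
        return PermanovaResult(float("nan"), float("nan"), float("nan"),
                               n_perm, df_among, df_within, degenerate=True)
    ss_among = ss_total - ss_within
    f_obs = (ss_among / df_among) / (ss_within / df_within)
    r2 = ss_among / ss_total

    rng = np.random.default_rng(seed)
    strata = None if strata is None else np.asarray(strata)
    hits = 0
    for _ in range(n_perm):
        perm = _permute_indices(n, rng, strata)
        _, ss_w = _permanova_ss(D2, labels[perm], uniq)
        f_p = ((ss_total - ss_w) / df_among) / (ss_w / df_within)
        if f_p >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm,
                           df_among, df_within)


def _permute_indices(n, rng, strata):
    if strata is None:
        return rng.permutation(n)
    perm = np.arange(n)
    for s in np.unique(strata):
        idx = np.where(strata == s)[0]
        perm[idx] = idx[rng.permutation(idx.size)]
    return perm


# --------------------------------------------------------------------------
# PCNM


class PCNM(BaseEstimator):
    """Principal coordinates of a truncated neighbour (distance) matrix.

    Distances beyond the truncation threshold (default: the longest edge of
    the minimum spanning tree, so the neighbour graph stays connected) are
    replaced by four times the threshold; principal coordinates of the result
    with positive eigenvalues form orthogonal spatial predictors, ordered from
    broadest to finest scale.

    Attributes
    ----------
    vectors_ : (n, m) orthonormal spatial eigenvectors (positive eigenvalues)
    eigenvalues_ : the m positive eigenvalues, descending
    threshold_ : truncation distance used
    """

    def __init__(self, truncation: float | None = None):
        self.truncation = truncation

    def fit(self, coords, y=None):
        P = np.asarray(coords, dtype=float)
        if P.ndim != 2 or P.shape[0] < 3:
            raise ValueError("need >= 3 points with planar coordinates")
        D = squareform(pdist(P))
        if D.max() <= 0:
            raise ValueError("all points are identical")
        if self.truncation is None:
            mst = minimum_spanning_tree(D).toarray()
            t = mst.max()
        else:
            t = float(self.truncation)
        Dt = np.where(D <= t, D, 4.0 * t)
        np.fill_diagonal(Dt, 0.0)
        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ (Dt**2) @ J
        vals, vecs = np.linalg.eigh(G)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        keep = vals > vals.max() * 1e-10
        self.eigenvalues_ = vals[keep]
        V = vecs[:, keep]
        for j in range(V.shape[1]):  # reproducible sign
            i = np.argmax(np.abs(V[:, j]))
            if V[i, j] < 0:
                V[:, j] = -V[:, j]
        self.vectors_ = V
        self.threshold_ = t
        return self

    def fit_transform(self, coords, y=None):
        return self.fit(coords).vectors_


def pcnm(coords, truncation: float | None = None):
    """Functional wrapper over :class:`PCNM`; returns (vectors, eigenvalues)."""
    model = PCNM(truncation=truncation).fit(coords)
    return model.vectors_, model.eigenvalues_


# --------------------------------------------------------------------------
# RDA / partial RDA


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel's adjustment 1 - (1 - R2)(n - 1)/(n - p - 1)."""
    if n - p - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _center(A):
    return A - A.mean(axis=0)


def _residualize(A, Z):
    """Residuals of columns of A after OLS on [1, Z]."""
    if Z is None or Z.shape[1] == 0:
        return _center(A)
    Zc = np.column_stack([np.ones(Z.shape[0]), Z])
    beta, *_ = np.linalg.lstsq(Zc, A, rcond=None)
    return A - Zc @ beta


def _colnames(X, prefix):
    if isinstance(X, pd.DataFrame):
        return list(X.columns)
    X = np.atleast_2d(X)
    return [f"{prefix}{i + 1}" for i in range(np.asarray(X).shape[1])]


class PartialRDA(BaseEstimator):
    """Redundancy analysis of Y on X, optionally conditioned on Z.

    Y and X are residualized on the conditioning block Z (multivariate OLS);
    the RDA is then the PCA of the fitted values of residual-Y regressed on
    residual-X. The overall pseudo-F is permutation-tested by permuting the
    rows of residual-Y; the reported R2 is the constrained share of the
    variance remaining after conditioning, with Ezekiel's adjustment using
    the conditioning-reduced degrees of freedom.

    Attributes (after ``fit(X, Y, Z=...)``)
    ---------------------------------------
    site_scores_ : weighted-average site scores (residual-Y projected on axes)
    lc_scores_ : linear-combination scores (fitted values projected)
    eigenvalues_, proportion_explained_ : per constrained axis
    r2_, adj_r2_, p_value_, axis_p_values_
    """

    def __init__(self, n_perm: int = 999, seed=None):
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, X, Y, Z=None):
        xnames = _colnames(X, "x")
        Ya = np.asarray(Y, dtype=float)
        Xa = np.atleast_2d(np.asarray(X, dtype=float))
        if Xa.shape[0] != Ya.shape[0]:
            Xa = Xa.T
        Za = None if Z is None else np.asarray(Z, dtype=float)
        if Za is not None and Za.ndim == 1:
            Za = Za[:, None]
        n = Ya.shape[0]
        q = 0 if Za is None else Za.shape[1]
        p = Xa.shape[1]
        if n <= p + q + 1:
            raise ValueError("not enough rows for the requested model")

        Yr = _residualize(_center(Ya), Za)
        Xr = _residualize(_center(Xa), Za)
        rank = np.linalg.matrix_rank(Xr)
        if rank < p:
            # name columns that add no rank
            bad = []
            for j in range(p):
                others = np.delete(Xr, j, axis=1)
                if np.linalg.matrix_rank(others) == rank:
                    bad.append(xnames[j])
            raise ValueError(f"rank-deficient predictors after conditioning: {bad}")

        stats = self._fit_stats(Yr, Xr)
        (self.eigenvalues_, V, self.r2_, ss_tot) = stats
        self.proportion_explained_ = (
            self.eigenvalues_ / self.eigenvalues_.sum()
            if self.eigenvalues_.sum() > 0
            else self.eigenvalues_
        )
        self.adj_r2_ = adjusted_r2(self.r2_, n - q, p)
        Yhat = Xr @ np.linalg.lstsq(Xr, Yr, rcond=None)[0]
        self.site_scores_ = Yr @ V
        self.lc_scores_ = Yhat @ V
        self.loadings_ = V

        # permutation tests: permute rows of residualized Y
        rng = np.random.default_rng(self.seed)
        dof = n - p - q - 1
        f_obs = (self.r2_ / p) / ((1 - self.r2_) / dof)
        hits = 0
        axis_hits = np.zeros(self.eigenvalues_.size)
        for _ in range(self.n_perm):
            perm = rng.permutation(n)
            ev_p, _, r2_p, _ = self._fit_stats(Yr[perm], Xr)
            f_p = (r2_p / p) / ((1 - r2_p) / dof)
            if f_p >= f_obs - 1e-12:
                hits += 1
            m = min(ev_p.size, axis_hits.size)
            axis_hits[:m] += ev_p[:m] >= self.eigenvalues_[:m] - 1e-12
        self.p_value_ = (1 + hits) / (1 + self.n_perm)
        self.axis_p_values_ = (1 + axis_hits) / (1 + self.n_perm)
        self.pseudo_f_ = float(f_obs)
        self.xnames_ = xnames
        return self

    @staticmethod
    def _fit_stats(Yr, Xr):
        beta, *_ = np.linalg.lstsq(Xr, Yr, rcond=None)
        Yhat = Xr @ beta
        n = Yr.shape[0]
        _, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
        ev = (s**2) / (n - 1)
        keep = ev > max(ev.max(), 1e-300) * 1e-12 if ev.size else slice(0)
        ev = ev[keep]
        V = Vt[keep].T
        ss_tot = np.sum(Yr**2)
        r2 = np.sum(Yhat**2) / ss_tot if ss_tot > 0 else 0.0
        return ev, V, float(r2), ss_tot

    def result(self, index=None) -> OrdinationResult:
        axes = [f"RDA{i + 1}" for i in range(self.site_scores_.shape[1])]
        return OrdinationResult(
            scores=pd.DataFrame(self.site_scores_, index=index, columns=axes),
            eigenvalues=self.eigenvalues_,
            proportion_explained=self.proportion_explained_,
            loadings=pd.DataFrame(self.loadings_, columns=axes),
            r2=self.r2_,
            adj_r2=self.adj_r2_,
            p_value=self.p_value_,
            axis_p_values=self.axis_p_values_,
            extras={"lc_scores": self.lc_scores_, "pseudo_f": self.pseudo_f_},
        )


def partial_rda(Y, X, Z=None, n_perm: int = 999, seed=None) -> OrdinationResult:
    """Functional wrapper over :class:`PartialRDA`."""
    model = PartialRDA(n_perm=n_perm, seed=seed).fit(X, Y, Z=Z)
    idx = Y.index if isinstance(Y, pd.DataFrame) else None
    return model.result(index=idx)


def rda(Y, X, n_perm: int = 999, seed=None) -> OrdinationResult:
    """Plain (unconditioned) redundancy analysis."""
    return partial_rda(Y, X, Z=None, n_perm=n_perm, seed=seed)


# --------------------------------------------------------------------------
# variation partitioning


def _block_adj_r2(Y, blocks, which, n):
    X = np.column_stack([np.asarray(blocks[i], dtype=float) for i in which])
    Yr = _center(np.asarray(Y, dtype=float))
    Xr = _center(X)
    beta, *_ = np.linalg.lstsq(Xr, Yr, rcond=None)
    r2 = np.sum((Xr @ beta) ** 2) / np.sum(Yr**2)
    return adjusted_r2(r2, n, X.shape[1])


def variation_partitioning(Y, X_blocks, n_perm: int = 199, seed=None,
                           names=None) -> VarpartResult:
    """Partition the adjusted R2 of Y over 2 or 3 predictor blocks.

    Adjusted R2 of every block union is computed by RDA; unique and shared
    fractions follow by inclusion-exclusion. Unique fractions are permutation
    tested through a partial RDA conditioned on the other blocks.
    """
    k = len(X_blocks)
    if k not in (2, 3):
        raise ValueError("variation partitioning supports 2 or 3 blocks")
    blocks = []
    for B in X_blocks:
        A = np.asarray(B, dtype=float)
        if A.ndim == 1:
            A = A[:, None]
        if A.shape[1] == 0:
            raise ValueError("empty predictor block")
        blocks.append(A)
    names = names or [f"X{i + 1}" for i in range(k)]
    n = np.asarray(Y).shape[0]

    R = {}
    from itertools import combinations

    for r in range(1, k + 1):
        for combo in combinations(range(k), r):
            R[combo] = _block_adj_r2(Y, blocks, combo, n)
    total = R[tuple(range(k))]

    frac = {}
    if k == 2:
        frac[f"{names[0]}|{names[1]}"] = total - R[(1,)]
        frac[f"{names[1]}|{names[0]}"] = total - R[(0,)]
        frac[f"{names[0]}&{names[1]}"] = R[(0,)] + R[(1,)] - total
    else:
        a = total - R[(1, 2)]
        b = total - R[(0, 2)]
        c = total - R[(0, 1)]
        ab = R[(0, 2)] + R[(1, 2)] - total - R[(2,)]
        ac = R[(0, 1)] + R[(1, 2)] - total - R[(1,)]
        bc = R[(0, 1)] + R[(0, 2)] - total - R[(0,)]
        abc = total - a - b - c - ab - ac - bc
        frac[f"{names[0]}|rest"] = a
        frac[f"{names[1]}|rest"] = b
        frac[f"{names[2]}|rest"] = c
        frac[f"{names[0]}&{names[1]}"] = ab
        frac[f"{names[0]}&{names[2]}"] = ac
        frac[f"{names[1]}&{names[2]}"] = bc
        frac["all_shared"] = abc
    assert abs(sum(frac.values()) - total) < 1e-10

    p_values = {}
    for i in range(k):
        others = np.column_stack([blocks[j] for j in range(k) if j != i])
        try:
            res = partial_rda(np.asarray(Y, dtype=float), blocks[i], Z=others,
                              n_perm=n_perm, seed=seed)
            key = f"{names[i]}|{names[1 - i]}" if k == 2 else f"{names[i]}|rest"
            p_values[key] = res.p_value
        except ValueError:
            pass

    truncated = {key: max(v, 0.0) for key, v in frac.items()}
    return VarpartResult(
        fractions=frac,
        fractions_truncated=truncated,
        residual=1.0 - total,
        total_adj_r2=total,
        p_values=p_values,
    )


# --------------------------------------------------------------------------
# predictor screening


def forward_select(Y, X_candidates, alpha: float = 0.05, n_perm: int = 1000,
                   adjR2_stop: float | None = None, seed=None):
    """Greedy forward selection of RDA predictors.

    At each step the candidate with the largest adjusted-R2 gain is
    permutation-tested (marginal pseudo-F with the current selection as
    conditioning; rows of the conditioned response permuted). Selection stops
    when the best candidate's p exceeds ``alpha`` or, if given, when the
    cumulative adjusted R2 exceeds ``adjR2_stop`` (double stopping).

    Returns a dict with ``selected`` (column names, in order), ``p_values``,
    and ``adj_r2_path``.
    """
    names = _colnames(X_candidates, "x")
    X = np.asarray(X_candidates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Ya = np.asarray(Y, dtype=float)
    if Ya.ndim == 1:
        Ya = Ya[:, None]
    n = Ya.shape[0]
    rng = np.random.default_rng(seed)

    selected: list[int] = []
    pvals: list[float] = []
    path: list[float] = []
    remaining = list(range(X.shape[1]))
    current_adj = 0.0
    while remaining:
        blocks = [X[:, selected + [j]] for j in remaining]
        gains = [
            _block_adj_r2(Ya, [B], (0,), n) for B in blocks
        ]
        best_pos = int(np.argmax(gains))
        j = remaining[best_pos]
        Zsel = X[:, selected] if selected else None
        res = partial_rda(Ya, X[:, [j]], Z=Zsel, n_perm=n_perm,
                          seed=int(rng.integers(2**31 - 1)))
        if res.p_value > alpha:
            break
        selected.append(j)
        remaining.remove(j)
        pvals.append(res.p_value)
        current_adj = gains[best_pos]
        path.append(current_adj)
        if adjR2_stop is not None and current_adj > adjR2_stop:
            break
    return {
        "selected": [names[j] for j in selected],
        "indices": selected,
        "p_values": pvals,
        "adj_r2_path": path,
    }


def collinearity_filter(X, r_max: float = 0.6):
    """Greedy collinearity screen in the given column (priority) order.

    A column is dropped when its |Pearson r| with an already-retained column
    is >= ``r_max``. Returns ``(retained_names, report)`` where the report
    lists each dropped column with the retained column that triggered it and
    their correlation.
    """
    names = _colnames(X, "x")
    A = np.asarray(X, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    retained: list[int] = []
    report: list[dict] = []
    for j in range(A.shape[1]):
        drop = None
        for i in retained:
            sd_i, sd_j = A[:, i].std(), A[:, j].std()
            if sd_i == 0 or sd_j == 0:
                r = 1.0 if sd_i == sd_j else 0.0
            else:
                r = float(np.corrcoef(A[:, i], A[:, j])[0, 1])
            if abs(r) >= r_max:
                drop = (i, r)
                break
        if drop is None:
            retained.append(j)
        else:
            report.append({"dropped": names[j], "against": names[drop[0]],
                           "r": drop[1]})
    return [names[j] for j in retained], report
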