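"""Hypothesis-testing layer: hierarchical partitioning and blocked ANOVA.

Hierarchical partitioning decomposes the explained variance (OLS R^2) of a
multiple regression into each predictor's independent effect I (the average
R^2 increment from adding that predictor, averaged within and across all
hierarchy levels of the 2^k possible subsets) and joint effect
J = univariate R^2 - I. Significance uses randomization Z-scores: the
response is permuted, I recomputed, and Z = (I_obs - mean)/sd; a predictor is
significant at the upper one-sided 95% limit (Z > 1.65).

The location effect (U2 / U1 / D) on a descriptor is tested with a
stream-blocked two-way ANOVA — the balanced-design equivalent of a mixed
model with stream as random intercept — with Tukey HSD contrasts on the
studentized range, a variance-component share for the stream factor, and
Cohen's d for downstream versus pooled upstream values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "HierarchicalPartitioning",
    "hierpart",
    "hierpart_z",
    "partial_correlation",
    "blocked_anova",
    "cohens_d",
    "AnovaResult",
]


# --------------------------------------------------------------------------
# hierarchical partitioning


def _subset_bases(Xc: np.ndarray) -> list[np.ndarray | None]:
    """Orthonormal bases of every predictor subset (index = bitmask)."""
    k = Xc.shape[1]
    bases: list[np.ndarray | None] = [None] * (1 << k)
    for mask in range(1, 1 << k):
        cols = [j for j in range(k) if mask >> j & 1]
        Q, R = np.linalg.qr(Xc[:, cols])
        rank = np.sum(np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R).max()))
        if rank < len(cols):
            raise np.linalg.LinAlgError(
                f"singular predictor subset: columns {cols}"
            )
        bases[mask] = Q
    return bases


def _all_r2(bases, yc: np.ndarray) -> np.ndarray:
    ss = float(yc @ yc)
    r2 = np.zeros(len(bases))
    for mask in range(1, len(bases)):
        proj = bases[mask].T @ yc
        r2[mask] = (proj @ proj) / ss
    return r2


def _independent_effects(r2: np.ndarray, k: int) -> np.ndarray:
    """Chevan-Sutherland averaging of R^2 increments over hierarchy levels."""
    I = np.zeros(k)
    for j in range(k):
        bit = 1 << j
        rest = [m for m in range(k) if m != j]
        for r in range(k):
            w = 1.0 / (k * comb(k - 1, r))
            for combo in combinations(rest, r):
                mask = sum(1 << m for m in combo)
                I[j] += w * (r2[mask | bit] - r2[mask])
    return I


class HierarchicalPartitioning(BaseEstimator):
    """All-subsets variance partitioning of an OLS regression.

    Parameters
    ----------
    n_randomizations : int
        Response permutations for the Z-scores (0 disables them).
    z_threshold : float
        One-sided significance limit on Z (default 1.65, upper 95%).
    seed : int or None

    Attributes (after ``fit(X, y)``)
    --------------------------------
    independent_effects_, joint_effects_, total_effects_ : per predictor
    pct_independent_ : 100 * I / sum(I)
    full_r2_, univariate_r2_
    z_scores_, significant_ : when randomizations were requested
    """

    def __init__(self, n_randomizations: int = 0, z_threshold: float = 1.65,
                 seed=None):
        self.n_randomizations = n_randomizations
        self.z_threshold = z_threshold
        self.seed = seed

    def fit(self, X, y):
        names = (
            list(X.columns) if isinstance(X, pd.DataFrame)
            else [f"x{j + 1}" for j in range(np.atleast_2d(np.asarray(X)).shape[1])]
        )
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        ya = np.asarray(y, dtype=float).ravel()
        n, k = Xa.shape
        if k > 12:
            raise ValueError("at most 12 predictors (2^k subset fits)")
        if n <= k + 1:
            raise ValueError("need n > k + 1 observations")
        if np.any(~np.isfinite(Xa)) or np.any(~np.isfinite(ya)):
            raise ValueError("missing values are not allowed")

        Xc = Xa - Xa.mean(axis=0)
        yc = ya - ya.mean()
        try:
            bases = _subset_bases(Xc)
        except np.linalg.LinAlgError as err:
            raise ValueError(str(err)) from None
        r2 = _all_r2(bases, yc)
        I = _independent_effects(r2, k)
        uni = np.array([r2[1 << j] for j in range(k)])
        full = r2[-1]
        assert abs(I.sum() - full) < 1e-10
        J = uni - I
        assert np.all(np.abs(I + J - uni) < 1e-10)

        self.feature_names_ = names
        self.independent_effects_ = I
        self.joint_effects_ = J
        self.total_effects_ = I + J
        self.pct_independent_ = 100.0 * I / I.sum() if I.sum() > 0 else np.full(k, np.nan)
        self.full_r2_ = full
        self.univariate_r2_ = uni

        if self.n_randomizations:
            rng = np.random.default_rng(self.seed)
            rand_I = np.empty((self.n_randomizations, k))
            for r in range(self.n_randomizations):
                yp = yc[rng.permutation(n)]
                rand_I[r] = _independent_effects(_all_r2(bases, yp), k)
            sd = rand_I.std(axis=0, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                z = (I - rand_I.mean(axis=0)) / sd
            if np.any(sd == 0):
                warnings.warn("zero randomization spread; Z undefined for some predictors")
                z = np.where(sd == 0, np.nan, z)
            self.z_scores_ = z
            self.significant_ = z > self.z_threshold
        else:
            self.z_scores_ = None
            self.significant_ = None
        return self

    def summary(self) -> pd.DataFrame:
        """Per-predictor table (I, J, total, %I, Z, significance), by %I desc."""
        out = pd.DataFrame({
            "I": self.independent_effects_,
            "J": self.joint_effects_,
            "total": self.total_effects_,
            "pct_I": self.pct_independent_,
        }, index=pd.Index(self.feature_names_, name="predictor"))
        if self.z_scores_ is not None:
            out["Z"] = self.z_scores_
            out["significant"] = self.significant_
        return out.sort_values("pct_I", ascending=False)


def hierpart(y, X) -> pd.DataFrame:
    """Independent/joint effects only (no randomization)."""
    return HierarchicalPartitioning().fit(X, y).summary()


def hierpart_z(y, X, n_rand: int = 1000, seed=None) -> pd.DataFrame:
    """Hierarchical partitioning with randomization Z-scores."""
    return HierarchicalPartitioning(n_randomizations=n_rand, seed=seed).fit(X, y).summary()


# --------------------------------------------------------------------------
# partial correlation


def partial_correlation(y, x, controls=None) -> float:
    """Pearson correlation of y and x after removing OLS fits on the controls."""
    ya = np.asarray(y, dtype=float).ravel()
    xa = np.asarray(x, dtype=float).ravel()
    if controls is None or (hasattr(controls, "__len__") and len(controls) == 0):
        return float(np.corrcoef(ya, xa)[0, 1])
    C = np.asarray(controls, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n = ya.size
    if n <= C.shape[1] + 2:
        raise ValueError("need n > number of controls + 2")
    Z = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("collinear controls")
    ry = ya - Z @ np.linalg.lstsq(Z, ya, rcond=None)[0]
    rx = xa - Z @ np.linalg.lstsq(Z, xa, rcond=None)[0]
    # residuals that vanish to numerical noise carry no correlation
    if (np.linalg.norm(ry) <= 1e-10 * np.linalg.norm(ya - ya.mean())
            or np.linalg.norm(rx) <= 1e-10 * np.linalg.norm(xa - xa.mean())):
        return 0.0
    return float(ry @ rx / (np.linalg.norm(ry) * np.linalg.norm(rx)))


# --------------------------------------------------------------------------
# blocked ANOVA


@dataclass
class AnovaResult:
    f: float
    df: tuple[int, int]
    p: float
    location_means: pd.Series
    tukey: pd.DataFrame
    stream_variance_pct: float
    cohens_d: float
    excluded_streams: list = field(default_factory=list)


def cohens_d(values_d, values_u) -> float:
    """Standardized mean difference with the n-weighted group-pooled SD."""
    a = np.asarray(values_d, dtype=float)
    b = np.asarray(values_u, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if sp2 == 0:
        warnings.warn("zero pooled SD; Cohen's d undefined")
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def blocked_anova(values, location, stream) -> AnovaResult:
    """Two-way ANOVA of a descriptor with stream as blocking factor.

    Equivalent, under the balanced design, to the mixed model with stream as
    random intercept. Streams missing a location are excluded listwise with a
    warning. The stream variance share is the intraclass estimate
    (MS_stream - MS_err) / (MS_stream + (a - 1) MS_err) in percent, floored
    at zero; Tukey HSD uses the studentized range with the error df.
    """
    df = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "loc": np.asarray(location),
        "stream": np.asarray(stream),
    }).dropna()
    locs = sorted(df["loc"].unique())
    a = len(locs)
    complete = df.groupby("stream")["loc"].nunique() == a
    excluded = sorted(complete.index[~complete])
    if excluded:
        warnings.warn(f"streams missing a location excluded: {excluded}")
        df = df[df["stream"].isin(complete.index[complete])]
    b = df["stream"].nunique()
    if b < 2:
        raise ValueError("need at least two complete streams")

    gm = df["y"].mean()
    loc_means = df.groupby("loc")["y"].mean().reindex(locs)
    stream_means = df.groupby("stream")["y"].mean()
    ss_loc = b * np.sum((loc_means - gm) ** 2)
    ss_stream = a * np.sum((stream_means - gm) ** 2)
    ss_tot = np.sum((df["y"] - gm) ** 2)
    ss_err = max(ss_tot - ss_loc - ss_stream, 0.0)
    df_loc, df_err = a - 1, (a - 1) * (b - 1)
    ms_loc = ss_loc / df_loc
    ms_stream = ss_stream / (b - 1)
    ms_err = ss_err / df_err

    if ms_err == 0:
        f = 0.0 if ms_loc == 0 else float("inf")
        p = 1.0 if ms_loc == 0 else 0.0
    else:
        f = ms_loc / ms_err
        p = float(stats.f.sf(f, df_loc, df_err))

    pairs = []
    for g1, g2 in combinations(locs, 2):
        diff = loc_means[g2] - loc_means[g1]
        if ms_err == 0:
            p_t = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / np.sqrt(ms_err / b)
            p_t = float(np.clip(stats.studentized_range.sf(q, a, df_err), 0, 1))
        pairs.append({"pair": f"{g2}-{g1}", "diff": float(diff), "p_tukey": p_t})
    tukey = pd.DataFrame(pairs).set_index("pair")

    denom = ms_stream + (a - 1) * ms_err
    share = 0.0 if denom == 0 else max(0.0, (ms_stream - ms_err) / denom) * 100.0

    d_vals = df.loc[df["loc"] == "D", "y"]
    u_vals = df.loc[df["loc"] != "D", "y"]
    try:
        d = cohens_d(d_vals, u_vals) if len(d_vals) >= 2 and len(u_vals) >= 2 else float("nan")
    except ValueError:
        d = float("nan")
    return AnovaResult(
        f=float(f), df=(df_loc, df_err), p=p, location_means=loc_means,
        tukey=tukey, stream_variance_pct=float(share), cohens_d=d,
        excluded_streams=excluded,
    )
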