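"""Taxonomy- and trait-based community descriptors.

Every descriptor operates on a single community (one sampling location): a
vector of non-negative integer counts aligned with a trait table that carries,
per taxon, the saprobic value ``s`` (1 = clean water, 4 = heavily organically
polluted), the saprobic indicator weight ``g`` (1..5), and boolean membership
flags for SPEAR (pesticide-sensitive "SPEcies At Risk"), EPT (Ephemeroptera,
Plecoptera, Trichoptera) and oligochaetes.

:func:`descriptor_matrix` assembles the full location x descriptor table used
by the downstream change statistics and ANOVA layer.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln

__all__ = [
    "taxa_richness",
    "rarefied_richness",
    "pielou_evenness",
    "fisher_alpha",
    "berger_parker",
    "saprobic_index",
    "spear_index",
    "ept_metrics",
    "descriptor_matrix",
    "DESCRIPTOR_COLUMNS",
]

DESCRIPTOR_COLUMNS = [
    "taxa_richness",
    "rarefied_richness",
    "evenness",
    "fisher_alpha",
    "saprobic",
    "spear",
    "total_abundance",
    "abundance_minus_oligo",
    "ept_richness",
    "pct_ept",
    "pct_ept_minus_oligo",
    "berger_parker",
]

TRAIT_COLUMNS = ["saprobic_value", "saprobic_weight", "spear", "ept", "oligochaete"]


def _as_counts(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("counts must be finite and non-negative")
    return x


def taxa_richness(counts) -> int:
    """Number of taxa with positive abundance."""
    x = _as_counts(counts)
    if x.sum() == 0:
        raise ValueError("undefined community: all counts are zero")
    return int(np.count_nonzero(x))


def rarefied_richness(counts, n: int) -> float:
    """Hurlbert's expected richness in a random subsample of ``n`` individuals.

    E[S_n] = sum_i [1 - C(N - x_i, n) / C(N, n)], evaluated with log-gamma
    arithmetic so large counts do not overflow.
    """
    x = _as_counts(counts)
    N = int(round(x.sum()))
    if not 1 <= n <= N:
        raise ValueError(
            f"rarefaction size n={n} out of range; smallest admissible "
            f"standardization is n=1 and the largest is the total count N={N}"
        )
    x = x[x > 0]

    def logC(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    terms = np.where(
        N - x >= n,
        np.exp(logC(N - x, n) - logC(N, n)),
        0.0,
    )
    return float(np.sum(1.0 - terms))


def pielou_evenness(counts) -> float:
    """Pielou's J = H' / ln S (Shannon entropy with natural log)."""
    x = _as_counts(counts)
    x = x[x > 0]
    S = x.size
    if S < 2:
        return float("nan")
    p = x / x.sum()
    H = -np.sum(p * np.log(p))
    return float(H / np.log(S))


def fisher_alpha(S: int, N: int) -> float:
    """Fisher's log-series alpha solving S = alpha * ln(1 + N / alpha).

    Solved by bracketed root finding to |residual| < 1e-10. Diverges when
    every individual is a distinct taxon (S == N).
    """
    if S < 1 or N < S:
        raise ValueError("need 1 <= S <= N")
    if S == N:
        raise OverflowError("Fisher's alpha diverges when S == N (all singletons)")

    def f(a):
        return S - a * np.log1p(N / a)

    lo, hi = 1e-12, 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - S==N guarded above
            raise OverflowError("Fisher's alpha did not converge")
    alpha = brentq(f, lo, hi, xtol=1e-14, rtol=1e-14)
    assert abs(f(alpha)) < 1e-8
    return float(alpha)


def berger_parker(counts) -> float:
    """Berger-Parker dominance: share of the single most abundant taxon."""
    x = _as_counts(counts)
    N = x.sum()
    if N == 0:
        raise ValueError("undefined community: all counts are zero")
    return float(x.max() / N)


def _aligned_traits(counts, traits: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    x = _as_counts(counts)
    if len(x) != len(traits):
        raise ValueError(
            f"counts ({len(x)}) and trait table ({len(traits)}) have different lengths"
        )
    return x, traits


def saprobic_index(counts, traits: pd.DataFrame, abundance_transform=None) -> float:
    """Saprobic Index: SI = sum(s_i g_i a_i) / sum(g_i a_i) over scored taxa.

    ``a_i`` is the abundance term; by default the raw count. An optional
    ``abundance_transform`` hook (e.g. an abundance-class mapping) is applied
    to the counts before weighting. Taxa with missing s or g are excluded
    from numerator and denominator.
    """
    x, traits = _aligned_traits(counts, traits)
    s = np.asarray(traits["saprobic_value"], dtype=float)
    g = np.asarray(traits["saprobic_weight"], dtype=float)
    a = abundance_transform(x) if abundance_transform is not None else x
    ok = (a > 0) & np.isfinite(s) & np.isfinite(g)
    if not ok.any():
        warnings.warn("no scored taxa present; Saprobic Index undefined")
        return float("nan")
    denom = np.sum(g[ok] * a[ok])
    return float(np.sum(s[ok] * g[ok] * a[ok]) / denom)


def spear_index(counts, traits: pd.DataFrame) -> float:
    """SPEAR index: abundance-weighted percentage of pesticide-sensitive taxa.

    SPEAR = 100 * sum_i w(x_i) 1[spear_i] / sum_i w(x_i) with the log-damped
    abundance weight w(x) = log10(4 x + 1).
    """
    x, traits = _aligned_traits(counts, traits)
    if x.sum() == 0:
        raise ValueError("undefined community: all counts are zero")
    w = np.log10(4.0 * x + 1.0)
    flag = np.asarray(traits["spear"], dtype=bool)
    return float(100.0 * np.sum(w[flag]) / np.sum(w))


def ept_metrics(counts, traits: pd.DataFrame) -> dict[str, float]:
    """EPT richness and relative-abundance metrics, plus abundance totals.

    ``pct_ept_minus_oligo`` recomputes both numerator and denominator with
    oligochaete-flagged taxa excluded (NaN if nothing remains).
    """
    x, traits = _aligned_traits(counts, traits)
    N = x.sum()
    if N == 0:
        raise ValueError("undefined community: all counts are zero")
    ept = np.asarray(traits["ept"], dtype=bool)
    oligo = np.asarray(traits["oligochaete"], dtype=bool)
    keep = ~oligo
    n_keep = x[keep].sum()
    return {
        "ept_richness": int(np.count_nonzero(x[ept] > 0)),
        "pct_ept": float(100.0 * x[ept].sum() / N),
        "pct_ept_minus_oligo": (
            float(100.0 * x[ept & keep].sum() / n_keep) if n_keep > 0 else float("nan")
        ),
        "total_abundance": float(N),
        "abundance_minus_oligo": float(n_keep),
    }


def descriptor_matrix(
    abundance: pd.DataFrame,
    traits: pd.DataFrame,
    rarefaction_n: int | None = None,
) -> pd.DataFrame:
    """All descriptors for every location (rows of ``abundance``).

    ``abundance`` is a wide locations x taxa count table whose columns must
    match the trait table index exactly. Rarefaction standardizes to
    ``rarefaction_n`` individuals, defaulting to the minimum location total.
    Per-descriptor failures yield NaN rather than aborting the batch.
    """
    traits = traits.loc[list(abundance.columns)]
    totals = abundance.sum(axis=1)
    if rarefaction_n is None:
        rarefaction_n = int(totals.min())
    rows = {}
    for loc, row in abundance.iterrows():
        x = row.to_numpy(dtype=float)
        rec: dict[str, float] = {}
        try:
            rec["taxa_richness"] = taxa_richness(x)
            rec["rarefied_richness"] = rarefied_richness(x, min(rarefaction_n, int(x.sum())))
            rec["evenness"] = pielou_evenness(x)
            S, N = rec["taxa_richness"], int(round(x.sum()))
            rec["fisher_alpha"] = fisher_alpha(S, N) if S < N else float("nan")
            rec["saprobic"] = saprobic_index(x, traits)
            rec["spear"] = spear_index(x, traits)
            rec.update(ept_metrics(x, traits))
            rec["berger_parker"] = berger_parker(x)
        except ValueError as err:
            warnings.warn(f"location {loc}: {err}")
            rec = {c: float("nan") for c in DESCRIPTOR_COLUMNS}
        rows[loc] = rec
    out = pd.DataFrame.from_dict(rows, orient="index")[DESCRIPTOR_COLUMNS]
    out.index.name = abundance.index.name or "location"
    return out
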