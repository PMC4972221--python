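"""Bespoke change statistics of the upstream/downstream design.

Each stream contributes one record: the wastewater dilution factor
``DF_ww = Q347 / Q_ww`` (small DF = weak dilution = strong disturbance), the
null-corrected descriptor change ``(D - U1) - (U1 - U2)`` (downstream change
minus natural drift between the two upstream references), the Total Community
Change in two-axis NMDS space, and the two PCA-derived predictors: a
wastewater-composition index (PC1 of the downstream chemistry block) and an
instream-habitat change score (two-stage PCA collapse of upstream-downstream
habitat shifts).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .ordination import pca
from .synthgen import CHEMISTRY_VARS, HABITAT_VARS

__all__ = [
    "dilution_factor",
    "descriptor_change",
    "total_community_change",
    "wastewater_composition_pc",
    "habitat_change_pc",
    "change_table",
]


def dilution_factor(q347, q_ww):
    """DF_ww = Q347 / Q_ww (both strictly positive; vectorized)."""
    q347 = np.asarray(q347, dtype=float)
    q_ww = np.asarray(q_ww, dtype=float)
    if np.any(q347 <= 0) or np.any(q_ww <= 0):
        raise ValueError("discharges must be strictly positive")
    out = q347 / q_ww
    return float(out) if out.ndim == 0 else out


def descriptor_change(d_D, d_U1, d_U2):
    """Null-corrected change: (D - U1) - (U1 - U2). NaN inputs warn and
    propagate to a missing change value."""
    vals = np.asarray([d_D, d_U1, d_U2], dtype=float)
    if np.any(~np.isfinite(vals)):
        warnings.warn("missing descriptor value; change set to NaN")
        return float("nan")
    return float((d_D - d_U1) - (d_U1 - d_U2))


def total_community_change(scores_u2, scores_u1, scores_d):
    """TCC = ||D - U1|| - ||U1 - U2|| in (two-axis) ordination space.

    Scores must come from one joint ordination of all locations. Negative
    values mean the downstream shift is smaller than the natural drift
    between the two upstream references; they are passed through as-is.
    """
    u2, u1, d = (np.asarray(v, dtype=float) for v in (scores_u2, scores_u1, scores_d))
    if any(np.any(~np.isfinite(v)) for v in (u2, u1, d)):
        return float("nan")
    change = np.linalg.norm(d - u1)
    null_change = np.linalg.norm(u1 - u2)
    return float(change - null_change)


def wastewater_composition_pc(chemistry: pd.DataFrame, orient_by: str = "total_n"):
    """Wastewater-composition index: PC1 of the per-stream chemistry block.

    ``chemistry`` has one row per stream (downstream or effluent samples) and
    the water-quality variables as columns. The PCA is correlation-scaled;
    constant variables are dropped with a warning. PC1 sign is fixed so that
    the score correlates positively with ``orient_by`` (total nitrogen by
    default), a reproducible convention since PCA sign is arbitrary.

    Returns ``(pc1_scores, variance_fraction)``.
    """
    if len(chemistry) < 2:
        raise ValueError("need at least two streams")
    X = chemistry.copy()
    const = X.columns[X.std(axis=0, ddof=1) == 0]
    if len(const):
        warnings.warn(f"dropping constant chemistry variables: {list(const)}")
        X = X.drop(columns=const)
    res = pca(X, center=True, scale=True)
    pc1 = res.scores["PC1"]
    if orient_by in X.columns:
        r = np.corrcoef(pc1, X[orient_by])[0, 1]
        if r < 0:
            pc1 = -pc1
    return pc1.rename("PC1_ww"), float(res.proportion_explained[0])


def habitat_change_pc(habitat_u: pd.DataFrame, habitat_d: pd.DataFrame,
                      n_components: int = 3, orient_by: str = "fine_sediment"):
    """Habitat-change score per stream (two-stage PCA collapse).

    Stage 1: PCA of the habitat block over all rows (upstream and downstream
    together, correlation-scaled). Stage 2: the per-stream change in the first
    ``n_components`` site scores is collapsed to one score by a second PCA.
    The sign is fixed so the score correlates positively with the change in
    ``orient_by`` (fine-sediment cover by default). Invariant to the ordering
    of habitat variables.

    Returns ``(scores, stage2_variance_fraction)``.
    """
    if not habitat_u.index.equals(habitat_d.index):
        raise ValueError("upstream and downstream habitat rows must align by stream")
    cols = sorted(habitat_u.columns)
    both = pd.concat([habitat_u[cols], habitat_d[cols]], keys=["U", "D"])
    if both.isna().any().any():
        missing = both.index[both.isna().any(axis=1)].tolist()
        warnings.warn(f"missing habitat rows: {missing}")
    res = pca(both, center=True, scale=True,
              n_components=min(n_components, len(cols)))
    scores = res.scores
    delta = scores.loc["D"].to_numpy() - scores.loc["U"].to_numpy()
    if np.allclose(delta, 0):
        out = pd.Series(0.0, index=habitat_u.index, name="PC_habitat")
        return out, 1.0
    stage2 = pca(delta, center=False, scale=False)
    score = stage2.scores["PC1"].to_numpy()
    d_orient = (habitat_d[orient_by] - habitat_u[orient_by]).to_numpy()
    if orient_by in cols and np.std(d_orient) > 0:
        r = np.corrcoef(score, d_orient)[0, 1]
        if r < 0:
            score = -score
    return pd.Series(score, index=habitat_u.index, name="PC_habitat"), float(
        stage2.proportion_explained[0]
    )


def change_table(descriptors: pd.DataFrame, sites: pd.DataFrame,
                 nmds_scores: pd.DataFrame | None = None,
                 rd_scores: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-stream response/predictor table (one row per stream).

    Assembles the null-corrected changes of the six scalar descriptors, the
    Total Community Change (if NMDS scores are given), the dilution factor,
    the chemistry and habitat PCA indices, and the upstream-composition axes
    (``rd_scores``: U1-site scores of the conditioned upstream ordination).
    Streams missing one of the three positions are excluded with a warning.
    """
    streams = sorted(sites["stream"].unique())
    loc = {(s, p): f"{s}_{p}" for s in streams for p in ("U2", "U1", "D")}
    keep = []
    for s in streams:
        if all(loc[(s, p)] in descriptors.index for p in ("U2", "U1", "D")):
            keep.append(s)
        else:
            warnings.warn(f"stream {s} lacks a complete U2/U1/D triple; excluded")

    resp_cols = {
        "delta_taxa": "taxa_richness", "delta_rarefied": "rarefied_richness",
        "delta_evenness": "evenness", "delta_fisher": "fisher_alpha",
        "delta_saprobic": "saprobic", "delta_spear": "spear",
    }
    rows = {}
    for s in keep:
        u2, u1, d = (descriptors.loc[loc[(s, p)]] for p in ("U2", "U1", "D"))
        rec = {
            out: descriptor_change(d[c], u1[c], u2[c]) for out, c in resp_cols.items()
        }
        if nmds_scores is not None:
            rec["total_community_change"] = total_community_change(
                nmds_scores.loc[loc[(s, "U2")]],
                nmds_scores.loc[loc[(s, "U1")]],
                nmds_scores.loc[loc[(s, "D")]],
            )
        srow = sites.loc[loc[(s, "U1")]]
        rec["DF_ww"] = dilution_factor(srow["q347"], srow["q_ww"])
        rows[s] = rec
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "stream"

    d_rows = [loc[(s, "D")] for s in keep]
    chem = sites.loc[d_rows, [c for c in CHEMISTRY_VARS if c in sites.columns]]
    chem.index = keep
    pc1, _ = wastewater_composition_pc(chem)
    out["PC1_ww"] = pc1

    hab_cols = [c for c in HABITAT_VARS if c in sites.columns]
    hab_u = sites.loc[[loc[(s, "U1")] for s in keep], hab_cols]
    hab_u.index = keep
    hab_d = sites.loc[d_rows, hab_cols]
    hab_d.index = keep
    pch, _ = habitat_change_pc(hab_u, hab_d)
    out["PC_habitat"] = pch

    if rd_scores is not None:
        for i, col in enumerate(rd_scores.columns[:3], start=1):
            out[f"RD{i}_invert"] = rd_scores.loc[keep, col]
    return out
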