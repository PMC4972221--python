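"""End-to-end orchestration: simulate/load -> descriptors -> ordinations ->
change statistics -> hierarchical partitioning and blocked ANOVA.

The sequence mirrors the study design the package analyses: a joint NMDS of
all sampling locations feeds the Total Community Change; an upstream-only
partial RDA conditioned on PCNM spatial eigenvectors yields the three
upstream-composition predictors (RD1-3_invert at the U1 sites); Eq.-style
change statistics and the two PCA indices complete the per-stream change
table; hierarchical partitioning with randomization Z-scores and the
stream-blocked ANOVA close the inference layer. All randomness is funneled
through one root seed, so a run is deterministic given its configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import change as change_mod
from . import indices, inference, ordination, synthgen

__all__ = ["RunConfig", "ReportBundle", "validate_inputs", "run_pipeline",
           "render_reports"]

# reach-scale environmental predictors offered to the upstream model
UPSTREAM_ENV_VARS = ["nh4", "srp", "no3", "conductivity", "dom", "tss", "velocity"]
LANDUSE_VARS = ["arable", "pasture"]

RESPONSES = ["delta_taxa", "delta_rarefied", "delta_evenness", "delta_fisher",
             "delta_saprobic", "delta_spear", "total_community_change"]
PREDICTORS = ["RD1_invert", "RD2_invert", "RD3_invert", "DF_ww", "PC1_ww",
              "PC_habitat"]


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Either set ``generator`` (synthetic mode) or the three input CSV paths.
    """

    generator: synthgen.GeneratorParams | None = None
    abundance_path: str | None = None
    traits_path: str | None = None
    sites_path: str | None = None
    rarefaction_n: int | None = None
    nmds_starts: int = 20
    n_perm: int = 999
    pcnm_axes: int = 2
    pcnm_selection: str = "first_k"  # or "forward"
    collinearity_r_max: float = 0.6
    hierpart_randomizations: int = 1000
    exclude_streams: tuple[str, ...] = ()
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        for name in ("nmds_starts", "n_perm", "hierpart_randomizations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class ReportBundle:
    descriptors: pd.DataFrame
    anova_table: pd.DataFrame
    change_table: pd.DataFrame
    hierpart_tables: dict[str, pd.DataFrame]
    nmds_scores: pd.DataFrame
    nmds_stress: float
    permanova: ordination.PermanovaResult
    upstream_rda: dict
    log: list[str] = field(default_factory=list)


def _seed(root: int, tag: int) -> int:
    return int(np.random.SeedSequence([root, tag]).generate_state(1)[0] % (2**31 - 1))


def validate_inputs(abundance: pd.DataFrame, traits: pd.DataFrame,
                    sites: pd.DataFrame) -> dict:
    """Cross-check table alignment and value bounds.

    Returns ``{"errors": [...], "warnings": [...]}``; errors are conditions
    the pipeline cannot proceed past (misaligned ids, negative counts),
    warnings are recoverable (a stream missing its U2 reference is excluded
    from the change statistics, which need both references).
    """
    errors, warns = [], []
    unknown = [t for t in abundance.columns if t not in traits.index]
    if unknown:
        errors.append(f"abundance has taxa missing from the trait table: {unknown}")
    missing = [t for t in traits.index if t not in abundance.columns]
    if missing:
        warns.append(f"trait-table taxa absent from abundance: {missing}")
    bad_loc = [loc for loc in abundance.index if loc not in sites.index]
    if bad_loc:
        errors.append(f"abundance locations missing from the site table: {bad_loc}")
    if (np.asarray(abundance, dtype=float) < 0).any():
        errors.append("negative abundance counts")
    s = traits["saprobic_value"]
    if ((s < 1) | (s > 4)).any():
        errors.append("saprobic values outside [1, 4]")
    if (traits["saprobic_weight"] < 1).any():
        errors.append("saprobic weights below 1")
    for stream, grp in sites.groupby("stream"):
        got = set(grp["position"])
        lack = {"U2", "U1", "D"} - got
        if lack:
            warns.append(
                f"stream {stream} missing position(s) {sorted(lack)}; "
                "excluded from change statistics (both references required)"
            )
    return {"errors": errors, "warnings": warns}


def _load_tables(config: RunConfig):
    if config.generator is not None:
        traits = synthgen.generate_traits(config.generator)
        sites = synthgen.generate_sites(config.generator)
        abundance = synthgen.generate_abundances(sites, traits, config.generator)
        return abundance, traits, sites
    if not (config.abundance_path and config.traits_path and config.sites_path):
        raise ValueError("provide generator params or all three input paths")
    abundance = pd.read_csv(config.abundance_path, index_col=0)
    traits = pd.read_csv(config.traits_path, index_col=0)
    for c in ("spear", "ept", "oligochaete"):
        traits[c] = traits[c].astype(bool)
    sites = pd.read_csv(config.sites_path, index_col=0)
    return abundance, traits, sites


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis; deterministic given the configuration."""
    log = [f"root seed: {config.seed}"]
    abundance, traits, sites = _load_tables(config)
    report = validate_inputs(abundance, traits, sites)
    if report["errors"]:
        raise ValueError("input validation failed: " + "; ".join(report["errors"]))
    for w in report["warnings"]:
        log.append(f"validation warning: {w}")

    if config.exclude_streams:
        keep = ~sites["stream"].isin(config.exclude_streams)
        dropped = sites.index[~keep]
        log.append(f"excluded streams {list(config.exclude_streams)}: "
                   f"{len(dropped)} locations dropped")
        sites = sites[keep]
        abundance = abundance.loc[[i for i in abundance.index if i in sites.index]]

    # descriptors -------------------------------------------------------
    desc = indices.descriptor_matrix(abundance, traits,
                                     rarefaction_n=config.rarefaction_n)
    log.append(f"descriptors computed for {len(desc)} locations")

    # joint NMDS over all locations ------------------------------------
    hel = ordination.hellinger(abundance)
    D = squareform(pdist(hel.to_numpy()))
    nm = ordination.nmds(pd.DataFrame(D, index=hel.index, columns=hel.index),
                         k=2, n_starts=config.nmds_starts,
                         seed=_seed(config.seed, 10))
    log.append(f"NMDS stress: {nm.stress:.6f} (converged: {nm.converged})")

    perm = ordination.permanova(D, sites.loc[hel.index, "position"],
                                n_perm=config.n_perm, seed=_seed(config.seed, 11))
    log.append(f"PERMANOVA F={perm.pseudo_f:.3f} R2={perm.r2:.3f} p={perm.p_value:.4f}")

    # upstream pRDA conditioned on PCNM --------------------------------
    up_idx = sites.index[sites["position"].isin(["U1", "U2"])]
    Yup = hel.loc[up_idx]
    coords = sites.loc[up_idx, ["x", "y"]].to_numpy()
    vecs, _ = ordination.pcnm(coords)
    env_cols = LANDUSE_VARS + [c for c in UPSTREAM_ENV_VARS if c in sites.columns]
    Xenv = sites.loc[up_idx, env_cols]
    retained, colrep = ordination.collinearity_filter(Xenv,
                                                      r_max=config.collinearity_r_max)
    for rec in colrep:
        log.append(f"collinearity filter dropped {rec['dropped']} "
                   f"(r={rec['r']:.2f} with {rec['against']})")
    if config.pcnm_selection == "forward":
        sel = ordination.forward_select(
            Yup.to_numpy(),
            pd.DataFrame(vecs, index=up_idx,
                         columns=[f"PCNM{i+1}" for i in range(vecs.shape[1])]),
            alpha=0.05, n_perm=min(config.n_perm, 199), seed=_seed(config.seed, 12),
        )
        z_idx = sel["indices"] or [0]
    else:
        # broad-scale axes only: conditioning on many fine-scale axes would
        # absorb the between-stream variance the context predictors live on
        z_idx = list(range(min(config.pcnm_axes, vecs.shape[1])))
    pcnm_names = [f"PCNM{i + 1}" for i in z_idx]
    log.append(f"PCNM axes retained for conditioning: {pcnm_names}")
    prda = ordination.partial_rda(Yup, Xenv[retained], Z=vecs[:, z_idx],
                                  n_perm=config.n_perm, seed=_seed(config.seed, 13))
    log.append(f"upstream pRDA adjR2={prda.adj_r2:.3f} p={prda.p_value:.4f}")
    u1_idx = [i for i in up_idx if sites.loc[i, "position"] == "U1"]
    rd = prda.scores.loc[u1_idx].iloc[:, :3]
    rd.index = sites.loc[u1_idx, "stream"]

    # change statistics -------------------------------------------------
    chg = change_mod.change_table(desc, sites, nmds_scores=nm.scores, rd_scores=rd)
    log.append(f"change table: {len(chg)} streams")

    # hierarchical partitioning -----------------------------------------
    hp_tables = {}
    preds = chg[[p for p in PREDICTORS if p in chg.columns]]
    for i, resp in enumerate(RESPONSES):
        if resp not in chg.columns:
            continue
        ok = chg[resp].notna()
        if ok.sum() <= preds.shape[1] + 1:
            log.append(f"hierpart skipped for {resp}: too few streams")
            continue
        hp = inference.hierpart_z(chg.loc[ok, resp], preds.loc[ok],
                                  n_rand=config.hierpart_randomizations,
                                  seed=_seed(config.seed, 20 + i))
        hp_tables[resp] = hp
        log.append(f"hierpart[{resp}]: top predictor {hp.index[0]} "
                   f"(%I={hp['pct_I'].iloc[0]:.1f}, Z={hp['Z'].iloc[0]:.2f})")

    # blocked ANOVA per descriptor --------------------------------------
    rows = {}
    for col in indices.DESCRIPTOR_COLUMNS:
        vals = desc[col]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = inference.blocked_anova(vals, sites.loc[desc.index, "position"],
                                          sites.loc[desc.index, "stream"])
        rec = {
            f"mean_{g}": res.location_means.get(g, np.nan) for g in ("U2", "U1", "D")
        }
        rec.update({
            "F": res.f, "df1": res.df[0], "df2": res.df[1], "p": res.p,
            "stream_var_pct": res.stream_variance_pct, "cohens_d": res.cohens_d,
        })
        rows[col] = rec
    anova_table = pd.DataFrame.from_dict(rows, orient="index")
    anova_table.index.name = "descriptor"

    bundle = ReportBundle(
        descriptors=desc, anova_table=anova_table, change_table=chg,
        hierpart_tables=hp_tables, nmds_scores=nm.scores, nmds_stress=nm.stress,
        permanova=perm,
        upstream_rda={"adj_r2": prda.adj_r2, "p_value": prda.p_value,
                      "eigenvalues": prda.eigenvalues,
                      "retained_env": retained,
                      "pcnm_axes": pcnm_names},
        log=log,
    )
    if config.outdir:
        render_reports(bundle, config.outdir, config=config)
    return bundle


def render_reports(bundle: ReportBundle, outdir, config: RunConfig | None = None,
                   plots: bool = True) -> list[str]:
    """Write CSV/markdown reports (and diagnostic plots) to ``outdir``.

    Hierarchical-partitioning tables are ordered by %I descending. Returns
    the list of files written.
    """
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def save(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, float_format="%.10g")
        written.append(str(path))

    save(bundle.descriptors, "descriptor_matrix.csv")
    save(bundle.anova_table, "descriptor_anova.csv")
    save(bundle.change_table, "change_table.csv")
    save(bundle.nmds_scores, "nmds_scores.csv")
    for resp, tab in bundle.hierpart_tables.items():
        save(tab, f"hierpart_{resp}.csv")

    lines = ["# Run log", ""]
    lines += [f"- {entry}" for entry in bundle.log]
    lines += ["", f"NMDS stress: {bundle.nmds_stress:.6f}",
              f"PERMANOVA: F={bundle.permanova.pseudo_f:.4f} "
              f"R2={bundle.permanova.r2:.4f} p={bundle.permanova.p_value:.4f}"]
    if config is not None:
        cfg = asdict(config)
        cfg["generator"] = None if config.generator is None else asdict(config.generator)
        lines += ["", "## Configuration", "```", repr(cfg), "```"]
    (out / "run_log.md").write_text("\n".join(lines) + "\n")
    written.append(str(out / "run_log.md"))

    if plots:
        written += _diagnostic_plots(bundle, out)
    return written


def _diagnostic_plots(bundle: ReportBundle, out) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    # NMDS biplot by position
    fig, ax = plt.subplots(figsize=(5, 4))
    pos = [i.rsplit("_", 1)[-1] for i in bundle.nmds_scores.index]
    for g, color in (("U2", "tab:blue"), ("U1", "tab:cyan"), ("D", "tab:red")):
        mask = [p == g for p in pos]
        pts = bundle.nmds_scores[mask]
        ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], label=g, color=color, s=20)
    ax.legend()
    ax.set_xlabel("NMDS1")
    ax.set_ylabel("NMDS2")
    ax.set_title(f"stress = {bundle.nmds_stress:.3f}")
    fig.tight_layout()
    p1 = out / "nmds_biplot.png"
    fig.savefig(p1, dpi=120)
    plt.close(fig)
    written.append(str(p1))

    chg = bundle.change_table
    panels = [("DF_ww", "delta_spear"), ("RD3_invert", "delta_saprobic")]
    panels = [(x, y) for x, y in panels if x in chg.columns and y in chg.columns]
    if panels:
        fig, axes = plt.subplots(1, len(panels), figsize=(4.5 * len(panels), 3.5))
        axes = np.atleast_1d(axes)
        for ax, (xcol, ycol) in zip(axes, panels):
            ax.scatter(chg[xcol], chg[ycol], color="k", s=18)
            ax.set_xlabel(xcol)
            ax.set_ylabel(ycol)
        fig.tight_layout()
        p2 = out / "change_regressions.png"
        fig.savefig(p2, dpi=120)
        plt.close(fig)
        written.append(str(p2))
    return written
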