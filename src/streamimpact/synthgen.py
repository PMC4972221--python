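"""Synthetic stream networks with a wastewater point-source disturbance.

The generator emulates a space-for-time BACI design: ``n_streams`` independent
streams, each with two upstream reference reaches (U2, U1) and one reach
downstream (D) of a wastewater treatment plant outfall. Across streams two
gradients are laid out, approximately orthogonal to each other:

* an *environmental context* gradient — catchment agriculture (arable +
  pasture cover), which tilts the upstream community toward saprobic-tolerant
  taxa (raising the upstream Saprobic Index) and away from pesticide-sensitive
  SPEAR taxa (lowering the upstream SPEAR index with arable cover);
* a *magnitude of disturbance* gradient — the wastewater fraction
  f = Q_ww / Q347, which at the downstream reach depresses the SPEAR index
  (slope ``gamma_spear_df``) and, together with the upstream saprobic state,
  controls the downstream boom of oligochaete worms.

Effects are parameterized on the descriptor scale (Saprobic Index units,
SPEAR percentage points, oligochaete share) and mapped to expected taxon
shares by solving exponential-tilt equations, so that the descriptors of the
noiseless expected composition hit the targets by construction. Counts are
drawn per taxon from a negative binomial around the expected shares.
:func:`ground_truth` returns those noiseless expectations for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import indices

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "generate_traits",
    "generate_sites",
    "generate_abundances",
    "ground_truth",
    "simulate",
    "CHEMISTRY_VARS",
    "HABITAT_VARS",
]

CHEMISTRY_VARS = [
    "conductivity", "ph", "alkalinity", "hardness",
    "nh4", "no2", "total_p", "srp", "no3", "total_n", "sio4",
    "na", "k", "ca", "mg", "cl", "so4",
    "tom", "dom", "tss",
]

HABITAT_VARS = [
    "bedrock", "boulder", "cobble", "gravel", "sand", "fine_sediment",
    "susp_sed_inorg", "susp_sed_org", "cpom", "algae",
    "macrophytes_sub", "macrophytes_em", "velocity", "width", "depth",
]

# chemistry loadings: response to catchment agriculture and to the
# wastewater fraction at the downstream reach (log scale)
_AGRI_LOAD = {"no3": 1.2, "total_n": 1.0, "total_p": 0.9, "srp": 0.9, "tss": 0.6}
_WW_LOAD = {
    "nh4": 1.0, "no2": 0.9, "srp": 0.9, "total_p": 0.8, "no3": 0.5,
    "total_n": 0.6, "na": 0.7, "cl": 0.7, "k": 0.5, "conductivity": 0.4,
    "dom": 0.6, "tom": 0.5, "tss": 0.3, "so4": 0.3, "sio4": 0.2,
    "alkalinity": 0.2, "hardness": 0.15, "ca": 0.1, "mg": 0.1, "ph": 0.0,
}

_POSITIONS = ("U2", "U1", "D")


@dataclass
class GeneratorParams:
    """Tunable knobs of the synthetic study; defaults match the emulated design.

    Slopes are on the descriptor scale: ``beta_si_agri`` in Saprobic-Index
    units per unit agriculture fraction, ``beta_spear_arable`` in SPEAR
    percentage points per unit arable fraction, ``gamma_spear_df`` in SPEAR
    points lost per unit wastewater fraction, and the oligochaete slopes in
    share units per Saprobic-Index unit.
    """

    n_streams: int = 12
    n_taxa: int = 60
    agriculture_range: tuple[float, float] = (0.05, 0.80)
    ww_fraction_range: tuple[float, float] = (0.23, 1.33)
    beta_si_agri: float = 0.45
    si_base: float = 1.75
    beta_spear_arable: float = -45.0
    spear_base: float = 55.0
    b_up_oligo: float = 0.468
    b_down_oligo: float = -0.9
    si_ref: float = 1.9
    oligo_base: float = 0.10
    oligo_boost: float = 0.30
    gamma_spear_df: float = 8.0
    dispersion: float = 50.0
    total_count_mean: float = 4000.0
    stream_sd: float = 0.2
    baseline_sd: float = 2.2
    occupancy: float = 1.0
    min_expected_count: float = 4.0
    si_scatter_sd: float = 0.10
    spear_scatter_sd: float = 4.0
    spear_fraction_band: tuple[float, float] = (0.2, 0.5)
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 10:
            raise ValueError("n_taxa must be >= 10")
        if self.n_streams < 2:
            raise ValueError("n_streams must be >= 2")
        for name in ("agriculture_range", "ww_fraction_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be ordered low <= high")
        lo, hi = self.agriculture_range
        if not (0 <= lo and hi <= 1):
            raise ValueError("agriculture_range must lie in [0, 1]")
        if self.ww_fraction_range[0] < 0:
            raise ValueError("ww_fraction_range must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 < self.occupancy <= 1:
            raise ValueError("occupancy must be in (0, 1]")


@dataclass
class GroundTruth:
    """Noiseless expectations underlying a generated dataset.

    ``streams`` has one row per stream (upstream/downstream descriptor
    expectations, expected changes, gradients); ``expected_shares`` are the
    expected taxon shares per location; ``dominant_predictor`` names, per
    change response, the predictor that truly drives it.
    """

    streams: pd.DataFrame
    expected_shares: pd.DataFrame
    dominant_predictor: dict[str, str] = field(default_factory=dict)


def _rng(params: GeneratorParams, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(params.seed) % 2**32, tag])


def generate_traits(params: GeneratorParams) -> pd.DataFrame:
    """Per-taxon trait table: saprobic value/weight, SPEAR/EPT/oligochaete flags.

    Community roles are blocked: a few oligochaete taxa (saprobic value near
    3.5), a SPEAR-and-EPT block of sensitive insects, tolerant
    chironomid/gammarid-like taxa with elevated baseline abundance, and a
    mixed remainder. ``baseline_logw`` carries the log relative-abundance
    baseline used by the abundance model.
    """
    rng = _rng(params, 1)
    n = params.n_taxa
    n_oligo = max(2, round(0.05 * n))
    n_spear_ept = max(3, round(0.30 * n))
    n_ept = max(1, round(0.10 * n))
    n_tolerant = max(2, round(0.17 * n))
    n_other = n - n_oligo - n_spear_ept - n_ept - n_tolerant
    if n_other < 0:
        raise ValueError("n_taxa too small for the configured community roles")

    recs = []
    for _ in range(n_oligo):
        recs.append((rng.uniform(3.2, 3.8), 4, False, False, True, 0.0))
    for _ in range(n_spear_ept):
        recs.append((rng.uniform(1.2, 2.2), int(rng.integers(2, 5)), True, True, False, 0.0))
    for _ in range(n_ept):
        recs.append((rng.uniform(1.6, 2.4), int(rng.integers(2, 5)), False, True, False, 0.0))
    for _ in range(n_tolerant):
        recs.append((rng.uniform(2.4, 3.0), int(rng.integers(3, 6)), False, False, False, 1.0))
    for _ in range(n_other):
        recs.append((rng.uniform(1.5, 3.0), int(rng.integers(1, 6)), False, False, False, 0.0))

    df = pd.DataFrame(
        recs,
        columns=["saprobic_value", "saprobic_weight", "spear", "ept",
                 "oligochaete", "_boost"],
        index=[f"t{i + 1:03d}" for i in range(n)],
    )
    df.index.name = "taxon"
    df["baseline_logw"] = rng.normal(0.0, params.baseline_sd, size=n) + df.pop("_boost")
    return df


def generate_sites(params: GeneratorParams) -> pd.DataFrame:
    """Site table: design, coordinates, hydrology, land use, chemistry, habitat.

    One row per sampling location (``n_streams`` x {U2, U1, D}). Agriculture
    and the wastewater fraction are evenly spaced across streams (spanning
    their configured ranges exactly) and independently shuffled, so the
    context and disturbance gradients are close to orthogonal.
    """
    rng = _rng(params, 2)
    ns = params.n_streams
    streams = [f"s{i + 1:02d}" for i in range(ns)]

    agri = np.linspace(*params.agriculture_range, ns)
    rng.shuffle(agri)
    fww = np.linspace(*params.ww_fraction_range, ns)
    rng.shuffle(fww)
    arable_share = rng.uniform(0.5, 0.9, size=ns)
    arable = agri * arable_share
    pasture = agri - arable
    q347 = np.exp(rng.normal(-1.2, 0.8, size=ns))
    q_ww = fww * q347

    # streams on a coarse grid, within-stream reaches co-linear ~200 m apart
    ncol = int(np.ceil(np.sqrt(ns)))
    bases = np.array([((i % ncol) * 10_000.0, (i // ncol) * 10_000.0) for i in range(ns)])
    bases += rng.uniform(-2000, 2000, size=bases.shape)
    theta = rng.uniform(0, 2 * np.pi, size=ns)

    effluent_strength = np.exp(rng.normal(0.0, 0.9, size=ns))
    chem_base = {v: np.exp(rng.normal(1.0, 0.3)) for v in CHEMISTRY_VARS}
    hab_base = {v: np.exp(rng.normal(0.5, 0.3)) for v in HABITAT_VARS}

    rows = []
    for i, s in enumerate(streams):
        stream_chem = rng.normal(0.0, 0.4, size=len(CHEMISTRY_VARS))
        effluent_var = effluent_strength[i] * np.exp(
            rng.normal(0.0, 0.4, size=len(CHEMISTRY_VARS))
        )
        stream_hab = rng.normal(0.0, 0.25, size=len(HABITAT_VARS))
        for j, pos in enumerate(_POSITIONS):
            offset = (-400.0 + 200.0 * j)
            rec = {
                "stream": s,
                "position": pos,
                "x": bases[i, 0] + offset * np.cos(theta[i]),
                "y": bases[i, 1] + offset * np.sin(theta[i]),
                "agriculture": agri[i],
                "arable": arable[i],
                "pasture": pasture[i],
                "q347": q347[i],
                "q_ww": q_ww[i],
                "ww_fraction": fww[i],
            }
            is_d = pos == "D"
            for v_i, v in enumerate(CHEMISTRY_VARS):
                lv = (
                    np.log(chem_base[v])
                    + stream_chem[v_i]
                    + _AGRI_LOAD.get(v, 0.1) * agri[i]
                    + (_WW_LOAD[v] * fww[i] * effluent_var[v_i] if is_d else 0.0)
                    + rng.normal(0.0, 0.05)
                )
                rec[v] = np.exp(lv)
            for v_i, v in enumerate(HABITAT_VARS):
                rec[v] = np.exp(
                    np.log(hab_base[v]) + stream_hab[v_i] + rng.normal(0.0, 0.08)
                )
            rows.append(rec)
    df = pd.DataFrame(rows, index=[f"{s}_{p}" for s in streams for p in _POSITIONS])
    df.index.name = "location"
    return df


# --------------------------------------------------------------------------
# expected composition model


def _tilt_root(fun, lo=-25.0, hi=25.0):
    """Root of a monotone function on [lo, hi]; clamp to the nearer bound if
    the target is unreachable."""
    flo, fhi = fun(lo), fun(hi)
    if flo == 0:
        return lo
    if fhi == 0:
        return hi
    if np.sign(flo) == np.sign(fhi):
        return lo if abs(flo) < abs(fhi) else hi
    return brentq(fun, lo, hi, xtol=1e-12)


def _compose(w_non_oligo, w_oligo, oligo_share, oligo_mask):
    shares = np.empty(oligo_mask.size)
    shares[oligo_mask] = oligo_share * w_oligo / w_oligo.sum()
    shares[~oligo_mask] = (1 - oligo_share) * w_non_oligo / w_non_oligo.sum()
    return shares


def _expected_shares(w, traits, si_target, spear_target, oligo_share, total):
    """Expected taxon shares hitting the oligochaete share exactly and the
    SI / SPEAR targets via exponential tilts (two rounds)."""
    oligo = traits["oligochaete"].to_numpy(bool)
    s = traits["saprobic_value"].to_numpy(float)
    spear_flag = traits["spear"].to_numpy(bool)
    w_o = w[oligo]
    w_no = w[~oligo].copy()
    s_no = s[~oligo]
    spear_no = spear_flag[~oligo]

    for _ in range(2):
        if si_target is not None:

            def si_gap(theta):
                wt = w_no * np.exp(theta * (s_no - 2.0))
                shares = _compose(wt, w_o, oligo_share, oligo)
                return indices.saprobic_index(shares * total, traits) - si_target

            w_no *= np.exp(_tilt_root(si_gap) * (s_no - 2.0))
            w_no /= w_no.max()

        def spear_gap(phi):
            wt = w_no * np.exp(phi * spear_no)
            shares = _compose(wt, w_o, oligo_share, oligo)
            return indices.spear_index(shares * total, traits) - spear_target

        w_no *= np.exp(_tilt_root(spear_gap) * spear_no)
        w_no /= w_no.max()

    return _compose(w_no, w_o, oligo_share, oligo)


def _stream_targets(params: GeneratorParams, sites: pd.DataFrame) -> pd.DataFrame:
    per = sites[sites["position"] == "U1"].set_index("stream")
    rng = _rng(params, 5)
    # between-stream scatter not explained by the land-use gradients
    si_u = (params.si_base + params.beta_si_agri * per["agriculture"]
            + rng.normal(0.0, params.si_scatter_sd, len(per)))
    spear_u = np.clip(
        params.spear_base + params.beta_spear_arable * per["arable"]
        + rng.normal(0.0, params.spear_scatter_sd, len(per)),
        5.0, 95.0,
    )
    oligo_u = np.clip(
        params.oligo_base + params.b_up_oligo * (si_u - params.si_ref), 0.01, 0.6
    )
    oligo_d = np.clip(
        params.oligo_base + params.oligo_boost
        + params.b_down_oligo * (si_u - params.si_ref),
        0.01, 0.8,
    )
    spear_d = np.clip(spear_u - params.gamma_spear_df * per["ww_fraction"], 1.0, 99.0)
    return pd.DataFrame({
        "si_u_target": si_u, "spear_u_target": spear_u,
        "oligo_u": oligo_u, "oligo_d": oligo_d, "spear_d_target": spear_d,
        "ww_fraction": per["ww_fraction"], "agriculture": per["agriculture"],
        "arable": per["arable"], "q347": per["q347"], "q_ww": per["q_ww"],
    })


def _stream_logweights(params: GeneratorParams, traits: pd.DataFrame,
                       n_streams: int) -> np.ndarray:
    """Per-stream log weights: regional baseline + stream heterogeneity +
    stream-level occupancy (each stream hosts a subset of the regional pool;
    a core of oligochaete, SPEAR and tolerant taxa is present everywhere)."""
    rng = _rng(params, 3)
    base = traits["baseline_logw"].to_numpy(float)
    lw = base[None, :] + rng.normal(0.0, params.stream_sd,
                                    size=(n_streams, len(traits)))
    present = rng.random(lw.shape) < params.occupancy
    core = np.zeros(len(traits), dtype=bool)
    for flag in ("oligochaete", "spear", "ept"):
        idx = np.flatnonzero(traits[flag].to_numpy(bool))[:4]
        core[idx] = True
    core[np.flatnonzero((~traits["spear"] & ~traits["oligochaete"]
                         & (traits["saprobic_value"] > 2.3)).to_numpy(bool))[:4]] = True
    present[:, core] = True
    return np.where(present, lw, -np.inf)


def _expected_composition(params: GeneratorParams, sites: pd.DataFrame,
                          traits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic expected shares for every location, plus stream targets."""
    targets = _stream_targets(params, sites)
    streams = list(targets.index)
    W = np.exp(_stream_logweights(params, traits, len(streams)))
    total = params.total_count_mean
    oligo = traits["oligochaete"].to_numpy(bool)

    spear_flag = traits["spear"].to_numpy(bool)

    # detection limit: taxa whose expected count falls below the threshold
    # are locally absent; the SPEAR tilt is re-solved on the reduced support
    # so the descriptor target survives the truncation
    def floor_shares(sh, spear_target, oligo_share):
        sp_no = spear_flag[~oligo]
        for _ in range(5):
            below = (sh > 0) & (sh * total < params.min_expected_count)
            if not below.any():
                break
            sh = np.where(below, 0.0, sh)
            sh = sh / sh.sum()
            w_no = sh[~oligo]

            def gap(phi):
                wt = w_no * np.exp(phi * sp_no)
                full = _compose(wt, sh[oligo], oligo_share, oligo)
                return indices.spear_index(full * total, traits) - spear_target

            w_t = w_no * np.exp(_tilt_root(gap) * sp_no)
            sh = _compose(w_t, sh[oligo], oligo_share, oligo)
        return sh

    rows, names = [], []
    for i, s in enumerate(streams):
        t = targets.loc[s]
        up = floor_shares(
            _expected_shares(W[i], traits, t["si_u_target"], t["spear_u_target"],
                             t["oligo_u"], total),
            t["spear_u_target"], t["oligo_u"],
        )
        # downstream: keep the upstream non-oligochaete profile, swap in the
        # downstream oligochaete share, re-tilt SPEAR only; SI is emergent
        w_no = up[~oligo]
        w_d = np.empty_like(up)
        w_d[~oligo] = w_no
        w_d[oligo] = up[oligo]
        down = floor_shares(
            _expected_shares(w_d, traits, None, t["spear_d_target"],
                             t["oligo_d"], total),
            t["spear_d_target"], t["oligo_d"],
        )
        for pos, shares in (("U2", up), ("U1", up), ("D", down)):
            rows.append(shares)
            names.append(f"{s}_{pos}")
    shares = pd.DataFrame(rows, index=names, columns=traits.index)
    return shares.loc[sites.index], targets


def generate_abundances(sites: pd.DataFrame, traits: pd.DataFrame,
                        params: GeneratorParams) -> pd.DataFrame:
    """Negative-binomial counts around the expected composition.

    Per taxon, counts are drawn with mean ``total_count_mean * share`` and
    dispersion ``params.dispersion`` (variance mu + mu^2/dispersion);
    ``dispersion=inf`` gives Poisson sampling.
    """
    if len(sites) != 3 * params.n_streams or len(traits) != params.n_taxa:
        raise ValueError("sites/traits tables are inconsistent with params")
    shares, _ = _expected_composition(params, sites, traits)
    rng = _rng(params, 4)
    mu = shares.to_numpy() * params.total_count_mean
    k = params.dispersion
    if np.isinf(k):
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=k, scale=np.maximum(mu, 1e-12) / k)
        counts = rng.poisson(lam)
    return pd.DataFrame(counts.astype(int), index=shares.index,
                        columns=shares.columns)


def ground_truth(params: GeneratorParams) -> GroundTruth:
    """Noiseless expectations consistent with :func:`generate_abundances`.

    Descriptor expectations are the descriptor functions applied to the
    expected (noise-free) compositions, so recovery tests compare like with
    like. The dominant predictor of the expected SPEAR change is the
    dilution/wastewater-fraction variable; the expected Saprobic change is
    driven by the upstream composition (saprobic state).
    """
    sites = generate_sites(params)
    traits = generate_traits(params)
    shares, targets = _expected_composition(params, sites, traits)
    total = params.total_count_mean
    oligo = traits["oligochaete"].to_numpy(bool)

    recs = {}
    for s in targets.index:
        up = shares.loc[f"{s}_U1"].to_numpy()
        down = shares.loc[f"{s}_D"].to_numpy()
        si_u = indices.saprobic_index(up * total, traits)
        si_d = indices.saprobic_index(down * total, traits)
        sp_u = indices.spear_index(up * total, traits)
        sp_d = indices.spear_index(down * total, traits)
        recs[s] = {
            "si_u": si_u, "si_d": si_d, "spear_u": sp_u, "spear_d": sp_d,
            # U1 and U2 expectations coincide, so Eq. 3 reduces to D - U1
            "delta_saprobic": si_d - si_u,
            "delta_spear": sp_d - sp_u,
            "oligo_share_u": up[oligo].sum(),
            "oligo_share_d": down[oligo].sum(),
            "ww_fraction": targets.loc[s, "ww_fraction"],
            "df_ww": targets.loc[s, "q347"] / targets.loc[s, "q_ww"],
            "agriculture": targets.loc[s, "agriculture"],
            "arable": targets.loc[s, "arable"],
        }
    streams = pd.DataFrame.from_dict(recs, orient="index")
    streams.index.name = "stream"
    return GroundTruth(
        streams=streams,
        expected_shares=shares,
        dominant_predictor={
            "delta_spear": "DF_ww",
            "delta_saprobic": "upstream_composition",
        },
    )


def simulate(params: GeneratorParams | None = None, outdir=None):
    """Generate the three tables (+ ground truth); optionally write CSVs.

    Returns ``(abundance, traits, sites, truth)``. With ``outdir`` the tables
    are written as ``abundance.csv``, ``traits.csv``, ``sites.csv``,
    ``ground_truth.csv`` and the parameters as ``params.yaml``.
    """
    params = params or GeneratorParams()
    traits = generate_traits(params)
    sites = generate_sites(params)
    abundance = generate_abundances(sites, traits, params)
    truth = ground_truth(params)
    if outdir is not None:
        import pathlib

        import yaml

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        abundance.to_csv(out / "abundance.csv")
        traits.to_csv(out / "traits.csv")
        sites.to_csv(out / "sites.csv")
        truth.streams.to_csv(out / "ground_truth.csv")
        snap = asdict(params)
        snap["agriculture_range"] = list(snap["agriculture_range"])
        snap["ww_fraction_range"] = list(snap["ww_fraction_range"])
        snap["spear_fraction_band"] = list(snap["spear_fraction_band"])
        (out / "params.yaml").write_text(yaml.safe_dump(snap, sort_keys=True))
    return abundance, traits, sites, truth
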