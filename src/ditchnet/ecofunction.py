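"""Biomass conversion, dissipation kinetics and the piecewise path model.

Counts become biomass through the aquatic-invertebrate allometry
``mass [mg] = 0.11 * length[mm] ** 1.79`` and feeding-preference trait
weights, giving per-ditch biomass of the functional feeding groups (FFG):
shredder, gatherer-collector, grazer, filter feeder, predator.  Insecticide
dissipation in water is fitted as first-order decay (DT50 = ln2/k,
DT90 = ln10/k).

The piecewise structural equation model (pSEM) encodes the a-priori causal
structure: the insecticide acts only on the feeding groups, and ecosystem
processes respond only to feeding-group biomass (plus the floating-algal-bed
cascade).  Component regressions are fitted separately (Gaussian with a
block random intercept when estimable, logistic for FLAB presence), paths
are reported as standardised coefficients, and the global structure is
evaluated by Shipley's d-separation test: each missing edge contributes an
independence claim, combined as Fisher's C = -2 sum(ln p) ~ chi-square with
2k degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .synth import FFG_GROUPS

__all__ = [
    "BiomassParams",
    "mass_from_length",
    "normalize_traits",
    "ffg_biomass",
    "DecayFit",
    "fit_decay",
    "ComponentFit",
    "fit_component",
    "standardize_paths",
    "DsepResult",
    "dsep_test",
    "PathModelResult",
    "run_psem",
    "PSEM_EDGES",
]


@dataclass(frozen=True)
class BiomassParams:
    """Length-mass allometry mass = a * length**b (mg, mm)."""

    a: float = 0.11
    b: float = 1.79

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("allometry parameters must be positive")


def mass_from_length(length_mm, params: BiomassParams = BiomassParams()):
    """Individual dry mass (mg) from body length (mm)."""
    length = np.asarray(length_mm, dtype=float)
    if np.any(length <= 0):
        raise ValueError("length must be positive")
    out = params.a * length**params.b
    return float(out) if np.isscalar(length_mm) else out


def normalize_traits(traits: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Long affinity scores -> per-taxon weights summing to one.

    ``traits`` has columns (taxon, group, affinity).  Raw scores are
    affinities (e.g. a 10-point scale), not fractions; taxa whose scores sum
    to zero cannot be assigned and are returned in the excluded list.
    """
    if np.any(traits["affinity"].to_numpy() < 0):
        raise ValueError("affinities must be non-negative")
    wide = (
        traits.pivot_table(index="taxon", columns="group", values="affinity", aggfunc="sum")
        .reindex(columns=list(FFG_GROUPS))
        .fillna(0.0)
    )
    totals = wide.sum(axis=1)
    excluded = list(wide.index[totals == 0])
    wide = wide.loc[totals > 0]
    weights = wide.div(wide.sum(axis=1), axis=0)
    return weights, excluded


def ffg_biomass(
    table,
    lengths: pd.DataFrame,
    traits: pd.DataFrame,
    period: str = "after",
    params: BiomassParams = BiomassParams(),
) -> pd.DataFrame:
    """Per-ditch biomass (mg per metre of ditch) by functional feeding group.

    biomass[ditch, group] = sum_s count * mass(length_s) * weight[s, group].
    Taxa without trait data are excluded (listed in ``.attrs['excluded']``);
    a missing length for a taxon with non-zero counts is an error.
    """
    counts = table.counts[table.meta["period"] == period]
    meta = table.meta[table.meta["period"] == period]
    length_map = lengths.set_index("taxon")["length_mm"]
    present = counts.columns[(counts.sum(axis=0) > 0)]
    missing = [t for t in present if t not in length_map.index]
    if missing:
        raise ValueError(f"missing length for taxa with non-zero counts: {missing[:5]}")
    weights, excluded = normalize_traits(traits)
    taxa = [t for t in counts.columns if t in weights.index and t in length_map.index]
    mass = mass_from_length(length_map.loc[taxa].to_numpy(), params)
    w = weights.loc[taxa].to_numpy()
    x = counts[taxa].to_numpy(dtype=float)
    biomass = (x * mass[None, :]) @ w
    out = pd.DataFrame(biomass, index=meta["ditch_id"].to_numpy(), columns=list(FFG_GROUPS))
    out.index.name = "ditch_id"
    out["shredder_plus_gc"] = out["shredder"] + out["gatherer_collector"]
    out.attrs["excluded"] = excluded
    return out


@dataclass
class DecayFit:
    """First-order dissipation fit: C(t) = c0 * exp(-k t)."""

    k: float
    c0: float
    dt50: float
    dt90: float
    r_squared: float
    no_decay: bool = False
    n_dropped: int = 0


def fit_decay(series: pd.DataFrame) -> DecayFit:
    """Least-squares fit of ln C against t.

    Non-positive concentrations are dropped (with a warning) before taking
    logs; a non-positive rate estimate is flagged ``no_decay``.
    """
    t = series["time_d"].to_numpy(dtype=float)
    c = series["conc_ugL"].to_numpy(dtype=float)
    keep = c > 0
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} non-positive concentrations", stacklevel=2)
    t, c = t[keep], c[keep]
    if len(c) < 3:
        raise ValueError("need at least three positive concentrations")
    res = stats.linregress(t, np.log(c))
    k = -res.slope
    no_decay = k <= 0
    return DecayFit(
        k=float(k),
        c0=float(np.exp(res.intercept)),
        dt50=float(np.log(2) / k) if not no_decay else np.inf,
        dt90=float(np.log(10) / k) if not no_decay else np.inf,
        r_squared=float(res.rvalue**2),
        no_decay=bool(no_decay),
        n_dropped=n_dropped,
    )


@dataclass
class ComponentFit:
    """One component regression of the piecewise model."""

    response: str
    predictors: list[str]
    family: str  # gaussian | binomial
    params: pd.Series
    pvalues: pd.Series
    bic: float
    random_intercept_used: bool = False
    separation: bool = False
    linear_predictor: np.ndarray | None = None


def fit_component(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    family: str = "gaussian",
    block: str | None = None,
) -> ComponentFit:
    """Fit one component model.

    Gaussian responses get a block random intercept (maximum likelihood)
    when ``block`` is given; if the variance component is estimated at the
    zero boundary or the fit fails, the model falls back to fixed block
    effects (the BIC reported is that of the fitted form).  Binomial
    responses (FLAB presence) are fitted by plain logistic regression;
    complete separation is flagged.
    """
    import statsmodels.api as sm

    x = sm.add_constant(data[predictors].astype(float), has_constant="add")
    y = data[response].astype(float)
    n = len(y)
    if family == "gaussian":
        if block is not None and data[block].nunique() >= 2:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    md = sm.MixedLM(y, x, groups=data[block])
                    mf = md.fit(reml=False, method="lbfgs")
                re_var = float(np.asarray(mf.cov_re).ravel()[0])
                if np.isfinite(mf.llf) and re_var > 1e-8 * max(float(mf.scale), 1e-12):
                    k_par = x.shape[1] + 2  # fixed effects + RE variance + residual
                    bic = -2 * mf.llf + k_par * np.log(n)
                    return ComponentFit(
                        response, list(predictors), family,
                        mf.params[x.columns], mf.pvalues[x.columns], float(bic),
                        random_intercept_used=True,
                        linear_predictor=np.asarray(x @ mf.params[x.columns]),
                    )
            except Exception:
                pass
        if block is not None and data[block].nunique() >= 2:
            xb = pd.concat([x, pd.get_dummies(data[block], prefix="blk", drop_first=True, dtype=float)], axis=1)
        else:
            xb = x
        of = sm.OLS(y, xb).fit()
        return ComponentFit(
            response, list(predictors), family,
            of.params[x.columns], of.pvalues[x.columns], float(of.bic),
            random_intercept_used=False,
            linear_predictor=np.asarray(x @ of.params[x.columns]),
        )
    elif family == "binomial":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lf = sm.Logit(y, x).fit(method="bfgs", maxiter=500, disp=0)
        from scipy.special import expit

        fitted = expit(np.asarray(x @ lf.params))
        perfect = np.all((fitted > 0.5) == (y.to_numpy() > 0.5)) and (
            np.min(np.abs(fitted - 0.5)) > 0.49
        )
        big = np.max(np.abs(lf.params[predictors].to_numpy())) > 10.0
        return ComponentFit(
            response, list(predictors), family,
            lf.params, lf.pvalues, float(lf.bic),
            separation=bool(perfect or big),
            linear_predictor=np.asarray(x @ lf.params),
        )
    raise ValueError(f"unknown family {family!r}")


def standardize_paths(fit: ComponentFit, data: pd.DataFrame) -> pd.Series:
    """Standardised coefficients beta * sd(x) / sd(y).

    For binomial responses the response scale is the latent logistic scale:
    sd(y*) = sqrt(var(linear predictor) + pi^2 / 3).
    """
    out = {}
    if fit.family == "gaussian":
        sd_y = float(np.std(data[fit.response].astype(float), ddof=1))
    else:
        if fit.linear_predictor is None:
            raise ValueError("binomial fit lacks a linear predictor")
        sd_y = float(np.sqrt(np.var(fit.linear_predictor, ddof=1) + np.pi**2 / 3.0))
    if sd_y == 0:
        raise ValueError("zero-variance response")
    for pred in fit.predictors:
        sd_x = float(np.std(data[pred].astype(float), ddof=1))
        if sd_x == 0:
            raise ValueError(f"zero-variance predictor {pred!r}")
        out[pred] = float(fit.params[pred]) * sd_x / sd_y
    return pd.Series(out, name="beta_std")


@dataclass
class DsepResult:
    claims: pd.DataFrame  # x, y, conditioning, p
    fisher_c: float
    df: int
    p_value: float

    @property
    def accepted(self) -> bool:
        return self.p_value > 0.05


def _independence_p(
    data: pd.DataFrame,
    x: str,
    y: str,
    conditioning: list[str],
    family: str,
    block: str | None,
) -> float:
    fit = fit_component(data, y, [x] + conditioning, family=family, block=block)
    return float(fit.pvalues[x])


def dsep_test(
    graph: nx.DiGraph,
    data: pd.DataFrame,
    families: dict[str, str] | None = None,
    block: str | None = None,
) -> DsepResult:
    """Shipley's d-separation test of an acyclic path diagram.

    The basis set holds one claim per non-adjacent variable pair,
    conditioned on the union of both variables' parents; each claim's p
    comes from the partial slope in the corresponding component regression
    (the descendant variable, or the topologically later one, is the
    response).  Fisher's C = -2 sum(ln p) is chi-square with 2k df under
    the model; large C (small global p) rejects the structure.
    """
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("path diagram must be acyclic")
    families = families or {}
    topo = list(nx.topological_sort(graph))
    order = {v: i for i, v in enumerate(topo)}
    nodes = topo
    claims = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            u, v = nodes[i], nodes[j]
            if graph.has_edge(u, v) or graph.has_edge(v, u):
                continue
            x, y = (u, v) if order[u] < order[v] else (v, u)
            cond = sorted(
                (set(graph.predecessors(x)) | set(graph.predecessors(y))) - {x, y}
            )
            fam = families.get(y, "gaussian")
            p = _independence_p(data, x, y, cond, fam, block)
            claims.append({"x": x, "y": y, "conditioning": ", ".join(cond), "p": p})
    if not claims:
        return DsepResult(pd.DataFrame(columns=["x", "y", "conditioning", "p"]), 0.0, 0, 1.0)
    df_claims = pd.DataFrame(claims)
    pvals = np.clip(df_claims["p"].to_numpy(dtype=float), 1e-300, 1.0)
    c = float(-2.0 * np.sum(np.log(pvals)))
    df = 2 * len(claims)
    return DsepResult(df_claims, c, df, float(stats.chi2.sf(c, df)))


# A-priori component structure: the insecticide touches only the feeding
# groups; processes respond to feeding-group biomass and the FLAB cascade.
PSEM_EDGES = [
    ("dose", "predator"),
    ("dose", "filter_feeder"),
    ("dose", "grazer"),
    ("dose", "shredder_plus_gc"),
    ("predator", "filter_feeder"),
    ("predator", "grazer"),
    ("predator", "shredder_plus_gc"),
    ("shredder_plus_gc", "OM_consumption"),
    ("shredder_plus_gc", "FLAB_presence"),
    ("shredder_plus_gc", "plant_growth"),
    ("grazer", "periphyton_growth"),
    ("FLAB_presence", "periphyton_growth"),
    ("filter_feeder", "phytoplankton_chlA"),
    ("FLAB_presence", "phytoplankton_chlA"),
]

_FAMILIES = {"FLAB_presence": "binomial"}


@dataclass
class PathModelResult:
    paths: pd.DataFrame  # response, predictor, beta, beta_std, p, family
    components: list[ComponentFit]
    dsep: DsepResult
    fisher_c: float
    df: int
    global_p: float
    bic: float

    @property
    def accepted(self) -> bool:
        return self.global_p > 0.05

    def path_lookup(self, predictor: str, response: str) -> pd.Series:
        m = (self.paths["predictor"] == predictor) & (self.paths["response"] == response)
        if not m.any():
            raise KeyError(f"no path {predictor} -> {response}")
        return self.paths[m].iloc[0]


def run_psem(
    ffg: pd.DataFrame,
    processes: pd.DataFrame,
    doses: pd.Series,
    blocks: pd.Series | None = None,
    edges: list[tuple[str, str]] | None = None,
    run_dsep: bool = True,
) -> PathModelResult:
    """Fit the full piecewise path model on the per-ditch tables.

    ``ffg`` is the FFG biomass table (index ditch), ``processes`` the
    ecosystem-process table (same index), ``doses`` the insecticide dose per
    ditch, and ``blocks`` (optional) the block labels used as random
    intercepts in the Gaussian components.  Returns standardised paths,
    the d-separation basis set, Fisher's C and the summed component BIC.
    """
    edges = edges or PSEM_EDGES
    data = pd.concat(
        [
            ffg[["predator", "filter_feeder", "grazer", "shredder_plus_gc"]],
            processes[
                ["OM_consumption", "FLAB_presence", "periphyton_growth",
                 "phytoplankton_chlA", "plant_growth"]
            ],
        ],
        axis=1,
    )
    data["dose"] = pd.Series(doses).reindex(data.index).to_numpy(dtype=float)
    block_col = None
    if blocks is not None:
        data["block"] = pd.Series(blocks).reindex(data.index).to_numpy()
        block_col = "block"

    graph = nx.DiGraph(edges)
    responses = sorted({r for _, r in edges})
    components, rows = [], []
    for resp in responses:
        preds = sorted(p for p, r in edges if r == resp)
        fam = _FAMILIES.get(resp, "gaussian")
        fit = fit_component(data, resp, preds, family=fam, block=block_col)
        std = standardize_paths(fit, data)
        components.append(fit)
        for pred in preds:
            rows.append(
                {
                    "response": resp,
                    "predictor": pred,
                    "beta": float(fit.params[pred]),
                    "beta_std": float(std[pred]),
                    "p": float(fit.pvalues[pred]),
                    "family": fam,
                }
            )
    if run_dsep:
        dsep = dsep_test(graph, data, families=_FAMILIES, block=block_col)
    else:  # path estimation only (e.g. simulation studies of sign recovery)
        dsep = DsepResult(pd.DataFrame(columns=["x", "y", "conditioning", "p"]), np.nan, 0, np.nan)
    bic = float(sum(c.bic for c in components))
    paths = pd.DataFrame(rows)
    return PathModelResult(
        paths=paths,
        components=components,
        dsep=dsep,
        fisher_c=dsep.fisher_c,
        df=dsep.df,
        global_p=dsep.p_value,
        bic=bic,
    )
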