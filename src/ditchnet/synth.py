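"""Synthetic mesocosm experiment generator.

Emulates a replicated outdoor ditch experiment: 36 ditches in 9 randomised
blocks, each block holding one ditch per insecticide dose (0, 0.1, 1 and
10 ug/L), sampled once before and once after application.  Communities are
drawn from a latent-factor Gaussian copula with zero-inflated
negative-binomial marginals, so that the degree of inter-taxon rank
correlation ("statistical coherence") is a tunable, dose-dependent quantity
while per-taxon abundance distributions stay realistic overdispersed counts.

Dose acts twice:

* marginally, each non-release taxon's mean is multiplied by the logistic
  survival ``1 / (1 + (dose/ec50)**hill)``; "release" taxa (short generation
  times, e.g. water mites and cladocerans in the field) instead increase by
  ``1 + r * dose / (dose + ec50)``;
* structurally, every copula factor loading is attenuated by
  ``exp(-decoherence_rate * log10(1 + dose))``, eroding pairwise correlation
  without touching the marginals.

Counts are per metre of ditch (the field protocol samples a one-metre
compartment).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Design",
    "CommunityParams",
    "AbundanceTable",
    "ProcessParams",
    "FFG_GROUPS",
    "generate_design",
    "default_community_params",
    "sample_community",
    "apply_subsample_counting",
    "default_length_table",
    "default_trait_table",
    "generate_processes",
    "generate_decay_series",
]

PERIODS = ("before", "after")

FFG_GROUPS = (
    "shredder",
    "gatherer_collector",
    "grazer",
    "filter_feeder",
    "predator",
    "other",
)


@dataclass(frozen=True)
class Design:
    """Randomised complete block layout: one ditch per dose per block."""

    table: pd.DataFrame  # columns: ditch_id, block, treatment_ugL
    concentrations: tuple[float, ...]
    n_replicates: int
    n_blocks: int
    periods: tuple[str, ...] = PERIODS

    @property
    def n_ditches(self) -> int:
        return len(self.table)


def generate_design(
    seed: int,
    concentrations: tuple[float, ...] = (0.0, 0.1, 1.0, 10.0),
    n_replicates: int = 9,
) -> Design:
    """Lay out ``len(concentrations) * n_replicates`` ditches in complete blocks.

    Each of the ``n_replicates`` blocks contains exactly one ditch per dose;
    ditch identities are assigned to block x dose cells by seeded permutation,
    mimicking field randomisation.
    """
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be non-negative")
    if 0.0 not in concentrations:
        raise ValueError("concentrations must include the control (0)")
    rng = np.random.default_rng(seed)
    n_treat = len(concentrations)
    n_ditches = n_treat * n_replicates
    ditch_ids = [f"D{i + 1:02d}" for i in range(n_ditches)]
    order = rng.permutation(n_ditches)
    rows = []
    k = 0
    for b in range(n_replicates):
        doses = rng.permutation(np.asarray(concentrations, dtype=float))
        for dose in doses:
            rows.append(
                {
                    "ditch_id": ditch_ids[order[k]],
                    "block": f"B{b + 1}",
                    "treatment_ugL": float(dose),
                }
            )
            k += 1
    table = pd.DataFrame(rows).sort_values("ditch_id", ignore_index=True)
    return Design(
        table=table,
        concentrations=tuple(float(c) for c in concentrations),
        n_replicates=n_replicates,
        n_blocks=n_replicates,
    )


@dataclass(frozen=True)
class CommunityParams:
    """Per-taxon marginals plus the copula structure.

    ``loadings`` has one row per taxon; the row norm (at dose 0) sets how
    strongly the taxon follows the latent community factors.  Marginals are
    negative binomial with mean ``mu`` and dispersion ``dispersion`` (shape
    parameter; variance = mu + mu**2/dispersion), zero-inflated with
    structural-absence probability ``zero_prob``.
    """

    taxa: tuple[str, ...]
    mu: np.ndarray
    dispersion: np.ndarray
    zero_prob: np.ndarray
    loadings: np.ndarray  # (n_taxa, n_factors)
    ec50: np.ndarray
    hill: np.ndarray
    release: np.ndarray  # bool mask
    release_strength: float = 0.5
    decoherence_rate: float = 2.0

    def __post_init__(self):
        for name in ("mu", "dispersion", "zero_prob", "loadings", "ec50", "hill"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        if np.any(self.mu <= 0):
            raise ValueError("mu must be positive")
        if np.any((self.zero_prob < 0) | (self.zero_prob >= 1)):
            raise ValueError("zero_prob must lie in [0, 1)")
        if np.any(self.ec50 <= 0):
            raise ValueError("ec50 must be positive")
        norms = np.linalg.norm(self.loadings, axis=1)
        if np.any(norms > 1.0 + 1e-12):
            raise ValueError("loading row norms must not exceed 1")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def with_(self, **kw) -> "CommunityParams":
        return replace(self, **kw)


def default_community_params(
    n_taxa: int = 85,
    n_latent_factors: int = 3,
    loading_scale: float = 0.85,
    decoherence_rate: float = 2.0,
    seed: int = 1234,
) -> CommunityParams:
    """Default ~85-taxon pool calibrated to the study's control condition.

    Targets roughly 1000 individuals and 30 observed taxa per control ditch:
    a geometric-like rank-abundance series for the means, structural-absence
    probability rising with rarity, and a block copula in which each taxon
    loads on a single latent factor (sign random) so coherent sub-guilds form.
    ec50 values spread log-normally around 2 ug/L; roughly one taxon in ten
    is a "release" taxon whose abundance increases with dose.
    """
    rng = np.random.default_rng(seed)
    taxa = tuple(f"taxon_{i + 1:03d}" for i in range(n_taxa))
    rank = np.arange(n_taxa)

    # Rank-abundance: geometric decay, scaled below to the target total.
    w = np.exp(-0.09 * rank)
    zero_prob = np.clip(0.10 + 0.85 * (rank / (n_taxa - 1)) ** 0.8, 0.0, 0.97)
    dispersion = np.full(n_taxa, 1.5)

    target_total = 1000.0
    mu = w * (target_total / np.sum((1.0 - zero_prob) * w))

    factor = rng.integers(0, n_latent_factors, size=n_taxa)
    sign = rng.choice([-1.0, 1.0], size=n_taxa, p=[0.25, 0.75])
    loadings = np.zeros((n_taxa, n_latent_factors))
    loadings[np.arange(n_taxa), factor] = sign * loading_scale

    ec50 = np.exp(rng.normal(np.log(2.0), 0.8, size=n_taxa))
    hill = np.full(n_taxa, 1.0)
    release = rng.random(n_taxa) < 0.10

    return CommunityParams(
        taxa=taxa,
        mu=mu,
        dispersion=dispersion,
        zero_prob=zero_prob,
        loadings=loadings,
        ec50=ec50,
        hill=hill,
        release=release,
        decoherence_rate=decoherence_rate,
    )


@dataclass
class AbundanceTable:
    """Sample x taxon count matrix with per-sample metadata.

    ``counts`` is indexed by sample id (``<ditch>:<period>``); ``meta`` shares
    that index and carries ditch_id, block, treatment_ugL and period.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and meta must share an index")
        if self.meta.duplicated(["ditch_id", "period"]).any():
            raise ValueError("duplicate (ditch, period) rows")
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be non-negative integers")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, *, period: str | None = None, treatment: float | None = None) -> "AbundanceTable":
        mask = pd.Series(True, index=self.meta.index)
        if period is not None:
            mask &= self.meta["period"] == period
        if treatment is not None:
            mask &= np.isclose(self.meta["treatment_ugL"], treatment)
        return AbundanceTable(self.counts.loc[mask], self.meta.loc[mask])

    def to_long(self) -> pd.DataFrame:
        long = (
            self.counts.stack()
            .rename("count")
            .reset_index()
            .rename(columns={"level_0": "sample_id", "level_1": "taxon"})
        )
        meta = self.meta.reset_index().rename(columns={"index": "sample_id"})
        out = meta.merge(long, on="sample_id")
        return out[["ditch_id", "block", "treatment_ugL", "period", "taxon", "count"]]


def survival_fraction(dose: float, ec50: np.ndarray, hill: np.ndarray) -> np.ndarray:
    """Fraction of the control mean surviving at ``dose`` (logistic dose-response)."""
    if dose < 0:
        raise ValueError("negative dose")
    if dose == 0:
        return np.ones_like(ec50)
    return 1.0 / (1.0 + (dose / ec50) ** hill)


def dose_adjusted_means(params: CommunityParams, dose: float) -> np.ndarray:
    """Expected NB mean per taxon at a given dose (analytic, no sampling)."""
    surv = survival_fraction(dose, params.ec50, params.hill)
    mult = np.where(
        params.release,
        1.0 + params.release_strength * dose / (dose + params.ec50),
        surv,
    )
    return params.mu * mult


def _attenuated_loadings(params: CommunityParams, dose: float) -> np.ndarray:
    att = np.exp(-params.decoherence_rate * np.log10(1.0 + dose))
    return params.loadings * att


def _zinb_ppf(u: np.ndarray, pi: np.ndarray, mean: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Quantile function of the zero-inflated negative binomial.

    Structural zeros occupy the lower ``pi`` tail of the uniform, so copula
    correlation carries through presence/absence as well as abundance.
    """
    out = np.zeros(np.broadcast_shapes(u.shape, pi.shape), dtype=np.int64)
    active = u > pi
    if np.any(active):
        u2 = (u - pi) / (1.0 - pi)
        p = k / (k + mean)
        uu = np.broadcast_to(u2, out.shape)[active]
        kk = np.broadcast_to(k, out.shape)[active]
        pp = np.broadcast_to(p, out.shape)[active]
        out[active] = stats.nbinom.ppf(np.clip(uu, 0.0, 1.0 - 1e-15), kk, pp).astype(np.int64)
    return out


def _draw_latent(loadings: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n draws of the copula normal scores z = L f + eps, unit marginal variance."""
    n_taxa, n_fac = loadings.shape
    resid_sd = np.sqrt(np.clip(1.0 - np.sum(loadings**2, axis=1), 0.0, 1.0))
    f = rng.standard_normal((n, n_fac))
    eps = rng.standard_normal((n, n_taxa)) * resid_sd
    return f @ loadings.T + eps


def sample_community(params: CommunityParams, design: Design, seed: int) -> AbundanceTable:
    """Draw the full before/after experiment.

    The before period is sampled at dose 0 for every ditch; the after period
    at each ditch's assigned dose, with dose acting on both marginal means
    and factor loadings (see module docstring).
    """
    rng = np.random.default_rng(seed)
    frames, metas = [], []
    for period in design.periods:
        for dose in sorted(set(design.table["treatment_ugL"])):
            sub = design.table[np.isclose(design.table["treatment_ugL"], dose)]
            eff_dose = 0.0 if period == "before" else float(dose)
            means = dose_adjusted_means(params, eff_dose)
            lam = _attenuated_loadings(params, eff_dose)
            z = _draw_latent(lam, len(sub), rng)
            u = stats.norm.cdf(z)
            counts = _zinb_ppf(u, params.zero_prob, means, params.dispersion)
            idx = [f"{d}:{period}" for d in sub["ditch_id"]]
            frames.append(pd.DataFrame(counts, index=idx, columns=list(params.taxa)))
            metas.append(
                pd.DataFrame(
                    {
                        "ditch_id": sub["ditch_id"].to_numpy(),
                        "block": sub["block"].to_numpy(),
                        "treatment_ugL": sub["treatment_ugL"].to_numpy(),
                        "period": period,
                    },
                    index=idx,
                )
            )
    counts = pd.concat(frames).sort_index()
    meta = pd.concat(metas).sort_index()
    return AbundanceTable(counts, meta)


def apply_subsample_counting(
    table: AbundanceTable,
    threshold_n: int = 50,
    threshold_frac: float = 0.25,
    seed: int = 0,
) -> AbundanceTable:
    """Emulate subsample counting of highly abundant taxa.

    Field protocol: homogenised subsets of abundant taxa are counted until at
    least ``threshold_n`` individuals of the taxon or ``threshold_frac`` of
    the whole sample have been processed.  Here each triggered taxon's count
    is replaced by a hypergeometric draw from a subsample of fraction
    ``f = max(threshold_n / count, threshold_frac)`` of the whole sample,
    scaled back up and rounded half-up.  Taxa whose full count is reached
    before either trigger are left exact.
    """
    if threshold_n <= 0:
        raise ValueError("threshold_n must be positive")
    if not (0.0 < threshold_frac <= 1.0):
        raise ValueError("threshold_frac must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy().copy()
    totals = counts.sum(axis=1)
    for i in range(counts.shape[0]):
        total = int(totals[i])
        if total == 0:
            continue
        for j in range(counts.shape[1]):
            n_sj = int(counts[i, j])
            if n_sj == 0:
                continue
            f = max(threshold_n / n_sj, threshold_frac)
            if f >= 1.0:
                continue
            m = int(round(f * total))
            m = min(max(m, 1), total)
            x = rng.hypergeometric(n_sj, total - n_sj, m)
            counts[i, j] = int(np.floor(x / f + 0.5))
    return AbundanceTable(
        pd.DataFrame(counts, index=table.counts.index, columns=table.counts.columns),
        table.meta.copy(),
    )


def default_length_table(params: CommunityParams, seed: int = 77) -> pd.DataFrame:
    """Body lengths (mm) per taxon, log-normal around ~4 mm (macroinvertebrate range)."""
    rng = np.random.default_rng(seed)
    lengths = np.exp(rng.normal(np.log(4.0), 0.45, size=params.n_taxa))
    return pd.DataFrame({"taxon": list(params.taxa), "length_mm": np.round(lengths, 2)})


def default_trait_table(params: CommunityParams, seed: int = 78) -> pd.DataFrame:
    """Feeding-preference affinity scores (10-point scale) per taxon.

    Each taxon gets a primary feeding group (affinity 10) and, with
    probability 0.4, a secondary group (affinity 5), mirroring multi-modal
    trait databases.  Release taxa are assigned predator/other primaries so
    the dose-sensitive guilds stay the detritivore groups.
    """
    rng = np.random.default_rng(seed)
    consumer_groups = ["shredder", "gatherer_collector", "grazer", "filter_feeder"]
    probs = [0.22, 0.28, 0.2, 0.3]
    rows = []
    for i, taxon in enumerate(params.taxa):
        if params.release[i]:
            primary = rng.choice(["predator", "other"], p=[0.6, 0.4])
        else:
            primary = rng.choice(consumer_groups + ["predator"], p=[p * 0.85 for p in probs] + [0.15])
        affinities = dict.fromkeys(FFG_GROUPS, 0.0)
        affinities[primary] = 10.0
        if rng.random() < 0.4:
            secondary = rng.choice([g for g in FFG_GROUPS if g != primary])
            affinities[secondary] = 5.0
        for group, aff in affinities.items():
            if aff > 0:
                rows.append({"taxon": taxon, "group": group, "affinity": aff})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ProcessParams:
    """Coefficients of the causal process generator.

    Organic-matter consumption and plant growth rise with shredder +
    gatherer-collector (SGC) biomass; floating algal bed (FLAB) presence is
    Bernoulli with logit ``b0 - b1 * SGC / sgc_scale``; phytoplankton
    chlorophyll-A drops when FLAB is present; periphyton tracks grazer
    biomass.  ``sgc_scale``/``grazer_scale`` are reference biomasses (mg) so
    slopes are per control-level unit.
    """

    om_intercept: float = 2.0
    om_slope: float = 8.0  # OM units per scaled SGC
    flab_b0: float = 1.5
    flab_b1: float = 4.0
    flab_biomass_mean: float = 120.0
    phyto_base: float = 30.0
    phyto_flab_effect: float = 10.0
    peri_base: float = 5.0
    peri_slope: float = 10.0
    plant_base: float = 1.0
    plant_slope: float = 2.0
    sgc_scale: float | None = None  # default: mean SGC of the input table
    grazer_scale: float | None = None


def generate_processes(
    ffg_biomass: pd.DataFrame,
    noise_sd: float = 0.15,
    seed: int = 0,
    params: ProcessParams = ProcessParams(),
) -> pd.DataFrame:
    """Ecosystem-process measurements per ditch, driven by feeding-group biomass.

    ``ffg_biomass`` is indexed by ditch with at least ``shredder_plus_gc``
    and ``grazer`` columns (mg per metre of ditch).  Gaussian noise of
    standard deviation ``noise_sd`` (on the scale of each response's
    deterministic part) is added to the continuous responses; FLAB presence
    is exactly Bernoulli.
    """
    if noise_sd < 0:
        raise ValueError("negative noise_sd")
    if np.any(ffg_biomass[["shredder_plus_gc", "grazer"]].to_numpy() < 0):
        raise ValueError("biomasses must be non-negative")
    rng = np.random.default_rng(seed)
    sgc = ffg_biomass["shredder_plus_gc"].to_numpy(dtype=float)
    grazer = ffg_biomass["grazer"].to_numpy(dtype=float)
    n = len(sgc)
    s_ref = params.sgc_scale if params.sgc_scale is not None else max(sgc.mean(), 1e-9)
    g_ref = params.grazer_scale if params.grazer_scale is not None else max(grazer.mean(), 1e-9)
    sgc_z = sgc / s_ref
    grazer_z = grazer / g_ref

    def noisy(det: np.ndarray) -> np.ndarray:
        scale = noise_sd * max(np.abs(det).mean(), 1e-9)
        return np.clip(det + rng.normal(0.0, scale, size=n), 0.0, None)

    om = noisy(params.om_intercept + params.om_slope * sgc_z)
    logit_p = params.flab_b0 - params.flab_b1 * sgc_z
    p_flab = 1.0 / (1.0 + np.exp(-logit_p))
    flab_presence = (rng.random(n) < p_flab).astype(int)
    flab_biomass = flab_presence * rng.lognormal(
        np.log(params.flab_biomass_mean), 0.3, size=n
    )
    phyto = noisy(params.phyto_base - params.phyto_flab_effect * flab_presence)
    peri = noisy(params.peri_base + params.peri_slope * grazer_z)
    plant = noisy(params.plant_base + params.plant_slope * sgc_z)
    return pd.DataFrame(
        {
            "OM_consumption": om,
            "FLAB_presence": flab_presence,
            "FLAB_biomass": flab_biomass,
            "phytoplankton_chlA": phyto,
            "periphyton_growth": peri,
            "plant_growth": plant,
        },
        index=ffg_biomass.index,
    )


def generate_decay_series(
    c0: float,
    dt50: float,
    times: np.ndarray | list[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """First-order dissipation series C(t) = c0 * exp(-ln2/DT50 * t).

    Multiplicative log-normal noise with coefficient of variation
    ``noise_cv`` (mean-one, so the series stays unbiased on the
    concentration scale).
    """
    if c0 <= 0 or dt50 <= 0:
        raise ValueError("c0 and dt50 must be positive")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative times")
    k = np.log(2.0) / dt50
    conc = c0 * np.exp(-k * t)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log(1.0 + noise_cv**2))
        conc = conc * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=t.shape))
    return pd.DataFrame({"time_d": t, "conc_ugL": conc})
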