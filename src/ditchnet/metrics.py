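"""Community descriptors and multivariate tests.

Covers the before/after community comparisons of the mesocosm analysis:
richness and Shannon diversity, Bray-Curtis / Jaccard dissimilarity, a
sequential (type-I) multi-term PERMANOVA whose treatment x period
interaction is the before-after-control-impact (BACI) effect, homogeneity
of multivariate dispersion, randomised species accumulation curves, and a
block-adjusted one-way ANOVA for per-ditch metrics.

Permutation tests use the add-one estimator p = (1 + #{stat* >= stat}) /
(1 + n_perm) and can be restricted within strata (blocks) to respect the
randomised-block layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "richness",
    "shannon",
    "DissimilarityMatrix",
    "dissimilarity",
    "PermanovaResult",
    "permanova",
    "BetaDispersionResult",
    "beta_dispersion",
    "accumulation_curve",
    "TreatmentEffectResult",
    "treatment_effect_test",
]


def richness(sample_counts) -> int:
    """Number of taxa with a positive count."""
    x = np.asarray(sample_counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative counts")
    return int(np.sum(x > 0))


def shannon(sample_counts) -> float:
    """Shannon diversity H = -sum p ln p, in nats."""
    x = np.asarray(sample_counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative counts")
    total = x.sum()
    if total == 0:
        raise ValueError("Shannon diversity undefined for an all-zero sample")
    p = x[x > 0] / total
    return float(-np.sum(p * np.log(p)))


@dataclass
class DissimilarityMatrix:
    """Square symmetric pairwise dissimilarities in [0, 1].

    Pairs involving an all-zero sample are undefined; they are stored as NaN
    and listed in ``undefined_pairs``.
    """

    data: np.ndarray
    ids: list[str]
    method: str
    presence_absence: bool
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        d = self.data
        if d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise ValueError("shape/ids mismatch")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(d)
        if not np.array_equal(d[finite], d.T[finite.T]):
            raise ValueError("matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


def dissimilarity(table, method: str = "braycurtis", presence_absence: bool = False) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis or Jaccard dissimilarities between samples.

    ``table`` is an :class:`~ditchnet.synth.AbundanceTable` (or a wide
    DataFrame of counts).  Jaccard operates on presence/absence sets
    regardless of the flag; Bray-Curtis honours the flag.
    """
    counts = table.counts if hasattr(table, "counts") else table
    x = counts.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least two samples")
    ids = [str(i) for i in counts.index]
    if method not in ("braycurtis", "jaccard"):
        raise ValueError(f"unknown method {method!r}")
    if method == "jaccard":
        presence_absence = True
    if presence_absence:
        x = (x > 0).astype(float)
    if method == "jaccard":
        d = squareform(pdist(x.astype(bool), metric="jaccard"))
    else:
        d = squareform(pdist(x, metric="braycurtis"))
    zero = x.sum(axis=1) == 0
    undefined = set()
    for i in np.flatnonzero(zero):
        for j in range(len(ids)):
            if j != i:
                d[i, j] = d[j, i] = np.nan
                undefined.add((ids[min(i, j)], ids[max(i, j)]))
    undefined = sorted(undefined)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(d, ids, method, presence_absence, undefined)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _dummies(meta: pd.DataFrame, term: str) -> np.ndarray:
    """Full-rank-free dummy block for a main effect or a:b interaction."""
    if ":" in term:
        parts = term.split(":")
        combo = meta[parts[0]].astype(str)
        for p in parts[1:]:
            combo = combo + "\x00" + meta[p].astype(str)
        series = combo
    else:
        series = meta[term].astype(str)
    return pd.get_dummies(series, dtype=float).to_numpy()


def _proj(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projection onto col(x) and its rank."""
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    keep = diag > diag.max() * 1e-10 if diag.size else np.array([], bool)
    q = q[:, keep]
    return q @ q.T, q.shape[1]


@dataclass
class PermanovaResult:
    """Sequential multi-term PERMANOVA table (pseudo-F, R-squared, permutation p)."""

    table: pd.DataFrame  # index: terms + Residual + Total
    n_permutations: int
    strata: str | None


def permanova(
    dm: DissimilarityMatrix,
    metadata: pd.DataFrame,
    terms: tuple[str, ...] = ("treatment_ugL", "period", "treatment_ugL:period"),
    n_perm: int = 999,
    seed: int = 0,
    strata: str | None = "block",
) -> PermanovaResult:
    """Permutational multivariate ANOVA with sequential sums of squares.

    Partitions the Gower-centred distance matrix over ``terms`` in order
    (type-I, as ``adonis2`` does by default) and computes permutation
    p-values by shuffling samples, optionally only within the levels of the
    ``strata`` metadata column.
    """
    if not np.all(np.isfinite(dm.data)):
        raise ValueError("dissimilarity matrix contains undefined pairs")
    meta = metadata.loc[dm.ids] if not metadata.index.equals(pd.Index(dm.ids)) else metadata
    n = dm.n
    g = _gower_center(dm.data)
    ss_total = float(np.trace(g))

    ones = np.ones((n, 1))
    blocks = [_dummies(meta, t) for t in terms]
    for t, b in zip(terms, blocks):
        if b.shape[1] < 2:
            raise ValueError(f"term {t!r} is constant")
    cum_proj, cum_rank = [], []
    x = ones
    p0, r0 = _proj(x)
    for b in blocks:
        x = np.hstack([x, b])
        p, r = _proj(x)
        cum_proj.append(p)
        cum_rank.append(r)
    df_terms = [cum_rank[0] - r0] + [cum_rank[i] - cum_rank[i - 1] for i in range(1, len(terms))]
    if any(d == 0 for d in df_terms):
        raise ValueError("a term adds no degrees of freedom (aliased factor)")
    df_res = n - cum_rank[-1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    tol = 1e-12 * max(abs(ss_total), 1.0)

    def term_stats(gm: np.ndarray) -> tuple[np.ndarray, float]:
        tr = np.array([np.sum(p * gm) for p in cum_proj])
        ss = np.diff(np.concatenate([[0.0], tr]))
        ss_res = np.trace(gm) - tr[-1]
        if ss_res < tol:  # saturated fit: numerically zero residual
            ss_res = 0.0
            f = np.where(ss > tol, np.inf, 0.0)
        else:
            f = (ss / np.array(df_terms)) / (ss_res / df_res)
        return f, ss_res

    f_obs, ss_res = term_stats(g)
    ss_obs = np.diff(np.concatenate([[0.0], [np.sum(p * g) for p in cum_proj]]))

    rng = np.random.default_rng(seed)
    if strata is not None:
        strata_levels = meta[strata].to_numpy()
        groups = [np.flatnonzero(strata_levels == lev) for lev in np.unique(strata_levels)]
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        if strata is None:
            perm = rng.permutation(n)
        else:
            perm = np.arange(n)
            for idx in groups:
                perm[idx] = idx[rng.permutation(len(idx))]
        gp = g[np.ix_(perm, perm)]
        f_perm, _ = term_stats(gp)
        exceed += f_perm >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for i, t in enumerate(terms):
        rows.append(
            {"df": df_terms[i], "SS": ss_obs[i], "R2": ss_obs[i] / ss_total,
             "F": f_obs[i], "p": pvals[i]}
        )
    rows.append({"df": df_res, "SS": ss_res, "R2": ss_res / ss_total, "F": np.nan, "p": np.nan})
    rows.append({"df": n - 1, "SS": ss_total, "R2": 1.0, "F": np.nan, "p": np.nan})
    table = pd.DataFrame(rows, index=[*terms, "Residual", "Total"])
    return PermanovaResult(table=table, n_permutations=n_perm, strata=strata)


def _pcoa_coords(dm: DissimilarityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate axes split into real (lam>0) and imaginary (lam<0) parts."""
    g = _gower_center(dm.data)
    lam, vec = np.linalg.eigh(g)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    tol = np.abs(lam).max() * 1e-10 if lam.size else 0.0
    pos = lam > tol
    neg = lam < -tol
    real = vec[:, pos] * np.sqrt(lam[pos])
    imag = vec[:, neg] * np.sqrt(-lam[neg])
    return real, imag


@dataclass
class BetaDispersionResult:
    distances: pd.Series
    group_means: pd.Series
    f_statistic: float
    p_value: float
    n_permutations: int


def beta_dispersion(
    dm: DissimilarityMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> BetaDispersionResult:
    """Homogeneity of multivariate dispersion (betadisper-style).

    Samples are embedded by principal-coordinate analysis; each sample's
    distance to its group centroid is corrected for negative eigenvalues
    (squared real-axis distance minus squared imaginary-axis distance).  The
    one-way F statistic on those distances is tested by permuting group
    labels.
    """
    groups = np.asarray(pd.Series(groups, index=dm.ids).loc[dm.ids])
    levels, inv = np.unique(groups, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(inv)
    if np.any(counts < 2):
        raise ValueError("every group needs at least two samples")
    real, imag = _pcoa_coords(dm)

    def dists(assign: np.ndarray) -> np.ndarray:
        d2 = np.zeros(dm.n)
        for gidx in range(len(levels)):
            m = assign == gidx
            cr = real[m].mean(axis=0)
            ci = imag[m].mean(axis=0) if imag.shape[1] else np.zeros(0)
            d2[m] = np.sum((real[m] - cr) ** 2, axis=1)
            if imag.shape[1]:
                d2[m] -= np.sum((imag[m] - ci) ** 2, axis=1)
        return np.sqrt(np.clip(d2, 0.0, None))

    def anova_f(vals: np.ndarray, assign: np.ndarray) -> float:
        grand = vals.mean()
        ss_between = sum(
            np.sum(assign == gidx) * (vals[assign == gidx].mean() - grand) ** 2
            for gidx in range(len(levels))
        )
        ss_within = sum(
            np.sum((vals[assign == gidx] - vals[assign == gidx].mean()) ** 2)
            for gidx in range(len(levels))
        )
        df_b = len(levels) - 1
        df_w = len(vals) - len(levels)
        if ss_within <= 1e-300:
            return np.inf if ss_between > 1e-300 else 0.0
        return (ss_between / df_b) / (ss_within / df_w)

    d_obs = dists(inv)
    f_obs = anova_f(d_obs, inv)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(inv))
        # permute which sample carries which label; distances recomputed
        # from the permuted assignment (vegan permutes the distances-to-
        # centroid residuals; permuting labels is the equivalent exchange
        # under the null of equal dispersion)
        f_p = anova_f(d_obs[perm], inv)
        exceed += f_p >= f_obs
    p = (1 + exceed) / (1 + n_perm)
    distances = pd.Series(d_obs, index=dm.ids, name="dist_to_centroid")
    group_means = pd.Series(
        [d_obs[inv == gidx].mean() for gidx in range(len(levels))], index=levels
    )
    return BetaDispersionResult(distances, group_means, float(f_obs), float(p), n_perm)


def accumulation_curve(table, n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Randomised species accumulation curve.

    Mean cumulative number of unique taxa as samples are added in random
    order, averaged over ``n_perm`` orderings.  The final point is the
    gamma diversity of the pooled table.
    """
    counts = table.counts if hasattr(table, "counts") else table
    presence = (counts.to_numpy() > 0)
    n = presence.shape[0]
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    acc = np.zeros(n)
    for _ in range(n_perm):
        order = rng.permutation(n)
        seen = np.maximum.accumulate(presence[order], axis=0)
        acc += seen.sum(axis=1)
    return pd.DataFrame({"n_samples": np.arange(1, n + 1), "mean_taxa": acc / n_perm})


@dataclass
class TreatmentEffectResult:
    f_statistic: float
    p_value: float
    df_num: int
    df_den: int
    flag: str | None = None


def treatment_effect_test(values, metadata: pd.DataFrame) -> TreatmentEffectResult:
    """One-way ANOVA across doses with the block as an additive covariate.

    ``values`` is a per-ditch metric aligned with ``metadata`` (columns
    ``treatment_ugL`` and ``block``).  Returns the treatment F on the
    residual degrees of freedom after removing block; a zero-residual fit is
    flagged rather than reported as an F value.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = metadata.copy()
    df["y"] = np.asarray(values, dtype=float)
    if df["treatment_ugL"].nunique() < 2:
        raise ValueError("need at least two treatment levels")
    fit = smf.ols("y ~ C(treatment_ugL) + C(block)", data=df).fit()
    if fit.df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    if fit.ssr < 1e-12 * max(fit.centered_tss, 1.0):
        return TreatmentEffectResult(np.nan, np.nan, 0, int(fit.df_resid), flag="zero_residual_variance")
    anova = sm.stats.anova_lm(fit, typ=2)
    row = anova.loc["C(treatment_ugL)"]
    return TreatmentEffectResult(
        f_statistic=float(row["F"]),
        p_value=float(row["PR(>F)"]),
        df_num=int(row["df"]),
        df_den=int(fit.df_resid),
    )
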