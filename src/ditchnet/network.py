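"""Per-treatment Spearman co-occurrence networks.

For each dose the nine replicate ditches give, per pair of retained taxa, a
Spearman rank correlation; pairs above |rho| > 0.67 are "significant"
(two-sided p < 0.05 at n = 9 under the t approximation) and pairs above
|rho| > 0.80 are "strong".  Connectance expresses each count as a
percentage of the control treatment's potential (computable) pairs, so
losses of taxa and losses of correlation strength both register.

A taxon pair is *computable* only when both count vectors vary across the
replicates; constant vectors have no defined rank correlation and are
excluded from both counts and the potential-pair denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilteredCommunity",
    "SpearmanNetwork",
    "filter_rare",
    "spearman_matrix",
    "critical_rho",
    "count_correlations",
    "connectance",
    "network_summary",
    "export_edges",
    "round_half_up",
]

SIGNIFICANT_RHO = 0.67
STRONG_RHO = 0.80


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (report convention; numpy rounds half-even)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FilteredCommunity:
    """One treatment's replicate x taxon matrix after the rare-taxon filter."""

    treatment: float
    taxa: list[str]
    matrix: np.ndarray  # (n_replicates, n_taxa)
    removed: list[tuple[str, str]]  # (taxon, reason)
    replicate_ids: list[str]

    @property
    def n_replicates(self) -> int:
        return self.matrix.shape[0]


def filter_rare(table, treatment: float, min_total: int = 5, period: str = "after") -> FilteredCommunity:
    """Drop taxa with <= ``min_total`` individuals summed over the treatment's replicates.

    Rare taxa mostly generate spurious co-occurrences at n = 9; the default
    cutoff of 5 matches taxa occurring in at least about half the replicates.
    """
    sub = table.subset(period=period, treatment=treatment)
    if sub.counts.shape[0] == 0:
        raise ValueError(f"treatment {treatment} not present in table")
    totals = sub.counts.sum(axis=0)
    keep = totals > min_total
    removed = [
        (taxon, f"total {int(totals[taxon])} <= {min_total}")
        for taxon in sub.counts.columns[~keep]
    ]
    if not keep.any():
        raise ValueError("empty community: no taxon exceeds the rare-species cutoff")
    kept = sub.counts.loc[:, keep]
    return FilteredCommunity(
        treatment=float(treatment),
        taxa=list(kept.columns),
        matrix=kept.to_numpy(dtype=float),
        removed=removed,
        replicate_ids=list(kept.index),
    )


@dataclass
class SpearmanNetwork:
    """Spearman rho matrix over retained taxa plus the computability mask."""

    treatment: float
    taxa: list[str]
    rho: np.ndarray
    computable: np.ndarray  # bool, per pair; diagonal False

    @property
    def n_potential(self) -> int:
        iu = np.triu_indices(len(self.taxa), k=1)
        return int(self.computable[iu].sum())

    def pair_values(self) -> np.ndarray:
        """|rho| of computable unordered pairs."""
        iu = np.triu_indices(len(self.taxa), k=1)
        mask = self.computable[iu]
        return np.abs(self.rho[iu][mask])


def spearman_matrix(fc: FilteredCommunity) -> SpearmanNetwork:
    """Average-rank (midrank) Spearman correlations over the replicates.

    Pairs where either taxon is constant across replicates are flagged
    non-computable; their rho entries are NaN.
    """
    x = fc.matrix
    if x.shape[0] < 3:
        raise ValueError("need at least three replicates")
    n_taxa = x.shape[1]
    nonconst = np.ptp(x, axis=0) > 0
    rho = np.full((n_taxa, n_taxa), np.nan)
    if nonconst.sum() >= 2:
        sub_rho = stats.spearmanr(x[:, nonconst], axis=0).statistic
        sub_rho = np.atleast_2d(sub_rho)
        if sub_rho.shape == (1, 1):  # spearmanr collapses the 2-column case
            r = float(sub_rho[0, 0])
            sub_rho = np.array([[1.0, r], [r, 1.0]])
        idx = np.flatnonzero(nonconst)
        rho[np.ix_(idx, idx)] = sub_rho
    rho[np.diag_indices(n_taxa)] = 1.0
    computable = np.outer(nonconst, nonconst)
    np.fill_diagonal(computable, False)
    return SpearmanNetwork(fc.treatment, list(fc.taxa), rho, computable)


def critical_rho(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical |rho| from the t approximation with n - 2 df.

    Solves t = rho * sqrt((n-2)/(1-rho^2)) at the alpha/2 t quantile:
    rho_crit = t_crit / sqrt(n - 2 + t_crit^2).  At n = 9, alpha = 0.05
    this is 0.666... , i.e. the 0.67 threshold used for "significant"
    correlations.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


def count_correlations(net: SpearmanNetwork, threshold: float) -> int:
    """Computable unordered pairs with |rho| strictly above ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return int(np.sum(net.pair_values() > threshold))


def connectance(count: int, control_potential: int) -> float:
    """Correlations as a percent of the control's potential pairs (2 dp, half-up)."""
    if control_potential <= 0:
        raise ValueError("control_potential must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return round_half_up(100.0 * count / control_potential, 2)


def network_summary(
    table,
    thresholds: tuple[float, float] = (SIGNIFICANT_RHO, STRONG_RHO),
    min_total: int = 5,
    period: str = "after",
    control: float = 0.0,
) -> pd.DataFrame:
    """Per-treatment network report: counts, median R-squared, connectance.

    One row per dose: potential (computable) pairs, counts above both
    thresholds, median R-squared (= rho^2) of the significant pairs, and
    both connectance percentages relative to the control's potential pairs.
    """
    sig_thr, strong_thr = thresholds
    doses = sorted(set(table.meta.loc[table.meta["period"] == period, "treatment_ugL"]))
    if not any(np.isclose(d, control) for d in doses):
        raise ValueError("control treatment missing")
    nets = {}
    for dose in doses:
        fc = filter_rare(table, dose, min_total=min_total, period=period)
        nets[dose] = spearman_matrix(fc)
    control_potential = nets[control].n_potential
    rows = []
    for dose in doses:
        net = nets[dose]
        vals = net.pair_values()
        n_sig = int(np.sum(vals > sig_thr))
        n_strong = int(np.sum(vals > strong_thr))
        sig_vals = vals[vals > sig_thr]
        median_r2 = round_half_up(float(np.median(sig_vals**2)), 2) if n_sig else np.nan
        rows.append(
            {
                "treatment_ugL": dose,
                "n_potential": net.n_potential,
                "n_significant": n_sig,
                "n_strong": n_strong,
                "median_r2_significant": median_r2,
                "connectance_significant_pct": connectance(n_sig, control_potential),
                "connectance_strong_pct": connectance(n_strong, control_potential),
            }
        )
    return pd.DataFrame(rows)


def export_edges(net: SpearmanNetwork, threshold: float) -> pd.DataFrame:
    """Edge list (taxon_a, taxon_b, rho, rho2) above ``threshold``, lexicographic."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    rows = []
    n = len(net.taxa)
    for i in range(n):
        for j in range(i + 1, n):
            if net.computable[i, j] and abs(net.rho[i, j]) > threshold:
                a, b = sorted((net.taxa[i], net.taxa[j]))
                rows.append(
                    {"taxon_a": a, "taxon_b": b,
                     "rho": float(net.rho[i, j]), "rho2": float(net.rho[i, j] ** 2)}
                )
    out = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "rho2"])
    return out.sort_values(["taxon_a", "taxon_b"], ignore_index=True)
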