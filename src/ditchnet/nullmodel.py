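"""Zero-inflated-Poisson null ensemble for co-occurrence networks.

The null destroys all inter-taxon association while preserving each control
taxon's occurrence probability and the control's mean total abundance:
taxon ``s`` is absent with probability ``pi_s`` (its observed fraction of
zero replicates) and otherwise Poisson with mean ``lambda_s``, chosen by
moment matching so that ``(1 - pi_s) * lambda_s`` equals the taxon's mean
control count.  An ensemble of independently drawn communities (default
1000, each with the same nine-replicate geometry as an observed treatment)
yields, per correlation-strength threshold, the distribution of pair counts
an unstructured community would produce; observed networks are compared to
its median and 0.025-0.975 envelope and by a continuity-corrected 2x2
chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import FilteredCommunity, SIGNIFICANT_RHO, STRONG_RHO

__all__ = [
    "ZipParams",
    "NullEnsemble",
    "default_threshold_grid",
    "fit_zip",
    "sample_null",
    "null_count_distribution",
    "batch_correlation_counts",
    "observed_counts_on_grid",
    "relative_curve",
    "chisq_vs_null",
    "coherence_verdict",
]


def default_threshold_grid() -> np.ndarray:
    """|rho| thresholds 0.50 ... 0.99 in steps of 0.01."""
    return np.round(np.arange(0.50, 0.995, 0.01), 2)


@dataclass(frozen=True)
class ZipParams:
    """Per-taxon zero-inflated Poisson parameters fitted to the control."""

    taxa: tuple[str, ...]
    pi: np.ndarray  # structural-absence probability
    lam: np.ndarray  # Poisson mean given occurrence
    mean_total: float  # control mean total abundance (calibration target)

    def __post_init__(self):
        if np.any((self.pi < 0) | (self.pi > 1)):
            raise ValueError("pi must lie in [0, 1]")
        if np.any(self.lam < 0):
            raise ValueError("lam must be non-negative")
        if abs(self.expected_total - self.mean_total) > 1e-6:
            raise ValueError("ZIP expectation does not match the control mean total")

    @property
    def expected_total(self) -> float:
        return float(np.sum((1.0 - self.pi) * self.lam))


def fit_zip(control_fc: FilteredCommunity, mode: str = "moment") -> ZipParams:
    """Fit the ZIP null to the control's filtered replicate matrix.

    ``moment`` (default): pi_s = observed zero fraction, lambda_s = mean
    count / (1 - pi_s), so both per-taxon and total expectations match the
    control.  ``uniform``: a single lambda shared by all taxa, scaled so
    only the mean *total* abundance matches (documented alternative; it
    discards relative-abundance structure).
    """
    x = control_fc.matrix
    if x.size == 0:
        raise ValueError("empty community")
    n_reps = x.shape[0]
    pi = (x == 0).sum(axis=0) / n_reps
    means = x.mean(axis=0)
    mean_total = float(x.sum(axis=1).mean())
    if mode == "moment":
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.where(pi < 1.0, means / (1.0 - pi), 0.0)
    elif mode == "uniform":
        occ = np.sum(1.0 - pi)
        if occ == 0:
            raise ValueError("all taxa always absent")
        lam = np.full(x.shape[1], mean_total / occ)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ZipParams(tuple(control_fc.taxa), pi, lam, mean_total)


def sample_null(
    params: ZipParams,
    n_reps: int = 9,
    n_communities: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Independent ZIP draws, shape (n_communities, n_reps, n_taxa)."""
    rng = np.random.default_rng(seed)
    shape = (n_communities, n_reps, len(params.taxa))
    present = rng.random(shape) >= params.pi
    counts = rng.poisson(params.lam, size=shape)
    return np.where(present, counts, 0)


def _rank_columns(x: np.ndarray) -> np.ndarray:
    """Average (mid) ranks down axis 0, vectorised over columns."""
    return stats.rankdata(x, method="average", axis=0)


def batch_correlation_counts(
    communities: np.ndarray, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per community: computable-pair count and |rho|>threshold counts.

    ``communities`` has shape (n_communities, n_reps, n_taxa).  Returns
    ``(potential, counts)`` with shapes (n_communities,) and
    (n_communities, len(grid)).  Spearman rho is computed as Pearson on
    midranks; constant taxa are dropped per community.
    """
    n_comm = communities.shape[0]
    counts = np.zeros((n_comm, len(grid)), dtype=int)
    potential = np.zeros(n_comm, dtype=int)
    for c in range(n_comm):
        x = communities[c]
        nonconst = np.ptp(x, axis=0) > 0
        m = int(nonconst.sum())
        potential[c] = m * (m - 1) // 2
        if m < 2:
            continue
        r = _rank_columns(x[:, nonconst].astype(float))
        rho = np.corrcoef(r, rowvar=False)
        iu = np.triu_indices(m, k=1)
        vals = np.abs(rho[iu])
        counts[c] = np.sum(vals[:, None] > grid[None, :], axis=0)
    return potential, counts


@dataclass
class NullEnsemble:
    """Distribution of null correlation counts over a threshold grid."""

    grid: np.ndarray
    counts: np.ndarray  # (n_communities, n_thresholds)
    potential: np.ndarray  # (n_communities,)

    def __post_init__(self):
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("threshold grid must be strictly increasing")

    @property
    def n_communities(self) -> int:
        return self.counts.shape[0]

    @property
    def median(self) -> np.ndarray:
        return np.median(self.counts, axis=0)

    @property
    def q025(self) -> np.ndarray:
        return np.quantile(self.counts, 0.025, axis=0)

    @property
    def q975(self) -> np.ndarray:
        return np.quantile(self.counts, 0.975, axis=0)

    @property
    def median_potential(self) -> float:
        return float(np.median(self.potential))

    def at_threshold(self, threshold: float) -> dict:
        i = int(np.argmin(np.abs(self.grid - threshold)))
        if abs(self.grid[i] - threshold) > 1e-9:
            raise ValueError(f"threshold {threshold} not on grid")
        return {
            "threshold": float(self.grid[i]),
            "median": float(self.median[i]),
            "q025": float(self.q025[i]),
            "q975": float(self.q975[i]),
        }

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.grid,
                "median": self.median,
                "q025": self.q025,
                "q975": self.q975,
            }
        )


def null_count_distribution(
    communities: np.ndarray, threshold_grid: np.ndarray | None = None
) -> NullEnsemble:
    """Count |rho|>threshold pairs for every null community on the grid."""
    grid = default_threshold_grid() if threshold_grid is None else np.asarray(threshold_grid)
    potential, counts = batch_correlation_counts(communities, grid)
    return NullEnsemble(grid=grid, counts=counts, potential=potential)


def observed_counts_on_grid(net, grid: np.ndarray | None = None) -> np.ndarray:
    """Observed |rho|>threshold counts of a SpearmanNetwork on a grid."""
    grid = default_threshold_grid() if grid is None else np.asarray(grid)
    vals = net.pair_values()
    return np.sum(vals[:, None] > grid[None, :], axis=0)


def relative_curve(
    observed_counts: np.ndarray,
    ensemble: NullEnsemble,
    smooth_window: int = 5,
) -> pd.DataFrame:
    """Observed counts as a percent of the null median, per threshold.

    Adds a centred moving average (``relative_smooth``) and flags thresholds
    where the observed count leaves the 0.025-0.975 null envelope.
    Thresholds with a zero null median are masked (NaN percent).
    """
    obs = np.asarray(observed_counts, dtype=float)
    if obs.shape != ensemble.grid.shape:
        raise ValueError("observed counts not on the ensemble grid")
    med = ensemble.median
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(med > 0, 100.0 * obs / med, np.nan)
    smooth = pd.Series(rel).rolling(smooth_window, center=True, min_periods=1).mean().to_numpy()
    return pd.DataFrame(
        {
            "threshold": ensemble.grid,
            "observed": obs,
            "null_median": med,
            "q025": ensemble.q025,
            "q975": ensemble.q975,
            "relative_pct": rel,
            "relative_smooth_pct": smooth,
            "above_envelope": obs > ensemble.q975,
            "below_envelope": obs < ensemble.q025,
        }
    )


def chisq_vs_null(
    observed_count: int,
    n_potential: int,
    null_median_count: float,
    null_potential: float,
) -> tuple[float, float]:
    """Continuity-corrected Pearson chi-square on the 2x2 table
    {correlated, uncorrelated} x {observed, null-median}."""
    if min(observed_count, null_median_count) < 0 or min(n_potential, null_potential) <= 0:
        raise ValueError("counts must be non-negative and potentials positive")
    table = np.array(
        [
            [observed_count, n_potential - observed_count],
            [null_median_count, null_potential - null_median_count],
        ],
        dtype=float,
    )
    if np.any(table < 0):
        raise ValueError("count exceeds potential")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero-margin contingency table")
    res = stats.chi2_contingency(table, correction=True)
    return float(res.statistic), float(res.pvalue)


VERDICTS = ("coherent-above-null", "indistinguishable", "degraded-below-null")


def coherence_verdict(
    observed_net,
    ensemble: NullEnsemble,
    thresholds: tuple[float, float] = (SIGNIFICANT_RHO, STRONG_RHO),
    alpha: float = 0.05,
) -> dict[str, dict]:
    """Classify a network against the null, per threshold class.

    For each class ("significant" at 0.67, "strong" at 0.80): the verdict is
    coherent-above-null when the observed count exceeds the 0.975 null
    quantile with chi-square p < alpha, degraded-below-null when it falls
    under the 0.025 quantile with chi-square p < alpha, and otherwise
    indistinguishable.
    """
    out = {}
    names = ("significant", "strong")
    for name, thr in zip(names, thresholds):
        env = ensemble.at_threshold(thr)
        vals = observed_net.pair_values()
        obs = int(np.sum(vals > thr))
        chi2, p = chisq_vs_null(
            obs, observed_net.n_potential, env["median"], ensemble.median_potential
        )
        if obs > env["q975"] and p < alpha:
            verdict = "coherent-above-null"
        elif obs < env["q025"] and p < alpha:
            verdict = "degraded-below-null"
        else:
            verdict = "indistinguishable"
        out[name] = {
            "threshold": thr,
            "observed": obs,
            "null_median": env["median"],
            "q025": env["q025"],
            "q975": env["q975"],
            "chi2": chi2,
            "p": p,
            "verdict": verdict,
        }
    return out
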