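"""M/M/inf birth-death model of entity-population dynamics.

With formations arriving as a Poisson stream at rate ``lambda_f`` and
each entity destroyed independently at rate ``lambda_d``, the entity
count is an M/M/inf queue. Its stationary law is closed-form:

* mean count  N = lambda_f / lambda_d  (the offered load rho);
* count distribution  P_n = rho^n e^(-rho) / n!  (Poisson).

Beyond the stationary predictions, the module estimates the empirical
birth-death transition matrix from a running count and analyses its
eigenvalue spectrum: the second largest eigenvalue modulus (SLEM) and
the spectral gap ``1 - SLEM``, identified with the mixing rate — the
speed at which the count chain approaches its quasi-stationary
distribution. Scaling both rates down at fixed rho leaves the mean
count unchanged but shrinks the gap (continuous-time eigenvalues are
``-k lambda_d``), the mechanism by which slowed rate constants are
associated with spontaneous termination of fibrillation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import (
    BDSpectrum,
    EventTable,
    MMInfPrediction,
    ParameterError,
    PopulationSeries,
    RateFit,
)

__all__ = [
    "predict_mean",
    "predict_pmf",
    "population_series",
    "ComparisonReport",
    "compare_to_observed",
    "predicted_observed_correlation",
    "estimate_bd_matrix",
    "analytic_generator",
    "generator_stationary",
    "GroupContrast",
    "termination_contrast",
]


def predict_mean(lambda_f: float, lambda_d: float) -> float:
    """Steady-state mean entity count N = lambda_f / lambda_d."""
    if lambda_d <= 0:
        raise ParameterError("lambda_d must be > 0")
    if lambda_f < 0:
        raise ParameterError("lambda_f must be >= 0")
    return lambda_f / lambda_d


def predict_pmf(lambda_f: float, lambda_d: float, n_max: int = 50) -> MMInfPrediction:
    """Stationary count distribution: Poisson(rho) truncated at n_max."""
    if n_max < 1:
        raise ParameterError("n_max must be >= 1")
    rho = predict_mean(lambda_f, lambda_d)
    pmf = stats.poisson.pmf(np.arange(n_max + 1), rho)
    return MMInfPrediction(rho=rho, pmf=pmf)


def population_series(events: EventTable, dt_ms: float = 1.0,
                      epoch_ms: float | None = None,
                      kind: str | None = None) -> PopulationSeries:
    """Concurrent entity count per frame (the running count).

    ``counts[t]`` is the number of entities with
    ``onset <= t * dt < offset`` (half-open convention).
    """
    if dt_ms <= 0:
        raise ParameterError("dt_ms must be > 0")
    if epoch_ms is None:
        epoch_ms = events.epoch_ms
    df = events.records
    if kind is not None:
        df = df[df["kind"] == kind]
    n_frames = int(np.ceil(epoch_ms / dt_ms))
    delta = np.zeros(n_frames + 1, dtype=int)
    starts = np.ceil(df["onset_ms"].to_numpy() / dt_ms).astype(int)
    stops = np.ceil(df["offset_ms"].to_numpy() / dt_ms).astype(int)
    starts = np.clip(starts, 0, n_frames)
    stops = np.clip(stops, 0, n_frames)
    np.add.at(delta, starts, 1)
    np.add.at(delta, stops, -1)
    counts = np.cumsum(delta[:-1])
    series_kind = kind if kind is not None else (
        df["kind"].iloc[0] if len(df) else "PS")
    return PopulationSeries(counts, dt_ms=dt_ms, kind=series_kind)


@dataclass
class ComparisonReport:
    """Observed running count versus the M/M/inf stationary prediction."""

    observed_mean: float
    predicted_mean: float
    chi2_stat: float
    chi2_p: float
    n_frames_used: int
    n_bins: int
    stride: int = 1

    @property
    def mean_ratio(self) -> float:
        return self.observed_mean / self.predicted_mean if self.predicted_mean else np.inf

    def to_dict(self) -> dict:
        return {
            "observed_mean": self.observed_mean,
            "predicted_mean": self.predicted_mean,
            "chi2_stat": self.chi2_stat,
            "chi2_p": self.chi2_p,
            "n_frames_used": self.n_frames_used,
            "n_bins": self.n_bins,
            "stride": self.stride,
        }


def compare_to_observed(pred: MMInfPrediction, series: PopulationSeries,
                        stride: int = 1, min_expected: float = 5.0) -> ComparisonReport:
    """Chi-square comparison of the empirical count histogram with the
    predicted Poisson pmf.

    Consecutive frames of a running count are strongly autocorrelated
    (the count decorrelates on the 1/lambda_d timescale), which would
    inflate the chi-square statistic; pass ``stride`` to subsample the
    series to approximately independent snapshots. Histogram bins are
    pooled from the high-count tail down until every expected count is
    at least ``min_expected``.
    """
    counts = series.counts[::stride]
    if counts.size < 100:
        raise ParameterError("comparison needs at least 100 frames")
    if np.ptp(counts) == 0:
        raise ParameterError("degenerate (constant) count histogram")
    n_max = max(int(counts.max()), pred.n_max)
    observed = np.bincount(counts, minlength=n_max + 1).astype(float)
    pmf = stats.poisson.pmf(np.arange(n_max + 1), pred.rho)
    pmf[-1] += max(1.0 - pmf.sum(), 0.0)  # fold the tail into the last cell
    expected = pmf * counts.size
    obs_pool, exp_pool = _pool_bins(observed, expected, min_expected)
    stat = float(((obs_pool - exp_pool) ** 2 / exp_pool).sum())
    dof = max(len(obs_pool) - 1, 1)
    p = float(stats.chi2.sf(stat, dof))
    return ComparisonReport(
        observed_mean=float(counts.mean()), predicted_mean=pred.mean_n,
        chi2_stat=stat, chi2_p=p, n_frames_used=int(counts.size),
        n_bins=len(obs_pool), stride=stride)


def _pool_bins(observed: np.ndarray, expected: np.ndarray,
               min_expected: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge adjacent histogram cells until all expected counts >= threshold."""
    obs, exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs.append(acc_o)
            exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and obs:
        obs[-1] += acc_o
        exp[-1] += acc_e
    if len(obs) < 2:
        raise ParameterError("too few usable bins after pooling")
    return np.array(obs), np.array(exp)


def predicted_observed_correlation(predicted: np.ndarray,
                                   observed: np.ndarray) -> dict:
    """Pearson correlation of predicted vs. observed mean counts across
    epochs (the cross-epoch validation of the mean equation)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.size != observed.size or predicted.size < 3:
        raise ParameterError("need >= 3 paired epochs")
    r, p = stats.pearsonr(predicted, observed)
    return {"r": float(r), "r2": float(r * r), "p": float(p), "n": predicted.size}


def estimate_bd_matrix(series: PopulationSeries) -> BDSpectrum:
    """Empirical birth-death transition matrix and its spectrum.

    Transitions are counted between consecutive frames on the state
    space ``0 .. max(counts)`` (the maximum number of tracked states);
    rows are normalized to probabilities. States never visited get an
    absorbing self-loop and are flagged. The spectrum is reported as
    sorted eigenvalue moduli, with SLEM, spectral gap ``1 - SLEM`` and
    mixing rate (= gap at the series' frame interval).
    """
    counts = series.counts
    if counts.size < 2 or np.ptp(counts) == 0:
        raise ParameterError("degenerate chain: series must visit >= 2 states")
    n_max = int(counts.max())
    C = np.zeros((n_max + 1, n_max + 1))
    np.add.at(C, (counts[:-1], counts[1:]), 1.0)
    row_sums = C.sum(axis=1)
    unvisited = np.flatnonzero(row_sums == 0)
    P = np.zeros_like(C)
    visited = row_sums > 0
    P[visited] = C[visited] / row_sums[visited, None]
    P[unvisited, unvisited] = 1.0
    eig = np.linalg.eigvals(P)
    moduli = np.sort(np.abs(eig))[::-1]
    return BDSpectrum(states=np.arange(n_max + 1), matrix=P,
                      eigen_moduli=moduli, dt_ms=series.dt_ms,
                      unvisited_states=unvisited)


def analytic_generator(lambda_f: float, lambda_d: float, n_max: int) -> np.ndarray:
    """Truncated M/M/inf generator: up-rate lambda_f, down-rate n*lambda_d.

    The infinite-state generator has eigenvalues ``-k lambda_d`` for
    k = 0, 1, 2, ...; the truncation is faithful once
    ``n_max >= 10 rho``. Serves as the oracle for the empirical
    transition-matrix estimate (``P ~ I + Q dt``) and the spectral-gap
    limit ``gap -> lambda_d * dt``.
    """
    if n_max < 2:
        raise ParameterError("n_max must be >= 2")
    if lambda_d <= 0 or lambda_f < 0:
        raise ParameterError("need lambda_f >= 0 and lambda_d > 0")
    Q = np.zeros((n_max + 1, n_max + 1))
    for n in range(n_max + 1):
        if n < n_max:
            Q[n, n + 1] = lambda_f
        if n > 0:
            Q[n, n - 1] = n * lambda_d
        Q[n, n] = -Q[n].sum()
    return Q


def discretize_generator(Q: np.ndarray, dt_ms: float,
                         method: str = "expm") -> np.ndarray:
    """One-frame transition matrix of a continuous-time generator.

    ``"expm"`` gives the exact lag-``dt`` chain ``exp(Q dt)`` (always
    stochastic; eigenvalues ``e^(mu dt)``, so the spectral gap tends to
    ``lambda_d * dt`` as ``dt -> 0``). ``"euler"`` gives the first-order
    ``I + Q dt``, valid only while ``dt < 1 / max |Q_nn|`` — beyond that
    it has negative entries and a spurious modulus above 1.
    """
    if method == "expm":
        from scipy.linalg import expm

        return expm(Q * dt_ms)
    if method == "euler":
        return np.eye(Q.shape[0]) + Q * dt_ms
    raise ParameterError(f"unknown discretization {method!r}")


def generator_stationary(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a generator: solve pi Q = 0, sum pi = 1."""
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


@dataclass
class GroupContrast:
    """Between-group comparison of per-epoch summary metrics."""

    metrics: dict = field(default_factory=dict)
    alpha: float = 0.05

    def significant(self, name: str) -> bool:
        return self.metrics[name]["p"] < self.alpha

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "metrics": self.metrics}


def _mean_ci(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    m = float(np.mean(x))
    if len(x) < 2:
        return m, (np.nan, np.nan)
    half = stats.t.ppf(0.975, len(x) - 1) * stats.sem(x)
    return m, (m - half, m + half)


def termination_contrast(group_a: list[dict], group_b: list[dict],
                         labels: tuple[str, str] = ("a", "b"),
                         alpha: float = 0.05) -> GroupContrast:
    """Compare per-epoch metrics between two groups of epochs.

    Each epoch is a mapping with (a subset of) the keys ``lambda_f``,
    ``lambda_d``, ``slem``, ``spectral_gap``, ``mixing_rate``,
    ``mean_count``. Per metric: group means with 95% CIs and a
    two-sample test — Student's t when Shapiro–Wilk accepts normality
    in both groups, Mann–Whitney U otherwise.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ParameterError("need >= 2 epochs per group")
    keys = [k for k in ("lambda_f", "lambda_d", "mean_count", "slem",
                        "spectral_gap", "mixing_rate")
            if all(k in e for e in group_a + group_b)]
    out = GroupContrast(alpha=alpha)
    for k in keys:
        xa = np.array([float(e[k]) for e in group_a])
        xb = np.array([float(e[k]) for e in group_b])
        normal = True
        for x in (xa, xb):
            if len(x) >= 3 and np.ptp(x) > 0:
                if stats.shapiro(x).pvalue < alpha:
                    normal = False
            elif np.ptp(x) == 0:
                normal = False
        if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa[0] == xb[0]:
            test, stat, p = "degenerate", 0.0, 1.0
        elif normal:
            res = stats.ttest_ind(xa, xb)
            test, stat, p = "t", float(res.statistic), float(res.pvalue)
        else:
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            test, stat, p = "mannwhitney", float(res.statistic), float(res.pvalue)
        ma, ca = _mean_ci(xa)
        mb, cb = _mean_ci(xb)
        out.metrics[k] = {
            f"mean_{labels[0]}": ma, f"ci95_{labels[0]}": ca,
            f"mean_{labels[1]}": mb, f"ci95_{labels[1]}": cb,
            "test": test, "stat": stat, "p": p,
        }
    return out
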