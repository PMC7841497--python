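"""Optional figures: running count, count histogram vs. prediction,
eigenvalue stem plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .types import BDSpectrum, MMInfPrediction, PopulationSeries  # noqa: E402

__all__ = ["plot_running_count", "plot_histogram_vs_pmf", "plot_eigen_stem"]


def plot_running_count(series: PopulationSeries, predicted_mean: float | None = None,
                       path=None):
    fig, ax = plt.subplots(figsize=(7, 2.5))
    t = np.arange(len(series.counts)) * series.dt_ms / 1000.0
    ax.step(t, series.counts, lw=0.6, where="post")
    ax.axhline(series.mean, color="k", ls="--", lw=1, label=f"observed mean {series.mean:.2f}")
    if predicted_mean is not None:
        ax.axhline(predicted_mean, color="C3", ls=":", lw=1.2,
                   label=f"predicted mean {predicted_mean:.2f}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel(f"{series.kind} count")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_histogram_vs_pmf(series: PopulationSeries, pred: MMInfPrediction,
                          stride: int = 1, path=None):
    fig, ax = plt.subplots(figsize=(4, 3))
    counts = series.counts[::stride]
    n_max = max(int(counts.max()), pred.n_max)
    obs = np.bincount(counts, minlength=n_max + 1) / counts.size
    n = np.arange(n_max + 1)
    ax.bar(n, obs, width=0.8, alpha=0.5, label="observed")
    pmf = np.zeros(n_max + 1)
    pmf[: pred.n_max + 1] = pred.pmf
    ax.plot(n, pmf, "o-", ms=3, color="C3", label=f"Poisson(rho={pred.rho:.2f})")
    ax.set_xlabel("concurrent count n")
    ax.set_ylabel("probability")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_eigen_stem(spectrum: BDSpectrum, path=None):
    fig, ax = plt.subplots(figsize=(4, 3))
    m = spectrum.eigen_moduli
    ax.stem(np.arange(len(m)), m)
    ax.axhline(spectrum.slem, color="C3", ls="--", lw=1,
               label=f"SLEM {spectrum.slem:.4f}; gap {spectrum.spectral_gap:.4f}")
    ax.set_xlabel("eigenvalue rank")
    ax.set_ylabel("|eigenvalue|")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
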