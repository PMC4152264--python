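"""Quick-look figures for the standard observables.

Matplotlib is an optional dependency (``pip install crowdbd[plot]``); every
function takes an optional Axes and returns it, so figures compose.
"""

from __future__ import annotations

import numpy as np

from .analysis import CorrelationSeries, MSDResult, time_dependent_D

__all__ = ["plot_msd_loglog", "plot_time_dependent_D", "plot_correlation"]


def _ax(ax):
    if ax is None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_msd_loglog(msd: MSDResult, ax=None, label=None):
    """log-log MSD vs lag with slope-1 and slope-2 guide lines."""
    ax = _ax(ax)
    m = msd.lags > 0
    ax.loglog(msd.lags[m], msd.msd[m], label=label)
    t = msd.lags[m]
    ref = msd.msd[m][0]
    ax.loglog(t, ref * (t / t[0]), ls=":", c="gray", lw=0.8)
    ax.loglog(t, ref * (t / t[0]) ** 2, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("lag (ns)")
    ax.set_ylabel(r"MSD ($\mathrm{\AA}^2$)")
    if label:
        ax.legend()
    return ax


def plot_time_dependent_D(msd: MSDResult, ax=None, label=None):
    """D(tau) = MSD/6tau vs lag; a decay followed by a plateau marks the
    subdiffusive-to-normal crossover."""
    ax = _ax(ax)
    lags, d = time_dependent_D(msd)
    ax.semilogx(lags, d * 10.0, label=label)  # µm²/s
    ax.set_xlabel("lag (ns)")
    ax.set_ylabel(r"D ($\mathrm{\mu m^2/s}$)")
    if label:
        ax.legend()
    return ax


def plot_correlation(corr: CorrelationSeries, ax=None, label=None, normalized=True):
    """Displacement autocorrelation C_delta(t); the dip below zero near
    t = delta is the FBM subdiffusion signature."""
    ax = _ax(ax)
    y = corr.normalized if normalized else corr.raw
    ax.plot(corr.t, y, label=label)
    ax.axhline(0.0, c="gray", lw=0.8)
    ax.axvline(corr.delta, c="gray", lw=0.8, ls=":")
    ax.set_xlabel("t (ns)")
    ax.set_ylabel(r"$C_\delta(t)/C_\delta(0)$" if normalized else r"$C_\delta(t)$")
    if label:
        ax.legend()
    return ax
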