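"""Minimal plotting helpers: state densities, equilibrium curves, TS diagram."""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_state_distributions(results, path=None):
    """Per-stream state-dependent densities of the fitted dive states."""
    from scipy import stats as sps

    from .params import beta_ab, gamma_shape_rate

    plt = _plt()
    p = results.params
    names = results.spec.dive_state_names
    fig, axes = plt.subplots(1, 4, figsize=(14, 3))
    streams = ["duration (min)", "hunting depth (m)", "prop. hunting", "salinity (psu)"]
    for d, name in enumerate(names):
        k, r = gamma_shape_rate(p.duration_mean[2 + d], p.duration_sd[2 + d])
        x = np.linspace(1, p.duration_mean[2 + d] * 3, 300)
        axes[0].plot(x / 60, sps.gamma.pdf(x, k, scale=1 / r) * 60, label=name)
        kz, rz = gamma_shape_rate(p.depth_mean[d], p.depth_sd[d])
        x = np.linspace(0.5, p.depth_mean[d] * 2.5, 300)
        axes[1].plot(x, sps.gamma.pdf(x, kz, scale=1 / rz), label=name)
        a, b = beta_ab(p.hunt_mean[d], p.hunt_precision[d])
        x = np.linspace(0.001, 0.999, 300)
        axes[2].plot(x, sps.beta.pdf(x, a, b), label=name)
        x = np.linspace(p.salinity_mean.min() - 0.3, p.salinity_mean.max() + 0.3, 300)
        axes[3].plot(
            x, sps.norm.pdf(x, p.salinity_mean[d], p.salinity_sd[d]), label=name
        )
    for ax, lab in zip(axes, streams):
        ax.set_xlabel(lab)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_equilibrium(curve, path=None):
    """Equilibrium probability vs hour, one row per week, one column per state."""
    plt = _plt()
    W, H, N = curve.probs.shape
    fig, axes = plt.subplots(W, N, figsize=(2.2 * N, 1.8 * W), sharex=True, sharey=True)
    axes = np.atleast_2d(axes)
    for wi in range(W):
        for si in range(N):
            ax = axes[wi, si]
            ax.plot(curve.hours, curve.probs[wi, :, si], lw=1.2)
            if np.isfinite(curve.lower[wi, :, si]).any():
                ax.fill_between(
                    curve.hours,
                    curve.lower[wi, :, si],
                    curve.upper[wi, :, si],
                    alpha=0.3,
                    color="grey",
                )
            if wi == 0:
                ax.set_title(curve.state_names[si], fontsize=8)
            if si == 0:
                ax.set_ylabel(f"week {curve.weeks[wi]:.0f}", fontsize=8)
    axes[-1, 0].set_xlabel("local hour")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_ts(ts_table, path=None):
    """Temperature-salinity scatter coloured by decoded state."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 4))
    for state, grp in ts_table.groupby("state"):
        ax.scatter(grp["salinity_psu"], grp["temperature_C"], s=4, label=state)
    ax.set_xlabel("salinity (psu)")
    ax.set_ylabel("temperature (°C)")
    ax.legend(fontsize=8, markerscale=2)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
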