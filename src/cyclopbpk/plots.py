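"""Agreement and residual plots.

Scatter of predicted vs observed troughs in log and linear scale with the
twofold (light grey) and threefold (dark grey) agreement bands shaded, and
residua stratified by body-weight-normalized dose or by patient.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .tdm import TWOFOLD_BAND, THREEFOLD_BAND, stratify  # noqa: E402

__all__ = ["scatter_pred_obs", "residua_stratified", "profile_plot"]


def _band(ax, x, k_inner=2.0, k_outer=3.0):
    x = np.asarray(x)
    ax.fill_between(x, x / k_outer, x * k_outer, color="0.55", alpha=0.35, lw=0)
    ax.fill_between(x, x / k_inner, x * k_inner, color="0.8", alpha=0.6, lw=0)
    ax.plot(x, x, "k-", lw=0.8)
    ax.plot(x, x * k_inner, "k--", lw=0.6)
    ax.plot(x, x / k_inner, "k--", lw=0.6)
    ax.plot(x, x * k_outer, "k:", lw=0.6)
    ax.plot(x, x / k_outer, "k:", lw=0.6)


def scatter_pred_obs(pairs, path=None):
    """Predicted vs observed trough scatter (log and linear panels)."""
    obs = np.array([p.c0_obs for p in pairs])
    pred = np.array([p.c0_pred for p in pairs])
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
    lo = max(min(obs.min(), pred.min()) * 0.5, 1e-2)
    hi = max(obs.max(), pred.max()) * 1.5
    for ax, scale in zip(axes, ("log", "linear")):
        xs = np.geomspace(lo, hi, 200) if scale == "log" else np.linspace(0, hi, 200)
        _band(ax, xs)
        ax.plot(obs, pred, "o", ms=4, mfc="C0", mec="k", mew=0.3, alpha=0.8)
        ax.set_xscale(scale)
        ax.set_yscale(scale)
        if scale == "log":
            ax.set_xlim(lo, hi)
            ax.set_ylim(lo, hi)
        else:
            ax.set_xlim(0, hi)
            ax.set_ylim(0, hi)
        ax.set_xlabel("observed trough (ng/ml)")
        ax.set_ylabel("predicted trough (ng/ml)")
        ax.set_title(f"{scale} scale")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def residua_stratified(pairs, by: str, path=None, bw_dose_bin_width: float = 0.25):
    """Residuum distribution per stratum with twofold/threefold bands."""
    groups = stratify(pairs, by=by, bw_dose_bin_width=bw_dose_bin_width)
    fig, ax = plt.subplots(figsize=(max(6, 0.35 * len(groups)), 4.5))
    for band, color in ((THREEFOLD_BAND, "0.55"), (TWOFOLD_BAND, "0.8")):
        ax.axhspan(-band, band, color=color, alpha=0.4, lw=0)
    positions = np.arange(len(groups))
    for pos, residua in zip(positions, groups["residua"]):
        ax.plot(np.full(len(residua), pos), residua, "o", ms=3.5,
                mfc="C0", mec="k", mew=0.3, alpha=0.7)
    ax.plot(positions, groups["median_residuum"], "_", ms=14, color="C3", mew=2)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(positions)
    labels = [f"{s:g}" if isinstance(s, float) else str(s) for s in groups["stratum"]]
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_xlabel("BW-normalized dose bin (mg/kg)" if by == "bw_dose_bin" else "patient")
    ax.set_ylabel("residuum log10(pred/obs)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def profile_plot(result, path=None):
    """Venous whole-blood concentration-time curve of a simulation."""
    p = result.profile
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(p.time_h, p.conc_ng_ml, "-", color="C0")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("whole-blood concentration (ng/ml)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
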