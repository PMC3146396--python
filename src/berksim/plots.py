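"""Standard figures: significance loss, attenuation, sweep, 1:1 concordance."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_pvalues(att: pd.DataFrame, path: str | Path) -> None:
    """p-value (from mean z) versus population-weighted semivariance, by type."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for t, grp in att.dropna(subset=["gamma_bar"]).groupby("type"):
        g = grp.sort_values("gamma_bar")
        ax.plot(g["gamma_bar"], g["p"], "o-", label=f"type {t}")
    ax.set_yscale("log")
    ax.set_xlabel(r"population-weighted semivariance $\bar\gamma'$")
    ax.set_ylabel("p-value (from mean z)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_attenuation(att: pd.DataFrame, path: str | Path) -> None:
    """Percent attenuation per unit and per IQR versus semivariance, by type."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for ax, col, sd, title in (
        (axes[0], "att_unit_mean", "att_unit_sd", "per unit of measurement"),
        (axes[1], "att_iqr_mean", "att_iqr_sd", "per IQR"),
    ):
        for t, grp in att.dropna(subset=["gamma_bar"]).groupby("type"):
            g = grp.sort_values("gamma_bar")
            ax.errorbar(g["gamma_bar"], g[col], yerr=g[sd], fmt="o-", label=f"type {t}")
        ax.axhline(0, color="grey", lw=0.8)
        ax.set_xlabel(r"$\bar\gamma'$")
        ax.set_title(title)
    axes[0].set_ylabel("% attenuation in RR")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sweep(sweep: pd.DataFrame, path: str | Path) -> None:
    """Attenuation across the type B -> type C continuum at fixed error amount."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(
        sweep["s_ratio"], sweep["att_unit_mean"], yerr=sweep["att_unit_sd"],
        fmt="o-", label="per unit",
    )
    ax.errorbar(
        sweep["s_ratio"], sweep["att_iqr_mean"], yerr=sweep["att_iqr_sd"],
        fmt="s-", label="per IQR",
    )
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel(r"$\sigma_{\ln Z}/\sigma_{\ln Z^*}$ (B $\to$ C)")
    ax.set_ylabel("% attenuation in RR")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_predicted_observed(comparison: pd.DataFrame, path: str | Path) -> None:
    """Predicted versus observed attenuation with the 1:1 line."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, pre, obs, sd, title in (
        (axes[0], "predicted_unit", "observed_unit", "observed_unit_sd", "per unit"),
        (axes[1], "predicted_iqr", "observed_iqr", "observed_iqr_sd", "per IQR"),
    ):
        for t, grp in comparison.groupby("type"):
            ax.errorbar(grp[pre], grp[obs], yerr=grp[sd], fmt="o", label=f"type {t}")
        lims = ax.get_xlim()
        ax.plot(lims, lims, "k--", lw=0.8, label="1:1")
        ax.set_xlabel("predicted % attenuation")
        ax.set_ylabel("observed % attenuation")
        ax.set_title(title)
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
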