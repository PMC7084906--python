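"""Basic diagnostic figures (tables remain the canonical outputs)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_gof", "plot_vpc", "plot_profiles"]


def plot_gof(gof_table, path=None):
    """Observed-vs-predicted and CWRES panels."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(8, 7))
    for ax, col in zip(axes[0], ["PRED", "IPRED"]):
        ax.loglog(gof_table[col], gof_table["DV"], "o", ms=3, alpha=0.6)
        lim = [gof_table["DV"].min() * 0.5, gof_table["DV"].max() * 2]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel(f"{col} (ng/mL)")
        ax.set_ylabel("observed (ng/mL)")
    axes[1, 0].plot(gof_table["TIME"], gof_table["CWRES"], "o", ms=3, alpha=0.6)
    axes[1, 0].axhline(0, color="k", lw=1)
    axes[1, 0].set_xlabel("time (h)")
    axes[1, 0].set_ylabel("CWRES")
    axes[1, 1].semilogx(gof_table["PRED"], gof_table["CWRES"], "o", ms=3, alpha=0.6)
    axes[1, 1].axhline(0, color="k", lw=1)
    axes[1, 1].set_xlabel("PRED (ng/mL)")
    axes[1, 1].set_ylabel("CWRES")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_vpc(vpc_table, path=None):
    """Observed percentiles over simulated prediction bands, per group/analyte."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = vpc_table["GROUP"].unique()
    analytes = vpc_table["ANALYTE"].unique()
    fig, axes = plt.subplots(len(analytes), len(groups),
                             figsize=(3.2 * len(groups), 3.0 * len(analytes)),
                             squeeze=False)
    for i, a in enumerate(analytes):
        for j, g in enumerate(groups):
            sub = vpc_table[(vpc_table["GROUP"] == g)
                            & (vpc_table["ANALYTE"] == a)].sort_values("TIME")
            ax = axes[i][j]
            ax.fill_between(sub["TIME"], sub["band_lo"], sub["band_hi"],
                            alpha=0.2, color="grey", label="5th-95th simulated")
            ax.fill_between(sub["TIME"], sub["median_ci_lo"], sub["median_ci_hi"],
                            alpha=0.4, color="grey", label="95% CI of median")
            ax.plot(sub["TIME"], sub["obs_median"], "r-", lw=1.5, label="observed median")
            ax.plot(sub["TIME"], sub["obs_p5"], "r--", lw=1)
            ax.plot(sub["TIME"], sub["obs_p95"], "r--", lw=1)
            ax.set_title(f"{g} / {a}", fontsize=9)
            ax.set_xlabel("time (h)")
            ax.set_ylabel("conc (ng/mL)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_profiles(profile, path=None):
    """Mean +/- SD concentration-time curves from a scenario simulation."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for analyte, sub in profile.groupby("analyte"):
        ax.plot(sub["time_h"], sub["mean"], label=analyte)
        ax.fill_between(sub["time_h"],
                        np.maximum(sub["mean"] - sub["sd"], 0.0),
                        sub["mean"] + sub["sd"], alpha=0.25)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (ng/mL)")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
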