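"""Plot helpers for model qualification (GOF panels, VPC bands).

Matplotlib is imported lazily so headless pipelines that only write tables
never touch a plotting backend.
"""

from __future__ import annotations

import numpy as np


def plot_gof(gof_table, path) -> None:
    """Four-panel GOF layout per analyte: DV vs IPRED, DV vs PRED,
    CWRES vs PRED, CWRES vs time."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    analytes = sorted(gof_table["analyte"].unique())
    fig, axes = plt.subplots(len(analytes), 4, figsize=(16, 4 * len(analytes)),
                             squeeze=False)
    for row, analyte in enumerate(analytes):
        sub = gof_table[gof_table["analyte"] == analyte]
        pairs = [("ipred", "dv"), ("pred", "dv"), ("pred", "cwres"),
                 ("time", "cwres")]
        for col, (x, y) in enumerate(pairs):
            ax = axes[row][col]
            ax.scatter(sub[x], sub[y], s=12, alpha=0.6)
            if y == "dv":
                lim = [0, max(sub[x].max(), sub[y].max()) * 1.05]
                ax.plot(lim, lim, "k--", lw=1)
            else:
                ax.axhline(0, color="k", ls="--", lw=1)
                for lvl in (-2, 2):
                    ax.axhline(lvl, color="grey", ls=":", lw=1)
            ax.set_xlabel(x.upper())
            ax.set_ylabel(f"{analyte} {y.upper()}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pta_heatmap(pta_table, path, criterion: str = "ari>=100") -> None:
    """Phenotype x weight x dose attainment heat map for one criterion.

    ``pta_table`` is the long-form frame written by the regimen optimiser
    (columns phenotype, weight, dose, criterion, pta).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = pta_table[pta_table["criterion"] == criterion]
    phenotypes = sorted(sub["phenotype"].unique())
    fig, axes = plt.subplots(1, len(phenotypes), figsize=(5 * len(phenotypes), 4),
                             squeeze=False, sharey=True)
    for col, ph in enumerate(phenotypes):
        ax = axes[0][col]
        grid = sub[sub["phenotype"] == ph].pivot_table(
            index="dose", columns="weight", values="pta")
        im = ax.imshow(grid.to_numpy(), aspect="auto", origin="lower",
                       vmin=0.0, vmax=1.0, cmap="viridis")
        ax.set_xticks(range(len(grid.columns)), [f"{w:g}" for w in grid.columns])
        ax.set_yticks(range(len(grid.index)), [f"{d:g}" for d in grid.index])
        ax.set_xlabel("weight (kg)")
        if col == 0:
            ax.set_ylabel("dose (mg qd)")
        ax.set_title(ph)
    fig.colorbar(im, ax=axes[0].tolist(), label=f"P({criterion})")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_vpc(vpc_result, path) -> None:
    """Observed percentiles over the simulated 90% prediction bands."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    analytes = sorted(vpc_result.observed["analyte"].unique())
    fig, axes = plt.subplots(1, len(analytes), figsize=(7 * len(analytes), 5),
                             squeeze=False)
    for col, analyte in enumerate(analytes):
        ax = axes[0][col]
        obs = vpc_result.observed[vpc_result.observed["analyte"] == analyte]
        bands = vpc_result.bands[vpc_result.bands["analyte"] == analyte]
        order = np.argsort(obs["t_mid"].to_numpy())
        t = obs["t_mid"].to_numpy()[order]
        for pct, style in ((5, ":"), (50, "-"), (95, ":")):
            b = bands[bands["percentile"] == pct].set_index("bin")
            b = b.loc[obs["bin"].to_numpy()[order]]
            ax.fill_between(t, b["lower"], b["upper"], alpha=0.25)
            ax.plot(t, obs[f"p{pct}"].to_numpy()[order], "r" + style, lw=1.5)
        ax.set_xlabel("time after dose (h)")
        ax.set_ylabel(f"{analyte} (ng/ml)")
        ax.set_title(f"VPC {analyte} (n_sim={vpc_result.n_sim})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
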