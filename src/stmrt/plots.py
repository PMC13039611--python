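"""Figure helpers: reciprobit plots and modulation-transfer-function curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.stats import norm

from .later_fit import fit_later, reciprobit_points

#: the seven broadband stimuli overlaid in the canonical reciprobit figure
BROADBAND_OVERLAY = (
    "bb_0Hz_0.25co",
    "bb_0Hz_0.5co",
    "bb_0Hz_1co",
    "bb_4Hz_0co",
    "bb_4Hz_0.5co",
    "bb_8Hz_0co",
    "bb_16Hz_0.25co",
)

_PROBIT_TICKS = (0.01, 0.05, 0.2, 0.5, 0.8, 0.95, 0.99)


def reciprobit_axes(ax) -> None:
    """Probit-scaled y axis and a flipped promptness x axis (fast on the left)."""
    ax.set_yticks(norm.ppf(_PROBIT_TICKS))
    ax.set_yticklabels([f"{100 * p:g}" for p in _PROBIT_TICKS])
    ax.set_ylabel("cumulative probability (%)")
    ax.set_xlabel("promptness (1/s), fast → slow")
    ax.invert_xaxis()


def plot_reciprobit(
    clean: pd.DataFrame,
    participant: str,
    implementation: str,
    stimuli=BROADBAND_OVERLAY,
    with_fit: bool = True,
    ax=None,
):
    """Reciprobit overlay for one participant and implementation."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sub = clean[
        (clean["participant"] == participant)
        & (clean["implementation"] == implementation)
    ]
    for sid in stimuli:
        grp = sub[sub["stimulus_id"] == sid]
        if len(grp) == 0:
            continue
        rts = grp["rt_s"].to_numpy()
        cens = grp["censored"].to_numpy()
        if (~cens).sum() < 2:
            continue
        x, y = reciprobit_points(rts, cens)
        (line,) = ax.plot(x, y, "o", ms=4, label=sid)
        if with_fit and (~cens).sum() >= 5:
            fit = fit_later(rts, cens)
            if fit.converged:
                xs = np.linspace(x.min(), x.max(), 50)
                ax.plot(
                    xs,
                    -(xs - fit.mu_p_hat) / fit.sigma_p_hat,
                    "-",
                    color=line.get_color(),
                    lw=1,
                    alpha=0.7,
                )
    reciprobit_axes(ax)
    ax.set_title(f"{participant} / {implementation}")
    ax.legend(fontsize=6)
    return ax


def reciprobit_grid(clean: pd.DataFrame, out_dir: Path) -> int:
    """One reciprobit figure per (participant, implementation); returns count."""
    n = 0
    for (participant, impl), _ in clean.groupby(["participant", "implementation"]):
        fig, ax = plt.subplots(figsize=(5, 4))
        plot_reciprobit(clean, participant, impl, ax=ax)
        fig.tight_layout()
        fig.savefig(out_dir / f"reciprobit_{participant}_{impl}.png", dpi=120)
        plt.close(fig)
        n += 1
    return n


def plot_mtf(mtf_table, ax=None):
    """Iso-velocity and iso-density MTF curves with 95% CI error bars."""
    if ax is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    else:
        axes = ax
    for rate, df in mtf_table.iso_velocity().items():
        axes[0].errorbar(
            df["omega"],
            df["mean"],
            yerr=[df["mean"] - df["ci_lo"], df["ci_hi"] - df["mean"]],
            marker="o",
            label=f"{rate:g} Hz",
        )
    axes[0].set_xlabel("spectral density (cycles/octave)")
    axes[0].set_ylabel(f"mean {'RT (s)' if mtf_table.scale == 'rt' else 'promptness (1/s)'}")
    axes[0].legend(title="rate")
    for omega, df in mtf_table.iso_density().items():
        axes[1].errorbar(
            df["rate_hz"],
            df["mean"],
            yerr=[df["mean"] - df["ci_lo"], df["ci_hi"] - df["mean"]],
            marker="o",
            label=f"{omega:g} c/o",
        )
    axes[1].set_xlabel("temporal rate (Hz)")
    axes[1].legend(title="density")
    if mtf_table.scale == "rt":
        for a in axes:
            a.invert_yaxis()  # faster (more sensitive) plotted upward
    return axes
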