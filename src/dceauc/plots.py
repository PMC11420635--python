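"""Static Kaplan-Meier and AIF/concentration curve plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless rendering; import order matters
import matplotlib.pyplot as plt
import numpy as np

from .survival import RISK_TABLE_MONTHS, km_estimate

__all__ = ["plot_km_by_group", "plot_aif"]


def plot_km_by_group(time, event, group, title: str = "", path=None):
    """KM curves per group with a number-at-risk table below the axis."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    rows = []
    for g in np.unique(group):
        sel = group == g
        km = km_estimate(time[sel], event[sel])
        ax.step(np.r_[0, km.times], np.r_[1.0, km.survival], where="post",
                label=f"{g} (n={km.n})")
        rows.append((g, km.risk_table["n_at_risk"].tolist()))
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_xlim(0, max(RISK_TABLE_MONTHS))
    ax.legend(loc="lower left", fontsize=8)
    if title:
        ax.set_title(title)
    table_text = [[str(n) for n in counts] for _, counts in rows]
    tab = ax.table(
        cellText=table_text,
        rowLabels=[str(g) for g, _ in rows],
        colLabels=[str(t) for t in RISK_TABLE_MONTHS],
        loc="bottom", bbox=[0.0, -0.45, 1.0, 0.25],
    )
    tab.auto_set_font_size(False)
    tab.set_fontsize(7)
    fig.subplots_adjust(bottom=0.35)
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_aif(times_s, conc, peak_index=None, path=None):
    """Arterial input function with the detected peak marked."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(times_s, conc, marker="o", ms=3)
    if peak_index is not None:
        ax.axvline(times_s[peak_index], ls="--", color="tab:red", lw=1,
                   label=f"peak at {times_s[peak_index]:.1f} s")
        ax.legend(fontsize=8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("concentration (mmol/L)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
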