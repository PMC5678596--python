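"""Basic PRA / RER figure helper."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_pra_rer"]


def plot_pra_rer(traits: pd.DataFrame, rer_table: pd.DataFrame):
    """Two stacked panels: per-plant PRA trajectories (dark periods shaded)
    and the diel RER series.  Returns the matplotlib Figure."""
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    t0 = pd.to_datetime(traits["timestamp"]).min()
    for pid, sub in traits.groupby("plant_id"):
        days = (pd.to_datetime(sub["timestamp"]) - t0).dt.total_seconds() / 86400
        ax1.plot(days, sub["pra_mm2"], lw=1, label=f"plant {pid}")
    # shade dark periods
    dark = traits[traits["period_kind"] == "dark"]
    for _, sub in dark.groupby("period_index"):
        ts = (pd.to_datetime(sub["timestamp"]) - t0).dt.total_seconds() / 86400
        ax1.axvspan(ts.min(), ts.max(), color="0.85", zorder=0)
        ax2.axvspan(ts.min(), ts.max(), color="0.85", zorder=0)
    ax1.set_ylabel("PRA (mm$^2$)")
    if traits["plant_id"].nunique() <= 8:
        ax1.legend(fontsize=7, ncol=4)
    diel = rer_table[rer_table["kind"] == "diel"]
    for pid, sub in diel.groupby("plant_id"):
        ax2.plot(sub["time_days"], sub["rer_per_day"], lw=0.8)
    ax2.axhline(0.0, color="k", lw=0.5)
    ax2.set_ylabel("RER (day$^{-1}$)")
    ax2.set_xlabel("time (days)")
    fig.tight_layout()
    return fig
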