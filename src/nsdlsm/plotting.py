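"""Static NSD-versus-time plot with mode coloring."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

MODE_COLORS = {1: "tab:blue", 2: "tab:orange", 3: "tab:green"}
MODE_NAMES = {1: "encamped 1", 2: "encamped 2", 3: "exploratory"}


def plot_nsd(series, seq=None, ax=None, raw: bool = False):
    """Plot the NSD series, optionally colored by decoded mode.

    Parameters
    ----------
    series : NSDSeries
    seq : StateSequence, optional
        Decoded modes; observed days are drawn as points colored by mode.
    raw : bool
        Plot nsd_raw (m^2) instead of the standardized series.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    y = series.nsd_raw if raw or series.nsd_std is None else series.nsd_std
    t = series.day_index
    ax.plot(t, y, color="0.8", lw=0.8, zorder=1)
    if seq is None:
        ax.plot(t[series.observed], y[series.observed], "k.", ms=3, zorder=2)
    else:
        for m in (1, 2, 3):
            sel = series.observed & (seq.modes == m)
            if sel.any():
                ax.plot(t[sel], y[sel], ".", ms=4, color=MODE_COLORS[m],
                        label=MODE_NAMES[m], zorder=2)
        ax.legend(loc="best", fontsize=8)
    ax.set_xlabel("day")
    ax.set_ylabel("NSD (m$^2$)" if raw else "NSD (standardized)")
    ax.set_title(series.animal_id)
    return ax
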