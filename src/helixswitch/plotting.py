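"""Optional plotting of metric traces (raw + running average).

Requires matplotlib (the ``plot`` extra).  The layout follows the usual
presentation of switch trajectories: raw per-frame values as faint points,
the running average as a solid line, with an optionally split time axis
(linear for the early nanoseconds, logarithmic afterwards) so both the fast
onset and the long stable tail stay readable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .trajectory_metrics import TimeSeriesMetric

__all__ = ["plot_series"]


def plot_series(
    series: Sequence[TimeSeriesMetric],
    path: str | Path,
    log_after: float | None = 10.0,
    reference_band: tuple[float, float] | None = None,
):
    """Write a stacked panel figure of the given metric traces to ``path``.

    ``log_after`` switches the time axis to logarithmic after that many ns
    (None keeps it linear); ``reference_band`` draws a horizontal band, e.g.
    a user-supplied mobility range from reference simulations.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        len(series), 1, figsize=(6.0, 2.0 * len(series)), sharex=True, squeeze=False
    )
    for ax, s in zip(axes[:, 0], series):
        ax.plot(s.times, s.values, ".", ms=2, alpha=0.3, color="gray")
        if s.smoothed is not None:
            ax.plot(s.times, s.smoothed, "-", lw=1.5, color="crimson")
        if reference_band is not None:
            ax.axhspan(*reference_band, color="lightgray", alpha=0.5, zorder=0)
        ax.set_ylabel(f"{s.name} ({s.units})")
        if log_after is not None and s.times[-1] > log_after > s.times[0]:
            ax.set_xscale("symlog", linthresh=log_after)
            ax.axvline(log_after, ls="--", lw=0.8, color="gray")
    axes[-1, 0].set_xlabel("time (ns)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
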