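"""Optional figures: histogram with smooth overlay, residual bars.

Matplotlib is imported lazily so the core pipeline has no plotting
dependency; install the ``plot`` extra to use these.
"""

from __future__ import annotations

from pathlib import Path

from .distribution import Histogram, SmoothFit


def plot_histogram_fit(
    hist: Histogram,
    fit: SmoothFit,
    path: str | Path,
    thresholds=(0.7, 0.8, 0.9),
) -> None:
    """Two-panel figure: counts with the smooth fit, and residuals."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mids = hist.spec.midpoints
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    ax1.bar(mids, hist.counts, width=0.01, color="#4477aa", edgecolor="none")
    ax1.plot(mids, fit.fitted, "k:", lw=1.5, label="smooth fit")
    ax1.set_ylabel("AUC values per 0.01 bin")
    ax1.legend(frameon=False)
    ax2.bar(mids, fit.residuals, width=0.01, color="#cc6677", edgecolor="none")
    ax2.axhline(0, color="k", lw=0.5)
    ax2.set_ylabel("observed - fitted")
    ax2.set_xlabel("AUC")
    for ax in (ax1, ax2):
        for t in thresholds:
            ax.axvline(t, color="grey", lw=0.5, ls="--")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
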