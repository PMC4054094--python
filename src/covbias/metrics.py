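"""Evenness-of-coverage metrics.

The retrieval bias studied here shows up as a megabase-scale "wave" in
per-window depth: the more biased a library, the wider its distribution of
per-window read counts.  This module provides the window-count histogram
used to display that width, scalar dispersion summaries of it, the
histogram of per-window differences between two depth-matched libraries
(the tissue-difference display), and the blockwise median smoothing used to
plot noisy per-probe signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import CountTrack


@dataclass
class EvennessHistogram:
    bin_edges: np.ndarray  # length nbins + 1, strictly increasing
    window_counts: np.ndarray  # windows per bin, sums to n_windows
    n_windows: int


@dataclass
class DispersionStats:
    """Scalar summaries of the per-window count distribution.

    sd is the sample standard deviation (ddof=1); iqr uses linear
    interpolation between order statistics (quantile type 7); mad is the
    unscaled median absolute deviation; cv = sd / mean.
    """

    sd: float
    iqr: float
    mad: float
    cv: float


def _finite(track: CountTrack) -> np.ndarray:
    vals = np.asarray(track.counts, dtype=float)
    return vals[np.isfinite(vals)]


def evenness_histogram(track: CountTrack, bin_width: float) -> EvennessHistogram:
    """Histogram of per-window counts with bins [m·w, (m+1)·w)."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    vals = _finite(track)
    if len(vals) == 0:
        raise ValueError("empty track: nothing to histogram")
    lo = int(np.floor(vals.min() / bin_width))
    hi = int(np.floor(vals.max() / bin_width)) + 1
    edges = np.arange(lo, hi + 1) * bin_width
    counts, _ = np.histogram(vals, bins=edges)
    return EvennessHistogram(bin_edges=edges, window_counts=counts, n_windows=len(vals))


def dispersion(track: CountTrack) -> DispersionStats:
    vals = _finite(track)
    if len(vals) == 0 or vals.mean() <= 0:
        raise ValueError("dispersion undefined for a track with non-positive mean")
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation = type 7
    mad = float(np.median(np.abs(vals - np.median(vals))))
    return DispersionStats(sd=sd, iqr=float(q3 - q1), mad=mad, cv=sd / float(vals.mean()))


def difference_distribution(
    track_a: CountTrack, track_b: CountTrack, bin_width: float
) -> EvennessHistogram:
    """Histogram of per-window count differences (a − b) between two
    depth-matched libraries on the same window grid."""
    if len(track_a) != len(track_b):
        raise ValueError("difference_distribution: track length mismatch")
    diff = np.asarray(track_a.counts, float) - np.asarray(track_b.counts, float)
    both = np.isfinite(diff)
    dummy = CountTrack(counts=diff[both], library_size=0, state=track_a.state)
    return evenness_histogram(dummy, bin_width)


def difference_sd(track_a: CountTrack, track_b: CountTrack) -> float:
    """Sample sd of the per-window difference (a − b); the scalar width of
    :func:`difference_distribution`."""
    diff = np.asarray(track_a.counts, float) - np.asarray(track_b.counts, float)
    diff = diff[np.isfinite(diff)]
    return float(np.std(diff, ddof=1))


def median_smooth(values: np.ndarray, k: int = 100) -> np.ndarray:
    """Reduce non-overlapping blocks of k consecutive values to their median.

    The terminal partial block is kept iff it holds at least k/2 values.
    Callers smoothing genome tracks should apply this per chromosome so
    blocks never straddle a chromosome boundary.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = np.asarray(values, dtype=float)
    n = len(values)
    n_full = n // k
    out = []
    if n_full:
        out.append(np.median(values[: n_full * k].reshape(n_full, k), axis=1))
    rem = n - n_full * k
    if rem and 2 * rem >= k:
        out.append(np.atleast_1d(np.median(values[n_full * k :])))
    if not out:
        return np.empty(0)
    return np.concatenate(out)


def plot_evenness(histograms, labels, path, title: str = "Evenness of coverage"):
    """Overlay evenness histograms as frequency polygons (one line per
    library) and save to ``path``.  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for hist, label in zip(histograms, labels):
        centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
        ax.plot(centers, hist.window_counts / 1000.0, label=str(label))
    ax.set_xlabel("reads per window")
    ax.set_ylabel("windows (x1000)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
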