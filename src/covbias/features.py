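"""Genome-feature tracks on the window grid and correlation panels.

Coverage waves track large-scale genome organisation, so a standard check
is to bin annotation features — SINE density, gene density, replication
timing, GC content — onto the same window grid as the coverage signal and
report Pearson correlations.  Interval features (BED) become
fraction-of-span-covered values; signal features (bedGraph) become
span-weighted means.  The reported p-values are nominal t-distribution
p-values: adjacent windows are strongly autocorrelated, so they overstate
significance and should be read as descriptive only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CountTrack
from .segments import RatioTrack
from .windows import WindowSet, merge_intervals


@dataclass
class FeatureTrack:
    values: np.ndarray  # per window; NaN = missing
    feature_name: str = "custom"
    kind: str = "interval-coverage"  # or "signal-mean"
    window_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.window_ids is None:
            self.window_ids = np.arange(len(self.values))

    def __len__(self) -> int:
        return len(self.values)


def _covered_before(x: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                    cumcov: np.ndarray) -> np.ndarray:
    """Union bp covered in (-inf, x) by merged intervals."""
    i = np.searchsorted(starts, x, side="right")
    out = np.where(i > 0, cumcov[i - 1] - np.maximum(0, ends[np.maximum(i, 1) - 1] - x), 0)
    return np.maximum(out, 0)


def bin_intervals(
    intervals: Mapping[str, Sequence[tuple[int, int]]],
    windows: WindowSet,
    feature_name: str = "custom",
) -> FeatureTrack:
    """Fraction of each window's span covered by the union of intervals."""
    known = set(windows.table["chrom"])
    unknown = set(intervals) - known
    if unknown:
        warnings.warn(
            f"feature intervals on chromosome(s) without windows ignored: {sorted(unknown)}",
            stacklevel=2,
        )
    values = np.zeros(len(windows))
    for chrom, sub in windows.table.groupby("chrom", sort=False):
        iv = merge_intervals(intervals.get(chrom, []))
        if iv.shape[0] == 0:
            continue
        starts, ends = iv[:, 0], iv[:, 1]
        cumcov = np.cumsum(ends - starts)
        w_start = sub["start"].to_numpy()
        w_end = sub["end"].to_numpy()
        cov = _covered_before(w_end, starts, ends, cumcov) - _covered_before(
            w_start, starts, ends, cumcov
        )
        values[sub.index.to_numpy()] = cov / (w_end - w_start)
    return FeatureTrack(values=values, feature_name=feature_name, kind="interval-coverage")


def bin_signal(
    steps: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    windows: WindowSet,
    feature_name: str = "custom",
) -> FeatureTrack:
    """Span-length-weighted mean of a step function (bedGraph) per window.

    ``steps[chrom]`` is (starts, ends, values) with non-overlapping steps.
    Windows with no overlapping signal are NaN.
    """
    values = np.full(len(windows), np.nan)
    for chrom, sub in windows.table.groupby("chrom", sort=False):
        if chrom not in steps:
            continue
        s, e, v = (np.asarray(a) for a in steps[chrom])
        order = np.argsort(s, kind="stable")
        s, e, v = s[order], e[order], v[order]
        if np.any(s[1:] < e[:-1]):
            j = int(np.flatnonzero(s[1:] < e[:-1])[0])
            raise ValueError(
                f"overlapping bedGraph steps on {chrom}: "
                f"({s[j]}, {e[j]}) and ({s[j + 1]}, {e[j + 1]})"
            )
        cumlen = np.cumsum(e - s)
        cumint = np.cumsum(v * (e - s))

        def before(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            """(signal bp, signal integral) in (-inf, x)."""
            i = np.searchsorted(s, x, side="right")
            j = np.maximum(i, 1) - 1
            cut = np.clip(e[j] - x, 0, e[j] - s[j])  # part of step j beyond x
            len_b = np.where(i > 0, cumlen[j] - cut, 0.0)
            int_b = np.where(i > 0, cumint[j] - cut * v[j], 0.0)
            return len_b, int_b

        w_start = sub["start"].to_numpy()
        w_end = sub["end"].to_numpy()
        len_hi, int_hi = before(w_end)
        len_lo, int_lo = before(w_start)
        length = len_hi - len_lo
        integral = int_hi - int_lo
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(length > 0, integral / np.where(length > 0, length, 1), np.nan)
        values[sub.index.to_numpy()] = vals
    return FeatureTrack(values=values, feature_name=feature_name, kind="signal-mean")


def _track_values(track) -> np.ndarray:
    if isinstance(track, CountTrack):
        return np.asarray(track.counts, float)
    if isinstance(track, RatioTrack):
        return np.asarray(track.log2_ratio, float)
    return np.asarray(track, float)


def pearson_panel(track, features: Sequence[FeatureTrack]) -> pd.DataFrame:
    """Pearson r of a coverage/ratio track against each feature.

    Pairwise-complete windows per feature; two-sided p from the
    t-distribution with n − 2 df (nominal; see module docstring).
    """
    y = _track_values(track)
    rows = []
    for feat in features:
        x = feat.values
        if len(x) != len(y):
            raise ValueError(f"feature {feat.feature_name!r} length mismatch with track")
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n < 3:
            raise ValueError(f"feature {feat.feature_name!r}: fewer than 3 paired windows")
        if np.std(x[ok]) == 0:
            raise ValueError(f"feature {feat.feature_name!r} has zero variance")
        if np.std(y[ok]) == 0:
            raise ValueError("track has zero variance over paired windows")
        r, p = stats.pearsonr(y[ok], x[ok])
        rows.append((feat.feature_name, float(r), n, float(p)))
    return pd.DataFrame(rows, columns=["feature_name", "r", "n", "p"])
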