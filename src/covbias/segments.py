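"""Log2 ratio tracks and differential-segment calling.

Two depth-normalized libraries are compared window by window through
L_i = log2((a_i + c) / (b_i + c)) with a small pseudocount c, and contiguous
runs of windows whose apparent copy ratio deviates by at least a threshold
fraction are merged into segments.  The segmenter is a deterministic
threshold-run rule: a window is deviant-up when 2^L ≥ 1 + t and deviant-down
when 2^L ≤ 1 − t; same-direction deviant windows are chained, tolerating up
to ``max_gap`` interleaved non-deviant (but never opposite-direction)
windows; chains with at least ``min_windows`` deviant windows become
segments spanning from their first to their last deviant window.  Reported
affected megabases therefore depend only on thresholded contiguity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import CountTrack
from .windows import WindowSet

GAIN = "gain"
LOSS = "loss"


@dataclass
class RatioTrack:
    """Per-window log2 ratio between two samples; NaN where either input
    is missing."""

    log2_ratio: np.ndarray
    samples: tuple[str, str] = ("A", "B")
    window_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.log2_ratio = np.asarray(self.log2_ratio, dtype=float)
        if self.window_ids is None:
            self.window_ids = np.arange(len(self.log2_ratio))

    def __len__(self) -> int:
        return len(self.log2_ratio)


@dataclass
class Segment:
    chrom: str
    start: int
    end: int
    n_windows: int  # number of deviant windows in the run
    mean_ratio: float  # mean log2 ratio over the deviant windows
    direction: str  # gain | loss


def log2_ratio(
    track_a: CountTrack, track_b: CountTrack, pseudocount: float = 0.5
) -> RatioTrack:
    """L_i = log2((a_i + pseudocount) / (b_i + pseudocount)).

    NaN propagates from either input; both tracks must be depth-normalized
    to the same scale (downsampled, RPM, quantile or GC-corrected).
    """
    if len(track_a) != len(track_b):
        raise ValueError("log2_ratio: track length mismatch")
    a = np.asarray(track_a.counts, float)
    b = np.asarray(track_b.counts, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.log2((a + pseudocount) / (b + pseudocount))
    ratio[~(np.isfinite(a) & np.isfinite(b))] = np.nan
    return RatioTrack(
        log2_ratio=ratio, samples=(track_a.sample or "A", track_b.sample or "B")
    )


def segment_differential(
    ratio: RatioTrack,
    windows: WindowSet,
    threshold: float = 0.10,
    min_windows: int = 3,
    max_gap: int = 1,
) -> list[Segment]:
    """Merge runs of windows whose copy ratio deviates by ≥ ``threshold``.

    Segment boundaries snap to deviant windows, so the reported span is
    conservative; runs never cross chromosomes.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if len(ratio) != len(windows):
        raise ValueError("ratio and window set length mismatch")
    fold = np.exp2(ratio.log2_ratio)
    state = np.zeros(len(ratio), dtype=np.int8)
    with np.errstate(invalid="ignore"):
        state[fold >= 1.0 + threshold] = 1
        state[fold <= 1.0 - threshold] = -1
    segments: list[Segment] = []
    table = windows.table

    def close(chrom: str, deviant: list[int], direction: int) -> None:
        if len(deviant) < min_windows:
            return
        vals = ratio.log2_ratio[deviant]
        segments.append(
            Segment(
                chrom=chrom,
                start=int(table["start"].iloc[deviant[0]]),
                end=int(table["end"].iloc[deviant[-1]]),
                n_windows=len(deviant),
                mean_ratio=float(np.mean(vals)),
                direction=GAIN if direction > 0 else LOSS,
            )
        )

    for chrom, sub in table.groupby("chrom", sort=False):
        run: list[int] = []
        run_dir = 0
        for i in sub.index:
            s = state[i]
            if s == 0:
                continue
            if run and s == run_dir and i - run[-1] - 1 <= max_gap:
                # any opposite-direction deviant inside the gap was itself
                # visited earlier and already broke the chain
                run.append(i)
            else:
                if run:
                    close(chrom, run, run_dir)
                run, run_dir = [i], s
        if run:
            close(chrom, run, run_dir)
    return segments


def total_affected_mb(segments: list[Segment]) -> float:
    """Total genomic span of the segments, in megabases."""
    return float(sum(s.end - s.start for s in segments)) / 1e6
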