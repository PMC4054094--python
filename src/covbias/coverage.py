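"""Per-window read counting and depth normalization.

A read is assigned to the unique window whose genomic span contains its
start position (half-open, so a read starting exactly on a boundary belongs
to the right-hand window).  Three normalizations used in depth-of-coverage
comparisons are provided: reads-per-million scaling, random downsampling of
the read set to a common depth, and cross-sample quantile normalization.
PCR duplicates are expected to be removed when the read set is constructed;
``ReadSet.total_mapped`` counts non-duplicate reads only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .windows import WindowSet

log = logging.getLogger(__name__)

STATE_RAW = "raw"
STATE_RPM = "rpm"
STATE_DOWNSAMPLED = "downsampled"
STATE_QUANTILE = "quantile"
STATE_GC = "gc-corrected"


@dataclass
class ReadSet:
    """Aligned read start positions per chromosome (0-based, sorted).

    Duplicate-flagged reads are dropped at construction time and tallied in
    ``duplicates_removed``.
    """

    positions: dict[str, np.ndarray]
    duplicates_removed: int = 0

    @classmethod
    def from_positions(
        cls,
        positions: Mapping[str, Sequence[int]],
        dup: Mapping[str, Sequence[int]] | None = None,
    ) -> "ReadSet":
        out: dict[str, np.ndarray] = {}
        n_dup = 0
        for chrom, pos in positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if dup is not None and chrom in dup:
                flags = np.asarray(dup[chrom], dtype=bool)
                n_dup += int(flags.sum())
                arr = arr[~flags]
            out[chrom] = np.sort(arr)
        return cls(positions=out, duplicates_removed=n_dup)

    @property
    def total_mapped(self) -> int:
        return int(sum(len(a) for a in self.positions.values()))


@dataclass
class CountTrack:
    """Per-window read counts for one library.

    ``counts`` is aligned positionally with a :class:`WindowSet`;
    ``window_ids`` carries the window ordinals.  ``state`` records which
    normalizations have been applied; raw counts are integers summing to at
    most ``library_size`` (reads outside any window are discarded and
    tallied in ``discarded``).  Missing values (e.g. windows flagged during
    GC correction) are NaN.
    """

    counts: np.ndarray
    library_size: int
    state: str = STATE_RAW
    window_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    discarded: int = 0
    sample: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.window_ids is None:
            self.window_ids = np.arange(len(self.counts))
        else:
            self.window_ids = np.asarray(self.window_ids)
        if len(self.window_ids) != len(self.counts):
            raise ValueError("window_ids and counts length mismatch")

    def __len__(self) -> int:
        return len(self.counts)


def count_reads(windows: WindowSet, reads: ReadSet, sample: str = "") -> CountTrack:
    """Assign each read to the window containing its start position.

    Reads on chromosomes absent from the window set are an error; reads in
    unwindowed leading/trailing sequence are discarded (and counted).
    """
    win_chroms = set(windows.table["chrom"])
    bad = sorted(set(reads.positions) - win_chroms - set(windows.mask.chrom_lengths))
    if bad:
        raise ValueError(f"reads on chromosome(s) unknown to the window set: {bad}")
    counts = np.zeros(len(windows), dtype=float)
    discarded = 0
    for chrom, sub in windows.table.groupby("chrom", sort=False):
        pos = reads.positions.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # windows abut within a chromosome, so spans are described by the
        # boundary vector [start_0, end_0 == start_1, ..., end_last]
        bounds = np.concatenate((starts, ends[-1:]))
        idx = np.searchsorted(bounds, pos, side="right") - 1
        inside = (idx >= 0) & (idx < len(sub)) & (pos < ends[np.clip(idx, 0, len(sub) - 1)])
        discarded += int((~inside).sum())
        counts[sub.index.to_numpy()] += np.bincount(idx[inside], minlength=len(sub))
    # reads on windowless chromosomes are discarded too
    for chrom, pos in reads.positions.items():
        if chrom not in set(windows.table["chrom"]):
            discarded += len(pos)
    if discarded:
        log.info("%d read(s) outside any window discarded", discarded)
    return CountTrack(
        counts=counts,
        library_size=reads.total_mapped,
        state=STATE_RAW,
        discarded=discarded,
        sample=sample,
    )


def rpm_normalize(track: CountTrack) -> CountTrack:
    """Scale counts to reads per million mapped reads."""
    if track.library_size <= 0:
        raise ValueError("cannot RPM-normalize a track with zero library size")
    if track.state != STATE_RAW:
        raise ValueError(f"RPM normalization expects raw counts, got state={track.state!r}")
    return replace(track, counts=track.counts * 1e6 / track.library_size, state=STATE_RPM)


def downsample(reads: ReadSet, target: int, seed: int) -> ReadSet:
    """Uniform random subset of exactly ``target`` reads, without replacement.

    Deterministic given ``seed``; mimics normalizing libraries to a common
    depth by random removal of reads.
    """
    total = reads.total_mapped
    if target > total:
        raise ValueError(f"downsample target {target} exceeds mapped reads {total}")
    if target == total:
        return ReadSet(positions={c: a.copy() for c, a in reads.positions.items()})
    rng = np.random.default_rng(seed)
    chroms = list(reads.positions)
    sizes = np.array([len(reads.positions[c]) for c in chroms])
    keep = rng.choice(total, size=target, replace=False)
    keep.sort()
    offsets = np.concatenate(([0], np.cumsum(sizes)))
    out: dict[str, np.ndarray] = {}
    for i, chrom in enumerate(chroms):
        lo, hi = np.searchsorted(keep, (offsets[i], offsets[i + 1]))
        out[chrom] = np.sort(reads.positions[chrom][keep[lo:hi] - offsets[i]])
    return ReadSet(positions=out)


def quantile_normalize(tracks: Sequence[CountTrack]) -> list[CountTrack]:
    """Rank-based quantile normalization across tracks on the same grid.

    Within each track values are ranked; the value at rank r is replaced by
    the mean across tracks of the rank-r values; tied values receive the
    mean over their rank range.
    """
    if len(tracks) < 2:
        raise ValueError("quantile normalization needs at least 2 tracks")
    n = len(tracks[0])
    if any(len(t) != n for t in tracks):
        raise ValueError("quantile normalization: track length mismatch")
    for t in tracks:
        if t.state not in (STATE_RAW, STATE_RPM, STATE_DOWNSAMPLED):
            raise ValueError(f"unexpected track state for quantile normalization: {t.state!r}")
    X = np.column_stack([t.counts for t in tracks])
    order = np.argsort(X, axis=0, kind="stable")
    mean_sorted = np.take_along_axis(X, order, axis=0).mean(axis=1)
    out_tracks = []
    for j, t in enumerate(tracks):
        assigned = np.empty(n)
        assigned[order[:, j]] = mean_sorted
        # ties get the mean of the rank-range values they span
        _, inv = np.unique(X[:, j], return_inverse=True)
        group_mean = np.bincount(inv, weights=assigned) / np.bincount(inv)
        out_tracks.append(replace(t, counts=group_mean[inv], state=STATE_QUANTILE))
    return out_tracks
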