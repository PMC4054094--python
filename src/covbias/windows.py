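"""Accessibility masks and genome windowing.

Read-depth analyses bin the genome into windows before counting reads.
Because repeats and assembly gaps carry no uniquely mappable signal, windows
are defined so that each one contains a fixed amount of *usable* sequence
rather than a fixed genomic span: the window boundary is cut exactly when the
accumulated accessible base count reaches the target.  Two flavours are
provided:

* ``partition_accessible`` — each window holds ``W`` bp of NGS-accessible
  sequence (non-repeat, non-gap); this is the grid used for fragment-library
  depth-of-coverage comparisons (default ``W`` = 20 kb).
* ``partition_span`` — each window holds ``S`` bp of non-gap sequence
  (repeats are *not* excluded); used for low-pass mate-pair coverage
  (default ``S`` = 100 kb).

Coordinates are 0-based half-open throughout, matching the BED convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_GAP_RE = re.compile(r"[Nn]+")

MODE_ACCESSIBLE = "accessible-content"
MODE_SPAN = "genomic-span"


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    """Sort and merge possibly-overlapping intervals into an (n, 2) array."""
    arr = np.asarray(list(intervals), dtype=np.int64).reshape(-1, 2)
    if arr.shape[0] == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def complement_intervals(intervals: np.ndarray, length: int) -> np.ndarray:
    """Complement of merged intervals within [0, length)."""
    out = []
    prev = 0
    for s, e in intervals:
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


@dataclass
class AccessibilityMask:
    """Per-chromosome intervals of usable sequence.

    ``accessible`` maps chromosome name to a sorted, merged (n, 2) int array
    of 0-based half-open intervals.  Invariants are enforced by
    :meth:`validate`.
    """

    chrom_lengths: dict[str, int]
    accessible: dict[str, np.ndarray]

    def validate(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            iv = self.accessible[chrom]
            if iv.shape[0] == 0:
                continue
            if not (iv[:, 0] < iv[:, 1]).all():
                raise ValueError(f"empty or inverted interval on {chrom}")
            if iv[0, 0] < 0 or iv[-1, 1] > length:
                raise ValueError(f"interval out of bounds on {chrom}")
            if not (iv[1:, 0] >= iv[:-1, 1]).all():
                raise ValueError(f"unsorted or overlapping intervals on {chrom}")

    def total_accessible(self, chrom: str | None = None) -> int:
        chroms = [chrom] if chrom is not None else list(self.accessible)
        return int(
            sum((self.accessible[c][:, 1] - self.accessible[c][:, 0]).sum() for c in chroms)
        )


def find_gap_runs(seq: str) -> np.ndarray:
    """Maximal runs of N/n in a sequence, as (n, 2) interval array."""
    return np.asarray(
        [(m.start(), m.end()) for m in _GAP_RE.finditer(seq)], dtype=np.int64
    ).reshape(-1, 2)


def build_mask(
    genome: Mapping[str, str],
    repeats: Mapping[str, Iterable[tuple[int, int]]] | None = None,
) -> AccessibilityMask:
    """Mask of accessible sequence: complement of repeats and N-gap runs.

    With ``repeats=None`` (or empty) the mask excludes assembly gaps only,
    which is the grid needed for span-mode windowing.
    """
    if not genome:
        raise ValueError("empty genome: no chromosomes")
    repeats = repeats or {}
    unknown = set(repeats) - set(genome)
    if unknown:
        raise ValueError(f"repeat intervals on unknown chromosome(s): {sorted(unknown)}")
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    accessible: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        length = chrom_lengths[chrom]
        excl = [tuple(g) for g in find_gap_runs(seq)]
        for s, e in repeats.get(chrom, []):
            if s < 0 or e > length:
                raise ValueError(
                    f"repeat interval ({s}, {e}) out of bounds on {chrom} (length {length})"
                )
            excl.append((int(s), int(e)))
        accessible[chrom] = complement_intervals(merge_intervals(excl), length)
    mask = AccessibilityMask(chrom_lengths, accessible)
    mask.validate()
    return mask


@dataclass
class WindowSet:
    """Ordered genomic windows over an :class:`AccessibilityMask`.

    ``table`` has one row per window with columns ``chrom, start, end,
    accessible_bp, gc`` (``gc`` is NaN until :func:`annotate_gc` runs, and
    stays NaN for windows with no unambiguous accessible base, which are
    excluded downstream).  Row order is genome order; the positional index is
    the window ordinal.
    """

    table: pd.DataFrame
    mode: str
    size: int
    mask: AccessibilityMask
    dropped_bp: int = 0

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gc(self) -> np.ndarray:
        return self.table["gc"].to_numpy()

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))


def _cut_chromosome(intervals: np.ndarray, width: int) -> tuple[list[tuple[int, int, int]], int]:
    """Scan accessible intervals left to right, cutting a boundary exactly
    when the accumulated accessible bp reaches ``width``.

    Returns (windows as (start, end, accessible_bp), dropped remainder bp).
    The terminal remainder is kept iff it holds at least ``width``/2
    accessible bp.
    """
    windows: list[tuple[int, int, int]] = []
    if intervals.shape[0] == 0:
        return windows, 0
    win_start = int(intervals[0, 0])
    acc = 0
    for s, e in intervals:
        pos = int(s)
        while acc + (e - pos) >= width:
            cut = pos + (width - acc)
            windows.append((win_start, int(cut), width))
            win_start = int(cut)
            pos = int(cut)
            acc = 0
        acc += int(e) - pos
    if acc > 0:
        if 2 * acc >= width:
            windows.append((win_start, int(intervals[-1, 1]), acc))
            return windows, 0
        return windows, acc
    return windows, 0


def _partition(mask: AccessibilityMask, width: int, mode: str) -> WindowSet:
    if width < 1:
        raise ValueError(f"window size must be >= 1, got {width}")
    rows = []
    dropped_total = 0
    for chrom in mask.chrom_lengths:
        wins, dropped = _cut_chromosome(mask.accessible[chrom], width)
        dropped_total += dropped
        if dropped:
            log.info("%s: dropped terminal remainder of %d accessible bp", chrom, dropped)
        for start, end, acc in wins:
            rows.append((chrom, start, end, acc))
    if not rows:
        log.warning(
            "window size %d exceeds the accessible sequence of every chromosome; "
            "empty window set",
            width,
        )
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "accessible_bp"])
    table["gc"] = np.nan
    return WindowSet(table=table, mode=mode, size=width, mask=mask, dropped_bp=dropped_total)


def partition_accessible(mask: AccessibilityMask, W: int) -> WindowSet:
    """Windows each holding ``W`` bp of accessible (non-repeat, non-gap)
    sequence.  Spans abut within a chromosome; every window but possibly the
    terminal one has ``accessible_bp == W``."""
    return _partition(mask, W, MODE_ACCESSIBLE)


def partition_span(mask: AccessibilityMask, S: int) -> WindowSet:
    """Windows each holding ``S`` bp of non-gap sequence.

    ``mask`` must be built with gaps only (``build_mask(genome)`` with no
    repeats): repeats are deliberately *not* excluded in this mode.
    """
    return _partition(mask, S, MODE_SPAN)


def annotate_gc(genome: Mapping[str, str], windows: WindowSet) -> WindowSet:
    """GC fraction per window over the accessible, unambiguous bases.

    gc = (#G + #C) / (#A + #C + #G + #T) within the window span restricted to
    the mask; ambiguous bases (N etc.) are excluded from the denominator.
    Windows with zero unambiguous accessible bases keep gc = NaN and are
    flagged out of downstream analyses.
    """
    table = windows.table.copy()
    gc_out = np.full(len(table), np.nan)
    for chrom, sub in table.groupby("chrom", sort=False):
        seq = np.frombuffer(genome[chrom].upper().encode("ascii"), dtype=np.uint8)
        acc = np.zeros(len(seq), dtype=bool)
        for s, e in windows.mask.accessible[chrom]:
            acc[s:e] = True
        is_gc = (seq == ord("G")) | (seq == ord("C"))
        is_at = (seq == ord("A")) | (seq == ord("T"))
        cs_gc = np.concatenate(([0], np.cumsum(is_gc & acc)))
        cs_acgt = np.concatenate(([0], np.cumsum((is_gc | is_at) & acc)))
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        n_gc = cs_gc[ends] - cs_gc[starts]
        n_acgt = cs_acgt[ends] - cs_acgt[starts]
        with np.errstate(invalid="ignore"):
            vals = np.where(n_acgt > 0, n_gc / np.maximum(n_acgt, 1), np.nan)
        gc_out[sub.index] = vals
    table["gc"] = gc_out
    n_flagged = int(np.isnan(gc_out).sum())
    if n_flagged:
        log.info("%d window(s) with no unambiguous accessible base flagged (gc=NaN)", n_flagged)
    return replace(windows, table=table)
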