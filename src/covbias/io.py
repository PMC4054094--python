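"""Readers and writers for the standard text formats the pipeline consumes.

Coordinates on disk follow BED conventions: 0-based half-open, tab
separation, ``track``/``browser``/``#`` lines tolerated and skipped on
input.  Tabular outputs are TSV with a header line preceded by
``#``-prefixed comment lines recording the tool version and the parameters
that produced the file, so results are self-describing.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from . import __version__
from .coverage import ReadSet

log = logging.getLogger(__name__)


# -- FASTA -------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Whole-genome FASTA into a name → sequence dict (IDs up to first
    whitespace)."""
    with open(path) as fh:
        return {name.split()[0]: seq for name, seq in SimpleFastaParser(fh)}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- BED ---------------------------------------------------------------------

def _is_skippable(line: str) -> bool:
    s = line.strip()
    return not s or s.startswith(("#", "track", "browser"))


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3+ into a DataFrame (chrom, start, end, payload columns).

    Malformed coordinates raise with the 1-based line number.
    """
    rows = []
    n_extra = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom, s, e = parts[0], parts[1], parts[2]
            try:
                start, end = int(s), int(e)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates {s!r}, {e!r}") from err
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            extra = parts[3:]
            n_extra = max(n_extra, len(extra))
            rows.append((chrom, start, end, *extra))
    cols = ["chrom", "start", "end"] + [f"col{i + 4}" for i in range(n_extra)]
    df = pd.DataFrame(
        [r + ("",) * (3 + n_extra - len(r)) for r in rows], columns=cols
    )
    if len(df):
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    return df


def intervals_by_chrom(bed: pd.DataFrame) -> dict[str, np.ndarray]:
    """Group a BED frame into per-chromosome (n, 2) interval arrays."""
    return {
        chrom: sub[["start", "end"]].to_numpy(dtype=np.int64)
        for chrom, sub in bed.groupby("chrom", sort=False)
    }


def write_bed(
    intervals: Mapping[str, np.ndarray] | pd.DataFrame, path: str | Path
) -> None:
    """Write per-chromosome intervals (or a BED-like DataFrame) as BED."""
    with open(path, "w") as fh:
        if isinstance(intervals, pd.DataFrame):
            for row in intervals.itertuples(index=False):
                fh.write("\t".join(str(v) for v in row) + "\n")
        else:
            for chrom, arr in intervals.items():
                for s, e, *rest in np.asarray(arr).reshape(-1, np.asarray(arr).shape[-1]):
                    fields = [chrom, str(int(s)), str(int(e))] + [str(r) for r in rest]
                    fh.write("\t".join(fields) + "\n")


def read_reads(path: str | Path) -> ReadSet:
    """Read aligned read positions from BED3+ or a 2-column (chrom, pos) TSV.

    A 4th BED column equal to ``0``/``1`` is interpreted as a PCR-duplicate
    flag; flagged reads are dropped and tallied.
    """
    positions: dict[str, list[int]] = {}
    dups: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                if len(parts) == 2:
                    chrom, pos, dup = parts[0], int(parts[1]), 0
                else:
                    chrom, pos = parts[0], int(parts[1])
                    int(parts[2])  # end coordinate, unused (start-position counting)
                    dup = int(parts[3]) if len(parts) > 3 and parts[3] in ("0", "1") else 0
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed read record") from err
            positions.setdefault(chrom, []).append(pos)
            dups.setdefault(chrom, []).append(dup)
    return ReadSet.from_positions(positions, dup=dups)


# -- bedGraph ----------------------------------------------------------------

def read_bedgraph(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """4-column bedGraph into per-chromosome sorted (starts, ends, values).

    Overlapping steps are rejected, naming both offending lines.
    """
    recs: dict[str, list[tuple[int, int, float, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph record") from err
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            recs.setdefault(parts[0], []).append((start, end, value, lineno))
    out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, rows in recs.items():
        rows.sort(key=lambda r: (r[0], r[1]))
        for a, b in zip(rows, rows[1:]):
            if b[0] < a[1]:
                raise ValueError(
                    f"{path}: overlapping steps on {chrom} at lines {a[3]} and {b[3]}"
                )
        arr = np.asarray([(r[0], r[1], r[2]) for r in rows], dtype=float)
        out[chrom] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
    return out


def write_bedgraph(
    steps: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for chrom, (s, e, v) in steps.items():
            for a, b, val in zip(s, e, v):
                fh.write(f"{chrom}\t{int(a)}\t{int(b)}\t{val:.10g}\n")


# -- TSV tracks --------------------------------------------------------------

def write_track_tsv(df: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    """TSV with '#' comment lines carrying tool version and parameters."""
    with open(path, "w") as fh:
        fh.write(f"# covbias {__version__}\n")
        for key, val in (params or {}).items():
            fh.write(f"# {key} = {val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def read_track_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
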