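"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately work per base (boolean arrays, linear scans)
so they stay independent of the interval arithmetic used by the package.
"""

from __future__ import annotations

import numpy as np
import pytest

from covbias.windows import AccessibilityMask


def mask_bool(mask: AccessibilityMask, chrom: str) -> np.ndarray:
    """Accessibility as a per-base boolean array."""
    arr = np.zeros(mask.chrom_lengths[chrom], dtype=bool)
    for s, e in mask.accessible[chrom]:
        arr[s:e] = True
    return arr


def partition_oracle(acc: np.ndarray, width: int) -> list[tuple[int, int, int]]:
    """Per-base scanning partition: cut a boundary exactly when the
    accumulated accessible base count reaches ``width``; keep the terminal
    remainder iff it holds >= width/2 accessible bases."""
    first = np.flatnonzero(acc)
    windows = []
    if len(first) == 0:
        return windows
    start = int(first[0])
    n_acc = 0
    last_acc = start
    for pos in range(start, len(acc)):
        if acc[pos]:
            n_acc += 1
            last_acc = pos
            if n_acc == width:
                windows.append((start, pos + 1, width))
                start = pos + 1
                n_acc = 0
    if n_acc and 2 * n_acc >= width:
        windows.append((start, last_acc + 1, n_acc))
    return windows


def random_masked_genome(rng: np.random.Generator, length: int = 10_000,
                         n_repeats: int = 50, n_gaps: int = 5):
    """Random sequence with N-gap runs plus random repeat intervals."""
    seq = rng.choice(list("ACGT"), size=length)
    for _ in range(n_gaps):
        s = int(rng.integers(0, length))
        seq[s : s + int(rng.integers(1, 400))] = "N"
    repeats = []
    for _ in range(n_repeats):
        s = int(rng.integers(0, length))
        repeats.append((s, min(length, s + int(rng.integers(1, 300)))))
    return "".join(seq), repeats


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
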