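"""GC-content correction of per-window read counts.

Library preparation and sequencing recover fragments with an efficiency that
depends on their GC content, which imprints a smooth GC-driven trend on
per-window depth.  The correction implemented here is non-parametric: each
window is normalized against the median count of the k windows (k = 100 by
default) whose GC content is most similar to its own,

    N_corr(i) = N_med * N_obs(i) / N_medGC(i)

where N_obs(i) is the observed count in window i, N_medGC(i) the median
count over its k GC-nearest windows, and N_med the median count over all
windows of the library.  The window itself is included in its own neighbor
set, so a library with constant counts is a fixed point.  Ties in |ΔGC| are
broken by genomic proximity (|Δindex|) and then by index, making the
neighbor sets deterministic.  Windows whose neighborhood median is zero
cannot be corrected and come back as NaN, flagged for downstream exclusion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .coverage import STATE_GC, CountTrack
from .windows import WindowSet

log = logging.getLogger(__name__)


@dataclass
class GCCorrectionModel:
    """Fitted correction: neighbor sets and the medians entering the formula."""

    k: int
    n_med: float
    neighbor_map: list[np.ndarray]  # per window: indices of its k GC-nearest windows
    n_medgc: np.ndarray  # per window: median count over the neighbor set (NaN if invalid)


def gc_neighbors(gc: np.ndarray, k: int, valid: np.ndarray | None = None) -> list[np.ndarray]:
    """For each valid window, the k windows most similar in GC.

    Similarity key is (|gc_j - gc_i|, |j - i|, j), the window itself included.
    Invalid windows (``valid`` False or gc NaN) get an empty neighbor list and
    never appear in anyone's neighborhood.
    """
    gc = np.asarray(gc, dtype=float)
    n = len(gc)
    if valid is None:
        valid = np.isfinite(gc)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(gc)
    idx_valid = np.flatnonzero(valid)
    m = len(idx_valid)
    k_eff = min(k, m)
    out: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * n
    if m == 0 or k_eff == 0:
        return out
    order = idx_valid[np.argsort(gc[idx_valid], kind="stable")]
    gcs = gc[order]
    pos_of = np.empty(n, dtype=np.int64)
    pos_of[order] = np.arange(m)
    for i in idx_valid:
        p = pos_of[i]
        lo = hi = p  # inclusive candidate band in GC-sorted order
        # grow the band to k_eff elements, preferring the smaller |ΔGC| side
        while hi - lo + 1 < k_eff:
            d_lo = gc[i] - gcs[lo - 1] if lo > 0 else np.inf
            d_hi = gcs[hi + 1] - gc[i] if hi < m - 1 else np.inf
            if d_lo <= d_hi:
                lo -= 1
            else:
                hi += 1
        # include every window tied with the current worst |ΔGC| so the
        # deterministic tie-break below sees all candidates
        worst = max(gc[i] - gcs[lo], gcs[hi] - gc[i])
        while lo > 0 and gc[i] - gcs[lo - 1] <= worst:
            lo -= 1
        while hi < m - 1 and gcs[hi + 1] - gc[i] <= worst:
            hi += 1
        cand = order[lo : hi + 1]
        key = np.lexsort((cand, np.abs(cand - i), np.abs(gc[cand] - gc[i])))
        out[i] = np.sort(cand[key[:k_eff]])
    return out


def gc_correct(
    track: CountTrack,
    windows: WindowSet,
    k: int = 100,
    return_model: bool = False,
) -> CountTrack | tuple[CountTrack, GCCorrectionModel]:
    """Apply the GC-nearest-neighbor median correction to a count track."""
    if len(track) != len(windows):
        raise ValueError("track and window set length mismatch")
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = track.counts
    valid = np.isfinite(counts) & np.isfinite(windows.gc)
    if not valid.any() or np.nansum(np.abs(counts)) == 0:
        raise ValueError("all-zero or all-missing track cannot be GC-corrected")
    n_valid = int(valid.sum())
    if k > n_valid:
        warnings.warn(
            f"k={k} exceeds the {n_valid} usable windows; clamping k to {n_valid}",
            stacklevel=2,
        )
        k = n_valid
    n_med = float(np.median(counts[valid]))
    neighbors = gc_neighbors(windows.gc, k, valid=valid)
    n_medgc = np.full(len(track), np.nan)
    corrected = np.full(len(track), np.nan)
    for i in np.flatnonzero(valid):
        med = float(np.median(counts[neighbors[i]]))
        n_medgc[i] = med
        if med > 0:
            corrected[i] = n_med * counts[i] / med
    n_zero = int((n_medgc == 0).sum())
    if n_zero:
        log.info("%d window(s) with zero neighborhood median flagged as missing", n_zero)
    out = replace(track, counts=corrected, state=STATE_GC)
    if return_model:
        return out, GCCorrectionModel(k=k, n_med=n_med, neighbor_map=neighbors, n_medgc=n_medgc)
    return out
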