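"""Synthetic genomes, chromatin tracks and biased read sets.

The generator encodes an explicit causal model of DNA-isolation retrieval
bias so that every pipeline stage can be tested against known truth:

* Genomes have isochore structure: a mean-reverting (AR(1)) GC target track
  with a configurable autocorrelation length, clipped to a GC range, from
  which bases are drawn independently per position.  Repeat intervals are
  placed at a configurable total density.
* Each tissue gets a chromatin-compaction track H in [0, 1]: a shared smooth
  baseline plus an independent smooth per-tissue perturbation scaled by
  ``tissue_divergence``, optionally coupled to (1 − GC) to mimic the
  association of compact chromatin with GC-poor isochores.
* Fragment retrieval probability per window is

      w_i ∝ copy_factor_i · f_GC(gc_i) · exp(−β(τ) · H_i),

  with β(τ) = beta0 · exp(−τ / tau0) so that longer proteinase-K lysis
  (larger τ, in minutes) shrinks the chromatin-dependent bias toward the
  unbiased limit, and f_GC a unimodal library-prep efficiency curve
  (default quadratic with peak at GC 0.45 and floor 0.3; set
  ``gc_bias=None`` for a flat control).  Reads are drawn multinomially over
  windows and uniformly within each window's accessible bases.
* Germline copy-number differences between "strains" are planted through
  ``cnv_list``; a window's copy factor is overlap-weighted.

Everything is deterministic given the config seed; independent substreams
are derived per library so adding a library never perturbs another.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .coverage import ReadSet
from .windows import AccessibilityMask, WindowSet, annotate_gc, build_mask, partition_accessible

OVERNIGHT_MIN = 1440  # "overnight" lysis encoded as 24 h in minutes

PRESETS = ("tiny", "gc-only", "chromatin-only", "lysis-series", "two-strain-cnv")


@dataclass(frozen=True)
class CNV:
    chrom: str
    start: int
    end: int
    copy_factor: float
    strain: str


@dataclass
class SimConfig:
    """Study conditions for the retrieval-bias simulator.

    Defaults describe a desk-scale two-tissue, single-strain study on a
    3.5 Mb two-chromosome genome with rat-like GC range and moderate repeat
    content; libraries of 500 k reads give roughly 700 reads per 5 kb
    accessible window, deep enough that the bias signal dominates counting
    noise without slowing the test suite.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 1_500_000}
    )
    isochore_scale: int = 300_000  # GC autocorrelation length, bp
    gc_range: tuple[float, float] = (0.30, 0.60)
    repeat_density: float = 0.25
    n_tissues: int = 2
    tissue_divergence: float = 0.8  # scale of per-tissue compaction perturbation
    compaction_gc_weight: float = 0.5  # 0 = compaction independent of GC
    gc_bias: dict | None = field(
        default_factory=lambda: {"peak": 0.45, "scale": 4.0, "floor": 0.3}
    )
    beta0: float = 1.5  # chromatin bias strength at τ = 0
    tau0: float = 60.0  # lysis decay constant, minutes
    lysis_times: tuple[float, ...] = (10, 30, 60, 120, OVERNIGHT_MIN)
    cnv_list: tuple[CNV, ...] = ()
    n_reads: int = 500_000
    window_size: int = 5_000  # accessible bp per window for truth tracks
    seed: int = 0

    def f_gc(self, gc: np.ndarray) -> np.ndarray:
        """Library-prep GC efficiency curve; flat (1.0) when gc_bias is None."""
        gc = np.asarray(gc, dtype=float)
        if self.gc_bias is None:
            return np.ones_like(gc)
        peak = self.gc_bias.get("peak", 0.45)
        scale = self.gc_bias.get("scale", 4.0)
        floor = self.gc_bias.get("floor", 0.3)
        return np.maximum(floor, 1.0 - scale * (gc - peak) ** 2)

    def beta(self, tau: float) -> float:
        """Residual chromatin bias after τ minutes of lysis."""
        if tau < 0:
            raise ValueError("lysis time must be >= 0")
        return float(self.beta0 * np.exp(-tau / self.tau0))


def _rng(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *[int(k) for k in key]])


def _ar1_track(rng: np.random.Generator, n: int, phi: float, mu: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series of length n with lag-1 coefficient phi."""
    eps = rng.normal(0.0, sd * np.sqrt(max(1.0 - phi**2, 1e-12)), size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return mu + x


GC_BIN = 200  # bp resolution of the GC target track


def simulate_genome(
    config: SimConfig,
) -> tuple[dict[str, str], dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Draw an isochore-structured genome.

    Returns (genome sequences, repeat intervals per chromosome, per-bin GC
    target track per chromosome at :data:`GC_BIN` resolution).
    """
    lo, hi = config.gc_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"gc_range must be within [0, 1], got {config.gc_range}")
    mu = 0.5 * (lo + hi)
    sd = (hi - lo) / 4.0
    phi = float(np.exp(-GC_BIN / max(config.isochore_scale, 1)))
    genome: dict[str, str] = {}
    repeats: dict[str, np.ndarray] = {}
    gc_target: dict[str, np.ndarray] = {}
    base_lut = np.frombuffer(b"ATGC", dtype=np.uint8)
    for ci, (chrom, length) in enumerate(config.chrom_lengths.items()):
        rng = _rng(config, 0, ci)
        n_bins = int(np.ceil(length / GC_BIN))
        track = np.clip(_ar1_track(rng, n_bins, phi, mu, sd), lo, hi)
        gc_target[chrom] = track
        p = np.repeat(track, GC_BIN)[:length]
        is_gc = rng.random(length) < p
        second = rng.random(length) < 0.5  # G vs C / A vs T
        codes = base_lut[(is_gc.astype(np.uint8) << 1) | second.astype(np.uint8)]
        genome[chrom] = codes.tobytes().decode("ascii")
        repeats[chrom] = _place_repeats(rng, length, config.repeat_density)
    return genome, repeats, gc_target


def _place_repeats(rng: np.random.Generator, length: int, density: float) -> np.ndarray:
    """Random repeat intervals whose union covers ~``density`` of the
    chromosome.  Lengths are lognormal (median 300 bp)."""
    from .windows import merge_intervals

    if density <= 0:
        return np.empty((0, 2), dtype=np.int64)
    target = int(density * length)
    merged = np.empty((0, 2), dtype=np.int64)
    union = 0
    intervals: list[tuple[int, int]] = []
    while union < target:
        n_draw = max(16, (target - union) // 350)
        starts = rng.integers(0, length, size=n_draw)
        lens = np.maximum(50, rng.lognormal(np.log(300), 0.8, size=n_draw).astype(np.int64))
        intervals.extend(
            (int(s), min(int(s) + int(ln), length)) for s, ln in zip(starts, lens)
        )
        merged = merge_intervals(intervals)
        union = int((merged[:, 1] - merged[:, 0]).sum())
    return merged


def simulate_compaction(config: SimConfig, windows: WindowSet) -> dict[str, np.ndarray]:
    """Per-tissue chromatin-compaction tracks H ∈ [0, 1] on the window grid.

    H = logistic(w·z_gc + (1 − w)·z_base + divergence·z_tissue) where z_gc is
    the standardized *negative* GC (compact chromatin sits in GC-poor
    isochores when ``compaction_gc_weight`` > 0), z_base a shared smooth
    track and z_tissue an independent smooth perturbation per tissue.
    """
    n = len(windows)
    gc = windows.gc
    gc_filled = np.where(np.isfinite(gc), gc, np.nanmean(gc))
    z_gc = -(gc_filled - gc_filled.mean()) / max(gc_filled.std(), 1e-9)
    rng = _rng(config, 1)
    z_base = _ar1_track(rng, n, 0.95, 0.0, 1.0)
    z_base = (z_base - z_base.mean()) / max(z_base.std(), 1e-9)
    w = config.compaction_gc_weight
    tracks: dict[str, np.ndarray] = {}
    for t in range(config.n_tissues):
        rng_t = _rng(config, 1, t + 1)
        z_t = _ar1_track(rng_t, n, 0.9, 0.0, 1.0)
        z_t = (z_t - z_t.mean()) / max(z_t.std(), 1e-9)
        raw = w * z_gc + (1.0 - w) * z_base + config.tissue_divergence * z_t
        tracks[f"tissue{t + 1}"] = 1.0 / (1.0 + np.exp(-raw))
    return tracks


def copy_factor_track(config: SimConfig, windows: WindowSet, strain: str) -> np.ndarray:
    """Per-window copy factor for a strain, overlap-weighted over cnv_list."""
    cf = np.ones(len(windows))
    table = windows.table
    for cnv in config.cnv_list:
        if cnv.strain != strain:
            continue
        sel = table["chrom"] == cnv.chrom
        ov = np.minimum(table["end"], cnv.end) - np.maximum(table["start"], cnv.start)
        frac = np.clip(ov / (table["end"] - table["start"]), 0, 1) * sel
        cf *= 1.0 + (cnv.copy_factor - 1.0) * frac.to_numpy()
    return cf


@dataclass
class SimTruth:
    """Ground truth for one simulated study."""

    windows: WindowSet
    compaction: dict[str, np.ndarray]
    copy_factor: dict[str, np.ndarray]
    expected_share: dict[str, np.ndarray] = field(default_factory=dict)
    beta: dict[str, float] = field(default_factory=dict)


def expected_weights(
    config: SimConfig,
    windows: WindowSet,
    compaction: np.ndarray,
    tau: float,
    strain: str = "A",
) -> np.ndarray:
    """Unnormalized per-window retrieval weights of the bias model."""
    gc = windows.gc
    ok = np.isfinite(gc) & (windows.table["accessible_bp"].to_numpy() > 0)
    beta = config.beta(tau)
    cf = copy_factor_track(config, windows, strain)
    w = np.where(ok, cf * config.f_gc(np.where(ok, gc, 0.5)) * np.exp(-beta * compaction), 0.0)
    return w


def simulate_reads(
    windows: WindowSet,
    compaction: np.ndarray,
    config: SimConfig,
    tau: float,
    strain: str = "A",
    stream: int = 0,
    n_reads: int | None = None,
) -> tuple[ReadSet, np.ndarray]:
    """Draw a read set under the retrieval-bias model.

    Reads are multinomial over windows with the model weights, then uniform
    over each window's accessible bases.  Returns (reads, expected share per
    window).  ``stream`` separates libraries sharing one config seed.
    """
    if tau < 0:
        raise ValueError("lysis time must be >= 0")
    n_reads = config.n_reads if n_reads is None else n_reads
    w = expected_weights(config, windows, compaction, tau, strain)
    total = w.sum()
    if total <= 0:
        raise ValueError("all window weights are zero; nothing to sample")
    p = w / total
    rng = _rng(config, 2, stream)
    counts = rng.multinomial(n_reads, p)
    table = windows.table
    positions: dict[str, list[np.ndarray]] = {c: [] for c in windows.chroms()}
    for chrom, sub in table.groupby("chrom", sort=False):
        acc = windows.mask.accessible[chrom]
        for row, c in zip(sub.itertuples(), counts[sub.index]):
            if c == 0:
                continue
            lo = np.searchsorted(acc[:, 1], row.start, side="right")
            hi = np.searchsorted(acc[:, 0], row.end, side="left")
            seg = acc[lo:hi].copy()
            if seg.shape[0] == 0:
                continue
            seg[0, 0] = max(seg[0, 0], row.start)
            seg[-1, 1] = min(seg[-1, 1], row.end)
            lens = seg[:, 1] - seg[:, 0]
            cum = np.concatenate(([0], np.cumsum(lens)))
            offs = rng.integers(0, cum[-1], size=c)
            j = np.searchsorted(cum, offs, side="right") - 1
            positions[chrom].append(seg[j, 0] + (offs - cum[j]))
    reads = ReadSet(
        positions={
            c: np.sort(np.concatenate(parts)) if parts else np.empty(0, dtype=np.int64)
            for c, parts in positions.items()
        }
    )
    return reads, p


def simulate_study(config: SimConfig, libraries: list[dict]) -> dict:
    """Run the full generator: genome → mask → windows → compaction → reads.

    ``libraries`` is a list of dicts with keys ``name, tissue, tau, strain``
    (and optional ``n_reads``).  Returns a dict with genome, repeats, mask,
    annotated windows, SimTruth and the read sets.
    """
    genome, repeats, _ = simulate_genome(config)
    mask = build_mask(genome, {c: list(map(tuple, iv)) for c, iv in repeats.items()})
    windows = annotate_gc(genome, partition_accessible(mask, config.window_size))
    compaction = simulate_compaction(config, windows)
    strains = {lib.get("strain", "A") for lib in libraries}
    truth = SimTruth(
        windows=windows,
        compaction=compaction,
        copy_factor={s: copy_factor_track(config, windows, s) for s in strains},
    )
    reads: dict[str, ReadSet] = {}
    for stream, lib in enumerate(libraries):
        tissue = lib.get("tissue", "tissue1")
        tau = float(lib.get("tau", 120))
        strain = lib.get("strain", "A")
        rs, share = simulate_reads(
            windows,
            compaction[tissue],
            config,
            tau,
            strain=strain,
            stream=stream,
            n_reads=lib.get("n_reads"),
        )
        reads[lib["name"]] = rs
        truth.expected_share[lib["name"]] = share
        truth.beta[lib["name"]] = config.beta(tau)
    return {
        "config": config,
        "genome": genome,
        "repeats": repeats,
        "mask": mask,
        "windows": windows,
        "truth": truth,
        "reads": reads,
    }


def _preset_spec(preset: str) -> tuple[SimConfig, list[dict]]:
    small = {"chr1": 1_200_000, "chr2": 800_000}
    if preset == "tiny":
        cfg = SimConfig(chrom_lengths=small, n_reads=150_000, seed=0)
        libs = [
            {"name": "tissue1_t120", "tissue": "tissue1", "tau": 120},
            {"name": "tissue2_t120", "tissue": "tissue2", "tau": 120},
        ]
    elif preset == "gc-only":
        cfg = SimConfig(chrom_lengths=small, beta0=0.0, n_tissues=1, n_reads=300_000, seed=0)
        libs = [{"name": "tissue1_t120", "tissue": "tissue1", "tau": 120}]
    elif preset == "chromatin-only":
        cfg = SimConfig(
            chrom_lengths=small,
            gc_bias=None,
            compaction_gc_weight=0.0,
            n_reads=300_000,
            seed=0,
        )
        libs = [
            {"name": "tissue1_t30", "tissue": "tissue1", "tau": 30},
            {"name": "tissue2_t30", "tissue": "tissue2", "tau": 30},
        ]
    elif preset == "lysis-series":
        cfg = SimConfig(seed=0)
        libs = []
        for tau in cfg.lysis_times:
            label = "ON" if tau >= OVERNIGHT_MIN else f"{int(tau)}min"
            libs.append({"name": f"tissue1_{label}", "tissue": "tissue1", "tau": tau})
            libs.append({"name": f"tissue2_{label}", "tissue": "tissue2", "tau": tau})
    elif preset == "two-strain-cnv":
        cfg = SimConfig(
            chrom_lengths=small,
            beta0=0.0,
            gc_bias=None,
            n_tissues=1,
            n_reads=400_000,
            cnv_list=(
                CNV("chr1", 300_000, 450_000, 1.5, "B"),
                CNV("chr2", 200_000, 300_000, 0.5, "B"),
            ),
            seed=0,
        )
        libs = [
            {"name": "strainA", "tissue": "tissue1", "tau": 120, "strain": "A"},
            {"name": "strainB", "tissue": "tissue1", "tau": 120, "strain": "B"},
        ]
    else:
        raise ValueError(f"unknown preset {preset!r}; choose one of {', '.join(PRESETS)}")
    return cfg, libs


def make_fixture_suite(preset: str, outdir: str | Path, seed: int | None = None) -> Path:
    """Write a complete fixture tree for a named preset.

    Emits genome FASTA, repeat BED, one read BED per library, truth tables
    (TSV) and a YAML manifest.  Output is byte-identical across runs for the
    same preset, seed and package version.
    """
    cfg, libs = _preset_spec(preset)
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_study(cfg, libs)
    files: dict[str, str] = {}

    def write(relpath: str, writer) -> None:
        path = out / relpath
        path.parent.mkdir(parents=True, exist_ok=True)
        writer(path)
        files[relpath] = hashlib.sha256(path.read_bytes()).hexdigest()

    write("genome.fa", lambda p: cio.write_fasta(study["genome"], p))
    write("repeats.bed", lambda p: cio.write_bed(study["repeats"], p))
    for name, rs in study["reads"].items():
        write(
            f"reads/{name}.bed",
            lambda p, rs=rs: cio.write_bed(
                {c: np.column_stack((a, a + 1)) for c, a in rs.positions.items()}, p
            ),
        )
    truth: SimTruth = study["truth"]
    tt = study["windows"].table.copy()
    for tissue, h in truth.compaction.items():
        tt[f"H_{tissue}"] = h
    for strain, cf in truth.copy_factor.items():
        tt[f"copy_factor_{strain}"] = cf
    for name, share in truth.expected_share.items():
        tt[f"share_{name}"] = share
    write(
        "truth/windows.tsv",
        lambda p: cio.write_track_tsv(tt, p, params={"preset": preset, "seed": cfg.seed}),
    )
    if cfg.cnv_list:
        cnv_df = pd.DataFrame([dataclasses.asdict(c) for c in cfg.cnv_list])
        write("truth/cnv.tsv", lambda p: cio.write_track_tsv(cnv_df, p, params={}))
    manifest = {
        "preset": preset,
        "seed": int(cfg.seed),
        "beta": {name: float(b) for name, b in truth.beta.items()},
        "libraries": [lib["name"] for lib in libs],
        "files": files,
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return out
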