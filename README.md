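# covbias

Depth-of-coverage bias analysis for low-pass whole-genome sequencing and
aCGH-style data, paired with a simulator of the DNA-isolation retrieval
artifact that produces megabase-scale "wave" patterns in such data.

## The problem

Copy-number analyses assume equimolar DNA representation: every locus
contributes material in proportion to its copy number. In practice,
per-window read depth shows reproducible megabase-scale waves that correlate
with GC content, replication timing, SINE and gene density — all proxies of
chromatin state — and that differ between tissues of the same animal.
Incomplete release of protein-bound DNA during isolation (short proteinase-K
lysis) preferentially depletes compact heterochromatin, and the artifact
shrinks as lysis is extended. Such waves masquerade as somatic CNVs unless
they are measured and corrected.

`covbias` implements the analysis side (windowing, counting, normalization,
GC correction, evenness metrics, differential segmentation, feature
correlation) and a generative model of the artifact so every stage can be
validated against known truth.

## Core methods

**Windowing.** The genome is partitioned into windows each containing a fixed
amount of usable sequence: `W` bp of NGS-accessible (non-repeat, non-gap)
sequence (default 20 kb) for fragment-library depth analysis, or `S` bp of
non-gap sequence (default 100 kb) for low-pass mate-pair data. Reads are
assigned to windows by start position; libraries are depth-matched by RPM
scaling, random downsampling to a common read count, or cross-sample
quantile normalization.

**GC correction.** Each window *i* is normalized against the *k* = 100
windows with the most similar GC content:

```
N_corr(i) = N_med · N_obs(i) / N_medGC(i)
```

with `N_obs` the observed count, `N_medGC` the median count over the GC
neighborhood, and `N_med` the library-wide median.

**Bias metrics.** Evenness histograms (number of windows vs reads per
window), dispersion summaries (sd, IQR, MAD, CV), between-tissue difference
distributions, and 100-value blockwise median smoothing for display.

**Differential segments.** Per-window log2 ratios
`L_i = log2((a_i + 0.5)/(b_i + 0.5))` are thresholded (a window is deviant
when its fold change deviates by ≥ 10%); same-direction runs tolerating one
interleaved neutral window and holding ≥ 3 deviant windows become segments,
and total affected megabases are reported.

**Feature correlations.** BED interval tracks (SINE, gene annotations)
become fraction-covered per window, bedGraph signals (replication timing)
become span-weighted means, and Pearson r (with nominal t-based p-values)
is reported per feature.

**Simulator.** Windows receive retrieval weights
`w_i ∝ copy_factor_i · f_GC(gc_i) · exp(−β(τ)·H_i)` where `H` is a per-tissue
chromatin-compaction track in [0, 1] and `β(τ) = β₀·exp(−τ/τ₀)` decays with
lysis duration τ; reads are drawn multinomially. Presets cover a lysis time
series (10, 30, 60, 120 min, overnight), GC-only and chromatin-only
controls, and a two-strain design with planted CNVs.

## Worked example

Simulate a two-tissue study at two lysis durations and compare tissues
after GC correction:

```python
import covbias as cb
from covbias.simulate import SimConfig, simulate_study
from covbias.metrics import dispersion
from covbias.gc_correct import gc_correct

cfg = SimConfig(seed=7)
st = simulate_study(cfg, [
    {"name": "brain_30min", "tissue": "tissue1", "tau": 30},
    {"name": "liver_30min", "tissue": "tissue2", "tau": 30},
    {"name": "brain_ON", "tissue": "tissue1", "tau": 1440},
    {"name": "liver_ON", "tissue": "tissue2", "tau": 1440},
])
ws = st["windows"]
print(f"windows: {len(ws)} ({cfg.window_size} accessible bp each)")
for tau in ("30min", "ON"):
    a = cb.count_reads(ws, st["reads"][f"brain_{tau}"])
    b = cb.count_reads(ws, st["reads"][f"liver_{tau}"])
    ratio = cb.log2_ratio(gc_correct(a, ws), gc_correct(b, ws))
    segs = cb.segment_differential(ratio, ws, threshold=0.10)
    print(f"tau={tau}: count sd {dispersion(a).sd:.1f}, cv {dispersion(a).cv:.3f}, "
          f"{len(segs)} differential segments, {cb.total_affected_mb(segs):.3f} Mb affected")
```

Output:

```
windows: 520 (5000 accessible bp each)
tau=30min: count sd 196.4, cv 0.204, 28 differential segments, 1.924 Mb affected
tau=ON: count sd 41.5, cv 0.043, 0 differential segments, 0.000 Mb affected
```

After a short 30-min lysis the chromatin bias is strong: per-window counts
are over-dispersed (cv 0.20) and 1.9 Mb of the 2.6 Mb accessible genome
would be called "differential" between the two tissues at the 10% level even
after GC correction. With overnight lysis the bias decays, the count
distribution tightens to near counting noise, and no differential segments
remain — the artifact, not real copy number, drove the calls.

The same stages are available from a shell:

```sh
covbias simulate --preset lysis-series --out fixtures/
covbias windows --genome fixtures/genome.fa --repeats fixtures/repeats.bed \
    --mode accessible --size 20000 --out windows.bed
covbias count --windows windows.bed.tsv --reads fixtures/reads/tissue1_30min.bed \
    --out counts.tsv
covbias gccorrect --counts counts.tsv --windows windows.bed.tsv --k 100 \
    --out corrected.tsv
covbias run --config pipeline.yaml   # full pipeline from YAML
```

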