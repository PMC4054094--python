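# Methods

This note documents the models and procedures implemented in `covbias`, the
parameter choices that matter, and what the synthetic-data experiments do
and do not demonstrate.

## Windowing

Windows are defined by accumulation: scanning a chromosome's accessible
intervals left to right, a boundary is cut exactly when the accumulated
usable base count reaches the window size. Two modes share this rule and
differ only in what "usable" means:

* **accessible-content** (default size `W` = 20 000 bp): usable = outside
  repeats and outside runs of N in the assembly. This is the grid for
  fragment-library depth comparisons.
* **genomic-span** (default size `S` = 100 000 bp): usable = outside
  N-runs only; repeats count toward the total, so a window's genomic span
  exceeds `S` only where it straddles assembly gaps.

Design choices that the data formats do not force:

* Window spans *abut* within a chromosome (each window starts where the
  previous one ends), so every read falling between the first and last
  accessible base is attributable to exactly one window. Reads upstream of
  the first window or downstream of the last are discarded and counted in
  the log.
* The terminal remainder of a chromosome is kept as a window iff it holds
  at least half the target size. The half rule bounds the count-variance
  distortion a short window would otherwise introduce (a window with half
  the accessible content has double the relative Poisson noise); smaller
  remainders are dropped and logged.
* Coordinates are 0-based half-open everywhere, BED dialect on disk.

GC per window is computed over accessible unambiguous bases:
(#G+#C)/(#A+#C+#G+#T). Windows with no such base get `gc = NaN` and are
excluded from GC correction and ratios.

## Counting and normalization

A read belongs to the window whose span contains its *start* position
(half-open, deterministic, standard single-position depth-of-coverage
practice; midpoint or fractional-overlap assignment would change counts
only at window boundaries). PCR-duplicate-flagged reads are dropped when a
read set is constructed and never counted.

Depth matching across libraries is by any of:

* **RPM**: counts × 10⁶ / library size.
* **Downsampling**: a uniform random subset of exactly the target number of
  reads, without replacement (the per-window kept counts are then
  multivariate hypergeometric — this is verified by a chi-square
  goodness-of-fit test over 200 replicate seeds). Every stochastic
  operation takes an explicit seed; there is no hidden global RNG state.
* **Quantile normalization** across ≥ 2 tracks: the value at rank r is
  replaced by the mean across tracks of the rank-r values; ties receive
  the mean over their rank range. With ties present the output multisets
  can differ slightly between tracks (the tie-group mean is not itself an
  order statistic); for tie-free inputs all outputs share one sorted value
  vector exactly.

## GC correction

`N_corr(i) = N_med · N_obs(i) / N_medGC(i)`, where `N_medGC(i)` is the
median count over the k = 100 windows most similar in GC and `N_med` the
median over all windows of the library, computed per library. Decisions:

* The window itself is a member of its own neighborhood. This makes the
  degenerate case (all windows identical) an exact identity and avoids an
  asymmetry at the GC extremes.
* Ties in |ΔGC| are broken by genomic proximity |Δindex|, then by index, so
  neighbor sets are deterministic and reproducible. The implementation is
  checked bit-exactly against a brute-force sort-everything oracle,
  including tie-heavy quantized-GC instances.
* Even-length medians are the mean of the two central values.
* A zero neighborhood median makes the window uncorrectable: it is flagged
  missing (NaN) rather than mapped to infinity, and excluded downstream.
* k larger than the usable window count is clamped with a warning; an
  all-zero track is an error.

The correction recenters but does not rescale (the median of corrected
counts stays within a few percent of `N_med`) and is linear in the counts.
By construction it removes *any* smooth GC-indexed trend, but nothing that
is GC-independent — which is precisely why a chromatin-driven bias survives
it (see below).

## Evenness metrics

Per-window count histograms use bins `[m·w, (m+1)·w)`. Scalar dispersion:
sample sd (ddof = 1), IQR with linear interpolation between order
statistics (quantile type 7, stated so results are bit-reproducible),
unscaled MAD, and CV = sd/mean. Tissue differences are summarized by the
histogram and sd of per-window count differences between depth-matched
libraries. Display smoothing reduces non-overlapping blocks of k = 100
consecutive values to their median (one point per block; the terminal block
is kept iff it holds ≥ k/2 values); callers smooth per chromosome.

## Differential segmentation

Per-window `L_i = log2((a_i + c)/(b_i + c))` with pseudocount c = 0.5 for
stability at low counts. A window is deviant-up when `2^L ≥ 1 + t` and
deviant-down when `2^L ≤ 1 − t` (default t = 0.10, i.e. a 10% apparent
copy-number difference). Maximal same-direction runs are merged, tolerating
up to `max_gap` = 1 interleaved non-deviant window (opposite-direction
deviants always break a run); runs with ≥ `min_windows` = 3 deviant windows
become segments spanning first-to-last deviant window, so reported affected
megabases are conservative. Raising the threshold can never increase the
affected total.

**Sensitivity at the threshold.** When a region's true fold change equals
the calling threshold exactly (e.g. a 1.10 copy factor called at t = 0.10),
each in-region window is classified deviant with probability approaching
1/2 *at any sequencing depth* — the classification margin is zero and
sampling noise decides each window. Recovery of such a region as one
contiguous segment is therefore unreliable by construction; reliable
recovery requires the true effect to exceed the threshold (a 1.25-fold
region is recovered essentially perfectly at t = 0.10 under the same
conditions). This is a property of any per-window threshold rule, not of
the implementation.

## Feature correlations

Interval features (BED) become fraction-of-span-covered per window; signal
features (bedGraph) become span-length-weighted means, missing where no
signal overlaps. Pearson r is computed over pairwise-complete windows with
a two-sided p from the t distribution (n − 2 df). These p-values are
*nominal*: adjacent windows are strongly autocorrelated, so they overstate
significance; they are reported for orientation, not inference.

## The retrieval-bias simulator

The generator encodes the causal model under test — chromatin-dependent DNA
retrieval during isolation — at window resolution:

* **Genome.** A per-200-bp GC target track follows a stationary AR(1)
  (mean-reverting) process whose lag-1 coefficient is `exp(−200/isochore_scale)`
  (default autocorrelation length 300 kb), clipped to `gc_range` (default
  0.30–0.60, rat-like); bases are drawn independently per position. Repeat
  intervals with lognormal lengths (median 300 bp) are placed to a target
  union density (default 25%). Repeats mask windows but do not change the
  sequence composition model.
* **Compaction.** Per tissue, `H = logistic(w·z_gc + (1−w)·z_base + d·z_t)`
  with `z_gc` the standardized negative GC (weight `w` = 0.5 by default,
  mirroring the association of compact chromatin with GC-poor isochores;
  `w` = 0 gives GC-independent compaction for controls), `z_base` a shared
  smooth AR track, and `z_t` an independent smooth per-tissue perturbation
  scaled by `tissue_divergence` (default 0.8, which puts between-tissue
  compaction correlation around 0.6 — distinct but related tissues).
* **Retrieval.** Window weights `w_i ∝ copy_factor_i · f_GC(gc_i) ·
  exp(−β(τ)·H_i)`; reads are multinomial over windows and uniform within a
  window's accessible bases. `f_GC` is a quadratic efficiency curve peaking
  at GC 0.45 with floor 0.3 (the shape of standard library-prep GC curves;
  `None` gives a flat control). `β(τ) = β₀·exp(−τ/τ₀)` is the simplest
  one-parameter monotone decay consistent with the qualitative observation
  that longer lysis evens out coverage; β₀ = 1.5 and τ₀ = 60 min place the
  10-min condition in a strongly biased regime and the overnight condition
  (encoded as τ = 1440 min) at effectively zero chromatin bias. The true
  functional form of the lysis dependence is unknown; this is an explicit
  modeling choice, config-overridable.
* **CNVs.** Planted per strain; a window's copy factor is weighted by its
  span overlap with the CNV.

Default problem sizes (3.5 Mb genome, 5 kb accessible windows giving ~520
windows, 500 k reads per library ≈ 950 reads/window) were chosen so that
the bias signal dominates counting noise while a full multi-library study
simulates in seconds; they are scaled-down analogues of a 2.5 Gb genome at
20 kb windows and 10 M reads.

**What the simulator does not model:** sequencing errors and quality,
mappability beyond the binary mask, fragment-level GC effects within
windows, mate-pair insert structure, true somatic mosaicism, and any
genome available only by download. Passing recovery tests therefore shows
the *analysis machinery* is correct and calibrated under the stated
generative model, not that real tissues obey that model quantitatively.

## Pipeline and reproducibility

The `run` pipeline (YAML-configured) executes windows → counts →
downsampling to a common depth → GC correction → evenness metrics →
pairwise segmentation → feature correlations. All tabular outputs are TSV
with `#` comment headers recording version and parameters; a manifest of
SHA-256 hashes of all outputs is written, and two runs with the same config
are byte-identical (verified in tests). Stages are cached on (input hash,
parameters) signatures; the run log and cache file are excluded from the
manifest so logging never breaks determinism checks.

## Known limitations

* The per-window threshold segmenter has the zero-margin sensitivity
  property described above; effects at or just below the threshold are
  detected erratically. A likelihood-based or circular-binary-segmentation
  caller would pool information across windows but is out of scope.
* GC correction assumes counts are exchangeable within a GC stratum; a
  bias that varies along the chromosome at fixed GC (as chromatin bias
  does) is untouched by design.
* Quantile normalization forces identical marginal distributions and will
  erase genuine global differences in dispersion if applied across
  conditions; it is intended for depth matching within a comparison.
* Correlation p-values ignore window autocorrelation (stated above).
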