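# Methods

This note documents the models, parameter choices and numerical policies of
the `mitobook` pipeline, and what its synthetic-data validation does and does
not establish about real data.

## Coordinates and units

Internally all coordinates are 0-based half-open; BED files keep that
convention, while human-readable reports (fragment coordinates, gene tables)
are 1-based inclusive. The conversion happens once, in `mitobook.io`. A *tag*
is a read's 5′-most mapped position; depth normalization is reads per
million: `rpm(k, N) = k·10⁶/N`.

## Peak calling

The caller is a transparent reimplementation of windowed Poisson peak
calling against a matched input, parameterized as published work in this
area typically runs it (p < 10⁻⁴, FDR 0.001, 1 RPM floor, 200-bp size). It
is not intended to be bit-compatible with any external tool; its test
surface is an exhaustive window-enumeration oracle.

* **Windows.** Width `w = 200` bp, stride `w/2`. Per window,
  `λ = max(r·k_input, N·w/G, 0.5)` with depth ratio `r`, ChIP depth `N`,
  genome size `G`. The 0.5-tag floor guards against `p = 0` artifacts in
  input deserts. The upper-tail probability uses the regularized incomplete
  gamma function (scipy), exact and stable beyond λ = 10⁴.
* **Greedy resolution and minimum peak distance.** Candidates (p < cutoff)
  are accepted by ascending p (ties: leftmost start, then chromosome name),
  and an accepted peak suppresses later candidates within **2w**. One
  binding event spreads tags over roughly twice the window width, so a
  nearer secondary window is the tail of the same event; without this
  suppression, satellite windows at ±w of strong sites are emitted as
  spurious secondary peaks and corrupt downstream pairing.
* **FDR control.** At threshold t the estimated FDR is
  `max(n_swap(t), n_windows·t)/n_forward(t)`: the sample-swap estimate
  (calling input against ChIP) and the Poisson expected false-positive
  count. The swap term alone cannot reject an isolated background window
  whose p undercuts every swapped p (the estimate collapses to 0/1); the
  expected-count term handles exactly that regime. The largest t meeting the
  target is used; identical ChIP and control therefore yield zero peaks.
* **Peak center.** Default is a mean-shift estimate: iterate the mean of the
  tags inside a window of `2.5w` (500 bp) re-centered on the current
  estimate until it moves < 0.5 bp, clipped into the fixed peak interval.
  A plain window-midpoint center (available as `center_mode =
  "window_midpoint"`) is quantized to the 100-bp stride grid, which makes
  center-to-center distances multiples of 100 bp and a 50-bp shift histogram
  meaningless. The refinement window is deliberately wider than the peak
  window: truncating the tag cloud both biases the local mean toward the
  initial grid offset and amplifies its sampling noise by ≈1/(1−ρ), where ρ
  is the fraction of the cloud crossing the window edges; at 2.5w the cloud
  is fully covered and center error is ≈ σ/√n (≈10 bp at the default
  simulation depth).
* **1 RPM floor.** Applied to the peak-window tag total, last. Whether such
  a height floor should read total or density is a policy choice; total is
  implemented and documented here.

## Differential classification

Both peak sets are tested against the other condition as background. For a
peak with own-region count `k₁` (depth `N₁`) and other-condition count `k₂`
(depth `N₂`) in the 200-bp region around its center:

* specific ⇔ `k₁/N₁ > 4·(k₂ + 0.5)/N₂` (strict, evaluated cross-multiplied
  so the boundary case is exact in floating point) **and**
  `P(Pois((k₂ + 0.5)·N₁/N₂) ≥ k₁) < 10⁻⁴`;
* all remaining peaks are common. Common peaks of the two calls with centers
  within 200 bp (the comparison width) are paired one-to-one, nearest first;
  unpaired non-specific peaks stay common with an absent partner. Common
  entries are referenced to the asynchronous center (a flag switches to
  mitotic centering, which also re-centers the motif-content windows).

The 0.5-tag pseudocount (depth-scaled) and the pairing rule are module
policy; the source analyses this follows do not state them.

## Shift analysis

Nearest-peak distances are center-to-center (peak widths are fixed by the
caller, so edge-to-edge adds nothing) and binned every 50 bp; distances
beyond 10 kb are reported as a separate overflow count rather than silently
binned or dropped. Paired common peaks with center displacement in
[50, 250] bp are flagged as shifted: below 50 bp (one bin) displacement is
indistinguishable from center-call jitter; 250 bp is where the empirical
excess of close-but-displaced peak pairs ends in the motivating data.

## Motif scanning and enrichment

IUPAC consensus matching is exact per position (N in a sequence matches
nothing); minus-strand hits are found by scanning the forward sequence with
the reverse-complemented pattern, so coordinates are already plus-strand.
For palindromic consensi a plus/minus pair at one position is one element
and reported once. PWMs (JASPAR-style count matrices) are scored as log-odds
against a uniform background with a threshold of 80 % of the maximum
achievable score, exposed as a parameter.

No CTCF matrix is shipped: the motivating work displays but does not print
one, and fabricating it would misrepresent the source. The generator and
fixtures use a synthetic 12-bp "CTCF-like" consensus (`CCACTAGGGGGC`, the
core of a printed CTCF-motif EMSA oligo); real analyses should supply a
measured matrix file.

Enrichment is a resampling test: observed = fraction of peak windows
(default 200 bp) containing ≥1 match; null = the same statistic over
`n_resamples` sets of equally many windows drawn uniformly from the genome
excluding peak windows; `p = (1 + #{null ≥ obs})/(1 + n)`, so the smallest
attainable p is `1/(1+n)`. This tests known-motif enrichment only — it is
not motif discovery.

## Genomic annotation

Priority order promoter (TSS −1000…+100), TTS (−100…+1000), exon, intron,
dTSS (TSS −10000…+1000), intergenic; windows are strand-relative (positive =
downstream of transcription) and inclusive at both ends; peaks are
classified by their center point, the only convention under which a priority
scheme is unambiguous. dTSS contains the promoter window by construction;
the priority order resolves the overlap. Ties among genes within a category
break by nearest TSS, then gene id. One TSS/TTS per gene record;
transcript-level annotation is out of scope.

## Image quantification

Per cell: five region means per compartment, compartment value = mean of the
five region means (region-level averaging; pixel-pooling is the undocumented
alternative), background subtracted, ratio of corrected chromatin to
corrected nucleocytoplasm. A non-positive corrected nucleocytoplasm is an
error (failed background or saturation), not a ratio. Groups are mean ± SEM
(sample SD/√n; SEM = 0 flagged when n = 1). The ratio is invariant to adding
a constant to every pixel and to rescaling all intensities, and both
invariances are tested.

## The synthetic-data generator

The generator emulates the study design, not sequencing physics:

* **Genome:** 2 × 1.5 Mb chromosomes of uniform base composition, 60
  non-overlapping genes (2–10 kb, 1–3 exons). Real mammalian genomes are
  ~1000× larger with non-uniform composition and repeats; nothing here
  models mappability or GC bias.
* **Sites:** 200 common + 100 asynchronous-specific + 50 mitotic-specific +
  50 shifted, ≥2 kb apart (so ground truth is unambiguous), placed on a
  jittered lattice. A shifted site is one element whose enrichment center
  moves +150 bp in mitosis while its motif stays at the asynchronous center.
  Motifs are embedded at planting time (RBPJ 8-mer at the center, resolving
  the degenerate last position A/G uniformly under the seed unless pinned;
  CTCF-like 12-mer at +15 bp) with probabilities 0.20/0.16, matching the
  observed motif content scale of real occupancy sites.
* **Tags:** background uniform at 0.04 tags/bp per library; each active site
  adds Poisson((fold−1)·rate·2h) tags, normal offsets (σ = h/2, clipped at
  ±h, h = 200), so a site window's total expectation is fold × background
  and fold = 1 is exactly the null. Defaults give ~160 expected tags per
  site window and ~1.5×10⁵ tags per library — a desk-scale stand-in for
  ~35 M-read libraries chosen so that peak centers localize to ~10 bp,
  the precision a 50-bp shift histogram needs. Strand structure of real
  ChIP fragments (5′ offsets differing by strand) is not modeled; strands
  are assigned at random.
* **Images:** concentric chromatin disk / nucleocytoplasm annulus /
  background corners with exact planted compartment means and Gaussian
  pixel noise. Default levels (100/200 a.u., σ = 10) keep clipping at zero
  from ever triggering. The group simulation adds 10 % cell-to-cell scatter
  in the true ratio, so group SEMs have realistic magnitude.

Passing the recovery tests therefore shows the pipeline is correct and
well-calibrated under its own generative assumptions (well-separated sites,
Poisson backgrounds, known truth); it does not certify performance on real
libraries with duplicated reads, copy-number variation, or open-chromatin
input structure.

## Validation design

* Exhaustive/naive oracles: the peak caller against full window enumeration
  on ≤10-kb fixtures; the Poisson tail against direct summation (≤10⁻¹²);
  the consensus scanner against a per-position character-class check; the
  annotator against an all-(gene, category)-pairs classifier; nearest
  distances against the O(n·m) scan.
* Ground-truth recovery at the study scale above: ≥90 % of planted sites
  must recover their class, the recovered-shift modal 50-bp bin must contain
  150 bp (recovered distances are symmetric about exactly 150, the shared
  edge of two bins, so containment is checked with closed bin bounds), and
  ≥90 % of shifted sites must be flagged in [100, 200] bp.
* Null calibration: identical-condition classification yields zero specific
  peaks; enrichment p-values on null peaks behave sub-uniformly (the
  resampling p is discrete and conservative).
* Image recovery: planted ratios 1.0/1.6/3.6 recovered within 3 Monte-Carlo
  SE over 100 images each.

## Known limitations

Single-end tags only (no fragment-length inference); no duplicate-read
collapsing; no replicate-aware statistics
(conditions are treated as pooled libraries); no de novo motif discovery or
GO analysis; no automatic cell segmentation (ROIs are supplied or sampled
from known masks).
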