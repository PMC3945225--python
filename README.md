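# mitobook

Analysis pipeline for studying **mitotic bookmarking** by a sequence-specific
transcription factor — the retention of the Notch effector RBPJ on condensed
mitotic chromatin — from paired ChIP-seq experiments (asynchronous vs
nocodazole-arrested mitotic cells, each with a matched input library) and
from live-cell fluorescence images. It is written for computational
biologists who want every step of such an analysis as a tested, seeded,
reusable library, exercised end-to-end on synthetic data with planted ground
truth.

## What it computes

**Peak calling.** Fixed 200-bp windows at 100-bp stride are tested against a
local Poisson background. For a window with ChIP count *k*,

    λ = max(r·(input count), N·w/G, λ₀),    p = P(Pois(λ) ≥ k),

where *r* is the ChIP/input depth ratio, *N·w/G* the genome-wide expectation
and λ₀ = 0.5 a floor. Windows with p < 10⁻⁴ are resolved greedily by
ascending p with a minimum peak distance of 2w; the p threshold is then
tightened until the estimated FDR — the larger of the sample-swap count
(input called against ChIP) and the Poisson expected false-positive count,
divided by the number of peaks — is ≤ 0.001, and peaks below 1 RPM
(reads per million, `count·10⁶/N`) are dropped. Peak centers are refined by
an iterated local tag mean, so occupancy shifts finer than the window stride
are resolvable.

**Differential classification.** A peak is *condition-specific* when its
200-bp region is more than 4-fold enriched (strict, on depth-normalized
counts with a 0.5-tag pseudocount on the background side) over the other
cell population **and** Poisson p < 10⁻⁴ against the depth-scaled
other-population count; remaining peaks are *common* and are paired across
conditions (centers within 200 bp), referenced to the asynchronous center.
Retention is summarized as `common/(common + async-specific)` and its
complements.

**Shift analysis.** Distances from each asynchronous peak to its closest
mitotic peak, histogrammed every 50 bp; paired common peaks displaced by
50–250 bp are flagged as shifted occupancy sites.

**Motif content.** IUPAC-consensus and PWM scanning on both strands (RBPJ
consensus `TTCCCACR`, i.e. TTCCCAC(A/G)); per-class contingency tables of
RBPJ/CTCF motif content in 200-bp windows; known-motif enrichment tested
against length-matched windows resampled from the genome
(`p = (1 + #{null ≥ obs})/(1 + n_resamples)`).

**Genomic annotation.** Each peak center is assigned the first matching
category of: promoter (TSS −1 kb…+100 bp), TTS (−100 bp…+1 kb), exon,
intron, dTSS (TSS −10 kb…+1 kb), intergenic.

**Image quantification.** Per cell, mean eGFP intensity in five regions each
on mitotic chromatin, in the nucleocytoplasm and outside the cell; retention
ratio = (chromatin − background)/(nucleocytoplasm − background); groups
summarized as mean ± SEM.

**Synthetic data.** `mitobook.simulate` generates the genome, gene models,
planted common/specific/shifted binding sites with embedded motifs, tag
libraries, the three 147-bp nucleosome fragment designs, and noisy cell
images with a known retention ratio — all byte-reproducible under one seed.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (raw run data goes to `scratch/`, tables to `results/`):

```bash
for s in analysis/0*.py; do python "$s" --seed 1; done
```

prints, among other things:

```
simulated 400 sites; library depths: {'asynchronous': 170506, 'mitotic': 162845, 'input': 120368}
asynchronous: 350 peaks (depth 170506, 1 RPM = 0.17 tags)
mitotic: 300 peaks (depth 162845, 1 RPM = 0.16 tags)
classes: {'async_specific': 100, 'mitotic_specific': 50, 'common': 250, 'common_paired': 250}
flagged shifted common peaks (50-250 bp): 50; recovered planted shift median 152 bp
RBPJ enrichment in common peaks: 15.9-fold, p = 0.004975
RBPJ: 3.7 +/- 0.05 (n=30)
RBPJ-end: motif at [127]
```

Reading this: all 400 planted sites were called (350 asynchronous = 200
common + 100 asynchronous-specific + 50 shifted; 300 mitotic), every peak
received its planted class, the planted 150-bp mitotic shift is recovered at
152 bp median, the RBPJ motif is strongly enriched in common peaks at the
resampling resolution floor, the wild-type image group recovers its planted
chromatin/nucleocytoplasm ratio, and the end-positioned nucleosome fragment
carries its single consensus match starting at base 127 of 147.

The same stages are exposed as a CLI (`mitobook simulate | call-peaks |
classify | shift | motif | annotate | quantify | run`) for use on real tag
BED/SAM, FASTA and gene-table inputs.

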