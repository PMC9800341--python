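# Methods

## Scope and model overview

polwave implements two measurement procedures and their supporting
infrastructure:

* classification of genes by proximal vs distal polyadenylation-site (PAS)
  usage shifts between two conditions, from single-base long-read 3′ ends;
* Pol II elongation-rate estimation from DRB/TT-seq release time courses,
  by regressing nascent-RNA wave-peak positions on release time;
* anchored ChIP metagene profiles and a windowed Poisson enrichment test;
* a simulator that generates all of the above with known ground truth.

All genomic coordinates are 0-based half-open; strand is never dropped.
Coverage is exchanged as plain-text bedGraph, annotation as BED6/GTF; this
keeps every intermediate diffable and makes the pipeline's determinism
checkable by file hash.

## APA classification

Reads are reduced to their 3′-terminal base (for FASTQ input, a trimming
helper keeps the last 200 nt so alignment is dominated by the 3′ end).
Each terminus is assigned to the nearest annotated same-strand PAS within a
window of ±50 bp. The window default reflects the typical scale of cleavage
heterogeneity around a site; it comfortably exceeds the simulator's 10-bp
end noise while staying far below realistic inter-PAS spacing. Distance
ties are broken toward the transcriptionally downstream (distal) site,
which is deterministic and conservative: it biases *against* proximal
calls, the direction of the headline effect.

Per gene and library: proximal count *p* (by default the sum over all
non-distal sites; `most_proximal` and `max_upstream` policies are
selectable), distal count *d* at the unique most TSS-distal site, ratio
*r = p/d*. A gene is testable in a library iff it has ≥2 annotated PAS and
*d* ≥ 5, and testable for a comparison iff testable in both libraries.
Between conditions, *f = r_case/r_control*; *f* ≥ τ ⇒ proximal-dependent,
*f* ≤ 1/τ ⇒ distal-dependent, otherwise independent (τ = 1.5). Zero
denominators: both ratios zero ⇒ independent; control zero, case positive ⇒
proximal-dependent with infinite fold.

Consensus sets intersect per-replicate categories: dependent in all
replicates, or independent (and testable) in all replicates. A calibration
fact worth stating precisely: with 200 reads/gene and true proximal usage
0.3 in both conditions, the exact binomial probability that one replicate
comparison leaves the independent category is 0.065; the probability that a
null gene is proximal-dependent in all three replicates is 3.4 × 10⁻⁵.
Replicate intersection — not the single-replicate call — is therefore the
operative false-positive control, and the recovery tests score false
*dependent* calls against the consensus sets.

The cytoplasmic-expression screen counts full-length reads per gene,
normalizes to reads per million, and flags genes with
control_rpm/case_rpm > 1.5 (infinite fold when the case level is zero).

## Elongation-rate estimation

Gene universe: genes overlapping any other annotated gene are removed, then
a 60–300 kb width filter is applied; analysis windows run from −2 kb to
+120 kb of the TSS in the direction of transcription and are discarded if
they would cross a chromosome edge. Coverage matrices are built at 200-bp
bins (610 bins over the 122-kb window), as mean per-base coverage × 10⁶ /
library total, with minus-strand rows reversed so bin index increases
5′→3′. The 200-bp default balances positional resolution against per-bin
Poisson noise.

The wave peak is the argmax, over bins strictly downstream of the TSS, of a
cubic smoothing spline fit to the profile with the penalty chosen by
generalized cross-validation (`scipy.interpolate.make_smoothing_spline`);
exactly flat profiles shortcut the spline. No multi-peak deconvolution is
attempted — the front of the advancing polymerase wave is a single maximum
in this model. Peaks landing in the last window bin are flagged as censored
and dropped from rate regression for that time point.

Gene-mode quality filters: total window coverage of the first time point
< 100 rpm, or a first-time-point peak < 2 kb (TSS noise), excludes the gene
from rate estimation. Both thresholds are exposed as parameters.

Rates are ordinary least squares of peak position (kb) on release time
(min); the slope is the rate, the intercept is free and absorbs any
constant labeling/synchronization offset, which also makes the estimate
invariant to the wave model's time offset t₀. Group comparisons use the
Welch (unequal-variance) two-sided t-test on per-gene rates with the fold
reported as the ratio of group means; two groups with zero variance are
handled explicitly (p = 1 when the means agree, else p = 0).

## Metagene profiles and peak calling

Metaplots average depth-normalized coverage in anchored coordinates: 50-bp
bins over 1 kb upstream of the TSS and 3 kb downstream of the polyA site,
with the gene body length-scaled to 100 bins by chunked averaging (a
constant signal stays exactly constant under this resampling). Rows are
strand-flipped before averaging.

The peak caller is a deliberately simple windowed Poisson test, not a MACS
re-implementation: per 500-bp window (100-bp step), the one-sided Poisson
tail probability of the observed count is computed against a null
expectation taken from the input track — depth-scaled and locally averaged
over a centered 5-kb region to damp the input's own shot noise — or against
the genome-wide mean density when no usable input exists. Windows at
p ≤ 10⁻⁵ (raw, no multiplicity correction, matching the convention of the
analysis it emulates) are merged when they overlap or abut; merged peaks
are annotated TSS if they touch any TSS ± 1 kb, else gene body, else
intergenic. The ChIP tracks carry one count value per 50-bp bin, and window
statistics sum those values, so background windows are exactly Poisson.

Peak intensities are rpm densities (region count × 10⁶ / library /
length). By default the library size is the track total, which makes
densities exactly invariant to scaling a track and its library together;
explicit library sizes can be supplied for partial-view tracks. Class folds
are ratios of mean densities, with a paired two-sided t-test on per-peak
log densities.

## The synthetic-data generator

The generator emulates three assays on one artificial chromosome of
non-overlapping, strand-alternating genes (default lengths 60–300 kb,
10-kb gaps):

* **Long-read 3′ ends** — per gene and library, a fixed number of reads
  (default 200; Poisson optionally) each choose a PAS multinomially from a
  per-condition usage vector; the 3′ end is the PAS position plus rounded
  Gaussian noise (sd 10 bp). The default design is the two-condition
  experiment: 2 PAS per gene, proximal usage 0.3 in control rising to 0.6
  in half of the genes, three replicates per condition.
* **DRB/TT-seq** — expected coverage at transcriptional distance x from the
  TSS at release time t is
  `background + body·1[0 ≤ x ≤ v(t−t₀)] + amplitude·exp(−(x−v(t−t₀))²/2w²)`,
  with per-gene velocity v, release times 10/20/30/40 min, a Gaussian front
  of width w = 2 kb standing in for the spread produced by the 10-min
  labeling window, and t₀ = 0 (the regression intercept absorbs any
  offset). Observed bin values are Poisson draws around the expectation
  (exact expectations in noiseless mode). Tracks are strand-specific — the
  assay is stranded, and with 10-kb gaps an unstranded 122-kb window would
  otherwise pick up the neighboring gene's wave. A per-gene
  `expression_scale` lets scenarios include poorly expressed genes for the
  quality-filter paths.
* **ChIP** — Poisson counts per 50-bp bin at a background rate (default
  2/bin), multiplied in expectation by 10 within TSS ± 1 kb and by 3 across
  gene bodies; the matched input is pure background.

Randomness is one numpy Generator per (operation, condition, replicate),
derived from the single master seed, so a fixed seed reproduces every file
byte for byte and partial re-runs are stable. A truth table (per-gene
proximal fractions, velocities, expression scales, read counts) is written
next to every dataset.

What the simulator does *not* model — and hence what passing tests do not
demonstrate about real data: basecalling and alignment error, splicing
structure, replicate batch effects, 4SU labeling chemistry and enrichment
bias, mappability, fragment-length effects, and PAS annotation error. The
Gaussian-front wave is a stand-in shape; real wave profiles are broader and
asymmetric, which is why rate estimation is validated on the regression
slope (offset-invariant) rather than on absolute peak positions.

## Problem sizes and numerical choices

The validation experiments run at the designed scales: 300 genes × 2
conditions × 3 replicates at 200 reads/gene for APA recovery; 200 genes (50
per velocity in {0.5, 1, 2, 3} kb/min) × 4 time points for rate recovery;
10⁴ independent background windows for caller calibration; a 6-gene,
2-time-point configuration for the end-to-end determinism check, kept small
because it exercises orchestration rather than statistics. Two discretization
grids meet in the TT-seq path (genome-anchored track bins vs TSS-anchored
analysis bins), so a noiseless argmax can sit up to two bins from the
analytic front; the offset is constant across time points and cancels in the
slope, which is why noiseless slopes are exact while single peaks are only
bin-accurate. Poisson tail tests subtract a 10⁻⁹ epsilon before integer
ceiling to keep float-accumulated counts from crossing the significance
boundary.

## Known limitations

* The peak caller omits MACS's duplicate handling, fragment-shift model and
  multi-scale local λ; it is calibrated for the simulator's count semantics
  and should be re-validated before use on real BAM-derived coverage.
* GTF support covers gene records only (the pipeline's own emission);
  transcript-level annotation should be reduced to genes upstream.
* Per-gene wave calling assumes a single dominant wave; convolved signals
  from bidirectional or nested transcription units will mislead the argmax.
* The spline's GCV penalty is chosen per profile; profiles with long flat
  stretches and one sharp spike can be under-smoothed.
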