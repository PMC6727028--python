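# Methods

`polterm` detects RNA polymerase II (RNAPII) processivity defects —
premature loss of polymerase and transcript signal before the annotated
gene end — from ChIP-seq, nuclear RNA-seq and 3'end RNA-seq data, and
ships a ground-truth simulator so every stage can be exercised at desk
scale. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data does and does not show.

## Coordinate and orientation conventions

All internal coordinates are 0-based half-open; GTF's 1-based inclusive
coordinates are converted on read and write. The TSS is the
transcript's 5' end in transcription direction, the TTS the 3' end.
"Gene length" is the genomic span of the selected transcript, introns
included. "Upstream" always means 5' in transcription direction, for
window geometry and for upstream-site detection alike.

## Representative transcripts

For each gene the transcript with the most library-size-normalized
RNAPII coverage in the ±3 kb windows around its TSS and TTS is selected
(windows are unioned, so an overlap is not double-counted). Ties go to
the longer transcript, then the lexicographically smaller id; without
RNAPII tracks the longest transcript is used. Poly(A) signal content is
the count of sense-strand AATAAA/ATTAAA hexamers in the representative
span divided by span length; counting only the sense strand within the
genomic span is a design choice — antisense hexamers are not substrates
of the sense transcript's 3'end machinery.

## Coverage

Alignments are filtered to primary, mapped records with MAPQ ≥ 20 (the
SAM MAPQ field; secondary/supplementary excluded, duplicates retained);
coverage at a base is the number of retained alignments whose aligned
segment covers it, with no fragment-size extension. bedGraph ingestion
(0-based half-open, overlapping records summed, library size from a
flag or sidecar TSV) provides an alignment-free input path; both paths
produce identical tracks on a shared fixture. Stranded RNA tracks keep
forward/reverse-read layers so only sense reads enter a gene's vector.
Replicates are normalized to reads-per-million (RPM) and averaged per
condition before per-gene statistics unless an operation states
otherwise. Promoter occupancy is the RPM count of reads overlapping
TSS ± 3 kb by at least one bp; for bedGraph-backed tracks (no read
records) the coverage area over the window divided by the recorded mean
read length stands in.

## Scaled metagene profiles

Transcripts shorter than 3,180 bp are excluded; the rest are laid on a
360-bin axis: 90 fixed 50-bp bins covering TSS−3 kb … TSS+1.5 kb, 180
variable-width bins tiling the remaining body, and 90 fixed 50-bp bins
covering TTS−1.5 kb … TTS+3 kb. Body edges sit at
`4500 + round(k·B/180)`, k = 0…180, with B the body length; rounding
proportional edges guarantees every body bin is ≥ 1 bp whenever the
length filter passes (B ≥ 180). Per-bin mean coverage is normalized so
each transcript sums to one (zero-signal transcripts are flagged
excluded for that sample), then averaged first across genes and second
across samples.

Condition comparisons pair each transcript's condition-mean profiles
(mean of the replicates; a transcript excluded in any sample of a
condition is dropped from the pairing entirely, keeping pairs aligned)
and run a two-sided paired Wilcoxon signed-rank test per bin. Zero
differences are dropped; the exact null is used for n ≤ 25 tie-free
differences, otherwise the normal approximation with continuity
correction. P-values are Bonferroni-adjusted across all bins of a
panel (360 by default) and banded at 1e-15 / 1e-10 / 1e-3.
Mark-to-RNAPII ratio curves use (mark + ε)/(RNAPII + ε) with ε = 1e-6,
both on group means and per transcript so the paired test can run on
ratios.

## X% distances and shortening classes

The X% distance is the minimum d ≥ 1 bp from the TSS at which the
cumulative coverage reaches X% of the gene total, computed on the
replicate-mean RPM vector over the representative transcript's full
genomic span (nuclear RNA includes introns). Absolute ΔX% is control
minus treated; relative ΔX% divides by gene length, so positive Δ90%
means shortening. Classes: shortened (relative Δ90% ≥ 0.2), else
extended (absolute Δ90% < −50 bp), else unaffected (|absolute Δ90%| ≤
25 bp), else unclassified; shortened takes precedence because the bands
can overlap for short genes. Genes with zero coverage in either
condition are excluded and logged. Length quantiles are rank-based
equal-size groups with id tie-breaks; the shortening curve reports, per
group, the fraction of genes with relative Δ90% at or above each grid
value and is monotone non-increasing by construction.

For a gene with uniform coverage truncated at fraction t of its length,
the expected relative Δ90% is 0.9·(1 − t); this closed form anchors the
recovery tests.

## Poly(A)-site windows

AATAAA and ATTAAA are scanned on both strands (minus-strand hits as
reverse-complement matches), overlapping matches included; oligo-A runs
are maximal stretches of ≥ 10 sense-strand As (≥ 10 Ts on the stored
sequence for the minus strand). Signal windows span −300/+50 bp around
the hexamer in transcription orientation; oligo-A windows −350 bp to
the run end (the full maximal run, avoiding arbitrary sub-run ends).
Windows are merged within each kind and strand when they share ≥ 1 bp
(touching windows stay separate), then merged signal windows
overlapping any merged oligo-A window on the same strand are removed —
the internal-priming exclusion. Windows are clipped to chromosome
bounds; construction is idempotent on its own output.

Surviving windows are labelled by same-strand feature overlap with
preference 3'UTR > exon > intron > intergenic, counted against stranded
3'end reads (≥ 1 bp overlap, strand-matched, once per window; counting
only the read 3' terminus is available behind a flag), and called
down/up/non at adjusted p < 0.01 on log2FC sign alone (no magnitude
cutoff). Per gene, the category is the first match of: down-regulated
3'UTR window > any up window > any non window > no tested window;
upstream up-regulated windows are counted strictly 5' of the 3'-most
down-regulated 3'UTR window.

## Differential tables and the stand-in tests

External DESeq2/DEXSeq-style tables are consumed through configurable
column maps; missing adjusted p marks a feature untested. Expression
classes use the printed strict bands (up: log2FC > 1 and adjusted
P < 0.01; down: log2FC < −1, P < 0.01; non: −0.1 < log2FC < 0.1,
P > 0.01; all else "other"); "P" is read as the BH-adjusted value.
Benjamini–Hochberg adjustment comes from statsmodels.

Two deliberately simple stand-in tests keep synthetic pipelines
self-contained; neither replaces negative-binomial modelling and
real-data runs should supply external tables:

* **ranksum** — exact two-sided Wilcoxon rank-sum on CPM values. Its
  power floor is structural: with 3 vs 3 replicates the smallest exact
  two-sided p is 2/20 = 0.1, so it can never reach adjusted p < 0.01
  at that design. It is retained for designs with more replicates.
* **pooled-binomial** (default for the synthetic pipeline) — the
  conditional binomial exact test on counts summed per condition, the
  classic test for a ratio of Poisson means. It has power at n = 3 but
  is anti-conservative under strong overdispersion; with the
  simulator's dispersion of 0.1 its false-call rate at adjusted
  p < 0.01 stays at or below nominal in the null test.

## The synthetic cohort

Defaults (one synthetic chromosome, deterministic given the seed):
300 genes, lengths log-uniform 4–300 kb, 3–20 exons, alternating
strands, 8 kb intergenic gaps; 40% affected, truncation fraction
t ~ U(0.3, 0.8); 3 replicates per condition; body depth 2 reads/bp,
promoter peak 8× body, TTS bump 2×, background 0.05 reads/bp, Poisson
sampling per base; 3'end counts negative-binomial (variance μ + 0.1 μ²)
averaging 300 reads per gene and sample, with 95% of a gene's mass on
its distal 3'UTR window and 70% of that mass moving to the planted
proximal window in treated affected genes (expected distal log2FC =
log2 0.3 ≈ −1.74). Affected genes are drawn with probability
proportional to length rank while keeping the overall affected
fraction: longer, poly(A)-signal-richer genes are the preferentially
shortened population this analysis targets, and the length-quintile
separation of the shortening curve only exists under that condition.

Coverage shapes: RNAPII/SPT6 = promoter Gaussian (sd 300 bp) + uniform
body + TTS bump (sd 200 bp); treated affected genes multiply body and
TTS bump by a logistic decay centred at t·L (scale max(50, 0.02·L) bp)
while the promoter peak persists — initiation is unaffected, elongating
polymerase is lost. P-Ser2 ramps 0.25→1 toward the 3' end in control
and, under truncation, re-centres its peak at t·L. Nuclear RNA is the
uniform body with the same decay, strand-specific. Every 3'UTR carries
a planted sense AATAAA; affected genes a second one at t·L; ~10% of
genes get an intergenic decoy signal overlapped by a planted 12-A run,
giving the internal-priming filter planted positives.

What the simulator does **not** emulate: read-sequence errors, GC and
mappability bias, fragment-size effects, splicing-aware read placement,
antisense transcription, overlapping genes, replicate-specific batch
structure, and real negative-binomial gene-level count variation for
the coverage tracks (per-base Poisson only). Passing recovery tests
therefore demonstrates correctness of the statistics under the stated
generative model, not robustness to every artefact of real libraries.

## Problem sizes and numerical choices

The recovery and end-to-end checks run on the default 300-gene cohort
(~22 Mb genome), chosen so the full pipeline — simulation, coverage,
metagene testing, distances, window calling — completes in about a
minute while leaving > 100 genes in the affected group for per-bin
paired tests. Profile sums are checked to 1e-9; float round-off at the
cumulative-threshold boundary of the X% distance is guarded by an
explicit post-check of the searched index. Classification thresholds,
band cutoffs and window geometries are module constants overridable per
call; the defaults are the printed analysis constants.

## Known limitations

* The signed-rank exact path requires tie-free absolute differences;
  profile data in practice is continuous, but heavily tied small-n
  input silently uses the normal approximation.
* Window-level differential calls ignore overdispersion beyond what the
  pooled-binomial test models; real analyses should use a count model
  (DESeq2 or similar) and feed the result table in.
* `promoter_occupancy` on bedGraph input is an area-based approximation
  and needs a recorded mean read length.
* Gene-level attribution of windows uses the representative transcript
  span only; windows in alternative terminal exons of non-representative
  isoforms are labelled by the representative model.
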