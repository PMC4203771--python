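# Methods

## Screening model

A maternal plasma sample is a mixture of maternal and placental cfDNA. Let f
be the fetal fraction. Under a fetal trisomy of chromosome t, the fetal
component carries three copies of t instead of two, so the expected share of
reads mapping to t is multiplied by (1 + f/2) relative to the euploid
baseline (then renormalized over chromosomes). At f = 0.10 this is a 5%
excess — far below per-sample noise at a glance, but detectable because the
standard deviation of a chromosome's read fraction at N retained reads scales
as sqrt(p(1−p)/N).

The test statistic is the per-chromosome z-score

    z(s, c) = (x_sc − mean_c) / sd_c

with x_sc the sample's representation of chromosome c and mean_c, sd_c the
mean and sample standard deviation (n−1 denominator) over the euploid
reference cohort. n−1 rather than the population denominator is a convention
choice; at a panel of 139 the difference is under 0.4%. A scored euploid
sample is not removed from its own panel (the reference is the full euploid
cohort for every sample, matching how such screens are run in practice); a
leave-one-out variant can be had by building a panel per sample.

Two representation modes exist. `count` mode uses the raw per-chromosome
mapped-read count — the statistic exactly as screening formulas print it —
but it confounds per-sample sequencing depth with dosage. `fraction` mode
(the default) divides by the sample's total autosomal count, which removes
depth as a nuisance while leaving the dosage signal intact; sex chromosomes
are excluded from the denominator because fetal sex shifts chrX/chrY totals.
The choice is surfaced in every artifact rather than hidden.

## Read QC

Filters run in a fixed order on raw reads: 3′ trimming (drop trailing bases
until the last base has Phred quality strictly above 15 — a trailing-run
rule, not a windowed Mott-style algorithm), length (trimmed reads shorter
than 50 bp removed; exactly 50 bp retained), GC content (G+C fraction of the
retained bases inside the inclusive band [0.35, 0.45]; N counts as non-GC),
then unique-mapping selection and positional duplicate removal on the
alignments of surviving reads. "Uniquely mapped" has no aligner-independent
definition; the default predicate (mapped, primary, MAPQ > 0) is a
configurable choice. Duplicates are defined single-end by the key
(chromosome, 0-based 5′ start, strand); the retained representative is the
first after a stable sort by key and read id, making output deterministic
under input reordering.

## Binning and coordinates

Coordinates are 0-based half-open internally; SAM input is converted at parse
time. Bins are fixed 300 kb half-open windows; the last bin of a chromosome
may be partial. A read belongs to exactly one bin, by its leftmost mapped
position. Per-bin counts are retained even though only chromosome totals
enter the z-score, so GC-weighting or bin-level QC can be added without
changing the counting stage. The shipped layout is hg19 chr1–22, X, Y
(unplaced/alt contigs excluded); any 2-column chrom/length TSV can replace
it, and small toy layouts are first-class for testing.

## Cutoff selection and calling

A sample is positive for chromosome c when z > cutoff, strictly. The cutoff
is selected by scanning every observed z value as a candidate and maximizing
the Youden index J = sensitivity + specificity − 1 under the strict-greater
rule, breaking ties toward the largest qualifying cutoff. Candidates are the
observed values themselves, not midpoints: with perfectly separated groups
the selected cutoff is then exactly the maximum negative-group z, which is
how interactive dot-diagram software reports the "minimal discriminating
value". Cutoffs selected and evaluated on the same cohort are in-sample and
optimistic; the report JSON records this flag.

## Evaluation

PPV = TP/(TP+FP), NPV = TN/(TN+FN); combined detection pools both trisomies
into one positive class over the same cohort. Binomial CIs come in two
flavours: Clopper–Pearson exact (Beta quantiles; at k = n the lower bound is
(α/2)^(1/n)) and Wilson score (at k = n, n/(n+z²), z = 1.959964 two-sided
95%). Screening reports sometimes label intervals "Wilson" while printing
exact numbers — the two differ markedly at small n (5/5: 47.8% exact vs
56.6% Wilson) — so both are implemented, the report defaults to exact, and
the method is recorded in every output. Quantities with zero denominator are
reported as not-available rather than raising. Percentages in reports are
rounded half-up to one decimal.

At k = n the two lower bounds cross once: exact ≈ 1 − 3.689/n sits below
Wilson ≈ 1 − 3.841/n for n ≲ 46 and above it afterwards; neither dominates
globally. The all-success sample-size planner iterates n directly on these
bounds (monotone in n, so the first qualifying n is the answer): a 98%
lower-bound target needs n = 183 (exact) or 189 (Wilson).

## Synthetic cohorts

Defaults describe the targeted study design: 139 euploid / 5 T18 / 11 T21
samples, 6.5 M raw reads per sample, 59% uniquely mapped, read length
150 ± 15 bp, fetal fraction ~10%. Parameters the design does not pin down
were fixed once at values typical for second-trimester cfDNA screening:
fetal-fraction SD 0.02 (truncated normal on [0.001, 0.999] — individual
fetal fractions vary substantially), duplicate rate 0.05, per-read GC target
Normal(0.41, 0.03) (human genome-wide GC with modest library spread),
quality plateau Q36 decaying linearly to Q8 over the final 12 bases.

The bin-count path draws each sample's retained reads
(reads_per_sample × unique_map_rate) from a multinomial over the bin grid,
with bin weights proportional to bin width (optionally GC-modulated) and the
trisomic chromosome's bins scaled by (1 + f/2). The read-level path emits
FASTQ plus a truth alignment table and exists to exercise QC at small scale;
read base composition matches each read's GC target exactly (rounded), so GC
variation across reads is exactly the target draw.

What the simulator does *not* model: GC-dependent coverage waviness along
the genome (unless a per-bin bias is supplied explicitly), mappability gaps,
maternal copy-number variants, placental mosaicism, and fragment-size
differences between fetal and maternal DNA. Consequently, passing tests
establish that the statistical machinery is correct under multinomial
sampling with the stated dosage model — not that real cohorts at this depth
will separate as cleanly; real euploid z distributions are typically
over-dispersed relative to multinomial noise.

## Numerical and testing choices

Identical config + seed reproduces identical output; all randomness flows
from one `numpy` Generator. Test problem sizes: the z-calibration property
uses a 2000-euploid panel with 1000 held-out euploids at ~200k retained
reads on a six-chromosome toy genome — sizes chosen so the standard error of
the held-out mean z (≈0.039) leaves clear headroom inside the |mean z| < 0.1
band being asserted; the separation property runs 100 seeded replicates of a
50/3/5 cohort at the same depth with fetal fraction ≥ 0.08. The full-scale
155-sample end-to-end run in the acceptance script takes seconds because the
bin-count path never materializes reads.

Degenerate inputs are rejected loudly: panels need ≥ 2 euploids and non-zero
SD on every scored chromosome; fraction-mode profiles need a non-zero
autosomal total; threshold selection needs both groups non-empty; empty
pipelines error before any stage runs. Reads trimmed to zero length simply
fail the length filter. 3′ trimming may not be how any particular instrument
vendor defines it (windowed algorithms exist); the declared rule is
documented above and applied consistently to both the filter and its oracle.

## Known limitations

Only chromosome-level calls for the two target trisomies (plus a pooled
class) are produced; no bin-level segmentation, no sex-chromosome aneuploidy
calling, no fetal-fraction estimation, no GC LOESS correction, no
prevalence-adjusted predictive values. In-sample cutoff selection overstates
performance on small cohorts — the CI lower bounds (47.8% PPV at 5/5) say as
much — and should be read as descriptive of the training cohort, not as a
validated operating point.
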