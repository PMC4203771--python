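# cfnipt

Non-invasive prenatal screening for fetal trisomy 18 and 21 from shallow
whole-genome sequencing of maternal plasma cell-free DNA (cfDNA).

Maternal plasma contains a mixture of maternal and placental DNA fragments.
A fetal trisomy of chromosome *t* over-represents that chromosome in the
mixture by a factor of approximately (1 + f/2), where f is the fetal
fraction (~10% in the second trimester). With a few million reads per
sample, this small excess is detectable: reads are counted into 300 kb bins,
each sample's per-chromosome representation x<sub>c</sub> (read count, or by
default its fraction of the autosomal total) is standardized against a
euploid reference cohort,

    z_c = (x_c − mean_c(euploid)) / SD_c(euploid),

and a sample is called positive when z on the target chromosome strictly
exceeds a cutoff chosen by the interactive dot-diagram (Youden-index)
criterion. Screening performance is summarized as PPV/NPV with exact
(Clopper–Pearson) and Wilson binomial confidence intervals, plus an
all-success sample-size planner.

The package is aimed at people building or teaching cfDNA aneuploidy
pipelines: every stage — read QC (3′ quality trimming at Q>15, length ≥50 bp,
GC 35–45%, unique-mapping selection, positional duplicate removal), bin
counting, reference-panel z-scores, cutoff selection, evaluation — is a
tested library function with a TSV contract, and a built-in cohort simulator
makes the whole pipeline runnable without any sequencing data.

## Worked example

Simulate a 155-sample high-risk cohort at the default study design
(139 euploid / 5 trisomy-18 / 11 trisomy-21, 6.5 M reads per sample of which
59% map uniquely, fetal fraction ≈ 10%) on the shipped hg19 layout, and run
the full analysis:

```python
import cfnipt as c

layout = c.hg19_layout()                      # chr1-22, X, Y; 300 kb bins
counts, labels = c.simulate_bin_counts(c.SimulationConfig(seed=7), layout)
result = c.run_full(counts, labels, layout)   # panel -> z -> cutoffs -> calls
for target in ("T18", "T21", "combined"):
    s = result.summaries[target]
    print(target, s["tp"], s["fp"], s["tn"], s["fn"], s["ppv_ci"])
```

which prints (formatted):

```
T18: TP=5 FP=0 TN=150 FN=0 PPV=1.000 (95% CI 47.8%-100.0%) NPV=1.000 (95% CI 97.6%-100.0%)
T21: TP=11 FP=0 TN=144 FN=0 PPV=1.000 (95% CI 71.5%-100.0%) NPV=1.000 (95% CI 97.5%-100.0%)
combined: TP=16 FP=0 TN=139 FN=0 PPV=1.000 (95% CI 79.4%-100.0%) NPV=1.000 (95% CI 97.4%-100.0%)
selected cutoff T18 (chr18): 3.281
selected cutoff T21 (chr21): 1.835
```

All 16 affected samples separate cleanly from the 139 euploids, so PPV and
NPV are both 100%; the CI lower bounds (47.8%, 97.6%, 71.5%, 97.5%, 79.4%,
97.4%) are the exact binomial bounds for the all-success counts 5/5, 150/150,
11/11, 144/144, 16/16 and 139/139. The in-sample cutoffs equal the largest
negative-group z on each target chromosome.

The same run is available from the shell:

```sh
cfnipt run-all --seed 7 --out out/        # simulate + analyse, artifacts in out/
cfnipt simulate --seed 7 --out sim/       # or stage by stage:
cfnipt run-all --counts sim/bin_counts.tsv --labels sim/labels.tsv --out out/
```

Real data enter as SAM alignments or per-bin count TSVs; `cfnipt qc`,
`cfnipt count`, `cfnipt panel`, `cfnipt zscore`, `cfnipt threshold`,
`cfnipt classify` and `cfnipt evaluate` expose the individual stages.

Planner example: for an all-negative validation cohort, the smallest n whose
95% CI lower bound on NPV reaches 98% is `sample_size_all_success(0.98,
"exact")` → 183 (Clopper–Pearson) or 189 (Wilson).

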