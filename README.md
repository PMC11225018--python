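# rloopkit

Strand-specific R-loop sequencing analysis: wR/cR strand partitioning,
RPGC and spike-in quantitative normalization, GC/AT skew profiling, peak
calling with boundary diagnostics, compartment accounting, permutation
overlap enrichment, and fuzzy c-means stage-dynamics clustering — plus a
synthetic-data generator that makes the whole pipeline testable without
any sequencing downloads.

## The problem

R-loops are three-stranded chromatin structures: an RNA:DNA hybrid plus a
displaced single-stranded DNA. Strand-specific DRIP-seq variants
(ssDRIP-seq and its ultra-low-input, spike-in-quantified form) map them
genome-wide and resolve which strand is displaced — a **wR-loop**
displaces the Watson strand, a **cR-loop** the Crick strand. Comparing
absolute R-loop levels *between* samples (developmental stages, tissues)
requires spike-in calibration, because immunoprecipitation efficiency and
library depth are not comparable across libraries. rloopkit provides the
complete post-alignment computational chain for such experiments, for
anyone analyzing stranded R-loop libraries or building simulations of
them.

## The core statistics

**Spike-in quantitative factor.** With fragment counts T_Rloop, T_input
on the target genome and S_Rloop, S_input on the spike-in genome:

    QF(n)  = [T_Rloop(n) × S_input(n)] / [S_Rloop(n) × T_input(n)]
    FNF(n) = QF(n) × NF(ref) / QF(ref)

where NF(ref) is the reference sample's RPGC (reads-per-genomic-content,
1× depth) factor. QF cancels both library depths exactly, so FNF-scaled
tracks and QF ratios report genuine between-sample R-loop level changes.

**GC/AT skew.** GC skew = (G−C)/(G+C), AT skew = (A−T)/(A+T) on the
Watson strand, 200 bp windows in 50 bp steps. wR-loop regions favor
positive skew; cR-loop regions mirror it.

**Fuzzy c-means dynamics.** Regions × stages matrices (row-standardized
FNF-scaled coverage) are clustered with standard Bezdek updates
(m = 2, c = 6 by default), giving soft memberships summing to 1 per
region.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

Simulate a 200 kb genome with 10 planted stranded R-loop regions and a
20,000-fragment library, then run the analysis:

```
$ rloopkit simulate --out-prefix sim --chrom-length 200000 \
      --n-regions 10 --depth 20000 --seed 3
wrote sim.fa/.truth.bed/.bam/.manifest.json

$ rloopkit split sim.bam sim.fa --out-prefix sp
{"wR": 8255, "cR": 11745, "excluded": 0, "dropped": {"pairs_emitted": 20000, "orphans": 0}}

$ rloopkit coverage sim.bam sim.fa --out cov.bedgraph --bin-size 10
scale=0.0143525

$ rloopkit callpeaks cov.bedgraph sim.fa --bin-size 10 --out peaks.bed
10 peaks

$ rloopkit cutsites sim.fa --out cuts.bed
3614 cut sites

$ rloopkit boundary peaks.bed cuts.bed
{"bins": {"0": 2, "1-10": 4, "11-50": 11, "51-200": 3, ">200": 0}, "fraction_bin0": 0.1, "n_boundaries": 20}
```

Reading the output: the library splits into 8,255 wR and 11,745 cR
fragments (planted strand mix plus random-strand background); the RPGC
scale 0.01435 makes genome-wide mean coverage exactly 1×; the caller
recovers all 10 planted regions; and only 10% of peak boundaries fall on
a restriction cut site — the expected result for nuclease-style
fragmentation, where boundaries track the R-loop itself rather than the
enzyme sites (compare `--boundary-model re`, which drives that fraction
to ~1.0).

Spike-in quantification across samples (each sample is a rloop/input BAM
pair over a combined target+spike-in reference):

```
$ rloopkit quant "s1=s1.rloop.bam,s1.input.bam" "s2=s2.rloop.bam,s2.input.bam" \
      comb.fa --spikein-chroms spk1 --reference s1
sample  T_Rloop T_input S_Rloop S_input QF      ...  relative_total_level
s1      7657    7683    2343    2317    0.9856  ...  1.0
s2      8669    7736    1331    2264    1.9061  ...  1.934
```

Sample s2 was simulated at 2× the global R-loop level of s1; the
recovered relative level is 1.93.

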