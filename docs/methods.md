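# Methods

## Scope and model

rloopkit re-implements the computational core of strand-specific R-loop
sequencing (ssDRIP-seq and its ultra-low-input, spike-in-quantified
variant) as a library and CLI. An R-loop is a three-stranded structure —
an RNA:DNA hybrid plus a displaced single-stranded DNA. Because the
displaced strand can be either the Watson or the Crick strand of the
reference, every fragment, track and peak carries a strand label: a
**wR-loop** displaces the Watson strand, a **cR-loop** the Crick strand.

The evidence unit throughout is the *fragment* — the full span of a
properly paired read pair — not the individual read. A pair is one
immunoprecipitated molecule; counting reads would double-weight molecules
and make counts depend on read length.

### Read filtering

Pairs are kept if they are primary, properly paired, mapped, pass the
mapping-quality floor and have at most 3 mismatches (NM tag) on each mate.
Pairs lacking NM pass the mismatch filter and are counted in the log;
aligner tagging conventions vary and silently dropping untagged pairs
would bias libraries from NM-free aligners.

### RPGC normalization

Coverage is scaled to 1x mean depth: scale = L_eff / B, with L_eff the
total length of non-ignored target chromosomes and B the total fragment
bases on them. `chrM` is ignored by default: mitochondrial copy number
varies wildly across samples (oocytes especially) and would otherwise
dominate the denominator. The scaled genome-wide mean is exactly 1 by
construction; tests assert it to 1e-9.

### Spike-in quantification

With a fixed absolute amount of foreign-genome spike-in DNA added to every
sample, per-sample fragment counts T_Rloop, T_input (target genome) and
S_Rloop, S_input (spike-in genome) give

    QF(n)  = [T_Rloop(n) x S_input(n)] / [S_Rloop(n) x T_input(n)]
    FNF(n) = QF(n) x NF(ref) / QF(ref)

where NF(ref) is the reference sample's RPGC factor. Both library depths
cancel in QF (verified exactly in tests), so FNF responds only to the
genuine target-to-spike R-loop ratio. The relative total R-loop level of
sample n is QF(n)/QF(ref), i.e. T_Rloop/T_input x S_input/S_Rloop
normalized to the reference. Counts are fragments on non-ignored target
chromosomes; the reference sample is user-chosen (default: first sample)
and recorded in the output table.

### GC/AT skew

GC skew = (G − C)/(G + C), AT skew = (A − T)/(A + T), counted on the
Watson strand, with a 200 bp window advanced in 50 bp steps (the field's
standard parameters for this assay). Three documented choices where the
convention is genuinely open:

* windows with zero informative bases are **missing** (NaN), never 0 —
  zero means "balanced", which is information;
* window values anchor at the window **midpoint** (symmetric,
  convention-free);
* skew is always computed on the Watson strand; strand orientation is
  applied only at metaprofile aggregation, where '-' regions are
  reverse-complement-oriented (bins reversed, sign flipped). A planted
  cR-loop region therefore contributes positively to a strand-aware
  metaprofile, matching the sign convention in which wR peaks show
  positive skew.

### Peak calling

A deliberately minimal caller, not a MACS2 re-implementation: background
lambda is the trimmed mean of all bins (top 1% excluded, robust to the
peaks themselves); candidate bins need value >= min_fold x lambda
(default 5) and Poisson tail p < 0.01; candidate runs within `merge_gap`
(default 100 bp) merge; peaks under 200 bp are discarded (the standard
post-filter for this assay — sub-200 bp calls are unreliable at these
fragment sizes). Calling is per strand on wR and cR tracks. Local-lambda
machinery is intentionally out of scope.

### Boundary diagnostic

Enzymatic fragmentation forces R-loop peak boundaries onto restriction
cut sites; single-strand-nuclease (mung bean) digestion trims to the true
hybrid boundary. The diagnostic measures, for each peak start/end, the
distance to the nearest cut site of the DdeI/MseI/NlaIII/MboI cocktail,
binned as {0 (<= 5 bp, "overlapping"), 1–10, 11–50, 51–200, >200}. The
bin layout beyond bin 0 is our documented default; the peak start/end are
used verbatim as boundaries. On simulations the enzymatic model puts
>= 90% of boundaries in bin 0 while the nuclease model is statistically
indistinguishable from length-matched random peaks — the qualitative
signature that motivates nuclease digestion. For this diagnostic tracks
are binned at 5 bp so bin-edge rounding (< 5 bp) cannot leave bin 0.

### Junction readout

The bundled artificial half-R-loop substrate is built from the designed
203-nt RNA, the 53-nt tailed RT primer and the 47-nt paired oligo.
Coordinates are on the cDNA strand: [0, 47) double-stranded tail,
[47, 53) single-stranded gap, [53, 256) RNA:DNA hybrid; the hybrid/dsDNA
junction is position 53. Exact single-strand-nuclease digestion yields
fragments spanning exactly the hybrid, so the modal Watson first base
equals the junction; Gaussian end jitter (the `noisy:sigma` model) leaves
the mode within ~2 bp at sigma = 5, n = 1e4.

### Permutation overlap test

The statistic is the number of query regions overlapping >= 1 reference
region. Each permutation re-places every query region uniformly at random
on its own chromosome, preserving lengths (placed regions may overlap one
another) — the simplest valid null, analogous to uniform region
randomization. p = (1 + #{perm >= obs})/(n_perm + 1), so p >= 1/(n_perm+1)
always; z = (obs − mean)/sd. Null calibration holds in the near-continuous
regime (enough query regions that the overlap count takes many values);
with very few regions the discrete statistic makes p conservative, which
is the standard behavior of count-based permutation tests.

### Stage dynamics clustering

Per-stage peaks are union-merged into a total region set; each region's
FNF-scaled mean coverage per stage forms the matrix; rows are
z-standardized with population sd (zero-variance rows dropped and
counted). Clustering is standard Bezdek fuzzy c-means with Euclidean
distance, fuzzifier m = 2 and c = 6 clusters by default (both flags,
both logged): the membership update 1/sum_j (d_ik/d_ij)^(2/(m−1)) and the
weighted-mean center update, iterated until max|dU| < 1e-6.

**Initialization.** Centers start at c distinct random data rows (seeded),
with the first membership matrix derived from those distances; 5 restarts
keep the lowest-objective solution. A uniform random membership matrix is
*not* a usable initializer: it places every center at the data centroid,
which is an exact fixed point of the updates, and the iteration never
leaves it. A point coinciding with a center gets membership 1 to the
first coinciding center (tie-break). The objective is non-increasing and
the result is bit-identical for a fixed seed (both tested).

## Synthetic data: what it emulates, what it does not

The generator produces i.i.d.-base genomes (default GC 0.4) with planted,
non-overlapping, strand-labeled regions whose Watson-strand composition
is skewed by `skew_strength` (P(G) = gc/2·(1+s) over P(C) = gc/2·(1−s),
A over T analogously; mirrored for '-' regions) — so skew profiling has a
closed-form expectation. Libraries draw each fragment from a planted
region with probability enrichment·W/(enrichment·W + B) (region-weighted,
correct strand) or from background (uniform, random strand). Boundary
chemistry: `mbn` trims signal fragments to the region boundary with
Gaussian jitter sigma = 2 bp by default (near-single-nucleotide
resolution without asserting perfection; set 0 for exactness tests);
`re` snaps all fragment ends to the nearest cut site. Fragment lengths
are truncated normal (mean 250, sd 50), the sonication target of the
protocol. Spike-in pairs allocate rloop-library fragments in proportion
to global_level x genome mass and input-library fragments by mass alone,
so the planted level ratio is identically the quantity the QF chain
recovers. The RNase-H null forces background-only sampling. Fragments are
emitted as already-aligned synthetic proper pairs (NM = 0); alignment is
out of scope and alignment-free fixtures keep the tests hermetic.

Not modeled: sequencing error, PCR duplicates, mappability, GC bias,
chromatin context, overlapping/nested R-loops, replicate variance. Passing
tests therefore demonstrate correctness of the *computations* under the
stated sampling model, not robustness to real-library artifacts.

## Default parameters

| parameter | default | unit | note |
|---|---|---|---|
| skew window / step | 200 / 50 | bp | assay-standard sliding window |
| fragment length | 250 ± 50 | bp | sonication target, truncated normal |
| MBN boundary jitter | 2 | bp | free parameter, not inferred |
| enrichment | 20 | fold | signal-vs-background sampling odds |
| peak min_fold / p / min size | 5 / 0.01 / 200 | — / — / bp | trimmed-mean lambda background |
| boundary extend | 5 | bp | bin-0 width of the distance histogram |
| promoter flank | 1000 | bp | upstream of TSS, strand-aware |
| fuzzifier m / clusters c | 2.0 / 6 | — | CLI flags, logged |
| FCM tol / max_iter / restarts | 1e-6 / 300 / 5 | — | lowest objective kept |
| ignored chromosomes | {chrM} | — | normalization and totals |

## Problem sizes

Simulated studies use 0.2–1 Mb genomes, 8–40 planted regions of
0.5–2 kb, and 1e5 fragments per library (2e4–1e5 in unit tests); the
permutation null calibration uses 200 independent runs of 199
permutations with 150 query regions. These sizes put every recovered
quantity's sampling error well inside the asserted tolerances while the
whole suite runs in well under a minute per module.

## Known limitations

* The peak caller has no local background model; closely spaced planted
  regions separated by less than `merge_gap` merge into one peak.
* Restriction-site snapping can produce zero-length spans when both
  boundaries snap to the same site; the end then advances to the next
  site (rare, counted in tests).
* The permutation null preserves per-chromosome placement only; GC- or
  gap-matched nulls are not implemented.
* Multi-mapped reads are handled by taking primary alignments only.
* Compartment assignment is by fragment midpoint — a true partition, at
  the cost of boundary-straddling fragments being assigned to one side.
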