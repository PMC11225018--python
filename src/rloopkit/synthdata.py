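"""Synthetic genomes, planted R-loops and simulated sequencing libraries.

The generator emulates the measurable structure of strand-specific R-loop
immunoprecipitation libraries:

* genomes of i.i.d. bases at a chosen GC content;
* planted R-loop regions whose Watson-strand composition is skewed toward
  G over C (and A over T) for wR-loops, mirrored for cR-loops, so the
  downstream skew profiling has a known expectation;
* fragment libraries in which a fragment is either drawn from a planted
  region (correct strand, boundary behavior set by the fragmentation
  chemistry) or from background (random strand);
* two fragmentation chemistries: single-strand-specific nuclease digestion
  ("mbn"), which trims fragments to the R-loop boundary with small Gaussian
  jitter, and restriction-enzyme digestion ("re"), which snaps every
  fragment end to the nearest recognition-site cut coordinate;
* paired target + spike-in libraries at controlled global R-loop levels,
  whose level ratio is the ground truth the quantification chain recovers;
* an RNase-H-style null mode producing background-only libraries;
* an artificial half-R-loop substrate (RNA:DNA hybrid joined to a
  double-stranded tail) with exact or jittered junction readout.

All randomness flows through a single ``numpy`` Generator per call, so a
fixed seed reproduces fragment lists and truth regions exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pysam

from .core_io import (
    SPIKEIN,
    TARGET,
    Fragment,
    GenomeRef,
    Region,
    RegionSet,
    write_bed,
)

BASES = np.array(["A", "C", "G", "T"])


def _base_probs(gc: float, skew: float = 0.0) -> np.ndarray:
    """Per-base probabilities (A,C,G,T) with optional G-over-C / A-over-T skew."""
    return np.array([
        (1 - gc) / 2 * (1 + skew),
        gc / 2 * (1 - skew),
        gc / 2 * (1 + skew),
        (1 - gc) / 2 * (1 - skew),
    ])


def make_genome(
    chrom_lengths: dict[str, int],
    gc_content: float = 0.4,
    seed: int = 0,
    namespace: str = TARGET,
) -> tuple[GenomeRef, dict[str, str]]:
    """Generate i.i.d. random chromosome sequences at a fixed GC content."""
    if not 0 < gc_content <= 1:
        raise ValueError("gc_content must be in (0, 1]")
    for c, L in chrom_lengths.items():
        if L < 1000:
            raise ValueError(f"chromosome {c!r} shorter than 1000 bp")
    rng = np.random.default_rng(seed)
    probs = _base_probs(gc_content)
    seqs = {
        c: "".join(rng.choice(BASES, size=L, p=probs))
        for c, L in chrom_lengths.items()
    }
    genome = GenomeRef(
        dict(chrom_lengths), namespace_map={c: namespace for c in chrom_lengths}
    )
    return genome, seqs


@dataclass
class RloopTruth:
    """Planted R-loop regions: strand '+' means wR (Watson ssDNA), '-' cR."""

    regions: RegionSet
    weights: np.ndarray  # per-region enrichment weight

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.regions):
            raise ValueError("one weight per region required")


def plant_rloops(
    genome: GenomeRef,
    seqs: dict[str, str],
    n_regions: int,
    length_range: tuple[int, int] = (500, 2000),
    strand_mix: float = 0.5,
    skew_strength: float = 0.3,
    gc_content: float = 0.4,
    seed: int = 0,
    max_tries: int = 200,
) -> tuple[RloopTruth, dict[str, str]]:
    """Plant non-overlapping skew-biased regions, rewriting the sequence.

    Inside a '+' (wR) region the Watson strand is resampled with
    P(G) = gc/2*(1+s), P(C) = gc/2*(1-s) and A over T analogously, so the
    expected GC and AT skew of the planted span is ``skew_strength``.
    '-' regions are mirrored (C over G, T over A). Regions are separated by
    at least one fragment length so truth regions stay distinct.
    """
    if not 0 <= skew_strength < 1:
        raise ValueError("skew_strength must be in [0, 1)")
    rng = np.random.default_rng(seed)
    chroms = genome.chroms(TARGET)
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    regions: list[Region] = []
    min_sep = 500
    for i in range(n_regions):
        ok = False
        for _ in range(max_tries):
            c = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
            L = int(rng.integers(length_range[0], length_range[1] + 1))
            if genome.chrom_lengths[c] <= L + 2 * min_sep:
                continue
            s = int(rng.integers(min_sep, genome.chrom_lengths[c] - L - min_sep))
            e = s + L
            if all(e + min_sep <= a or s >= b + min_sep for a, b in placed[c]):
                placed[c].append((s, e))
                strand = "+" if rng.random() < strand_mix else "-"
                regions.append(Region(c, s, e, f"rloop_{i}", 0.0, strand))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place region {i + 1}/{n_regions} after {max_tries} tries"
            )
    new_seqs = {c: list(s) for c, s in seqs.items()}
    for r in regions:
        s = skew_strength if r.strand == "+" else -skew_strength
        probs = _base_probs(gc_content, s)
        span = rng.choice(BASES, size=r.end - r.start, p=probs)
        new_seqs[r.chrom][r.start:r.end] = span
    seqs_out = {c: "".join(v) for c, v in new_seqs.items()}
    truth = RloopTruth(RegionSet(regions).sort(), np.ones(len(regions)))
    return truth, seqs_out


# ---------------------------------------------------------------------------
# fragment libraries


def _truncnorm_lengths(rng, n, mean, sd, lo=50):
    out = rng.normal(mean, sd, size=n)
    bad = out < lo
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < lo
    return out.astype(int)


def _snap_to_sites(pos: int, sites: np.ndarray) -> int:
    i = np.searchsorted(sites, pos)
    if i == 0:
        return int(sites[0])
    if i == len(sites):
        return int(sites[-1])
    return int(sites[i - 1] if pos - sites[i - 1] <= sites[i] - pos else sites[i])


def simulate_fragments(
    genome: GenomeRef,
    truth: RloopTruth,
    depth: int = 100_000,
    frag_len_mean: float = 250.0,
    frag_len_sd: float = 50.0,
    enrichment: float = 20.0,
    background_rate: float = 1.0,
    boundary_model: str = "mbn",
    mbn_sigma: float = 2.0,
    cut_sites: dict[str, np.ndarray] | None = None,
    rnaseh_null: bool = False,
    namespace: str = TARGET,
    library: str = "rloop",
    seed: int = 0,
) -> tuple[list[Fragment], np.ndarray]:
    """Simulate one fragment library over the planted truth.

    Each fragment is a planted-region draw with probability
    ``p_sig = enrichment*W / (enrichment*W + background_rate*B)`` (W = total
    planted bases weighted by region weight, B = total background bases),
    else a uniform background draw with random strand.

    ``boundary_model="mbn"`` trims signal fragments to the planted region
    boundaries with Gaussian jitter (sd ``mbn_sigma``); ``"re"`` snaps every
    fragment end (signal and background) to the nearest cut coordinate in
    ``cut_sites`` (per-chromosome sorted arrays, required for this model).

    Returns the fragment list and a boolean array marking signal draws.
    """
    if boundary_model not in ("mbn", "re"):
        raise ValueError(f"unknown boundary_model {boundary_model!r}")
    rng = np.random.default_rng(seed)
    chroms = genome.chroms(namespace)
    if boundary_model == "re":
        if cut_sites is None:
            raise ValueError("re boundary model requires cut_sites")
        for c in chroms:
            if c not in cut_sites or len(cut_sites[c]) == 0:
                raise ValueError(f"no cut sites on chromosome {c!r}")
    chrom_len = {c: genome.chrom_lengths[c] for c in chroms}
    genome_mass = float(sum(chrom_len.values()))
    reg = [r for r in truth.regions if r.chrom in chrom_len]
    w_per_region = np.array(
        [(r.end - r.start) * w for r, w in zip(truth.regions, truth.weights)
         if r.chrom in chrom_len]
    )
    W = float(w_per_region.sum())
    B = max(genome_mass - sum(r.end - r.start for r in reg), 1.0)
    p_sig = 0.0 if (rnaseh_null or W == 0) else (
        enrichment * W / (enrichment * W + background_rate * B)
    )

    is_signal = rng.random(depth) < p_sig
    n_sig = int(is_signal.sum())
    frag_lens = _truncnorm_lengths(rng, depth, frag_len_mean, frag_len_sd)

    fragments: list[Fragment] = [None] * depth  # type: ignore[list-item]
    if n_sig:
        ridx = rng.choice(len(reg), size=n_sig, p=w_per_region / W)
    sig_i = 0
    chrom_arr = np.array(chroms)
    probs = np.array([chrom_len[c] for c in chroms], dtype=float)
    bg_chroms = chrom_arr[rng.choice(len(chroms), size=depth, p=probs / probs.sum())]
    bg_strands = np.where(rng.random(depth) < 0.5, "+", "-")
    for i in range(depth):
        if is_signal[i]:
            r = reg[ridx[sig_i]]
            sig_i += 1
            if boundary_model == "mbn":
                s = int(round(r.start + rng.normal(0, mbn_sigma))) if mbn_sigma else r.start
                e = int(round(r.end + rng.normal(0, mbn_sigma))) if mbn_sigma else r.end
                s = max(0, min(s, r.end - 1))
                e = min(chrom_len[r.chrom], max(e, s + 1))
            else:
                sites = cut_sites[r.chrom]
                s = _snap_to_sites(r.start, sites)
                e = _snap_to_sites(r.end, sites)
                if e <= s:
                    j = min(np.searchsorted(sites, s, side="right"), len(sites) - 1)
                    e = int(sites[j]) if sites[j] > s else s + 1
            strand = r.strand
            chrom = r.chrom
        else:
            chrom = bg_chroms[i]
            L = min(int(frag_lens[i]), chrom_len[chrom] - 1)
            s = int(rng.integers(0, chrom_len[chrom] - L))
            e = s + L
            if boundary_model == "re":
                sites = cut_sites[chrom]
                s2, e2 = _snap_to_sites(s, sites), _snap_to_sites(e, sites)
                if e2 > s2:
                    s, e = s2, e2
                else:
                    j = min(np.searchsorted(sites, s2, side="right"), len(sites) - 1)
                    s, e = s2, (int(sites[j]) if sites[j] > s2 else s2 + 1)
            strand = str(bg_strands[i])
        if library == "input":
            strand = "."
        fragments[i] = Fragment(chrom, s, e, strand, namespace, library)
    return fragments, is_signal


def simulate_spikein_pair(
    genome: GenomeRef,
    target_truth: RloopTruth,
    spike_truth: RloopTruth,
    target_global_level: float = 1.0,
    spike_global_level: float = 1.0,
    depths: dict[str, int] | None = None,
    enrichment: float = 20.0,
    seed: int = 0,
) -> dict[str, list[Fragment]]:
    """Simulate matched rloop + input libraries over a combined namespace.

    The rloop library allocates fragments to the target vs. spike-in genome
    in proportion to ``global_level x genome mass``; the input library in
    proportion to genome mass alone. The ratio of two samples'
    ``target_global_level`` (at equal spike settings) is therefore the
    ground truth that the quantification chain must recover.
    """
    if target_global_level <= 0 or spike_global_level <= 0:
        raise ValueError("global levels must be > 0")
    depths = depths or {"rloop": 100_000, "input": 100_000}
    if depths.get("rloop", 0) <= 0 or depths.get("input", 0) <= 0:
        raise ValueError("both library depths must be positive")
    rng = np.random.default_rng(seed)
    m_t = float(sum(genome.chrom_lengths[c] for c in genome.chroms(TARGET)))
    m_s = float(sum(genome.chrom_lengths[c] for c in genome.chroms(SPIKEIN)))
    if m_s == 0:
        raise ValueError("genome has no spike-in chromosomes")
    out: dict[str, list[Fragment]] = {}
    for lib in ("rloop", "input"):
        if lib == "rloop":
            w_t = target_global_level * m_t
            w_s = spike_global_level * m_s
        else:
            w_t, w_s = m_t, m_s
        n = depths[lib]
        n_t = int(rng.binomial(n, w_t / (w_t + w_s)))
        frags: list[Fragment] = []
        for ns, truth, n_ns in (
            (TARGET, target_truth, n_t),
            (SPIKEIN, spike_truth, n - n_t),
        ):
            f, _ = simulate_fragments(
                genome, truth, depth=n_ns,
                enrichment=enrichment if lib == "rloop" else 0.0,
                rnaseh_null=(lib == "input"),
                namespace=ns, library=lib,
                seed=int(rng.integers(2**31)),
            )
            frags.extend(f)
        out[lib] = frags
    return out


# ---------------------------------------------------------------------------
# BAM emission


def write_fragments_bam(
    fragments: Sequence[Fragment],
    genome: GenomeRef,
    path: str | Path,
    read_len: int = 75,
    strand_convention: str = "mate1-forward",
) -> None:
    """Encode fragments as coordinate-sorted synthetic proper pairs (NM=0).

    Under ``mate1-forward``, a '+' fragment puts mate1 on the forward strand
    at the fragment start; '-' reverses the roles; '.' fragments (input
    libraries) get an arbitrary '+' layout.
    """
    path = str(path)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": c, "LN": genome.chrom_lengths[c]} for c in genome.chrom_lengths
        ],
    }
    tid = {c: i for i, c in enumerate(genome.chrom_lengths)}
    flip = strand_convention == "mate1-reverse"
    tmp = path + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
        for i, frag in enumerate(fragments):
            rl = min(read_len, len(frag))
            plus_layout = (frag.strand == "+") != flip or frag.strand == "."
            for is_read1 in (True, False):
                a = pysam.AlignedSegment()
                a.query_name = f"frag{i}"
                a.reference_id = tid[frag.chrom]
                fwd = is_read1 == plus_layout
                a.reference_start = frag.start if fwd else frag.end - rl
                a.cigarstring = f"{rl}M"
                a.query_sequence = "A" * rl
                a.query_qualities = pysam.qualitystring_to_array("I" * rl)
                a.mapping_quality = 60
                a.is_paired = True
                a.is_proper_pair = True
                a.is_read1 = is_read1
                a.is_read2 = not is_read1
                a.is_reverse = not fwd
                a.mate_is_reverse = fwd
                a.next_reference_id = tid[frag.chrom]
                a.next_reference_start = frag.end - rl if fwd else frag.start
                a.template_length = len(frag) if fwd else -len(frag)
                a.set_tag("NM", 0)
                bam.write(a)
    pysam.sort("-o", path, tmp)
    Path(tmp).unlink()
    pysam.index(path)


def write_truth_bed(truth: RloopTruth, path: str | Path) -> None:
    write_bed(truth.regions, path)


# ---------------------------------------------------------------------------
# artificial half-R-loop substrate

# Designed substrate components: an in-vitro-transcribed RNA reverse
# transcribed from a tailed primer, with a paired oligo making most of the
# tail double-stranded. Coordinates below are on the cDNA strand (Watson):
# [0, 47) double-stranded tail, [47, 53) single-stranded gap, [53, 256)
# RNA:DNA hybrid. The hybrid/dsDNA junction is h_start = 53.
SUBSTRATE_RNA = (
    "GGGAUGGUGCUGGACUCAUUCGGCAUCGGCGCUACAGAAGAUGCAGAACGCUUUGGUGACGUCGGGGCUGAC"
    "ACCCUGGGUCAUAUCGCAGAAGCUUGUGCCAAAGGCGAAGCUGAUAACGGUCGUAAAGGCCCGCUCAAUCUG"
    "CCAAAUCUGACCCGUCUGGGGCUGGCGAAAGCACACGAAGGUUCUACCGGUUUCAUUCC"
)
SUBSTRATE_PRIMER = "ACGTGTCATGACTGACACTGGCAGTACGTAGCAGTGGTAGAACCTTCGTGTGC"
SUBSTRATE_OLIGO = "TTCTACCACGGAACTGCTACGTACTGCCAGTGTCAGTCATGACACGT"

_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


@dataclass
class SubstrateDesign:
    """Artificial half R-loop: hybrid span joined to a (partly) ds tail."""

    sequence: str
    h_start: int
    h_end: int
    ds_span: tuple[int, int] = (0, 0)
    ss_span: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not (0 <= self.h_start < self.h_end <= len(self.sequence)):
            raise ValueError("hybrid span outside substrate")

    @property
    def junction(self) -> int:
        return self.h_start


def default_substrate() -> SubstrateDesign:
    """The bundled substrate built from the designed RNA/primer/oligo."""
    cdna = SUBSTRATE_PRIMER + _revcomp(SUBSTRATE_RNA.replace("U", "T"))
    return SubstrateDesign(
        sequence=cdna,
        h_start=len(SUBSTRATE_PRIMER),
        h_end=len(cdna),
        ds_span=(0, len(SUBSTRATE_OLIGO)),
        ss_span=(len(SUBSTRATE_OLIGO), len(SUBSTRATE_PRIMER)),
    )


class SubstrateRead(NamedTuple):
    strand: str
    start: int
    end: int

    @property
    def first_base(self) -> int:
        """5'-most template coordinate of the read."""
        return self.start if self.strand == "+" else self.end - 1


def simulate_substrate_reads(
    design: SubstrateDesign,
    nuclease_model: str = "mbn",
    n_reads: int = 10_000,
    seed: int = 0,
) -> list[SubstrateRead]:
    """Simulate hybrid-product reads; model 'mbn' is exact, 'noisy:S' jitters.

    Exact digestion yields fragments spanning exactly [h_start, h_end);
    'noisy:S' adds independent Gaussian jitter (sd S) to both ends. Reads
    alternate Watson/Crick so both first-base profiles are populated.
    """
    rng = np.random.default_rng(seed)
    sigma = 0.0
    if nuclease_model.startswith("noisy"):
        sigma = float(nuclease_model.split(":")[1]) if ":" in nuclease_model else 1.0
    elif nuclease_model != "mbn":
        raise ValueError(f"unknown nuclease_model {nuclease_model!r}")
    L = len(design.sequence)
    reads = []
    for i in range(n_reads):
        s, e = design.h_start, design.h_end
        if sigma:
            s = int(round(s + rng.normal(0, sigma)))
            e = int(round(e + rng.normal(0, sigma)))
            s = max(0, min(s, L - 1))
            e = max(s + 1, min(e, L))
        reads.append(SubstrateRead("+" if i % 2 == 0 else "-", s, e))
    return reads
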