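"""Domain types and readers/writers shared by every analysis stage.

Coordinate convention: 0-based half-open everywhere internally. BED and
bedGraph are native to that convention; SAM's 1-based coordinates are
converted at the boundary by pysam.

The central objects are :class:`GenomeRef` (the coordinate frame, including
the target/spike-in namespace split and the set of chromosomes excluded
from normalization, by default chrM), :class:`Fragment` (one sequenced
molecule, i.e. the full span of a properly paired read pair), and
:class:`SignalTrack` (binned strand-resolved coverage).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pysam
from Bio.SeqIO.FastaIO import SimpleFastaParser

TARGET = "target"
SPIKEIN = "spikein"

VALID_STRANDS = {"+", "-", "."}


class Region(NamedTuple):
    """One BED-style interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."


@dataclass
class GenomeRef:
    """Named chromosomes with lengths, namespaces and normalization exclusions.

    Parameters
    ----------
    chrom_lengths
        Ordered mapping of chromosome name to length in bases.
    namespace_map
        Chromosome -> ``"target"`` or ``"spikein"``. Defaults to all-target.
    ignored_chroms
        Chromosomes excluded from RPGC normalization and total-level counts.
        Defaults to ``{"chrM"}`` intersected with the present chromosomes;
        an explicitly passed set must be a subset of the chromosome names.
    """

    chrom_lengths: dict[str, int]
    namespace_map: dict[str, str] = field(default_factory=dict)
    ignored_chroms: frozenset[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("genome has no chromosomes")
        for chrom, length in self.chrom_lengths.items():
            if length < 1:
                raise ValueError(f"chromosome {chrom!r} has length {length} < 1")
        if not self.namespace_map:
            self.namespace_map = {c: TARGET for c in self.chrom_lengths}
        missing = set(self.chrom_lengths) - set(self.namespace_map)
        if missing:
            raise ValueError(f"namespace_map misses chromosomes: {sorted(missing)}")
        bad_ns = {v for v in self.namespace_map.values()} - {TARGET, SPIKEIN}
        if bad_ns:
            raise ValueError(f"unknown namespaces: {sorted(bad_ns)}")
        if self.ignored_chroms is None:
            self.ignored_chroms = frozenset({"chrM"} & set(self.chrom_lengths))
        else:
            self.ignored_chroms = frozenset(self.ignored_chroms)
            extra = self.ignored_chroms - set(self.chrom_lengths)
            if extra:
                raise ValueError(f"ignored_chroms not in genome: {sorted(extra)}")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    def chroms(self, namespace: str | None = None, include_ignored: bool = True) -> list[str]:
        out = []
        for c in self.chrom_lengths:
            if namespace is not None and self.namespace_map[c] != namespace:
                continue
            if not include_ignored and c in self.ignored_chroms:
                continue
            out.append(c)
        return out

    def effective_length(self, namespace: str = TARGET) -> int:
        """Total bases on non-ignored chromosomes of a namespace."""
        return sum(
            self.chrom_lengths[c] for c in self.chroms(namespace, include_ignored=False)
        )


class Fragment(NamedTuple):
    """One sequenced DNA fragment (full pair span), the R-loop evidence unit."""

    chrom: str
    start: int
    end: int
    strand: str  # '+', '-' or '.' (input libraries)
    namespace: str  # 'target' | 'spikein'
    library: str  # 'rloop' | 'input'

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:  # span length in bases
        return self.end - self.start


class RegionSet:
    """Ordered BED-semantics intervals with optional strand/score."""

    def __init__(self, regions: Iterable[Region] = (), sorted_: bool = False):
        self.regions: list[Region] = [Region(*r) for r in regions]
        for r in self.regions:
            if r.start >= r.end:
                raise ValueError(f"empty/inverted interval {r}")
            if r.strand not in VALID_STRANDS:
                raise ValueError(f"bad strand in {r}")
        self.sorted = sorted_

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __getitem__(self, i):
        return self.regions[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionSet) and self.regions == other.regions

    def sort(self) -> "RegionSet":
        self.regions.sort(key=lambda r: (r.chrom, r.start, r.end))
        self.sorted = True
        return self

    def filter(self, predicate) -> "RegionSet":
        return RegionSet([r for r in self.regions if predicate(r)], sorted_=self.sorted)

    def total_bases(self) -> int:
        return sum(r.end - r.start for r in self.regions)

    def merge(self, gap: int = 0) -> "RegionSet":
        """Union-merge overlapping or within-``gap`` intervals (strand ignored)."""
        merged: list[Region] = []
        for r in sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end)):
            if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end + gap:
                last = merged[-1]
                merged[-1] = last._replace(end=max(last.end, r.end))
            else:
                merged.append(Region(r.chrom, r.start, r.end))
        return RegionSet(merged, sorted_=True)


@dataclass
class SignalTrack:
    """Binned coverage with the multiplicative normalization already applied."""

    bin_size: int
    data: dict[str, np.ndarray]
    strand: str = "both"  # '+', '-' or 'both'
    norm_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")

    def n_bins(self, chrom: str) -> int:
        return len(self.data[chrom])

    def values_over(self, chrom: str, start: int, end: int) -> float:
        """Mean track value over [start, end), weighting partial bins."""
        arr = self.data[chrom]
        b0 = start // self.bin_size
        b1 = (end - 1) // self.bin_size
        total = 0.0
        for b in range(b0, min(b1, len(arr) - 1) + 1):
            lo = max(start, b * self.bin_size)
            hi = min(end, (b + 1) * self.bin_size)
            total += arr[b] * (hi - lo)
        return total / (end - start)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, namespace_map: dict[str, str] | None = None,
               ignored_chroms: set[str] | None = None) -> tuple[GenomeRef, dict[str, str]]:
    """Read a FASTA file into a GenomeRef plus upper-cased sequences.

    Order is preserved; duplicate names and empty files are errors.
    """
    seqs: dict[str, str] = {}
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            name = title.split()[0]
            if name in seqs:
                raise ValueError(f"duplicate sequence name {name!r} in {path}")
            seqs[name] = seq.upper()
    if not seqs:
        raise ValueError(f"empty FASTA file: {path}")
    genome = GenomeRef(
        {n: len(s) for n, s in seqs.items()},
        namespace_map=dict(namespace_map) if namespace_map else {},
        ignored_chroms=ignored_chroms,
    )
    return genome, seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM/BAM -> fragments


def load_fragments(
    alignment_path: str | Path,
    genome: GenomeRef,
    min_mapq: int = 0,
    strand_convention: str = "mate1-forward",
    library: str = "rloop",
    max_mismatches: int = 3,
) -> tuple[list[Fragment], Counter]:
    """Load properly paired primary alignments as fragments.

    One :class:`Fragment` per proper pair, spanning leftmost to rightmost
    aligned base of the two mates. Pairs failing the mapq, properly-paired
    or mismatch filter (NM > ``max_mismatches`` on either mate) are dropped
    and counted. Pairs lacking an NM tag pass the mismatch filter.

    Returns ``(fragments, dropped)`` where ``dropped`` counts the drop
    reasons plus ``"pairs_emitted"``.
    """
    if strand_convention not in ("mate1-forward", "mate1-reverse"):
        raise ValueError(f"unknown strand_convention {strand_convention!r}")
    path = str(alignment_path)
    mode = "rb" if path.endswith(".bam") else "r"
    counts: Counter = Counter()
    fragments: list[Fragment] = []
    pending: dict[str, pysam.AlignedSegment] = {}

    with pysam.AlignmentFile(path, mode) as af:
        so = (af.header.to_dict().get("HD") or {}).get("SO")
        if so is not None and so != "coordinate":
            raise ValueError(f"alignment not coordinate-sorted (SO={so})")
        last_pos: dict[str, int] = {}
        for read in af:
            if read.is_unmapped or read.mate_is_unmapped:
                counts["unmapped"] += 1
                continue
            if read.is_secondary or read.is_supplementary:
                counts["secondary"] += 1
                continue
            chrom = read.reference_name
            if chrom not in genome.chrom_lengths:
                raise ValueError(f"chromosome {chrom!r} absent from genome reference")
            if so is None:
                if read.reference_start < last_pos.get(chrom, 0):
                    raise ValueError("alignment not coordinate-sorted")
                last_pos[chrom] = read.reference_start
            if not read.is_proper_pair:
                counts["not_proper_pair"] += 1
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            pair = (mate, read)
            if any(r.mapping_quality < min_mapq for r in pair):
                counts["low_mapq"] += 1
                continue
            nm = [r.get_tag("NM") for r in pair if r.has_tag("NM")]
            if len(nm) < 2:
                counts["missing_nm"] += 1  # logged, still passes
            if any(v > max_mismatches for v in nm):
                counts["high_mismatch"] += 1
                continue
            if pair[0].reference_name != pair[1].reference_name:
                counts["interchrom"] += 1
                continue
            start = min(r.reference_start for r in pair)
            end = max(r.reference_end for r in pair)
            mate1 = pair[0] if pair[0].is_read1 else pair[1]
            strand = "-" if mate1.is_reverse else "+"
            if strand_convention == "mate1-reverse":
                strand = "+" if strand == "-" else "-"
            if library == "input":
                strand = "."
            fragments.append(
                Fragment(chrom, start, end, strand, genome.namespace_map[chrom], library)
            )
            counts["pairs_emitted"] += 1
    counts["orphans"] += len(pending)
    return fragments, counts


# ---------------------------------------------------------------------------
# BED


def write_bed(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            score = int(r.score) if float(r.score).is_integer() else r.score
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{score}\t{r.strand}\n")


def read_bed(path: str | Path) -> RegionSet:
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "."
                score = float(fields[4]) if len(fields) > 4 else 0.0
                strand = fields[5] if len(fields) > 5 else "."
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}") from exc
            regions.append(Region(chrom, start, end, name, score, strand))
    return RegionSet(regions)


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Emit non-zero runs of equal-valued bins; zero bins are implicit."""
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom, arr in track.data.items():
            run_start = None
            run_val = 0.0
            for i, v in enumerate(arr):
                if run_start is not None and v != run_val:
                    if run_val != 0:
                        fh.write(f"{chrom}\t{run_start * bs}\t{i * bs}\t{run_val:g}\n")
                    run_start = None
                if run_start is None and v != 0:
                    run_start, run_val = i, v
            if run_start is not None and run_val != 0:
                fh.write(f"{chrom}\t{run_start * bs}\t{len(arr) * bs}\t{run_val:g}\n")


def read_bedgraph(
    path: str | Path, genome: GenomeRef, bin_size: int, strand: str = "both"
) -> SignalTrack:
    """Read a bedGraph whose intervals are aligned to ``bin_size`` bins.

    The final interval of a chromosome may end at the chromosome end even
    when that is not a bin multiple (the last bin is partial).
    """
    data = {
        c: np.zeros(math.ceil(L / bin_size)) for c, L in genome.chrom_lengths.items()
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end, value = (
                    fields[0], int(fields[1]), int(fields[2]), float(fields[3]),
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"{path}: malformed bedGraph line {lineno}: {line!r}"
                ) from exc
            if chrom not in data:
                raise ValueError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
            chrom_len = genome.chrom_lengths[chrom]
            if start % bin_size or (end % bin_size and end != chrom_len):
                raise ValueError(
                    f"{path}: line {lineno}: interval [{start},{end}) not aligned "
                    f"to bin size {bin_size}"
                )
            data[chrom][start // bin_size: math.ceil(end / bin_size)] = value
    return SignalTrack(bin_size=bin_size, data=data, strand=strand)
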