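"""Strand partitioning, RPGC coverage, and spike-in quantification.

The quantification chain makes R-loop levels comparable across samples that
received the same absolute amount of spike-in DNA. Per sample *n* with
fragment counts T_Rloop (rloop library on the target genome), T_input,
S_Rloop and S_input (spike-in genome):

    QF(n)  = [T_Rloop(n) * S_input(n)] / [S_Rloop(n) * T_input(n)]
    FNF(n) = QF(n) * NF(ref) / QF(ref)

where NF(ref) is the RPGC (reads-per-genomic-content, 1x depth) factor of
the reference sample's target rloop fragments. QF cancels both library
depths, so it responds only to the genuine target-to-spike-in R-loop ratio.
Mitochondrial (or otherwise ignored) chromosomes never enter the factors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import SPIKEIN, TARGET, Fragment, GenomeRef, SignalTrack


def split_strands(
    fragments: Iterable[Fragment], convention: str = "mate1-forward"
) -> tuple[list[Fragment], list[Fragment], int]:
    """Partition stranded fragments into (wR, cR, n_excluded).

    Under ``mate1-forward`` a '+' fragment is a wR-loop (Watson ssDNA
    displaced) and '-' a cR-loop; ``mate1-reverse`` swaps the sets.
    Unstranded ('.') fragments are excluded with a warning count.
    """
    if convention not in ("mate1-forward", "mate1-reverse"):
        raise ValueError(f"unknown convention {convention!r}")
    flip = convention == "mate1-reverse"
    wr, cr, excluded = [], [], 0
    for f in fragments:
        if f.strand == ".":
            excluded += 1
        elif (f.strand == "+") != flip:
            wr.append(f)
        else:
            cr.append(f)
    if excluded:
        warnings.warn(f"{excluded} unstranded fragments excluded from wR/cR split")
    return wr, cr, excluded


def rpgc_factor(fragments: Sequence[Fragment], genome: GenomeRef) -> float:
    """RPGC scale: effective genome length / total fragment bases.

    Ignored chromosomes (chrM by default) contribute neither length nor
    bases, matching the ignoreForNormalization convention. Applying the
    factor makes genome-wide mean coverage exactly 1.
    """
    keep = set(genome.chroms(TARGET, include_ignored=False))
    l_eff = genome.effective_length(TARGET)
    b = sum(len(f) for f in fragments if f.chrom in keep)
    if b == 0:
        raise ValueError("no fragment bases on non-ignored chromosomes")
    return l_eff / b


def coverage_track(
    fragments: Iterable[Fragment],
    genome: GenomeRef,
    bin_size: int = 10,
    strand: str = "both",
    scale: float = 1.0,
    namespace: str = TARGET,
) -> SignalTrack:
    """Binned fragment-base coverage: bin value = overlap bases / bin_size * scale."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    chroms = genome.chroms(namespace)
    # base-resolution difference arrays, then cumulative sum and bin-sum
    diffs = {c: np.zeros(genome.chrom_lengths[c] + 1) for c in chroms}
    for f in fragments:
        if strand != "both" and f.strand != strand:
            continue
        if f.chrom not in diffs:
            continue
        diffs[f.chrom][f.start] += 1
        diffs[f.chrom][f.end] -= 1
    data = {}
    for c in chroms:
        cov = np.cumsum(diffs[c][:-1])
        n_bins = math.ceil(len(cov) / bin_size)
        pad = n_bins * bin_size - len(cov)
        if pad:
            cov = np.concatenate([cov, np.zeros(pad)])
        data[c] = cov.reshape(n_bins, bin_size).sum(axis=1) / bin_size * scale
    return SignalTrack(bin_size=bin_size, data=data, strand=strand, norm_factor=scale)


@dataclass
class Sample:
    """One sequencing sample: matched rloop and input fragment lists."""

    name: str
    rloop: list[Fragment]
    input: list[Fragment]


def _counts(sample: Sample, genome: GenomeRef) -> dict[str, int]:
    target_keep = set(genome.chroms(TARGET, include_ignored=False))
    spike = set(genome.chroms(SPIKEIN))
    return {
        "T_Rloop": sum(1 for f in sample.rloop if f.chrom in target_keep),
        "T_input": sum(1 for f in sample.input if f.chrom in target_keep),
        "S_Rloop": sum(1 for f in sample.rloop if f.chrom in spike),
        "S_input": sum(1 for f in sample.input if f.chrom in spike),
    }


def quant_factors(
    samples: Sequence[Sample], genome: GenomeRef, reference_sample: str | None = None
) -> pd.DataFrame:
    """Compute the per-sample quantification table (counts, QF, FNF).

    Counts are fragments (molecules), restricted to non-ignored target
    chromosomes on the target side. The reference sample's FNF equals its
    own RPGC factor exactly.
    """
    if not samples:
        raise ValueError("no samples")
    names = [s.name for s in samples]
    reference_sample = reference_sample or names[0]
    if reference_sample not in names:
        raise ValueError(f"reference sample {reference_sample!r} not among {names}")
    rows = []
    for s in samples:
        c = _counts(s, genome)
        for key in ("S_Rloop", "T_input"):
            if c[key] == 0:
                raise ValueError(f"sample {s.name!r}: zero {key} count")
        c["QF"] = (c["T_Rloop"] * c["S_input"]) / (c["S_Rloop"] * c["T_input"])
        rows.append({"sample": s.name, **c})
    table = pd.DataFrame(rows).set_index("sample")
    ref = next(s for s in samples if s.name == reference_sample)
    target_keep = set(genome.chroms(TARGET, include_ignored=False))
    nf_ref = rpgc_factor([f for f in ref.rloop if f.chrom in target_keep], genome)
    table["NF_ref"] = nf_ref
    table["FNF"] = table["QF"] * nf_ref / table.loc[reference_sample, "QF"]
    table.attrs["reference_sample"] = reference_sample
    return table


def total_rloop_level(quant: pd.DataFrame, reference_sample: str | None = None) -> pd.Series:
    """Relative total R-loop level per sample (reference = 1.0).

    level(n) = T_Rloop(n)/T_input(n) * S_input(n)/S_Rloop(n), i.e. the
    spike-calibrated R-loop content of the target genome, reported relative
    to the reference sample.
    """
    reference_sample = reference_sample or quant.attrs.get(
        "reference_sample", quant.index[0]
    )
    raw = (quant["T_Rloop"] / quant["T_input"]) * (quant["S_input"] / quant["S_Rloop"])
    out = raw / raw.loc[reference_sample]
    out.name = "relative_total_rloop_level"
    return out
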