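"""GC and AT skew: per-sequence values, sliding-window tracks, metaprofiles.

GC skew = (G - C) / (G + C) and AT skew = (A - T) / (A + T), counted on the
Watson strand of the reference. R-loops whose displaced ssDNA is the Watson
strand (wR) favor positive skew; cR-loops mirror it. Windows with no
informative bases are missing values (NaN), never 0: zero means "balanced".

Defaults follow the field convention of a 200 bp window advanced in 50 bp
steps, with each window's value anchored at its midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import GenomeRef, RegionSet

_ALLOWED = set("ACGTN")


def _base_counts(seq: str) -> dict[str, int]:
    bad = set(seq.upper()) - _ALLOWED
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    s = seq.upper()
    return {b: s.count(b) for b in "ACGT"}


def gc_skew(sequence: str) -> float:
    """(G - C)/(G + C) on the Watson strand; NaN when G + C = 0."""
    c = _base_counts(sequence)
    denom = c["G"] + c["C"]
    return (c["G"] - c["C"]) / denom if denom else float("nan")


def at_skew(sequence: str) -> float:
    """(A - T)/(A + T) on the Watson strand; NaN when A + T = 0."""
    c = _base_counts(sequence)
    denom = c["A"] + c["T"]
    return (c["A"] - c["T"]) / denom if denom else float("nan")


def _cum_counts(seq: str) -> dict[str, np.ndarray]:
    """Cumulative base counts for O(1) window queries."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    bad = set(np.unique(arr)) - {ord(b) for b in _ALLOWED}
    if bad:
        raise ValueError(f"non-IUPAC characters: {[chr(b) for b in sorted(bad)]}")
    out = {}
    for b in "ACGT":
        out[b] = np.concatenate([[0], np.cumsum(arr == ord(b))])
    return out


def _window_skews(cum, starts, window):
    g = cum["G"][starts + window] - cum["G"][starts]
    c = cum["C"][starts + window] - cum["C"][starts]
    a = cum["A"][starts + window] - cum["A"][starts]
    t = cum["T"][starts + window] - cum["T"][starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = np.where(g + c > 0, (g - c) / np.maximum(g + c, 1), np.nan)
        at = np.where(a + t > 0, (a - t) / np.maximum(a + t, 1), np.nan)
    return gc, at


@dataclass
class SkewProfile:
    """Windowed skew values per chromosome, anchored at window midpoints."""

    window: int
    step: int
    starts: dict[str, np.ndarray] = field(default_factory=dict)
    gc: dict[str, np.ndarray] = field(default_factory=dict)
    at: dict[str, np.ndarray] = field(default_factory=dict)

    def midpoints(self, chrom: str) -> np.ndarray:
        return self.starts[chrom] + self.window // 2


def skew_track(
    seqs: dict[str, str], window: int = 200, step: int = 50
) -> SkewProfile:
    """Sliding-window GC/AT skew; windows fully inside the chromosome."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    prof = SkewProfile(window=window, step=step)
    for chrom, seq in seqs.items():
        if len(seq) < window:
            prof.starts[chrom] = np.array([], dtype=int)
            prof.gc[chrom] = np.array([])
            prof.at[chrom] = np.array([])
            continue
        starts = np.arange(0, len(seq) - window + 1, step)
        cum = _cum_counts(seq)
        gc, at = _window_skews(cum, starts, window)
        prof.starts[chrom] = starts
        prof.gc[chrom] = gc
        prof.at[chrom] = at
    return prof


def skew_metaprofile(
    seqs: dict[str, str],
    regions: RegionSet,
    flank: int = 2000,
    n_bins: int = 40,
    strand_aware: bool = True,
    genome: GenomeRef | None = None,
) -> dict[str, np.ndarray]:
    """Mean GC/AT skew in ``n_bins`` bins across region midpoints +- flank.

    With ``strand_aware`` the bins of '-' regions are reversed and their
    skews negated (the reverse-complement view), so cR-loop regions with
    mirrored composition contribute positively. Regions whose window falls
    outside the chromosome are skipped and counted.

    Returns per-bin means and the per-region matrices (rows = used regions).
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    if 2 * flank % n_bins:
        raise ValueError("2*flank must be divisible by n_bins")
    bin_w = 2 * flank // n_bins
    mats = {"gc": [], "at": []}
    skipped = 0
    cums: dict[str, dict[str, np.ndarray]] = {}
    for r in regions:
        mid = (r.start + r.end) // 2
        lo = mid - flank
        if lo < 0 or mid + flank > len(seqs[r.chrom]):
            skipped += 1
            continue
        if r.chrom not in cums:
            cums[r.chrom] = _cum_counts(seqs[r.chrom])
        starts = lo + bin_w * np.arange(n_bins)
        gc, at = _window_skews(cums[r.chrom], starts, bin_w)
        if strand_aware and r.strand == "-":
            gc, at = -gc[::-1], -at[::-1]
        mats["gc"].append(gc)
        mats["at"].append(at)
    if not mats["gc"]:
        raise ValueError("all regions fell outside chromosome bounds")
    gc_mat = np.vstack(mats["gc"])
    at_mat = np.vstack(mats["at"])
    return {
        "gc_mean": np.nanmean(gc_mat, axis=0),
        "at_mean": np.nanmean(at_mat, axis=0),
        "gc_matrix": gc_mat,
        "at_matrix": at_mat,
        "n_skipped": skipped,
    }
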