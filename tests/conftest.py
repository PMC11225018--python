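"""Shared fixtures: small synthetic genomes with planted R-loop truth."""

import numpy as np
import pytest

from rloopkit import RegionSet, Region
from rloopkit.core_io import SPIKEIN, TARGET, GenomeRef
from rloopkit import synthdata as sd


@pytest.fixture(scope="session")
def planted():
    """1 Mb genome with 40 planted skew-biased R-loop regions (seed-fixed)."""
    genome, seqs = sd.make_genome({"chr1": 1_000_000}, gc_content=0.4, seed=11)
    truth, seqs = sd.plant_rloops(
        genome, seqs, n_regions=40, length_range=(500, 2000),
        strand_mix=0.5, skew_strength=0.3, seed=12,
    )
    return genome, seqs, truth


@pytest.fixture(scope="session")
def small_genome():
    """200 kb target chromosome plus a chrM, no spike-in."""
    genome, seqs = sd.make_genome({"chr1": 200_000, "chrM": 20_000}, seed=21)
    return genome, seqs


@pytest.fixture(scope="session")
def combined_genome():
    """Target + spike-in namespace genome with one planted truth each."""
    lengths = {"t1": 400_000, "spk1": 80_000}
    genome = GenomeRef(lengths, {"t1": TARGET, "spk1": SPIKEIN})
    rng = np.random.default_rng(31)
    t_truth = sd.RloopTruth(
        RegionSet([Region("t1", int(s), int(s) + 1500, f"t{i}", 0.0, "+")
                   for i, s in enumerate(rng.choice(380_000, 8, replace=False) // 2000 * 2000 + 2000)]).sort(),
        np.ones(8),
    )
    s_truth = sd.RloopTruth(
        RegionSet([Region("spk1", 10_000, 12_000, "s0", 0.0, "+"),
                   Region("spk1", 40_000, 42_000, "s1", 0.0, "-")]),
        np.ones(2),
    )
    return genome, t_truth, s_truth
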