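"""Peak calling, cut sites, boundary/junction diagnostics, compartments,
annotation, permutation enrichment, metaprofiles."""

import numpy as np
import pytest

from rloopkit import (
    Fragment,
    GenomeRef,
    Region,
    RegionSet,
    SignalTrack,
    annotate_peaks,
    boundary_distances,
    call_peaks,
    compartment_fractions,
    coverage_track,
    find_cut_sites,
    overlap_permutation_test,
    random_matched_regions,
    rpgc_factor,
    signal_metaprofile,
)
from rloopkit.regions import BUILTIN_ENZYMES, EnzymeSpec
from rloopkit import synthdata as sd


def brute_force_sites(seq, motif, offset):
    """Independent degenerate-motif scan used as oracle."""
    iupac = {"N": "ACGT", "A": "A", "C": "C", "G": "G", "T": "T"}
    hits = []
    for i in range(len(seq) - len(motif) + 1):
        if all(seq[i + j] in iupac[b] for j, b in enumerate(motif)):
            hits.append(i + offset)
    return hits


class TestCutSites:
    def test_mboi_example(self):
        sites = find_cut_sites({"c": "AAGATCAA"}, [BUILTIN_ENZYMES["MboI"]])
        assert sites["c"].tolist() == [2]

    def test_ddei_degenerate_example(self):
        sites = find_cut_sites({"c": "ACTGAGA"}, [BUILTIN_ENZYMES["DdeI"]])
        assert sites["c"].tolist() == [2]  # CTGAG at 1, cut offset 1

    def test_no_motif_empty(self):
        sites = find_cut_sites({"c": "AAAAAA"}, [BUILTIN_ENZYMES["MboI"]])
        assert len(sites["c"]) == 0

    def test_matches_brute_force_oracle(self, small_genome):
        _, seqs = small_genome
        seq = seqs["chr1"][:20_000]
        for enz in BUILTIN_ENZYMES.values():
            got = find_cut_sites({"c": seq}, [enz])["c"].tolist()
            assert got == sorted(set(brute_force_sites(seq, enz.motif, enz.cut_offset)))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            EnzymeSpec("bad", "GA", 0)
        with pytest.raises(ValueError):
            EnzymeSpec("bad", "GATC", 9)


@pytest.fixture(scope="module")
def called_peaks(planted):
    genome, _, truth = planted
    frags, _ = sd.simulate_fragments(genome, truth, depth=100_000,
                                     enrichment=20.0, seed=51)
    scale = rpgc_factor(frags, genome)
    track = coverage_track(frags, genome, bin_size=10, scale=scale)
    return call_peaks(track, genome), truth


class TestCallPeaks:
    def test_constant_track_yields_no_peaks(self):
        genome = GenomeRef({"c": 10_000})
        track = SignalTrack(10, {"c": np.ones(1000)})
        assert len(call_peaks(track, genome)) == 0

    def test_flat_zero_track_empty(self):
        genome = GenomeRef({"c": 10_000})
        track = SignalTrack(10, {"c": np.zeros(1000)})
        assert len(call_peaks(track, genome)) == 0

    def test_single_planted_block_found_once(self):
        genome = GenomeRef({"c": 100_000})
        vals = np.ones(10_000)
        vals[5000:5100] = 20.0  # 1 kb block at 20x background
        track = SignalTrack(10, {"c": vals})
        peaks = call_peaks(track, genome)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.start <= 50_000 and p.end >= 51_000 and p.end - p.start >= 200

    def test_size_filter_discards_small_candidate(self):
        genome = GenomeRef({"c": 100_000})
        vals = np.ones(10_000)
        vals[1000:1015] = 20.0  # 150 bp candidate
        vals[5000:5025] = 20.0  # 250 bp candidate
        track = SignalTrack(10, {"c": vals})
        peaks = call_peaks(track, genome, merge_gap=100, min_size=200)
        assert len(peaks) == 1
        assert peaks[0].start == 50_000

    def test_recall_precision_on_planted_truth(self, called_peaks):
        peaks, truth = called_peaks
        truth_spans = [(r.start, r.end) for r in truth.regions]
        hit = lambda a, b: a[0] < b[1] and b[0] < a[1]
        recall = np.mean([any(hit((r.start, r.end), t) for r in peaks)
                          for t in truth_spans])
        precision = np.mean([any(hit((p.start, p.end), t) for t in truth_spans)
                             for p in peaks])
        assert recall >= 0.9 and precision >= 0.9

    def test_every_peak_at_least_min_size(self, called_peaks):
        peaks, _ = called_peaks
        assert all(p.end - p.start >= 200 for p in peaks)


class TestBoundaryDistances:
    def test_bin_zero_within_extension(self):
        peaks = RegionSet([Region("c", 100, 400)])
        sites = {"c": np.array([97, 200, 395])}
        res = boundary_distances(peaks, sites, extend=5)
        assert res["bins"]["0"] == 2  # |100-97|=3, |400-395|=5

    def test_plain_distance(self):
        peaks = RegionSet([Region("c", 100, 1000)])
        res = boundary_distances(peaks, {"c": np.array([150, 1040])}, extend=5)
        assert sorted(res["distances"].tolist()) == [40, 50]
        assert res["bins"]["11-50"] == 2

    def test_empty_cut_sites_rejected(self):
        peaks = RegionSet([Region("c", 100, 400)])
        with pytest.raises(ValueError):
            boundary_distances(peaks, {"c": np.array([])})


class TestCompartments:
    def test_fraction_arithmetic(self):
        frags = (
            [Fragment("chrM", 0, 100, ".", "target", "rloop")] * 5
            + [Fragment("c", 1000, 1100, "+", "target", "rloop")] * 3
            + [Fragment("c", 9000, 9100, "+", "target", "rloop")] * 2
        )
        comps = [("mito", RegionSet([Region("chrM", 0, 20_000)])),
                 ("rDNA", RegionSet([Region("c", 500, 2000)]))]
        frac, _ = compartment_fractions(frags, comps)
        assert frac == {"mito": 0.5, "rDNA": 0.3, "other": 0.2}

    def test_priority_wins_on_overlap(self):
        f = Fragment("c", 100, 200, "+", "target", "rloop")
        comps = [("first", RegionSet([Region("c", 0, 1000)])),
                 ("second", RegionSet([Region("c", 0, 1000)]))]
        _, assign = compartment_fractions([f], comps)
        assert assign == ["first"]

    def test_partition_sums_to_one_fuzzed(self, planted):
        genome, _, truth = planted
        frags, _ = sd.simulate_fragments(genome, truth, depth=3000, seed=61)
        rng = np.random.default_rng(62)
        comps = []
        for i in range(3):
            s = int(rng.integers(0, 900_000))
            comps.append((f"c{i}", RegionSet([Region("chr1", s, s + 50_000)])))
        frac, assign = compartment_fractions(frags, comps)
        assert sum(frac.values()) == pytest.approx(1.0)
        assert len(assign) == len(frags)


class TestAnnotatePeaks:
    GENES = RegionSet([Region("c", 5000, 8000, "g1", 0.0, "+"),
                       Region("c", 20_000, 25_000, "g2", 0.0, "-")])

    def test_promoter_upstream_of_plus_gene(self):
        peaks = RegionSet([Region("c", 4400, 4600)])  # midpoint 4500
        assert annotate_peaks(peaks, self.GENES) == ["promoter"]

    def test_promoter_strand_aware_for_minus_gene(self):
        peaks = RegionSet([Region("c", 25_300, 25_500)])
        assert annotate_peaks(peaks, self.GENES) == ["promoter"]

    def test_gene_body_and_intergenic(self):
        peaks = RegionSet([Region("c", 6000, 6200), Region("c", 100, 300)])
        assert annotate_peaks(peaks, self.GENES) == ["gene_body", "intergenic"]

    def test_exhaustive_partition(self, planted):
        genome, _, truth = planted
        cats = annotate_peaks(truth.regions, self.GENES)
        assert len(cats) == len(truth.regions)
        assert set(cats) <= {"promoter", "gene_body", "intergenic"}


class TestPermutationTest:
    GENOME = GenomeRef({"c": 200_000})

    def test_nested_query_in_sparse_reference_extreme_p(self):
        rng = np.random.default_rng(71)
        starts = rng.choice(190_000, 20, replace=False)
        ref = RegionSet([Region("c", int(s), int(s) + 300) for s in starts])
        query = RegionSet([Region("c", r.start, r.end) for r in ref.regions[:10]])
        res = overlap_permutation_test(query, ref, self.GENOME, n_perm=999, seed=72)
        assert res["p"] <= 0.002
        assert res["observed"] == 10

    def test_p_bounds(self):
        ref = RegionSet([Region("c", 0, 200_000)])
        query = RegionSet([Region("c", 10, 20)])
        res = overlap_permutation_test(query, ref, self.GENOME, n_perm=99, seed=1)
        assert 1 / 100 <= res["p"] <= 1.0

    def test_zero_permutations_rejected(self):
        query = RegionSet([Region("c", 10, 20)])
        with pytest.raises(ValueError):
            overlap_permutation_test(query, query, self.GENOME, n_perm=0)

    def test_oversized_region_rejected(self):
        query = RegionSet([Region("c", 0, 200_000)])
        genome = GenomeRef({"c": 100})
        with pytest.raises(ValueError):
            overlap_permutation_test(query, query, genome, n_perm=10)

    def test_depletion_alternative(self):
        rng = np.random.default_rng(73)
        ref = RegionSet([Region("c", int(s), int(s) + 500)
                         for s in rng.choice(150_000, 50, replace=False)])
        far = RegionSet([Region("c", 190_000, 190_100)])
        res = overlap_permutation_test(far, ref, self.GENOME, n_perm=199,
                                       alternative="depletion", seed=74)
        assert 0 < res["p"] <= 1


class TestSignalMetaprofile:
    GENOME = GenomeRef({"c": 100_000})

    def _track(self, vals):
        return SignalTrack(10, {"c": vals})

    def test_constant_track(self):
        track = self._track(np.full(10_000, 3.0))
        regs = RegionSet([Region("c", 40_000, 42_000)])
        res = signal_metaprofile(track, regs, flank=1000, n_bins=20)
        np.testing.assert_allclose(res["mean"], 3.0)

    def test_center_mode_enriched_middle(self):
        vals = np.ones(10_000)
        vals[4000:4200] = 10.0
        track = self._track(vals)
        regs = RegionSet([Region("c", 40_000, 42_000)])
        res = signal_metaprofile(track, regs, flank=2000, n_bins=20)
        assert res["mean"][10] > res["mean"][0]

    def test_scale_regions_mode_runs(self):
        vals = np.ones(10_000)
        track = self._track(vals)
        regs = RegionSet([Region("c", 40_000, 41_000), Region("c", 60_000, 63_000)])
        res = signal_metaprofile(track, regs, flank=500, n_bins=20,
                                 mode="scale-regions")
        assert res["n_used"] == 2

    def test_matched_random_regions_preserve_lengths(self, planted):
        genome, _, truth = planted
        rnd = random_matched_regions(truth.regions, genome, seed=81)
        assert sorted(r.end - r.start for r in rnd) == sorted(
            r.end - r.start for r in truth.regions
        )
        assert [r.chrom for r in rnd] == [r.chrom for r in truth.regions]

    def test_empty_regions_rejected(self):
        with pytest.raises(ValueError):
            signal_metaprofile(self._track(np.ones(10)), RegionSet([]))
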