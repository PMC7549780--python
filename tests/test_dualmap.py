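"""Mapper: index geometry, seed-and-verify vs brute force, call rules."""

import numpy as np
import pytest

from hybridase import dualmap, simdata
from hybridase.dualmap import AlignmentHit, OriginCall, PairAlignment


def _mutate(seq: str, positions, rng) -> str:
    out = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != out[p]]
        out[p] = alternatives[rng.integers(0, 3)]
    return "".join(out)


class TestIndex:
    def test_forward_kmer_positions_per_gene(self):
        refs = simdata.simulate_references(1, 300, 0.0, seed=1, min_length=300)
        index = dualmap.DualIndex(refs, k=31)
        assert index.n_kmer_positions("A", "g0001") == 300 - 31 + 1
        assert index.n_kmer_positions("B", "g0001") == 270

    def test_duplicate_gene_triggers_multimap(self):
        seq = "".join(np.random.default_rng(2).choice(list("ACGT"), 400))
        refs = simdata.ParentalReferencePair(
            ["dup1", "dup2"], [seq, seq], [seq, seq], 0.0, 0
        )
        index = dualmap.DualIndex(refs, k=31)
        read = seq[50:150]
        hits = index.map_read(read, "A", 0)
        assert {(h.gene, h.position) for h in hits} == {("dup1", 50), ("dup2", 50)}

    def test_zero_divergence_hits_mirror_across_genomes(self):
        refs = simdata.simulate_references(3, 400, 0.0, seed=3)
        index = dualmap.DualIndex(refs, k=31)
        read = refs.seqs_a[1][100:200]
        hits_a = index.map_read(read, "A", 2)
        hits_b = index.map_read(read, "B", 2)
        assert [(h.gene, h.position, h.strand) for h in hits_a] == [
            (h.gene, h.position, h.strand) for h in hits_b
        ]


class TestMapRead:
    def test_exact_substring_single_hit(self, small_refs, small_index):
        read = small_refs.seqs_a[2][17:117]
        hits = small_index.map_read(read, "A", 2)
        assert hits == [AlignmentHit("A", small_refs.gene_ids[2], 17, "+", 0)]

    def test_reverse_strand_hit(self, small_refs, small_index):
        read = simdata.revcomp(small_refs.seqs_a[4][200:300])
        hits = small_index.map_read(read, "A", 0)
        assert hits == [AlignmentHit("A", small_refs.gene_ids[4], 200, "-", 0)]

    def test_three_mismatches_excluded_at_budget_two(self, small_refs, small_index):
        rng = np.random.default_rng(4)
        read = _mutate(small_refs.seqs_a[0][50:150], [10, 55, 90], rng)
        assert small_index.map_read(read, "A", 2) == []
        assert len(small_index.map_read(read, "A", 3)) == 1

    def test_n_counts_as_mismatch(self, small_refs, small_index):
        read = small_refs.seqs_a[1][30:130]
        read = read[:10] + "NNN" + read[13:]
        assert small_index.map_read(read, "A", 2) == []
        hits = small_index.map_read(read, "A", 3)
        assert hits and hits[0].mismatches == 3

    def test_invalid_character_rejected(self, small_index):
        with pytest.raises(ValueError, match="invalid characters"):
            small_index.map_read("ACGT" * 24 + "ACGX", "A", 2)

    @pytest.mark.parametrize("k", [31, 15])
    def test_equivalent_to_bruteforce_scan(self, k):
        """Seeded search equals the all-window oracle on 100 random reads.

        Mismatches are planted so that at least one intact k-length window
        remains, guaranteeing a seed exists for the true location.
        """
        refs = simdata.simulate_references(20, 500, 0.07, seed=11)
        index = dualmap.DualIndex(refs, k=k)
        rng = np.random.default_rng(12)
        for _ in range(100):
            gi = int(rng.integers(0, 20))
            start = int(rng.integers(0, 500 - 100 + 1))
            genome = "A" if rng.random() < 0.5 else "B"
            src = (refs.seqs_a if genome == "A" else refs.seqs_b)[gi]
            read = src[start : start + 100]
            n_mm = int(rng.integers(0, 3))
            # confine mismatches to the first third: windows beyond stay intact
            read = _mutate(read, rng.choice(33, size=n_mm, replace=False), rng)
            if rng.random() < 0.5:
                read = simdata.revcomp(read)
            for target in ("A", "B"):
                seeded = index.map_read(read, target, 2)
                brute = dualmap.map_read_bruteforce(read, refs, target, 2)
                assert seeded == brute


def _hit(genome, gene, pos, strand, mm):
    return AlignmentHit(genome, gene, pos, strand, mm)


def _pa(hits1, hits2, rid="p1"):
    h1 = {"A": [], "B": []}
    h2 = {"A": [], "B": []}
    for h in hits1:
        h1[h.genome].append(h)
    for h in hits2:
        h2[h.genome].append(h)
    return PairAlignment(rid, h1, h2, 100)


class TestClassifyPair:
    def test_unique_concordant_in_a_only_is_a_specific(self):
        pa = _pa([_hit("A", "g1", 10, "+", 0)], [_hit("A", "g1", 160, "-", 1)])
        call = dualmap.classify_pair(pa, "hybrid")
        assert call == OriginCall("p1", "A_specific", gene="g1", mismatches=1)

    def test_concordant_in_both_is_common(self):
        pa = _pa(
            [_hit("A", "g1", 10, "+", 0), _hit("B", "g1", 10, "+", 2)],
            [_hit("A", "g1", 160, "-", 0), _hit("B", "g1", 160, "-", 2)],
        )
        assert dualmap.classify_pair(pa, "hybrid").call == "common"

    def test_orphan_when_one_mate_unmapped(self):
        pa = _pa([_hit("A", "g1", 10, "+", 0)], [])
        call = dualmap.classify_pair(pa, "hybrid")
        assert (call.call, call.reason) == ("discarded", "orphan")

    def test_unmapped_when_no_mate_maps(self):
        call = dualmap.classify_pair(_pa([], []), "hybrid")
        assert (call.call, call.reason) == ("discarded", "unmapped")

    def test_discordant_same_strand(self):
        pa = _pa([_hit("A", "g1", 10, "+", 0)], [_hit("A", "g1", 160, "+", 0)])
        call = dualmap.classify_pair(pa, "hybrid")
        assert (call.call, call.reason) == ("discarded", "discordant")

    def test_fragment_span_outside_window_is_discordant(self):
        pa = _pa([_hit("A", "g1", 10, "+", 0)], [_hit("A", "g1", 400, "-", 0)])
        call = dualmap.classify_pair(pa, "hybrid")
        assert (call.call, call.reason) == ("discarded", "discordant")

    def test_two_best_locations_multimapped(self):
        pa = _pa(
            [_hit("A", "g1", 10, "+", 0), _hit("A", "g2", 50, "+", 0)],
            [_hit("A", "g1", 160, "-", 0), _hit("A", "g2", 200, "-", 0)],
        )
        call = dualmap.classify_pair(pa, "hybrid")
        assert (call.call, call.reason) == ("discarded", "multimapped")

    def test_suboptimal_second_location_is_not_multimapped(self):
        pa = _pa(
            [_hit("A", "g1", 10, "+", 0), _hit("A", "g2", 50, "+", 2)],
            [_hit("A", "g1", 160, "-", 0), _hit("A", "g2", 200, "-", 2)],
        )
        call = dualmap.classify_pair(pa, "hybrid")
        assert (call.call, call.gene) == ("A_specific", "g1")

    def test_parental_mode_consults_one_genome(self):
        pa = _pa(
            [_hit("A", "g1", 10, "+", 0), _hit("B", "g1", 10, "+", 1)],
            [_hit("A", "g1", 160, "-", 0), _hit("B", "g1", 160, "-", 1)],
        )
        call = dualmap.classify_pair(pa, "parental", conspecific="B")
        assert (call.call, call.gene) == ("B_specific", "g1")

    def test_mode_validation(self):
        with pytest.raises(ValueError, match="mode"):
            dualmap.classify_pair(_pa([], []), "other")


@pytest.fixture(scope="module")
def classified_sample():
    refs = simdata.simulate_references(10, 600, 0.07, seed=21)
    index = dualmap.DualIndex(refs, k=31)
    recs, truth = simdata.simulate_reads(
        refs, {"A": np.ones(10), "B": np.ones(10)}, 1000, error_rate=0.001, seed=22
    )
    calls = dualmap.classify_reads(recs, index, "hybrid")
    return refs, index, recs, truth, calls


class TestPipelineProperties:
    def test_partition_conservation(self, classified_sample):
        _, _, recs, _, calls = classified_sample
        assert len(calls) == len(recs)
        assert all(c.call in ("A_specific", "B_specific", "common", "discarded") for c in calls)

    def test_origin_accuracy_against_truth(self, classified_sample):
        _, _, _, truth, calls = classified_sample
        species = dict(zip(truth.table["read_id"], truth.table["species"]))
        specific = [c for c in calls if c.call.endswith("_specific")]
        correct = sum(c.call[0] == species[c.read_pair_id] for c in specific)
        assert len(specific) > 800
        assert correct / len(specific) >= 0.99

    def test_label_swap_symmetry(self, classified_sample):
        refs, _, recs, _, calls = classified_sample
        swapped_index = dualmap.DualIndex(refs.swapped(), k=31)
        swapped = dualmap.classify_reads(recs, swapped_index, "hybrid")
        orig = {c.read_pair_id: c.call for c in calls}
        flip = {"A_specific": "B_specific", "B_specific": "A_specific"}
        for c in swapped:
            assert c.call == flip.get(orig[c.read_pair_id], orig[c.read_pair_id])


class TestMismatchSweep:
    def test_fractions_partition_to_one(self, classified_sample):
        _, index, recs, _, _ = classified_sample
        sweep = dualmap.mismatch_sweep(recs[:300], index, [0, 1, 2])
        sums = sweep[["A_specific", "B_specific", "common", "discarded"]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_common_fraction_nondecreasing(self, classified_sample):
        _, index, recs, _, _ = classified_sample
        sweep = dualmap.mismatch_sweep(recs[:300], index, [0, 1, 2, 5, 10])
        common = sweep["common"].to_numpy()
        assert (np.diff(common) >= 0).all()

    def test_undiverged_references_yield_no_specific_reads(self):
        refs = simdata.simulate_references(5, 600, 0.0, seed=23)
        index = dualmap.DualIndex(refs, k=31)
        recs, _ = simdata.simulate_reads(refs, {"A": np.ones(5)}, 200, error_rate=0.0, seed=24)
        sweep = dualmap.mismatch_sweep(recs, index, [0, 1, 2])
        assert (sweep["A_specific"] == 0).all() and (sweep["B_specific"] == 0).all()
        assert (sweep["common"] > 0.9).all()

    def test_sweep_rejects_empty_or_negative(self, small_index):
        with pytest.raises(ValueError):
            dualmap.mismatch_sweep([], small_index, [])
        with pytest.raises(ValueError):
            dualmap.mismatch_sweep([("r", "A" * 100, "T" * 100)], small_index, [-1])


def test_classify_over_bruteforce_hits_matches_seeded(small_refs):
    """End-to-end oracle equivalence on a small instance."""
    index = dualmap.DualIndex(small_refs, k=31)
    recs, _ = simdata.simulate_reads(
        small_refs, {"A": np.ones(10), "B": np.ones(10)}, 150, error_rate=0.002, seed=31
    )
    seeded_calls = dualmap.classify_reads(recs, index, "hybrid")
    for (rid, m1, m2), seeded in zip(recs, seeded_calls):
        pa = PairAlignment(
            rid,
            {g: dualmap.map_read_bruteforce(m1, small_refs, g, 2) for g in "AB"},
            {g: dualmap.map_read_bruteforce(m2, small_refs, g, 2) for g in "AB"},
            100,
        )
        brute = dualmap.classify_pair(pa, "hybrid")
        assert brute == seeded
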