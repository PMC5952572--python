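"""Read attribution: exhaustive gapless mapping, host-first partition,
decoy filtering, locus construction and cross-mapping correction."""

import numpy as np
import pytest

from srnaclean._util import random_dna, revcomp
from srnaclean.attribution import (
    Locus,
    MappingHit,
    attribute_host,
    build_loci,
    crossmap_correct,
    decoy_filter,
    hits_to_sam,
    loci_to_bed,
    map_reads,
    shuffle_decoys,
)


def brute_force_hits(seq, reference, max_mm):
    """Independent oracle: scan every window on both strands."""
    hits = []
    for rid, ref in reference.items():
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            for p in range(len(ref) - len(query) + 1):
                mm = sum(a != b for a, b in zip(ref[p : p + len(query)], query))
                if mm <= max_mm:
                    hits.append((rid, p, strand, mm))
    return sorted(hits)


class TestMapReads:
    def test_exact_substring_found_at_planting_position(self):
        rng = np.random.default_rng(1)
        ref = random_dna(rng, 2000)
        read = ref[500:525]
        hits = map_reads([read], {"r": ref})
        assert any(h.position == 500 and h.strand == "+" and h.mismatches == 0 for h in hits)

    def test_three_substitutions_not_reported(self):
        rng = np.random.default_rng(2)
        ref = random_dna(rng, 500)
        read = list(ref[100:125])
        for i in (3, 10, 17):
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        hits = map_reads(["".join(read)], {"r": ref}, max_mm=2)
        assert not any(h.position == 100 for h in hits)

    def test_reverse_strand_hit(self):
        rng = np.random.default_rng(3)
        ref = random_dna(rng, 1000)
        read = revcomp(ref[200:222])
        hits = map_reads([read], {"r": ref})
        assert any(h.position == 200 and h.strand == "-" for h in hits)

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_equals_brute_force_scan(self, max_mm):
        rng = np.random.default_rng(4)
        ref = random_dna(rng, 10_000)
        reads = [ref[i : i + 25] for i in (10, 5000)] + [random_dna(rng, 25) for _ in range(3)]
        for read in reads:
            got = sorted(
                (h.reference_id, h.position, h.strand, h.mismatches)
                for h in map_reads([read], {"r": ref}, max_mm)
            )
            assert got == brute_force_hits(read, {"r": ref}, max_mm)

    def test_empty_reference_is_error(self):
        with pytest.raises(ValueError):
            map_reads(["ACGTACGTACGTACGT"], {})


class TestAttributeHost:
    def test_host_wins_over_nonhost(self):
        # the host-first rule ignores any non-host hits
        hits = [MappingHit("AAAC" * 5, "host_chr1", 0, "+", 0)]
        host, nonhost = attribute_host(["AAAC" * 5, "GGGT" * 5], hits)
        assert host == ["AAAC" * 5]
        assert nonhost == ["GGGT" * 5]

    def test_unmapped_sequence_is_nonhost(self):
        host, nonhost = attribute_host(["ACGT" * 5], [])
        assert host == [] and nonhost == ["ACGT" * 5]

    def test_empty_partition(self):
        assert attribute_host([], []) == ([], [])


class TestDecoyFilter:
    def test_long_real_read_retains_genome(self):
        rng = np.random.default_rng(5)
        genome = random_dna(rng, 3000)
        read = genome[100:126]  # 26 nt
        assert decoy_filter([read], {"g": genome}, seed=0) == ["g"]

    def test_short_reads_only_drops_genome(self):
        rng = np.random.default_rng(6)
        genome = random_dna(rng, 3000)
        reads = [genome[i : i + 18] for i in (100, 700, 1500)]
        assert decoy_filter(reads, {"g": genome}, seed=0) == []

    def test_decoy_excess_drops_genome(self):
        # homopolymer genome: a shuffled homopolymer read maps exactly as
        # well as the real one, so there is no recruitment excess
        genome = "A" * 3000
        retained = decoy_filter(["A" * 26], {"g": genome}, seed=0)
        assert retained == []

    def test_shuffle_preserves_composition_and_length(self):
        seqs = ["ACGTACGTACGGTTTACG", "AAACCCGGGTTTAAACCC"]
        decoys = shuffle_decoys(seqs, seed=1)
        for s, d in zip(seqs, decoys):
            assert sorted(s) == sorted(d) and len(s) == len(d)

    def test_decoy_symmetry_few_false_retentions(self):
        # running the filter on decoy reads themselves retains ~no genomes
        rng = np.random.default_rng(7)
        genomes = {f"g{i}": random_dna(rng, 2000) for i in range(5)}
        decoy_input = shuffle_decoys([random_dna(rng, 26) for _ in range(20)], seed=2)
        retained = decoy_filter(decoy_input, genomes, seed=3)
        assert len(retained) <= 1


class TestBuildLoci:
    def test_overlapping_same_strand_hits_merge(self):
        hits = [
            MappingHit("A" * 20, "r", 100, "+", 0),
            MappingHit("C" * 20, "r", 110, "+", 0),
        ]
        (locus,) = build_loci(hits)
        assert (locus.start, locus.end) == (100, 130)

    def test_opposite_strands_stay_separate(self):
        hits = [
            MappingHit("A" * 20, "r", 100, "+", 0),
            MappingHit("C" * 20, "r", 100, "-", 0),
        ]
        loci = build_loci(hits)
        assert len(loci) == 2
        assert {l.strand for l in loci} == {"+", "-"}

    def test_no_hits_no_loci(self):
        assert build_loci([]) == []

    def test_raw_count_weights_by_collapse_count(self):
        hits = [
            MappingHit("A" * 20, "r", 100, "+", 0),
            MappingHit("C" * 20, "r", 105, "+", 0),
        ]
        (locus,) = build_loci(hits, {"A" * 20: 7, "C" * 20: 2})
        assert locus.raw_count == 9


class TestExports:
    def test_sam_rendering_parses_with_pysam(self, tmp_path):
        import pysam

        rng = np.random.default_rng(9)
        ref = random_dna(rng, 500)
        read = ref[50:75]
        hits = map_reads([read, revcomp(read)], {"r": ref})
        path = tmp_path / "hits.sam"
        path.write_text(hits_to_sam(hits, {"r": ref}))
        with pysam.AlignmentFile(str(path), "r") as sam:
            records = list(sam)
        assert len(records) == len(hits)
        assert {r.reference_start for r in records} == {50}
        assert {r.is_reverse for r in records} == {True, False}

    def test_bed_is_zero_based_with_corrected_count_column(self):
        locus = Locus("r", 10, 35, "+", raw_count=4, corrected_count=3.5)
        line = loci_to_bed([locus]).strip().split("\t")
        assert line[:3] == ["r", "10", "35"]
        assert line[5] == "+" and line[6] == "3.5"


def brute_force_em(incidence, counts, n_iter=500):
    """Independent oracle: plain iteration of the proportional allocation."""
    loci = sorted({l for ls in incidence.values() for l in ls})
    unique = {l: 0.0 for l in loci}
    for r, ls in incidence.items():
        if len(ls) == 1:
            unique[ls[0]] += counts[r]
    totals = dict(unique)
    for _ in range(n_iter):
        new = dict(unique)
        for r, ls in incidence.items():
            if len(ls) == 1:
                continue
            w = [totals[l] for l in ls]
            s = sum(w)
            if s <= 0:
                w = [1.0] * len(ls)
                s = float(len(ls))
            for l, wi in zip(ls, w):
                new[l] += counts[r] * wi / s
        totals = new
    return totals


class TestCrossmapCorrect:
    def test_unique_read_keeps_full_count(self):
        res = crossmap_correct({"r1": ["L1"]}, {"r1": 7})
        assert res.corrected["L1"] == pytest.approx(7)

    def test_hand_computed_allocation(self):
        # unique counts 10 and 2; a shared read of count 6 splits 5:1
        incidence = {"u1": ["A"], "u2": ["B"], "s": ["A", "B"]}
        counts = {"u1": 10, "u2": 2, "s": 6}
        res = crossmap_correct(incidence, counts)
        assert res.corrected["A"] == pytest.approx(15, abs=1e-6)
        assert res.corrected["B"] == pytest.approx(3, abs=1e-6)
        assert res.converged

    def test_symmetric_split_without_unique_evidence(self):
        res = crossmap_correct({"s": ["A", "B"]}, {"s": 8})
        assert res.corrected["A"] == pytest.approx(4)
        assert res.corrected["B"] == pytest.approx(4)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n_loci = int(rng.integers(2, 10))
            loci = [f"L{i}" for i in range(n_loci)]
            incidence, counts = {}, {}
            for r in range(int(rng.integers(3, 15))):
                k = int(rng.integers(1, min(4, n_loci) + 1))
                incidence[f"r{r}"] = list(rng.choice(loci, size=k, replace=False))
                counts[f"r{r}"] = int(rng.integers(1, 50))
            res = crossmap_correct(incidence, counts, tol=1e-10, max_iter=2000)
            oracle = brute_force_em(incidence, counts)
            for l in oracle:
                assert res.corrected[l] == pytest.approx(oracle[l], abs=1e-4)

    def test_total_count_conserved(self):
        incidence = {"a": ["L1", "L2"], "b": ["L2", "L3"], "c": ["L3"]}
        counts = {"a": 11, "b": 5, "c": 9}
        res = crossmap_correct(incidence, counts)
        assert sum(res.corrected.values()) == pytest.approx(25, abs=1e-6)
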