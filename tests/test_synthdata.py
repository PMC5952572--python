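"""The synthetic-data generator: determinism, composition model,
inverse-volume behaviour and the titration/control study designs."""

import numpy as np
import pytest

from srnaclean.preprocess import LibraryMeta, TRUSEQ_SMALL_RNA_ADAPTER as ADAPTER
from srnaclean.synthdata import (
    DEFAULT_CONTAMINANT_COPIES,
    LibraryDesign,
    ReferenceConfig,
    SPIKE_IN_SEQUENCE,
    CONFIRMED_CONTAMINANTS,
    fragment_pool,
    make_control_designs,
    make_references,
    metadata_frame,
    simulate_collapsed,
    simulate_counts,
    simulate_library,
    simulate_study,
    simulate_titration,
)

CFG = ReferenceConfig(host_length=20_000, n_host_srnas=20, nonhost_genome_length=4_000)


def plasma_design(volume=100.0, total_reads=5000, seed=3, **kw):
    meta = LibraryMeta("p1", "plasma", volume_uL=volume)
    return LibraryDesign(meta=meta, total_reads=total_reads, seed=seed, **kw)


def mock_design(total_reads=5000, seed=3, spike=0.0, **kw):
    meta = LibraryMeta("m1", "mock", spikein_copies_per_uL=spike)
    return LibraryDesign(meta=meta, total_reads=total_reads, seed=seed, **kw)


class TestMakeReferences:
    def test_confirmed_panel_included_verbatim(self, refs):
        assert refs.contaminant_panel["sRNA 2"] == "ACGGACAAGAATAGGCTTCGGCT"
        assert set(CONFIRMED_CONTAMINANTS) <= set(refs.contaminant_panel)

    def test_deterministic_for_fixed_config_and_seed(self):
        a = make_references(CFG, seed=5)
        b = make_references(CFG, seed=5)
        assert a.host_genome == b.host_genome
        assert a.exogenous_panel == b.exogenous_panel
        assert a.host_srna_weights == b.host_srna_weights

    def test_seed_changes_host_genome(self):
        a = make_references(CFG, seed=5)
        b = make_references(CFG, seed=6)
        assert a.host_genome["host_chr1"] != b.host_genome["host_chr1"]

    def test_panels_absent_from_host_genome(self, refs):
        host = refs.host_genome["host_chr1"]
        for seq in list(refs.contaminant_panel.values()) + list(refs.exogenous_panel.values()):
            assert seq not in host
        assert SPIKE_IN_SEQUENCE not in host

    def test_planted_sequences_within_srna_length_range(self, refs):
        for seq in refs.all_planted().values():
            assert 15 <= len(seq) <= 45

    def test_host_srnas_are_genome_substrings(self, refs):
        host = refs.host_genome["host_chr1"]
        assert all(s in host for s in refs.host_srnas.values())


class TestSimulateLibrary:
    def test_mock_contains_only_contaminants_and_spike(self, refs):
        d = mock_design(spike=40_000.0, error_rate=0.0)
        counts = simulate_counts(d, refs)
        assert set(counts["category"]) <= {"contaminant", "spike_in"}

    def test_error_free_reads_end_with_adapter(self, refs):
        d = plasma_design(error_rate=0.0)
        for _, seq, _ in simulate_library(d, refs)[:200]:
            insert_candidates = [
                s for s in refs.all_planted().values() if seq.startswith(s)
            ]
            assert insert_candidates
            insert = max(insert_candidates, key=len)
            tail = seq[len(insert):]
            assert tail == (ADAPTER * 5)[: len(tail)]

    def test_volume_ratio_reflected_in_contaminant_fraction(self, refs):
        # doubling cpm check: same contaminant copies, 100 vs 1000 uL input;
        # binomial proportion oracle gives the sampling tolerance
        n = 40_000
        frac = {}
        for v in (100.0, 1000.0):
            d = plasma_design(volume=v, total_reads=n, seed=11, error_rate=0.0)
            counts = simulate_counts(d, refs)
            frac[v] = counts.loc[counts["category"] == "contaminant", "count"].sum() / n
        pool = fragment_pool(plasma_design(volume=100.0), refs)
        c = pool.loc[pool["category"] == "contaminant", "copies"].sum()
        e = pool.loc[pool["category"] != "contaminant", "copies"].sum()
        for v in (100.0, 1000.0):
            p = c / (c + e * v / 100.0)
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(frac[v] - p) < 4 * sd
        assert frac[100.0] / frac[1000.0] == pytest.approx(10.0, rel=0.15)

    def test_byte_identical_for_same_seed(self, refs):
        a = simulate_library(plasma_design(seed=21), refs)
        b = simulate_library(plasma_design(seed=21), refs)
        assert a == b

    def test_empty_pool_with_reads_is_error(self, refs):
        meta = LibraryMeta("w1", "water")
        d = LibraryDesign(meta=meta, total_reads=100, seed=1)
        with pytest.raises(ValueError, match="empty fragment pool"):
            simulate_counts(d, refs)

    def test_zero_read_library_is_empty(self, refs):
        meta = LibraryMeta("w1", "water")
        d = LibraryDesign(meta=meta, total_reads=0, seed=1)
        assert simulate_library(d, refs) == []

    def test_missing_adapter_rejected(self):
        with pytest.raises(ValueError, match="adapter"):
            plasma_design(adapter="")

    def test_read_length_constant(self, refs):
        for _, seq, qual in simulate_library(plasma_design(), refs)[:50]:
            assert len(seq) == 75 and len(qual) == 75

    def test_low_quality_injection_fails_quality_filter(self, refs):
        from srnaclean.preprocess import quality_filter

        d = plasma_design(low_quality_frac=1.0, total_reads=500)
        reads = [(s, q) for _, s, q in simulate_library(d, refs)]
        assert len(quality_filter(reads)) < len(reads)

    def test_collapsed_view_matches_multinomial_counts(self, refs):
        d = plasma_design(error_rate=0.0, total_reads=2000)
        collapsed = simulate_collapsed(d, refs)
        assert sum(c.count for c in collapsed) == 2000
        counts = simulate_counts(d, refs)
        assert {c.sequence: c.count for c in collapsed} == dict(
            zip(counts["sequence"], counts["count"])
        )


class TestComposition:
    def test_category_fractions_within_four_sds(self, refs):
        n = 1000
        d = plasma_design(total_reads=n, seed=17)
        counts = simulate_counts(d, refs)
        pool = fragment_pool(d, refs)
        expected = pool.groupby("category")["copies"].sum() / pool["copies"].sum()
        observed = counts.groupby("category")["count"].sum().reindex(expected.index).fillna(0) / n
        for cat in expected.index:
            p = expected[cat]
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(observed[cat] - p) <= 4 * sd + 1e-12


class TestTitrationDesigns:
    def test_5x2x2_gives_20_distinct_libraries(self, refs):
        base = plasma_design()
        designs = simulate_titration(
            (45.0, 100.0, 225.0, 500.0, 1115.0), ("regular", "ultraclean"),
            refs, base, seed=1, replicates=2,
        )
        ids = [d.meta.library_id for d in designs]
        assert len(designs) == 20 and len(set(ids)) == 20

    def test_single_volume_propagates_to_metadata(self, refs):
        designs = simulate_titration([100.0], ["regular"], refs, plasma_design(), seed=1)
        assert all(d.meta.volume_uL == 100.0 for d in designs)

    def test_ultraclean_scales_contaminant_copies(self, refs):
        designs = simulate_titration(
            [100.0], ["regular", "ultraclean"], refs, plasma_design(), seed=1,
            replicates=1, ultraclean_factor=60.0,
        )
        reg = next(d for d in designs if d.meta.column == "regular")
        uc = next(d for d in designs if d.meta.column == "ultraclean")
        for name in DEFAULT_CONTAMINANT_COPIES:
            ratio = reg.contaminant_copies_per_column[name] / uc.contaminant_copies_per_column[name]
            assert ratio == pytest.approx(60.0)

    def test_ultraclean_cpm_reduction_close_to_factor(self, refs):
        # simulation oracle: observed mean contaminant cpm ratio tracks the
        # clean-up factor within sampling error
        designs = simulate_titration(
            [100.0], ["regular", "ultraclean"], refs,
            plasma_design(total_reads=150_000, error_rate=0.0), seed=2,
            replicates=2, ultraclean_factor=60.0,
        )
        cpm = {}
        for d in designs:
            counts = simulate_counts(d, refs)
            total = counts["count"].sum()
            cont = counts.loc[counts["category"] == "contaminant", "count"].sum()
            cpm.setdefault(d.meta.column, []).append(cont / total * 1e6)
        ratio = np.mean(cpm["regular"]) / np.mean(cpm["ultraclean"])
        assert ratio == pytest.approx(60.0, rel=0.25)

    def test_empty_volumes_rejected(self, refs):
        with pytest.raises(ValueError):
            simulate_titration([], ["regular"], refs, plasma_design(), seed=1)

    def test_study_design_has_28_plasma_and_controls(self, refs):
        designs = simulate_study(refs, seed=3, total_reads=1000)
        plasma = [d for d in designs if d.meta.type == "plasma"]
        controls = [d for d in designs if d.meta.is_control]
        assert len(plasma) == 28
        assert len(controls) >= 10
        meta = metadata_frame(designs)
        assert len(meta) == len(designs)
        assert meta["library_id"].is_unique

    def test_controls_include_spiked_mocks(self, refs):
        designs = make_control_designs(refs, plasma_design(), seed=4)
        mocks = [d for d in designs if d.meta.type == "mock"]
        assert all(d.meta.spikein_copies_per_uL == 40_000.0 for d in mocks)
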