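"""Trimming/filtering, hybrid-reference indexing, split-read calling and
breakpoint resolution on constructed fixtures and simulator output."""

import numpy as np
import pytest

from piggytools.junctions import (
    HybridReferenceError,
    MalformedReadError,
    _split_one,
    build_hybrid_reference,
    find_split_reads,
    resolve_breakpoint,
    trim_and_filter,
)
from piggytools.reference import ReferenceSet, revcomp
from piggytools.simulate import (
    ADAPTER_P5,
    ADAPTER_P7,
    ReadPair,
    SimulationConfig,
    generate_reads,
    make_genome,
    simulate_integrations,
)
from conftest import random_reporter


def _pair(rid, s1, s2, q=35, source="junction"):
    return ReadPair(
        rid, s1, s2,
        np.full(len(s1), q, dtype=np.int64),
        np.full(len(s2), q, dtype=np.int64),
        source,
    )


class TestTrimAndFilter:
    def test_high_quality_pair_unchanged(self):
        p = _pair("r", "ACGT" * 20, "TGCA" * 20)
        kept, rep = trim_and_filter([p])
        assert kept[0].seq1 == p.seq1 and kept[0].seq2 == p.seq2
        assert rep.quality_trimmed_bases == 0
        assert rep.surviving_pairs == rep.deduplicated_pairs == 1

    def test_low_quality_tail_trimmed(self):
        seq = "ACGT" * 30
        qual = np.full(120, 35, dtype=np.int64)
        qual[-30:] = 5  # well below the Q20 cutoff
        p = ReadPair("r", seq, seq, qual, qual.copy(), "junction")
        kept, rep = trim_and_filter([p])
        assert len(kept[0].seq1) == 90
        assert rep.quality_trimmed_bases == 60
        # trimming never lengthens a read
        assert len(kept[0].seq1) <= len(seq)

    def test_adapter_dimer_excluded(self):
        dimer = (ADAPTER_P7 + ADAPTER_P5)[:100]
        good = "ACGT" * 25
        pairs = [_pair("d", dimer, dimer, source="adapter_dimer"), _pair("g", good, good)]
        kept, rep = trim_and_filter(pairs)
        assert rep.dimer_excluded == 1
        assert [p.read_id for p in kept] == ["g"]

    def test_simulated_dimers_all_excluded(self, reporter):
        cfg = SimulationConfig(genome_length=100_000, contig_count=1, n_events=10,
                               seed=4, duplicate_fraction=0.0, adapter_dimer_fraction=0.2)
        g = make_genome(cfg)
        mod, ev = simulate_integrations(g, reporter, cfg)
        pairs = generate_reads(mod, ev, reporter, cfg)
        n_dimer = sum(p.source == "adapter_dimer" for p in pairs)
        _, rep = trim_and_filter(pairs)
        assert rep.dimer_excluded == n_dimer > 0

    def test_dedup_fraction_matches_simulator(self, reporter):
        cfg = SimulationConfig(genome_length=200_000, contig_count=1, n_events=25,
                               depth=20, seed=6, duplicate_fraction=0.6,
                               adapter_dimer_fraction=0.0)
        g = make_genome(cfg)
        mod, ev = simulate_integrations(g, reporter, cfg)
        pairs = generate_reads(mod, ev, reporter, cfg)
        assert len(pairs) >= 500
        kept, rep = trim_and_filter(pairs, dedup=True)
        ratio = rep.deduplicated_pairs / rep.surviving_pairs
        p0 = 0.4
        se = np.sqrt(p0 * (1 - p0) / rep.surviving_pairs)
        assert abs(ratio - p0) < 4 * se

    def test_dedup_idempotent(self):
        pairs = [_pair("a", "ACGT" * 20, "ACGT" * 20), _pair("b", "ACGT" * 20, "ACGT" * 20)]
        once, _ = trim_and_filter(pairs, dedup=True)
        twice, _ = trim_and_filter(once, dedup=True)
        assert [(p.seq1, p.seq2) for p in once] == [(p.seq1, p.seq2) for p in twice]

    def test_length_mismatch_raises_with_read_id(self):
        p = _pair("ok", "ACGT" * 20, "ACGT" * 20)
        p.qual1 = p.qual1[:-1]
        with pytest.raises(MalformedReadError, match="ok"):
            trim_and_filter([p])


class TestHybridReference:
    def test_contig_count_and_name_clash(self, small_genome):
        hyb = build_hybrid_reference(small_genome, "ACGT" * 50, "plasmid")
        assert len(hyb.refset) == len(small_genome) + 1
        with pytest.raises(HybridReferenceError):
            build_hybrid_reference(small_genome, "ACGT" * 50, "chr1")

    def test_empty_plasmid_rejected(self, small_genome):
        with pytest.raises(HybridReferenceError):
            build_hybrid_reference(small_genome, "")

    def test_kmer_locate_exhaustive(self):
        rng = np.random.default_rng(3)
        from piggytools.simulate import _sample_sequence

        g = ReferenceSet({"c1": _sample_sequence(rng, 1500, 0.5),
                          "c2": _sample_sequence(rng, 800, 0.5)})
        plasmid = _sample_sequence(rng, 400, 0.5)
        hyb = build_hybrid_reference(g, plasmid, "p")
        # every 31-mer from every source maps back to its true position(s)
        for name, seq in list(g.items()) + [("p", plasmid)]:
            for i in range(0, len(seq) - 31, 7):
                q = seq[i : i + 31]
                hits = hyb.locate(q)
                assert (name, i) in hits
                for cname, pos in hits:
                    assert hyb.refset[cname][pos : pos + 31] == q


@pytest.fixture(scope="module")
def fixture_world():
    rng = np.random.default_rng(7)
    from piggytools.simulate import _sample_sequence

    reporter = random_reporter(7)
    cfg = SimulationConfig(genome_length=100_000, contig_count=1, n_events=0,
                           seed=2, duplicate_fraction=0.0)
    g = make_genome(cfg)
    hyb = build_hybrid_reference(g, reporter.element, "plasmid")
    return g, reporter, hyb


class TestFindSplitReads:
    def test_constructed_sixty_bp_read(self, fixture_world):
        g, rep, hyb = fixture_world
        seq = g["chr1"]
        read = seq[1000:1030] + rep.element[:30]
        call = _split_one(hyb, "r", read, 20, 0.04, 7)
        assert call is not None
        assert call.contig == "chr1" and call.genome_pos == 1030
        assert call.transposon_end == "5prime" and call.transposon_offset == 0

    def test_fully_genomic_read_no_call(self, fixture_world):
        g, rep, hyb = fixture_world
        assert _split_one(hyb, "r", g["chr1"][2000:2300], 20, 0.04, 7) is None

    def test_fully_plasmid_read_no_call(self, fixture_world):
        g, rep, hyb = fixture_world
        assert _split_one(hyb, "r", rep.element[10:290], 20, 0.04, 7) is None

    def test_short_genome_anchor_no_call(self, fixture_world):
        g, rep, hyb = fixture_world
        read = g["chr1"][1000:1010] + rep.element[:50]
        assert _split_one(hyb, "r", read, 20, 0.04, 7) is None

    def test_orientation_invariance(self, fixture_world):
        g, rep, hyb = fixture_world
        seq = g["chr1"]
        read = rep.element[-60:] + seq[5000:5160]
        fields = []
        for r in (read, revcomp(read)):
            c = _split_one(hyb, "r", r, 20, 0.04, 7)
            fields.append((c.contig, c.genome_pos, c.transposon_end,
                           c.transposon_offset, c.orientation, c.target_tetra, c.tsd_start))
        assert fields[0] == fields[1]

    def test_pairs_api_counts_both_mates(self, fixture_world):
        g, rep, hyb = fixture_world
        seq = g["chr1"]
        junction_read = rep.element[-100:] + seq[3000:3200]
        pair = _pair("p1", junction_read, revcomp(junction_read))
        calls = find_split_reads([pair], hyb)
        assert len(calls) == 2
        assert {c.read_id for c in calls} == {"p1/1", "p1/2"}
        assert len({(c.contig, c.genome_pos) for c in calls}) == 1


class TestResolveBreakpoint:
    def test_idempotent_without_ambiguity(self, fixture_world):
        g, rep, hyb = fixture_world
        seq = g["chr1"]
        # pick a junction where the base 5' of the genomic anchor cannot
        # extend the plasmid (no chance microhomology)
        j = next(i for i in range(4000, 5000) if seq[i - 1] != rep.element[-1])
        read = rep.element[-60:] + seq[j : j + 160]
        call = _split_one(hyb, "r", read, 20, 0.04, 7)
        resolved = resolve_breakpoint(call, hyb)
        assert resolved.microhomology == 0
        assert resolved.genome_pos == call.genome_pos
        again = resolve_breakpoint(resolved, hyb)
        assert again == resolved

    def test_two_bp_microhomology_resolved_to_terminus(self):
        rng = np.random.default_rng(9)
        from piggytools.simulate import _sample_sequence

        rep = random_reporter(9)
        # genome locus whose two bases before the junction repeat the ITR
        # terminal GG: the breakpoint is ambiguous within 2 bp
        left = _sample_sequence(rng, 600, 0.5)
        right = _sample_sequence(rng, 600, 0.5)
        assert rep.element.endswith("GGG")
        contig = left + "C" + "GG" + right
        g = ReferenceSet({"chr1": contig})
        hyb = build_hybrid_reference(g, rep.element, "plasmid")
        j = len(left) + 3  # junction right after the genomic ...CGG
        read = rep.element[-80:] + contig[j : j + 160]
        call = _split_one(hyb, "r", read, 20, 0.04, 7)
        resolved = resolve_breakpoint(call, hyb)
        assert resolved.microhomology == 2
        assert resolved.transposon_offset == 0
        assert resolved.genome_pos == j

    def test_unknown_contig_rejected(self, fixture_world):
        g, rep, hyb = fixture_world
        read = rep.element[-60:] + g["chr1"][5000:5160]
        call = _split_one(hyb, "r", read, 20, 0.04, 7)
        call.contig = "chrX"
        with pytest.raises(HybridReferenceError):
            resolve_breakpoint(call, hyb)


class TestSimulatedRecovery:
    def test_noise_free_exact_recovery_and_no_false_positives(self, reporter):
        from piggytools.sites import aggregate_sites, classify_sites

        cfg = SimulationConfig(genome_length=200_000, contig_count=2, n_events=20,
                               seed=5, substitution_rate=0.0, duplicate_fraction=0.0,
                               adapter_dimer_fraction=0.0)
        g = make_genome(cfg)
        mod, ev = simulate_integrations(g, reporter, cfg)
        pairs = generate_reads(mod, ev, reporter, cfg)
        kept, _ = trim_and_filter(pairs)
        hyb = build_hybrid_reference(g, reporter.element, "plasmid")
        calls = [resolve_breakpoint(c, hyb) for c in find_split_reads(kept, hyb)]
        sites = classify_sites(aggregate_sites(calls))
        truth = {(e.contig, e.tsd_start) for e in ev}
        found = {(s.contig, s.tsd_start) for s in sites}
        assert found == truth
        assert all(s.target_tetra == "TTAA" for s in sites)
        assert all(s.max_offset == 0 for s in sites)

    def test_no_events_no_calls(self, reporter):
        cfg = SimulationConfig(genome_length=100_000, contig_count=1, n_events=0,
                               seed=2, duplicate_fraction=0.0,
                               adapter_dimer_fraction=0.3, background_fraction=0.5)
        g = make_genome(cfg)
        mod, ev = simulate_integrations(g, reporter, cfg)
        pairs = generate_reads(mod, ev, reporter, cfg)
        kept, _ = trim_and_filter(pairs)
        hyb = build_hybrid_reference(g, reporter.element, "plasmid")
        assert find_split_reads(kept, hyb) == []
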