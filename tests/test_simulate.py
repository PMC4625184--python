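"""Simulator unit and property tests: genome composition, the TSD rule,
precise excision, read generation and artifact fractions."""

import numpy as np
import pytest

from piggytools.io import write_fasta
from piggytools.reference import ReferenceSet, revcomp
from piggytools.reporter import ReporterError, TransposonReporter, build_reporter
from piggytools.simulate import (
    ExcisionError,
    SimulationConfig,
    SimulationParameterError,
    excise_all,
    generate_reads,
    make_genome,
    simulate_excision,
    simulate_integrations,
)
from conftest import random_reporter


def _fasta_bytes(refset) -> bytes:
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as d:
        p = pathlib.Path(d) / "g.fa"
        write_fasta(refset, p)
        return p.read_bytes()


class TestMakeGenome:
    def test_deterministic_fasta(self):
        cfg = SimulationConfig(genome_length=10_000, contig_count=1, n_events=5, seed=1)
        assert _fasta_bytes(make_genome(cfg)) == _fasta_bytes(make_genome(cfg))

    def test_gc_zero_gives_at_only(self):
        cfg = SimulationConfig(genome_length=10_000, contig_count=1, gc_fraction=0.0,
                               n_events=5, seed=2)
        g = make_genome(cfg)
        assert set(g["chr1"]) <= {"A", "T"}

    def test_ttaa_count_matches_iid_expectation(self):
        # closed form under the i.i.d. model: each of the L-3 windows is
        # TTAA with probability pT^2 * pA^2, pT = pA = (1-gc)/2
        L, gc = 10_000, 0.4
        p = ((1 - gc) / 2) ** 4
        expected = (L - 3) * p
        counts = []
        for seed in range(100):
            cfg = SimulationConfig(genome_length=L, contig_count=1, gc_fraction=gc,
                                   n_events=1, seed=seed)
            seq = make_genome(cfg)["chr1"]
            n = sum(1 for i in range(L - 3) if seq[i : i + 4] == "TTAA")
            counts.append(n)
            assert 0.5 * expected <= n <= 1.5 * expected
        # Monte-Carlo mean tight around the closed form
        se = np.sqrt(expected) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(SimulationParameterError, match="n_events"):
            SimulationConfig(genome_length=100, contig_count=1, n_events=50)
        with pytest.raises(SimulationParameterError, match="gc_fraction"):
            SimulationConfig(gc_fraction=1.5)


class TestBuildReporter:
    ITR5 = "CCCTAGAAAGATA"
    ITR3 = revcomp("CCCTAGAAAGATA")

    def test_intact_concatenation(self):
        r = build_reporter(self.ITR5, "ACGTT", self.ITR3, "intact")
        assert self.ITR3 == "TATCTTTCTAGGG"
        assert r.element == self.ITR5 + "ACGTT" + self.ITR3

    def test_deleted_is_bare_cargo(self):
        r = build_reporter(self.ITR5, "ACGTT", self.ITR3, "deleted")
        assert r.element == "ACGTT"

    def test_mutant_termini(self):
        r = build_reporter(self.ITR5, "ACGTT", self.ITR3, "mutant")
        assert r.itr5.startswith("TAT")
        assert r.itr3.endswith("ATA")
        assert r.itr5[3:] == self.ITR5[3:]
        assert r.itr3[:-3] == self.ITR3[:-3]

    def test_noncanonical_termini_rejected(self):
        with pytest.raises(ReporterError):
            build_reporter("AAATAGAAAGATA", "ACGTT", self.ITR3, "intact")
        with pytest.raises(ReporterError):
            build_reporter(self.ITR5, "ACGTT", "TATCTTTCTAAAA", "intact")


class TestIntegrations:
    def test_tsd_duplication_rule(self):
        # TTAA at p=4 duplicated around the inserted element
        g = ReferenceSet({"c": "GGGGTTAACCCC"})
        rep = build_reporter("CCC", "T", "GGG", "intact", name="mini")
        cfg = SimulationConfig(genome_length=12, contig_count=1, n_events=1,
                               min_event_spacing=1, seed=0)
        mod, events = simulate_integrations(g, rep, cfg)
        (ev,) = events
        assert ev.tsd_start == 4 and ev.on_ttaa
        elem = rep.element if ev.orientation == "+" else revcomp(rep.element)
        assert mod["c"] == "GGGGTTAA" + elem + "TTAACCCC"

    def test_zero_events_is_identity(self, small_genome, small_config, reporter):
        from dataclasses import replace

        cfg = replace(small_config, n_events=0)
        mod, events = simulate_integrations(small_genome, reporter, cfg)
        assert events == []
        assert mod == small_genome

    def test_full_fidelity_targets_ttaa(self, reporter):
        cfg = SimulationConfig(genome_length=500_000, contig_count=1, n_events=50,
                               ttaa_fidelity=1.0, seed=7)
        g = make_genome(cfg)
        _, events = simulate_integrations(g, reporter, cfg)
        assert len(events) == 50
        for ev in events:
            assert g[ev.contig][ev.tsd_start : ev.tsd_start + 4] == "TTAA"
        # non-overlapping and sorted
        keys = [(e.contig, e.tsd_start) for e in events]
        assert keys == sorted(keys) and len(set(keys)) == 50

    def test_tsd_conservation_count(self, small_genome, small_config, reporter):
        # each on-TTAA event contributes one extra genomic TTAA (the TSD
        # copy) plus whatever TTAAs the element body itself carries
        mod, events = simulate_integrations(small_genome, reporter, small_config)
        contig = events[0].contig
        before = small_genome[contig].count("TTAA")
        after = mod[contig].count("TTAA")
        extra = 0
        for e in events:
            if e.contig != contig:
                continue
            elem = reporter.element if e.orientation == "+" else revcomp(reporter.element)
            extra += (1 if e.on_ttaa else 0) + elem.count("TTAA")
        assert after == before + extra


class TestExcision:
    def test_single_cassette_excised(self):
        rep = build_reporter("CCC", "T", "GGG", "intact")
        donor = "GGATCCTTAA" + rep.element + "TTAAGAATTC"
        assert simulate_excision(donor, rep) == "GGATCCTTAAGAATTC"

    def test_missing_element_errors(self):
        rep = build_reporter("CCC", "T", "GGG", "intact")
        with pytest.raises(ExcisionError, match="0"):
            simulate_excision("GGATCCTTAAGAATTC", rep)

    def test_multiple_cassettes_error(self):
        rep = build_reporter("CCC", "T", "GGG", "intact")
        unit = "TTAA" + rep.element + "TTAA"
        with pytest.raises(ExcisionError):
            simulate_excision(unit + "ACGT" + unit, rep)

    def test_roundtrip_restores_genome(self, reporter):
        cfg = SimulationConfig(genome_length=150_000, contig_count=1, n_events=10, seed=3)
        g = make_genome(cfg)
        mod, _ = simulate_integrations(g, reporter, cfg)
        assert excise_all(mod, reporter) == g


class TestGenerateReads:
    def test_pair_count_poisson(self, reporter):
        # sum of 10 independent Poisson(20) junctions ~ Poisson(200)
        counts = []
        for seed in range(50):
            cfg = SimulationConfig(genome_length=100_000, contig_count=1, n_events=10,
                                   depth=20, duplicate_fraction=0.0,
                                   adapter_dimer_fraction=0.0, seed=seed)
            g = make_genome(cfg)
            mod, ev = simulate_integrations(g, reporter, cfg)
            counts.append(len(generate_reads(mod, ev, reporter, cfg)))
        sigma = np.sqrt(200)
        assert all(abs(c - 200) < 5 * sigma for c in counts)
        assert abs(np.mean(counts) - 200) < 3 * sigma / np.sqrt(50)

    def test_error_free_reads_match_genome(self, small_genome, small_config, reporter):
        mod, ev = simulate_integrations(small_genome, reporter, small_config)
        pairs = generate_reads(mod, ev, reporter, small_config)
        joined = {name: seq for name, seq in mod.items()}
        for p in pairs[:50]:
            found = any(
                p.seq1 in s or revcomp(p.seq1) in s for s in joined.values()
            )
            assert found, f"{p.read_id}: mate 1 not a substring of the modified genome"

    def test_all_adapter_dimers(self, small_genome, small_config, reporter):
        from dataclasses import replace

        cfg = replace(small_config, adapter_dimer_fraction=1.0, duplicate_fraction=0.0)
        mod, ev = simulate_integrations(small_genome, reporter, cfg)
        pairs = generate_reads(mod, ev, reporter, cfg)
        assert pairs and all(p.source == "adapter_dimer" for p in pairs)

    def test_duplicates_marked_and_fraction(self, small_genome, small_config, reporter):
        from dataclasses import replace

        cfg = replace(small_config, duplicate_fraction=0.6)
        mod, ev = simulate_integrations(small_genome, reporter, cfg)
        pairs = generate_reads(mod, ev, reporter, cfg)
        dup = [p for p in pairs if p.duplicate_of is not None]
        frac = len(dup) / len(pairs)
        assert abs(frac - 0.6) < 0.05
        ids = {p.read_id for p in pairs}
        assert all(p.duplicate_of in ids for p in dup)
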