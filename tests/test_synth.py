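"""Synthetic community generator: genomes, series, reads, alignment tables."""

import numpy as np
import pytest

from lignopipe.assign import parse_tabular_hits
from lignopipe.synth import (
    CommunityProfile,
    GeneCassette,
    build_series,
    emit_alignment_tables,
    expected_family_ra,
    family_template,
    generate_genome,
    simulate_reads,
)


class TestGenerateGenome:
    def test_balanced_gc_no_cassettes(self):
        g = generate_genome("g", 10_000, 0.5, [], seed=1)
        assert len(g.sequence) == 10_000
        assert 0.46 <= g.realized_gc <= 0.54

    def test_same_seed_identical(self):
        a = generate_genome("g", 5_000, 0.4, [(100, 700, "+", "GH43")], seed=3)
        b = generate_genome("g", 5_000, 0.4, [(100, 700, "+", "GH43")], seed=3)
        assert a.sequence == b.sequence

    def test_low_gc_target_100kb(self):
        g = generate_genome("g", 100_000, 0.41, [], seed=2)
        assert abs(g.realized_gc - 0.41) <= 0.02

    def test_cassette_carries_template(self):
        g = generate_genome("g", 5_000, 0.5, [(1000, 1600, "+", "GH43")], seed=4)
        assert g.sequence[1000:1600] == family_template("GH43")

    def test_minus_strand_cassette(self):
        g = generate_genome("g", 5_000, 0.5, [(1000, 1600, "-", "GH43")], seed=4)
        rc = g.sequence[1000:1600].translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert rc == family_template("GH43")

    def test_overlap_rejected_with_pair_named(self):
        with pytest.raises(ValueError, match="GH43.*GH2|GH2.*GH43"):
            generate_genome(
                "g", 5_000, 0.5,
                [(100, 700, "+", "GH43"), (600, 1200, "+", "GH2")], seed=5,
            )

    def test_bad_gc_rejected(self):
        with pytest.raises(ValueError):
            generate_genome("g", 5_000, 0.0, [], seed=1)

    def test_cassette_beyond_genome_rejected(self):
        with pytest.raises(ValueError):
            generate_genome("g", 1_000, 0.5, [(600, 1300, "+", "GH2")], seed=1)


class TestBuildSeries:
    def test_neutral_factors_preserve_inoculum(self):
        inoc = CommunityProfile("FS1", {"a": 0.5, "b": 0.5})
        for prof in build_series(inoc, {"a": 1.0, "b": 1.0}, 3):
            assert prof.abundances == pytest.approx(inoc.abundances)

    def test_hand_renormalization(self):
        inoc = CommunityProfile("FS1", {"a": 0.5, "b": 0.5})
        (t1,) = build_series(inoc, {"a": 10.0, "b": 1.0}, 1)
        assert t1.abundances["a"] == pytest.approx(10 / 11)
        assert t1.abundances["b"] == pytest.approx(1 / 11)

    def test_zero_factor_eliminates(self):
        inoc = CommunityProfile("FS1", {"a": 0.5, "b": 0.5})
        series = build_series(inoc, {"a": 0.0, "b": 1.0}, 3)
        assert all(p.abundances["a"] == 0.0 for p in series)

    def test_all_zero_factors_error(self):
        inoc = CommunityProfile("FS1", {"a": 1.0})
        with pytest.raises(ValueError):
            build_series(inoc, {"a": 0.0}, 1)

    def test_geometric_composition(self):
        inoc = CommunityProfile("FS1", {"a": 0.5, "b": 0.5})
        t = build_series(inoc, {"a": 2.0, "b": 1.0}, 3)
        assert t[2].abundances["a"] / t[2].abundances["b"] == pytest.approx(8.0)


@pytest.fixture(scope="module")
def genome_pair():
    g1 = generate_genome("g1", 20_000, 0.4, [(5_000, 5_600, "+", "GH43")], seed=6)
    g2 = generate_genome("g2", 20_000, 0.6, [], seed=6)
    return [g1, g2]


class TestSimulateReads:

    def test_error_free_reads_are_substrings(self, genome_pair):
        prof = CommunityProfile("s", {"g1": 1.0, "g2": 0.0})
        reads, origins = simulate_reads(genome_pair, prof, 200, error_rate=0.0, seed=1)
        g = genome_pair[0].sequence
        comp = str.maketrans("ACGT", "TGCA")
        for rid, seq in reads.items():
            assert seq in g or seq.translate(comp)[::-1] in g

    def test_single_genome_truth(self, genome_pair):
        prof = CommunityProfile("s", {"g1": 1.0, "g2": 0.0})
        _, origins = simulate_reads(genome_pair, prof, 1000, seed=2)
        assert all(o.genome_id == "g1" for o in origins.values())

    def test_weight_recovery_binomial_bound(self, genome_pair):
        prof = CommunityProfile("s", {"g1": 0.8, "g2": 0.2})
        _, origins = simulate_reads(genome_pair, prof, 10_000, seed=3)
        frac = sum(o.genome_id == "g1" for o in origins.values()) / 10_000
        sd = (0.8 * 0.2 / 10_000) ** 0.5
        assert abs(frac - 0.8) <= 3 * sd

    def test_truth_conservation(self, genome_pair):
        prof = CommunityProfile("s", {"g1": 0.5, "g2": 0.5})
        reads, origins = simulate_reads(genome_pair, prof, 500, seed=4)
        assert set(reads) == set(origins)
        assert len(reads) == 500

    def test_cassette_labelling_half_overlap(self, genome_pair):
        prof = CommunityProfile("s", {"g1": 1.0, "g2": 0.0})
        _, origins = simulate_reads(genome_pair, prof, 5000, error_rate=0.0, seed=5)
        for o in origins.values():
            ov = min(o.start + 272, 5_600) - max(o.start, 5_000)
            if o.label == "GH43":
                assert ov >= 136
            else:
                assert ov < 136

    def test_reproducible(self, genome_pair):
        prof = CommunityProfile("s", {"g1": 0.5, "g2": 0.5})
        r1, o1 = simulate_reads(genome_pair, prof, 300, error_rate=0.02, seed=9)
        r2, o2 = simulate_reads(genome_pair, prof, 300, error_rate=0.02, seed=9)
        assert r1 == r2 and o1 == o2

    def test_gc_recovery(self, genome_pair):
        prof = CommunityProfile("s", {"g1": 0.7, "g2": 0.3})
        reads, _ = simulate_reads(genome_pair, prof, 20_000, seed=10)
        got = sum(s.count("G") + s.count("C") for s in reads.values()) / (20_000 * 272)
        want = 0.7 * genome_pair[0].realized_gc + 0.3 * genome_pair[1].realized_gc
        assert abs(got - want) <= 0.01

    def test_empty_profile_rejected(self, genome_pair):
        with pytest.raises(ValueError):
            CommunityProfile("s", {})  # weights cannot sum to 1
        with pytest.raises(ValueError):
            simulate_reads(genome_pair, CommunityProfile("s", {"ghost": 1.0}), 10, seed=1)


@pytest.fixture(scope="module")
def emitted(tmp_path_factory):
    d = tmp_path_factory.mktemp("emit")
    g = generate_genome(
        "g1", 20_000, 0.45,
        [(5_000, 5_600, "+", "GH43"), (10_000, 11_500, "-", "rRNA16S")],
        seed=20,
    )
    prof = CommunityProfile("s", {"g1": 1.0})
    reads, origins = simulate_reads([g], prof, 3_000, error_rate=0.0, seed=21)
    fam, rrna = d / "fam.tsv", d / "rrna.tsv"
    emit_alignment_tables(reads, [g], origins, fam, rrna)
    return g, reads, origins, fam, rrna


class TestEmitAlignmentTables:

    def test_gh_read_best_hit_family(self, emitted):
        g, reads, origins, fam, _ = emitted
        hits = parse_tabular_hits(fam)
        by_read = {}
        for h in hits:
            by_read.setdefault(h.query_id, []).append(h)
        labelled = [rid for rid, o in origins.items() if o.label == "GH43"]
        assert labelled
        for rid in labelled:
            assert rid in by_read
            best = max(by_read[rid], key=lambda h: h.bitscore)
            assert best.subject_id == "GH43|g1"

    def test_intergenic_reads_emit_nothing(self, emitted):
        g, reads, origins, fam, rrna = emitted
        hit_reads = {h.query_id for h in parse_tabular_hits(fam)}
        hit_reads |= {h.query_id for h in parse_tabular_hits(rrna)}
        for rid, o in origins.items():
            s, e = o.start, o.start + 272
            touches = any(
                min(e, c.end) - max(s, c.start) >= 30 for c in g.cassettes
            )
            if not touches:
                assert rid not in hit_reads

    def test_full_16s_read_identity_100(self, emitted):
        g, reads, origins, _, rrna = emitted
        hits = parse_tabular_hits(rrna)
        inside = [
            h for h in hits
            if origins[h.query_id].start >= 10_000
            and origins[h.query_id].start + 272 <= 11_500
        ]
        assert inside
        for h in inside:
            assert h.pct_identity == pytest.approx(100.0)
            assert h.aln_length == 272

    def test_deterministic_output(self, emitted, tmp_path):
        g, reads, origins, fam, rrna = emitted
        f2, r2 = tmp_path / "f2.tsv", tmp_path / "r2.tsv"
        emit_alignment_tables(reads, [g], origins, f2, r2)
        assert f2.read_bytes() == fam.read_bytes()
        assert r2.read_bytes() == rrna.read_bytes()


class TestExpectedRa:
    def test_analytic_matches_empirical_labels(self):
        g1 = generate_genome("g1", 20_000, 0.45, [(5_000, 5_600, "+", "GH43")], seed=30)
        g2 = generate_genome("g2", 20_000, 0.45, [(8_000, 8_600, "-", "GH2")], seed=31)
        prof = CommunityProfile("s", {"g1": 0.6, "g2": 0.4})
        ra = expected_family_ra([g1, g2], prof)
        assert set(ra) == {"GH43", "GH2"}
        assert sum(ra.values()) == pytest.approx(100.0)
        # empirical check by direct truth-label counting
        _, origins = simulate_reads([g1, g2], prof, 40_000, seed=32)
        counts = {"GH43": 0, "GH2": 0}
        for o in origins.values():
            if o.label in counts:
                counts[o.label] += 1
        tot = sum(counts.values())
        for fam in counts:
            assert 100 * counts[fam] / tot == pytest.approx(ra[fam], abs=2.5)
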