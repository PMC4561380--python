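"""HUL scan: selection rules, TTNF, fragment ANI, affiliation, coverage."""

import numpy as np
import pytest

from lignopipe.hul import (
    ContigRecord,
    GeneAnnotation,
    affiliate,
    anib,
    contig_read_coverage,
    select_gh_contigs,
    select_hotspots,
    tnf_vector,
    ttnf_correlation,
)
from lignopipe.synth import generate_genome, mutate_sequence


def _contig(cid, length, seed=0):
    rng = np.random.default_rng(seed)
    seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length).tobytes().decode()
    return ContigRecord(contig_id=cid, sequence=seq)


class TestSelection:
    def test_gh_contig_selected(self):
        c = _contig("c1", 6000)
        ann = [GeneAnnotation("c1", 100, 1000, "+", "GH43")]
        assert select_gh_contigs([c], ann) == [c]

    def test_non_target_family_not_selected(self):
        c = _contig("c1", 6000)
        ann = [GeneAnnotation("c1", 100, 1000, "+", "GT2")]
        assert select_gh_contigs([c], ann) == []

    def test_short_contig_excluded(self):
        c = _contig("c1", 4900)
        ann = [GeneAnnotation("c1", i, i + 500, "+", "GH2") for i in (0, 600, 1200)]
        assert select_gh_contigs([c], ann) == []

    def test_dangling_annotation_raises(self):
        with pytest.raises(ValueError, match="ghost"):
            select_gh_contigs([_contig("c1", 6000)], [GeneAnnotation("ghost", 0, 10, "+", "GH2")])

    @pytest.mark.parametrize(
        "length,n_gh,expected_rules",
        [
            (12_000, 2, ["hotspot-10kb-2GH"]),
            (9_900, 4, []),
            (40_000, 1, ["hotspot-35kb-1GH"]),
            (40_000, 2, ["hotspot-10kb-2GH", "hotspot-35kb-1GH"]),
            (10_000, 1, []),
            (35_000, 1, ["hotspot-35kb-1GH"]),
        ],
    )
    def test_hotspot_rules(self, length, n_gh, expected_rules):
        c = _contig("c1", length)
        ann = [GeneAnnotation("c1", 100 + 1200 * i, 1000 + 1200 * i, "+", "GH2") for i in range(n_gh)]
        records = select_hotspots([c], ann)
        if expected_rules:
            assert records[0].rules_fired == expected_rules
            assert records[0].n_gh == n_gh
        else:
            assert records == []

    def test_monotone_in_annotations(self):
        c = _contig("c1", 12_000)
        ann = [GeneAnnotation("c1", 100, 1000, "+", "GH2")]
        assert select_hotspots([c], ann) == []
        ann.append(GeneAnnotation("c1", 2000, 2900, "+", "GH43"))
        assert len(select_hotspots([c], ann)) == 1

    def test_planted_panel_precision_recall(self, contig_panel):
        contigs, annotations, truth, _sources = contig_panel
        recs = [ContigRecord(cid, seq) for cid, seq, _src in contigs]
        anns = [GeneAnnotation(*a) for a in annotations]
        hot = {h.contig_id for h in select_hotspots(recs, anns)}
        expected = {cid for cid, sel in truth.items() if sel}
        assert hot == expected  # precision = recall = 1.0


class TestTnf:
    def test_sums_to_one(self):
        v = tnf_vector(_contig("c", 5000, seed=1).sequence)
        assert v.sum() == pytest.approx(1.0)
        assert v.shape == (256,)

    def test_strand_symmetry(self):
        seq = _contig("c", 3000, seed=2).sequence
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert np.allclose(tnf_vector(seq), tnf_vector(rc))

    def test_hand_tally(self):
        # ACGTACGT windows: ACGT x2, CGTA, GTAC, TACG; its reverse complement
        # is itself, so every count doubles; total 10 windows
        import itertools

        v = tnf_vector("ACGTACGT")
        tetramers = ["".join(p) for p in itertools.product("ACGT", repeat=4)]
        lookup = {t: i for i, t in enumerate(tetramers)}
        assert v[lookup["ACGT"]] == pytest.approx(4 / 10)
        for t in ("CGTA", "GTAC", "TACG"):
            assert v[lookup[t]] == pytest.approx(2 / 10)
        assert v.sum() == pytest.approx(1.0)

    def test_ambiguous_windows_skipped(self):
        # every window of ACGTNACGT containing the N drops out; only the two
        # flanking ACGT windows (doubled by the reverse complement) remain
        v = tnf_vector("ACGTNACGT")
        assert v.sum() == pytest.approx(1.0)
        assert np.count_nonzero(v) == 1

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            tnf_vector("ACG")

    def test_correlation_self(self):
        v = tnf_vector(_contig("c", 4000, seed=3).sequence)
        assert ttnf_correlation(v, v) == pytest.approx(1.0)

    def test_correlation_zero_variance(self):
        assert ttnf_correlation(np.full(256, 1 / 256), np.full(256, 1 / 256)) is None

    def test_same_genome_fragment_correlates(self):
        g = generate_genome("g", 40_000, 0.35, [], seed=5)
        frag = g.sequence[5_000: 27_000]
        r_same = ttnf_correlation(tnf_vector(frag), tnf_vector(g.sequence))
        assert r_same >= 0.9

    def test_gc_contrast_lowers_correlation(self):
        low = generate_genome("low", 30_000, 0.30, [], seed=6)
        high = generate_genome("high", 30_000, 0.65, [], seed=7)
        frag = low.sequence[2_000: 22_000]
        r_same = ttnf_correlation(tnf_vector(frag), tnf_vector(low.sequence))
        r_other = ttnf_correlation(tnf_vector(frag), tnf_vector(high.sequence))
        assert r_other < r_same


@pytest.fixture(scope="module")
def genome():
    return generate_genome("ref", 30_000, 0.45, [], seed=8)


class TestAnib:

    def test_verbatim_contig(self, genome):
        contig = genome.sequence[4_000:12_000]
        ani, frac = anib(contig, genome.sequence)
        assert ani == pytest.approx(100.0)
        assert frac == pytest.approx(1.0)

    def test_ten_percent_divergence(self, genome):
        contig = mutate_sequence(genome.sequence[4_000:12_000], rate=0.10, seed=9)
        ani, frac = anib(contig, genome.sequence)
        assert ani == pytest.approx(90.0, abs=1.5)
        assert frac == pytest.approx(1.0)

    def test_unrelated_genome_no_hits(self, genome):
        other = generate_genome("other", 30_000, 0.45, [], seed=10)
        contig = other.sequence[2_000:8_000]
        ani, frac = anib(contig, genome.sequence)
        assert frac <= 0.2

    def test_diverged_contig_flagged_below_95(self, genome):
        # > 5% divergence from the nearest reference must report ANI < 95
        contig = mutate_sequence(genome.sequence[4_000:12_000], rate=0.06, seed=11)
        ani, _ = anib(contig, genome.sequence)
        assert ani < 95.0

    def test_too_short_contig_rejected(self, genome):
        with pytest.raises(ValueError):
            anib("ACGT" * 50, genome.sequence)


class TestAffiliate:
    def test_source_genome_wins(self):
        src = generate_genome("src", 25_000, 0.40, [], seed=12)
        other = generate_genome("other", 25_000, 0.60, [], seed=13)
        contig = src.sequence[3_000:15_000]
        ref, ani, r = affiliate(contig, {"src": src.sequence, "other": other.sequence})
        assert ref == "src"
        assert ani == pytest.approx(100.0)
        assert r > 0.9

    def test_single_reference(self):
        src = generate_genome("solo", 20_000, 0.5, [], seed=14)
        ref, ani, r = affiliate(src.sequence[1_000:9_000], {"solo": src.sequence})
        assert ref == "solo" and ani == pytest.approx(100.0)

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            affiliate("ACGT" * 1000, {})


class TestReadCoverage:
    def test_no_reads(self):
        assert contig_read_coverage(1000, []) == 0.0

    def test_full_single_read(self):
        assert contig_read_coverage(1000, [(0, 1000)]) == pytest.approx(1.0)

    def test_ten_reads_272bp(self):
        placements = [(i * 70, i * 70 + 272) for i in range(10)]
        placements = [(s, min(e, 1000)) for s, e in placements]
        total = sum(e - s for s, e in placements)
        assert contig_read_coverage(1000, placements) == pytest.approx(total / 1000)

    def test_arithmetic_example(self):
        # 10 reads of 272 bp fully on a 1000 bp contig -> 2.72X
        placements = [(j, j + 272) for j in [0] * 10]
        assert contig_read_coverage(1000, placements) == pytest.approx(2.72)

    def test_clipping(self):
        assert contig_read_coverage(100, [(-50, 50), (80, 200)]) == pytest.approx(0.7)
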