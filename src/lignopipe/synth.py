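"""Synthetic enrichment-community generator with known ground truth.

Emulates the data shape of a dilution-transfer enrichment experiment on
plant biomass: a diverse soil-like inoculum plus sequential-transfer
consortium samples, sequenced as short reads (272 bp by default). Genomes
carry planted gene cassettes (CAZy families, 16S rRNA, transport/sensing
genes) on controllable G+C backgrounds, so that low-G+C taxa can be enriched
and per-family abundance fold-changes are known analytically. Alignment
tables in the blast-tab dialect are synthesized with the exact aligner, so
the downstream filter/assignment/profiling stages run exactly as they would
on real search output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from .align import align_pair

__all__ = [
    "GeneCassette",
    "GenomeModel",
    "CommunityProfile",
    "ReadOrigin",
    "SyntheticTruth",
    "family_template",
    "generate_genome",
    "build_series",
    "simulate_reads",
    "emit_alignment_tables",
    "expected_family_ra",
    "planted_log_folds",
    "Scenario",
    "enrichment_scenario",
    "hul_panel",
    "mutate_sequence",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

#: CAZy class prefixes recognized as family cassettes.
_CAZY_PREFIXES = ("GH", "GT", "CBM", "CE", "PL", "AA")

DEFAULT_READ_LENGTH = 272
DEFAULT_GENE_LENGTH = 600
RRNA_LENGTH = 1500


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _is_cazy(label: str) -> bool:
    return label.startswith(_CAZY_PREFIXES)


def _stable_int(text: str) -> int:
    """Deterministic 31-bit integer from a string (process-independent)."""
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "little") & 0x7FFFFFFF


@dataclass(frozen=True)
class GeneCassette:
    """A planted gene region; 0-based half-open coordinates on the genome."""

    start: int
    end: int
    strand: str
    functional_label: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"cassette end must exceed start: [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeModel:
    genome_id: str
    taxon_path: tuple[str, ...]
    length_bp: int
    gc_target: float
    cassettes: list[GeneCassette]
    sequence: str = ""

    @property
    def realized_gc(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class CommunityProfile:
    sample_id: str
    abundances: dict[str, float]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.abundances.values()):
            raise ValueError("abundances must be non-negative")
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1, got {total}")


@dataclass(frozen=True)
class ReadOrigin:
    genome_id: str
    start: int
    strand: str
    label: str | None


@dataclass
class SyntheticTruth:
    """Per-read provenance plus the planted sample-level quantities."""

    reads: dict[str, ReadOrigin] = field(default_factory=dict)
    planted_log_folds: dict[str, dict[str, float]] = field(default_factory=dict)
    hul_contigs: list[str] = field(default_factory=list)


@lru_cache(maxsize=None)
def family_template(label: str) -> str:
    """Bundled constant template sequence for a functional label.

    Templates are fixed pseudo-random sequences (balanced composition) keyed
    by the label, 1500 bp for 16S rRNA and 600 bp for genes, so alignment
    hits against the family reference are recoverable by construction.
    """
    length = RRNA_LENGTH if label == "rRNA16S" else DEFAULT_GENE_LENGTH
    rng = np.random.default_rng(_stable_int("template::" + label))
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def generate_genome(
    genome_id: str,
    length_bp: int,
    gc_target: float,
    cassette_spec: list[GeneCassette] | list[tuple],
    seed: int,
    taxon_path: tuple[str, ...] = (),
    balance_gc: bool = False,
) -> GenomeModel:
    """Emit a genome sequence with planted cassettes on a G+C background.

    Intergenic bases are i.i.d. with P(G)+P(C) equal to ``gc_target``;
    with ``balance_gc`` the intergenic composition instead compensates the
    (balanced) cassette composition so the genome-wide G+C meets the target.
    Cassette regions are filled from the per-label templates, tiled or
    truncated to the cassette length, reverse-complemented on the minus
    strand. Overlapping cassettes are rejected with the offending pair named.
    """
    if length_bp < 1000:
        raise ValueError("length_bp must be >= 1000")
    if not 0.0 < gc_target < 1.0:
        raise ValueError("gc_target must lie strictly between 0 and 1")
    cassettes = [c if isinstance(c, GeneCassette) else GeneCassette(*c) for c in cassette_spec]
    cassettes.sort(key=lambda c: c.start)
    for c in cassettes:
        if c.end > length_bp:
            raise ValueError(f"cassette [{c.start}, {c.end}) exceeds genome length {length_bp}")
    for prev, nxt in zip(cassettes, cassettes[1:]):
        if nxt.start < prev.end:
            raise ValueError(
                f"overlapping cassettes in {genome_id!r}: "
                f"[{prev.start}, {prev.end}) {prev.functional_label} vs "
                f"[{nxt.start}, {nxt.end}) {nxt.functional_label}"
            )

    cassette_bp = sum(c.length for c in cassettes)
    intergenic_bp = length_bp - cassette_bp
    gc_bg = gc_target
    if balance_gc and intergenic_bp > 0:
        # cassette templates are composition-balanced (G+C ~ 0.5)
        gc_bg = (gc_target * length_bp - 0.5 * cassette_bp) / intergenic_bp
        gc_bg = min(max(gc_bg, 0.02), 0.98)
    p = np.array([(1 - gc_bg) / 2, gc_bg / 2, gc_bg / 2, (1 - gc_bg) / 2])
    rng = np.random.default_rng([seed & 0x7FFFFFFF, _stable_int("genome::" + genome_id)])
    arr = rng.choice(_BASES, size=length_bp, p=p)
    seq = bytearray(arr.tobytes())
    for c in cassettes:
        tmpl = family_template(c.functional_label)
        reps = -(-c.length // len(tmpl))
        insert = (tmpl * reps)[: c.length]
        if c.strand == "-":
            insert = _revcomp(insert)
        seq[c.start : c.end] = insert.encode("ascii")
    return GenomeModel(
        genome_id=genome_id,
        taxon_path=tuple(taxon_path),
        length_bp=length_bp,
        gc_target=gc_target,
        cassettes=cassettes,
        sequence=seq.decode("ascii"),
    )


def build_series(
    inoculum_profile: CommunityProfile,
    fold_spec: dict[str, float],
    n_transfers: int,
    sample_prefix: str = "T",
) -> list[CommunityProfile]:
    """Deterministic transfer series: abundance(t) proportional to w0 * factor^t."""
    if n_transfers < 1:
        raise ValueError("n_transfers must be >= 1")
    if any(f < 0 for f in fold_spec.values()):
        raise ValueError("fold factors must be non-negative")
    out = []
    for t in range(1, n_transfers + 1):
        raw = {
            g: w * fold_spec.get(g, 1.0) ** t for g, w in inoculum_profile.abundances.items()
        }
        total = sum(raw.values())
        if total == 0:
            raise ValueError("all abundances vanish: every fold factor is zero")
        out.append(
            CommunityProfile(
                sample_id=f"{sample_prefix}{t}",
                abundances={g: w / total for g, w in raw.items()},
            )
        )
    return out


def simulate_reads(
    genomes: list[GenomeModel],
    profile: CommunityProfile,
    n_reads: int,
    read_length: int = DEFAULT_READ_LENGTH,
    error_rate: float = 0.0,
    seed: int = 0,
    read_prefix: str = "r",
) -> tuple[dict[str, str], dict[str, ReadOrigin]]:
    """Draw fixed-length reads from a weighted genome mixture.

    Genome chosen by profile weight, start uniform, strand uniform;
    substitution errors i.i.d. at ``error_rate``. A read inherits a
    cassette's functional label when at least half of it overlaps the
    cassette. Returns (read_id -> sequence, read_id -> origin).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0.0 <= error_rate < 0.2:
        raise ValueError("error_rate must lie in [0, 0.2)")
    by_id = {g.genome_id: g for g in genomes}
    gids = [g for g in sorted(profile.abundances) if profile.abundances[g] > 0]
    if not gids:
        raise ValueError("profile has no genome with positive weight")
    for g in gids:
        if g not in by_id:
            raise ValueError(f"profile references unknown genome {g!r}")
        if by_id[g].length_bp < read_length:
            raise ValueError(f"genome {g!r} shorter than the read length")
    w = np.array([profile.abundances[g] for g in gids])
    w = w / w.sum()
    rng = np.random.default_rng(
        [seed & 0x7FFFFFFF, _stable_int("reads::" + profile.sample_id)]
    )
    gidx = rng.choice(len(gids), size=n_reads, p=w)
    max_start = np.array([by_id[g].length_bp - read_length for g in gids])
    starts = (rng.random(n_reads) * (max_start[gidx] + 1)).astype(np.int64)
    strands = rng.integers(0, 2, size=n_reads)
    n_errors = rng.binomial(read_length, error_rate, size=n_reads) if error_rate > 0 else None

    half = read_length / 2.0
    ndigits = len(str(n_reads))
    reads: dict[str, str] = {}
    origins: dict[str, ReadOrigin] = {}
    for i in range(n_reads):
        g = by_id[gids[gidx[i]]]
        s = int(starts[i])
        segment = g.sequence[s : s + read_length]
        strand = "+" if strands[i] == 0 else "-"
        if strand == "-":
            segment = _revcomp(segment)
        if n_errors is not None and n_errors[i] > 0:
            b = bytearray(segment.encode("ascii"))
            pos = rng.choice(read_length, size=n_errors[i], replace=False)
            shift = rng.integers(1, 4, size=n_errors[i])
            for pj, sh in zip(pos, shift):
                cur = b"ACGT".index(b[pj : pj + 1])
                b[pj] = b"ACGT"[(cur + sh) % 4]
            segment = b.decode("ascii")
        label = None
        best_ov = 0
        for c in g.cassettes:
            ov = min(s + read_length, c.end) - max(s, c.start)
            if ov >= half and ov > best_ov:
                best_ov = ov
                label = c.functional_label
        rid = f"{read_prefix}{i:0{ndigits}d}"
        reads[rid] = segment
        origins[rid] = ReadOrigin(genome_id=g.genome_id, start=s, strand=strand, label=label)
    return reads, origins


def _synthetic_evalue(score: int, read_length: int) -> float:
    """Karlin-Altschul-shaped e-value from the raw alignment score."""
    return min(10.0, read_length * 1e6 * 2.0 ** (-score))


def emit_alignment_tables(
    reads: dict[str, str],
    genomes: list[GenomeModel],
    origins: dict[str, ReadOrigin],
    family_path: str | Path,
    rrna_path: str | Path,
    min_overlap: int = 30,
    score_floor: int = 40,
) -> tuple[int, int]:
    """Synthesize the two tabular alignment files a homology search would yield.

    Each read overlapping a cassette by >= ``min_overlap`` bp is aligned
    (exact local alignment) against that cassette's template; alignments
    scoring at or above ``score_floor`` are emitted as 13-column blast-tab
    rows. CAZy-family cassettes go to the family-reference table with
    amino-acid alignment lengths (floor(nt/3), translated-search convention);
    16S cassettes go to the rRNA table in nucleotide units. Subject ids are
    ``<label>|<genome>``; minus-orientation hits carry swapped subject
    coordinates. Reads overlapping no cassette produce no rows.
    """
    by_id = {g.genome_id: g for g in genomes}
    read_ids = sorted(reads)
    n_fam = 0
    n_rrna = 0
    with open(family_path, "w") as fam_fh, open(rrna_path, "w") as rrna_fh:
        for rid in read_ids:
            origin = origins[rid]
            g = by_id[origin.genome_id]
            seq = reads[rid]
            L = len(seq)
            s = origin.start
            for c in g.cassettes:
                ov = min(s + L, c.end) - max(s, c.start)
                if ov < min_overlap:
                    continue
                same_orientation = origin.strand == c.strand
                oriented = seq if same_orientation else _revcomp(seq)
                tmpl = family_template(c.functional_label)
                # restrict the DP to the template window the overlap maps to
                os_, oe = max(s, c.start), min(s + L, c.end)
                if c.length <= len(tmpl):
                    if c.strand == "+":
                        w0, w1 = os_ - c.start, oe - c.start
                    else:
                        w0, w1 = c.length - (oe - c.start), c.length - (os_ - c.start)
                    margin = 24
                    w0 = max(0, w0 - margin)
                    w1 = min(len(tmpl), w1 + margin)
                else:  # tiled cassette: fall back to the whole template
                    w0, w1 = 0, len(tmpl)
                aln0 = align_pair(oriented, tmpl[w0:w1], mode="local")
                if aln0.score < score_floor or aln0.aln_length == 0:
                    continue
                aln = dataclasses.replace(
                    aln0, b_start=aln0.b_start + w0, b_end=aln0.b_end + w0
                )
                pident = 100.0 * aln.identities / aln.aln_length
                evalue = _synthetic_evalue(aln.score, L)
                subject = f"{c.functional_label}|{g.genome_id}"
                if same_orientation:
                    qstart, qend = aln.a_start + 1, aln.a_end
                    sstart, send = aln.b_start + 1, aln.b_end
                else:
                    qstart, qend = L - aln.a_end + 1, L - aln.a_start
                    sstart, send = aln.b_end, aln.b_start + 1
                if c.functional_label == "rRNA16S":
                    length = aln.aln_length
                    mism = aln.aln_length - aln.identities
                    row_fh = rrna_fh
                    n_rrna += 1
                else:
                    if not _is_cazy(c.functional_label):
                        continue
                    length = max(1, aln.aln_length // 3)
                    mism = (aln.aln_length - aln.identities) // 3
                    row_fh = fam_fh
                    n_fam += 1
                row_fh.write(
                    f"{rid}\t{subject}\t{pident:.2f}\t{length}\t{mism}\t0\t"
                    f"{qstart}\t{qend}\t{sstart}\t{send}\t{evalue:.3g}\t"
                    f"{float(aln.score):.1f}\t{L}\n"
                )
    return n_fam, n_rrna


def expected_family_ra(
    genomes: list[GenomeModel],
    profile: CommunityProfile,
    read_length: int = DEFAULT_READ_LENGTH,
) -> dict[str, float]:
    """Analytic expected RA (percent) per CAZy family under the truth labels.

    A uniform read start acquires a cassette's label when at least half the
    read overlaps it; the counting is exact over the valid start positions.
    """
    half = int(math.ceil(read_length / 2))
    num: dict[str, float] = {}
    for g in genomes:
        wg = profile.abundances.get(g.genome_id, 0.0)
        if wg == 0:
            continue
        n_pos = g.length_bp - read_length + 1
        for c in g.cassettes:
            if not _is_cazy(c.functional_label):
                continue
            lo = max(0, c.start - (read_length - half))
            hi = min(n_pos - 1, c.end - half)
            count = max(0, hi - lo + 1)
            num[c.functional_label] = num.get(c.functional_label, 0.0) + wg * count / n_pos
    total = sum(num.values())
    if total == 0:
        return {}
    return {f: 100.0 * v / total for f, v in num.items()}


def planted_log_folds(
    genomes: list[GenomeModel],
    sample_profile: CommunityProfile,
    inoculum_profile: CommunityProfile,
    read_length: int = DEFAULT_READ_LENGTH,
) -> dict[str, float]:
    """Planted log10 fold of each family's RA versus the inoculum."""
    ra_s = expected_family_ra(genomes, sample_profile, read_length)
    ra_0 = expected_family_ra(genomes, inoculum_profile, read_length)
    out = {}
    for f in ra_s:
        if f in ra_0 and ra_0[f] > 0 and ra_s[f] > 0:
            out[f] = math.log10(ra_s[f] / ra_0[f])
    return out


# --------------------------------------------------------------------------
# Bundled study scenario: soil-like inoculum plus transfer series
# --------------------------------------------------------------------------

#: (genome id, G+C target, planted families, taxon path, inoculum weight,
#:  per-transfer factor for series W and T). Low-G+C taxa are the enriched
#:  ones, mirroring the G+C contrast the enrichment selects for.
GENOME_SPECS = [
    ("Sphingobacterium_S1", 0.38, ("GH43", "GH2", "GH92"),
     ("root", "Bacteria", "Bacteroidetes", "Sphingobacterium", "Sphingobacterium_S1"),
     0.12, 1.8, 1.5),
    ("Bacteroides_B1", 0.42, ("GH29", "GH95", "GH31"),
     ("root", "Bacteria", "Bacteroidetes", "Bacteroides", "Bacteroides_B1"),
     0.18, 1.4, 1.7),
    ("Klebsiella_K1", 0.50, ("GH13", "GH1", "GH3"),
     ("root", "Bacteria", "Proteobacteria", "Klebsiella", "Klebsiella_K1"),
     0.30, 1.0, 0.9),
    ("Streptomyces_A1", 0.62, ("GH20", "CBM50", "GT2"),
     ("root", "Bacteria", "Actinobacteria", "Streptomyces", "Streptomyces_A1"),
     0.22, 0.85, 0.8),
    ("Mycobacterium_A2", 0.65, ("GH5", "GH6", "PL1"),
     ("root", "Bacteria", "Actinobacteria", "Mycobacterium", "Mycobacterium_A2"),
     0.18, 0.8, 0.85),
]

_TAXON_RANKS = ("root", "domain", "phylum", "genus", "species")

SCENARIO_GENOME_LENGTH = 60_000
CASSETTE_COPIES_PER_FAMILY = 8


def _scenario_cassettes(families: tuple[str, ...]) -> list[GeneCassette]:
    """Evenly spaced cassette layout: 8 copies per family plus one 16S."""
    labels = [f for f in families for _ in range(CASSETTE_COPIES_PER_FAMILY)] + ["rRNA16S"]
    total_bp = sum(RRNA_LENGTH if l == "rRNA16S" else DEFAULT_GENE_LENGTH for l in labels)
    gap = (SCENARIO_GENOME_LENGTH - total_bp) // (len(labels) + 1)
    cassettes = []
    pos = gap
    for i, label in enumerate(labels):
        length = RRNA_LENGTH if label == "rRNA16S" else DEFAULT_GENE_LENGTH
        cassettes.append(
            GeneCassette(pos, pos + length, "+" if i % 2 == 0 else "-", label)
        )
        pos += length + gap
    return cassettes


@dataclass
class Scenario:
    """A complete synthetic study: genomes, profiles, reads and truth."""

    genomes: list[GenomeModel]
    profiles: dict[str, CommunityProfile]
    inoculum_id: str
    reads: dict[str, dict[str, str]]
    truth: SyntheticTruth

    @property
    def sample_ids(self) -> list[str]:
        return list(self.profiles)

    def taxonomy_nodes(self) -> dict[str, tuple[str | None, str, str]]:
        nodes: dict[str, tuple[str | None, str, str]] = {}
        for g in self.genomes:
            path = g.taxon_path
            for level, node in enumerate(path):
                parent = path[level - 1] if level else None
                rank = _TAXON_RANKS[min(level, len(_TAXON_RANKS) - 1)]
                nodes[node] = (parent, rank, node)
        return nodes

    def subject_family_map(self) -> dict[str, str]:
        out = {}
        for g in self.genomes:
            for c in g.cassettes:
                if _is_cazy(c.functional_label):
                    out[f"{c.functional_label}|{g.genome_id}"] = c.functional_label
        return out

    def subject_taxon_map(self) -> dict[str, str]:
        out = {}
        for g in self.genomes:
            for c in g.cassettes:
                out[f"{c.functional_label}|{g.genome_id}"] = g.taxon_path[-1]
        return out


def enrichment_scenario(
    seed: int,
    n_reads_per_sample: int = 50_000,
    error_rate: float = 0.01,
    series: tuple[str, ...] = ("W", "T"),
    n_transfers: int = 3,
    read_length: int = DEFAULT_READ_LENGTH,
) -> Scenario:
    """Build the bundled study: inoculum FS1 plus transfer series.

    Five genomes at contrasting G+C (0.38-0.65) each carry three exclusive
    CAZy families; series "W" and "T" apply different per-transfer selection
    factors favouring the low-G+C genomes, so each family's log10 fold
    against FS1 is planted and known exactly.
    """
    genomes = [
        generate_genome(
            gid, SCENARIO_GENOME_LENGTH, gc, _scenario_cassettes(fams),
            seed=seed, taxon_path=path, balance_gc=True,
        )
        for gid, gc, fams, path, _, _, _ in GENOME_SPECS
    ]
    inoculum = CommunityProfile(
        sample_id="FS1",
        abundances={spec[0]: spec[4] for spec in GENOME_SPECS},
    )
    profiles: dict[str, CommunityProfile] = {"FS1": inoculum}
    for label in series:
        col = 5 if label == "W" else 6
        factors = {spec[0]: spec[col] for spec in GENOME_SPECS}
        for prof in build_series(inoculum, factors, n_transfers, sample_prefix=label):
            profiles[prof.sample_id] = prof

    reads: dict[str, dict[str, str]] = {}
    truth = SyntheticTruth()
    for sid, prof in profiles.items():
        sample_reads, origins = simulate_reads(
            genomes, prof, n_reads_per_sample,
            read_length=read_length, error_rate=error_rate,
            seed=seed, read_prefix=f"{sid}_",
        )
        reads[sid] = sample_reads
        truth.reads.update(origins)
        if sid != "FS1":
            truth.planted_log_folds[sid] = planted_log_folds(
                genomes, prof, inoculum, read_length
            )
    return Scenario(
        genomes=genomes, profiles=profiles, inoculum_id="FS1", reads=reads, truth=truth
    )


def write_scenario(scenario: Scenario, outdir: str | Path, seed: int = 0) -> Path:
    """Materialize a scenario as pipeline-ready files plus a run config.

    Writes per-sample reads FASTA and alignment tables, the genome FASTA,
    subject->family and subject->taxon maps, the taxonomy TSV, the per-read
    truth table, and a ``config.yaml`` runnable by the pipeline. Returns the
    config path. Byte-identical for identical (scenario, seed).
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample_entries = []
    for sid in scenario.sample_ids:
        reads_path = outdir / f"{sid}.reads.fasta"
        with open(reads_path, "w") as fh:
            for rid in sorted(scenario.reads[sid]):
                fh.write(f">{rid}\n{scenario.reads[sid][rid]}\n")
        fam_path = outdir / f"{sid}.family.tsv"
        rrna_path = outdir / f"{sid}.rrna.tsv"
        emit_alignment_tables(
            scenario.reads[sid], scenario.genomes, scenario.truth.reads,
            fam_path, rrna_path,
        )
        sample_entries.append(
            {
                "id": sid,
                "role": "inoculum" if sid == scenario.inoculum_id else "consortium",
                "reads": reads_path.name,
                "family_hits": fam_path.name,
                "rrna_hits": rrna_path.name,
            }
        )
    with open(outdir / "genomes.fasta", "w") as fh:
        for g in scenario.genomes:
            fh.write(f">{g.genome_id}\n{g.sequence}\n")
    with open(outdir / "subject_family.tsv", "w") as fh:
        for k, v in sorted(scenario.subject_family_map().items()):
            fh.write(f"{k}\t{v}\n")
    with open(outdir / "subject_taxon.tsv", "w") as fh:
        for k, v in sorted(scenario.subject_taxon_map().items()):
            fh.write(f"{k}\t{v}\n")
    with open(outdir / "taxonomy.tsv", "w") as fh:
        fh.write("node_id\tparent_id\trank\tname\n")
        for node, (parent, rank, name) in sorted(scenario.taxonomy_nodes().items()):
            fh.write(f"{node}\t{parent or ''}\t{rank}\t{name}\n")
    with open(outdir / "truth_reads.tsv", "w") as fh:
        fh.write("read_id\tgenome_id\tstart\tstrand\tlabel\n")
        for rid in sorted(scenario.truth.reads):
            o = scenario.truth.reads[rid]
            fh.write(f"{rid}\t{o.genome_id}\t{o.start}\t{o.strand}\t{o.label or ''}\n")
    with open(outdir / "truth_folds.tsv", "w") as fh:
        fh.write("sample\tfamily\tplanted_log10_fold\n")
        for sid in sorted(scenario.truth.planted_log_folds):
            for fam, lf in sorted(scenario.truth.planted_log_folds[sid].items()):
                fh.write(f"{sid}\t{fam}\t{lf:.6f}\n")
    config = {
        "seed": seed,
        "output_dir": "results",
        "samples": sample_entries,
        "references": {
            "family_map": "subject_family.tsv",
            "taxonomy": "taxonomy.tsv",
            "subject_taxon": "subject_taxon.tsv",
            "genomes": "genomes.fasta",
        },
    }
    config_path = outdir / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return config_path


def mutate_sequence(seq: str, rate: float, seed: int) -> str:
    """Apply i.i.d. substitutions at the given per-base rate."""
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    b = bytearray(seq.encode("ascii"))
    mask = np.nonzero(rng.random(len(b)) < rate)[0]
    shift = rng.integers(1, 4, size=mask.size)
    for pos, sh in zip(mask, shift):
        cur = b"ACGT".find(b[pos : pos + 1])
        if cur >= 0:
            b[pos] = b"ACGT"[(cur + sh) % 4]
    return b.decode("ascii")


def hul_panel(seed: int):
    """Planted contig panel spanning the HUL rule boundaries.

    Returns (contigs, annotations, truth, sources) where contigs is a list
    of (contig_id, sequence, source_genome_id), annotations is a list of
    (contig_id, start, end, strand, label) tuples, truth maps contig id to
    whether the hotspot rules should select it, and sources maps source
    genome id to its sequence. Thirty contigs: the full
    size x GH-count grid (9.9/10/12/34.9/35/40 kb x 0-3 target-family GH
    genes) plus six two-GH contigs padded with transporter/sensor genes.
    Sequences are cut verbatim from two synthetic source genomes.
    """
    sizes = [9_900, 10_000, 12_000, 34_900, 35_000, 40_000]
    gh_families = ["GH2", "GH43", "GH92"]
    flank_labels = ["TBR", "ABCT", "TCSP"]
    sources = [
        generate_genome(
            f"source_{i}", 50_000, gc, [], seed=seed + i,
            taxon_path=("root", "Bacteria", f"phylum_{i}", f"genus_{i}", f"source_{i}"),
        )
        for i, gc in enumerate((0.38, 0.55))
    ]
    contigs = []
    annotations = []
    truth: dict[str, bool] = {}
    spec_rows = [(size, n_gh, False) for size in sizes for n_gh in range(4)]
    spec_rows += [(size, 2, True) for size in sizes]
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    for i, (size, n_gh, flanked) in enumerate(spec_rows):
        cid = f"contig_{i:02d}"
        src = sources[i % 2]
        offset = int(rng.integers(0, src.length_bp - size + 1))
        contigs.append((cid, src.sequence[offset : offset + size], src.genome_id))
        pos = 200
        for j in range(n_gh):
            annotations.append((cid, pos, pos + 900, "+", gh_families[j % 3]))
            pos += 1200
        if flanked:
            for j in range(3):
                annotations.append((cid, pos, pos + 800, "-", flank_labels[j]))
                pos += 1000
        truth[cid] = (size >= 10_000 and n_gh >= 2) or (size >= 35_000 and n_gh >= 1)
    return contigs, annotations, truth, {g.genome_id: g.sequence for g in sources}
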