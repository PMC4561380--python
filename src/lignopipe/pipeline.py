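"""End-to-end pipeline: configuration, stage sequencing, and report tables.

Stage order follows the analysis procedure: hit filtering and family
assignment, per-sample profiles and inoculum-referenced fold changes,
Fisher/Newcombe enrichment with FDR control, 16S ratio and coverage, 97%
clustering richness, LCA taxonomy, and the HUL contig scan. Every stage
writes a plain TSV, so any of them can equally be driven by real search
output instead of the bundled simulator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO

from . import __version__
from .assign import (
    AlignmentHit,
    assignments_from_table,
    hit_ratio,
    parse_tabular_hits,
    rrna_ratio,
)
from .cluster import greedy_cluster, richness
from .enrich import TwoSampleCount, enrichment_table
from .hul import (
    ContigRecord,
    GeneAnnotation,
    affiliate,
    select_gh_contigs,
    select_hotspots,
)
from .lca import LcaParams, TaxonomyTree, apply_min_support, assign_reads
from .profiles import coverage_estimate, fold_table, gc_content, relative_abundance

__all__ = ["SampleSpec", "RunConfig", "load_config", "validate_config", "run_pipeline"]

#: families clustered for richness by default (the re-annotated family set).
DEFAULT_RICHNESS_FAMILIES = (
    "CBM50", "GH1", "GH2", "GH3", "GH20", "GH29", "GH31", "GH43", "GH92", "GH95",
)

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class SampleSpec:
    sample_id: str
    role: str  # "inoculum" | "consortium"
    reads: Path
    family_hits: Path
    rrna_hits: Path | None = None


@dataclass
class Thresholds:
    ratio: float = 30.0
    evalue: float = 1e-15
    cluster_identity: float = 0.97
    richness_max_reads: int = 150
    otu_max_reads: int = 200
    genome_size_mb: float = 4.0
    lca: LcaParams = field(default_factory=LcaParams)


@dataclass
class RunConfig:
    samples: list[SampleSpec]
    family_map: Path
    output_dir: Path
    seed: int = 0
    taxonomy: Path | None = None
    subject_taxon: Path | None = None
    reference_genomes: Path | None = None
    contigs: Path | None = None
    contig_annotations: Path | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)

    @property
    def inoculum_id(self) -> str:
        return next(s.sample_id for s in self.samples if s.role == "inoculum")


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration; relative paths resolve next to the file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def _p(v):
        return None if v is None else (base / v if not Path(v).is_absolute() else Path(v))

    samples = [
        SampleSpec(
            sample_id=s["id"],
            role=s.get("role", "consortium"),
            reads=_p(s["reads"]),
            family_hits=_p(s["family_hits"]),
            rrna_hits=_p(s.get("rrna_hits")),
        )
        for s in raw.get("samples", [])
    ]
    refs = raw.get("references", {})
    th = raw.get("thresholds", {})
    lca_kwargs = th.pop("lca", {})
    thresholds = Thresholds(**th, lca=LcaParams(**lca_kwargs))
    contigs = raw.get("contigs", {})
    return RunConfig(
        samples=samples,
        family_map=_p(refs.get("family_map")),
        taxonomy=_p(refs.get("taxonomy")),
        subject_taxon=_p(refs.get("subject_taxon")),
        reference_genomes=_p(refs.get("genomes")),
        contigs=_p(contigs.get("sequences")),
        contig_annotations=_p(contigs.get("annotations")),
        output_dir=_p(raw.get("output_dir", "results")),
        seed=int(raw.get("seed", 0)),
        thresholds=thresholds,
    )


def validate_config(config: RunConfig) -> list[str]:
    """Collect configuration errors; an empty list means the config is runnable."""
    errors = []
    if not config.samples:
        errors.append("no samples configured")
    ids = [s.sample_id for s in config.samples]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        errors.append(f"duplicate sample ids: {', '.join(dupes)}")
    roles = [s.role for s in config.samples]
    if roles.count("inoculum") != 1:
        errors.append(
            f"exactly one sample must have role 'inoculum', found {roles.count('inoculum')}"
        )
    for s in config.samples:
        if s.role not in ("inoculum", "consortium"):
            errors.append(f"sample {s.sample_id!r}: unknown role {s.role!r}")
        for label, p in (("reads", s.reads), ("family_hits", s.family_hits)):
            if p is None or not Path(p).exists():
                errors.append(f"sample {s.sample_id!r}: {label} path not found: {p}")
    if config.family_map is None or not Path(config.family_map).exists():
        errors.append(f"family map not found: {config.family_map}")
    t = config.thresholds
    if t.ratio <= 0:
        errors.append("ratio threshold must be positive")
    if t.evalue <= 0:
        errors.append("e-value cutoff must be positive")
    if not 0 < t.cluster_identity <= 1:
        errors.append("cluster identity must lie in (0, 1]")
    return errors


def _read_two_col(path: Path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        k, v = line.split("\t")[:2]
        out[k] = v
    return out


def _read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute all configured stages; returns the written output tables.

    Deterministic for a fixed config and seed. A stage failure aborts with
    the stage name attached to the exception.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    family_map = _read_two_col(config.family_map)
    written: dict[str, Path] = {}
    inoc = config.inoculum_id

    stage = "assign"
    try:
        profiles = {}
        reads_by_sample = {}
        hits_by_sample = {}
        assignments_by_sample = {}
        for s in config.samples:
            hits = parse_tabular_hits(s.family_hits, query_fasta=s.reads)
            hits_by_sample[s.sample_id] = hits
            assignments = assignments_from_table(
                hits, family_map, threshold=th.ratio, evalue_max=th.evalue
            )
            assignments_by_sample[s.sample_id] = assignments
            path = out / f"assignments_{s.sample_id}.tsv"
            with open(path, "w") as fh:
                fh.write("read_id\tfamily\tclass\tbitscore\tratio\n")
                for a in assignments:
                    fh.write(
                        f"{a.query_id}\t{a.family}\t{a.cazy_class}\t"
                        f"{a.hit.bitscore:.1f}\t{hit_ratio(a.hit):.2f}\n"
                    )
            written[f"assignments_{s.sample_id}"] = path
            profiles[s.sample_id] = relative_abundance(assignments, sample_id=s.sample_id)
            reads_by_sample[s.sample_id] = _read_fasta(s.reads)

        stage = "profile"
        families = sorted({f for p in profiles.values() for f in p.counts})
        ra_path = out / "family_ra.tsv"
        with open(ra_path, "w") as fh:
            fh.write("family\t" + "\t".join(profiles) + "\n")
            for f in families:
                fh.write(
                    f
                    + "\t"
                    + "\t".join(f"{profiles[s].ra.get(f, 0.0):.3f}" for s in profiles)
                    + "\n"
                )
        written["family_ra"] = ra_path

        fold_path = out / "fold_changes.tsv"
        with open(fold_path, "w") as fh:
            fh.write("sample\tfamily\tra_sample\tra_reference\tlog10_fold\n")
            for sid, prof in profiles.items():
                if sid == inoc:
                    continue
                for fc in fold_table(prof, profiles[inoc]):
                    lf = "n.d." if fc.log10_fold is None else f"{fc.log10_fold:.3f}"
                    fh.write(
                        f"{sid}\t{fc.family}\t{fc.ra_sample:.3f}\t{fc.ra_reference:.3f}\t{lf}\n"
                    )
        written["fold_changes"] = fold_path

        gc_path = out / "sample_gc.tsv"
        with open(gc_path, "w") as fh:
            fh.write("sample\tgc_pooled\tgc_read_mean\tgc_read_sd\n")
            for sid, reads in reads_by_sample.items():
                pooled, mean, sd = gc_content(reads.values())
                fh.write(f"{sid}\t{pooled:.4f}\t{mean:.4f}\t{sd:.4f}\n")
        written["sample_gc"] = gc_path

        stage = "enrich"
        enrich_path = out / "enrichment.tsv"
        with open(enrich_path, "w") as fh:
            fh.write(
                "sample\tfamily\tx1\tn1\tx2\tn2\tp_value\tdiff\tci_low\tci_high\t"
                "q_bh\tq_storey\tsignificant\n"
            )
            for sid, prof in profiles.items():
                if sid == inoc:
                    continue
                ref = profiles[inoc]
                fams = sorted(set(prof.counts) | set(ref.counts))
                counts = [
                    TwoSampleCount(
                        family=f,
                        x1=prof.counts.get(f, 0),
                        n1=prof.total_matched,
                        x2=ref.counts.get(f, 0),
                        n2=ref.total_matched,
                    )
                    for f in fams
                ]
                for c, r in zip(counts, enrichment_table(counts)):
                    fh.write(
                        f"{sid}\t{r.family}\t{c.x1}\t{c.n1}\t{c.x2}\t{c.n2}\t"
                        f"{r.p_value:.3g}\t{r.diff:.5f}\t{r.ci_low:.5f}\t{r.ci_high:.5f}\t"
                        f"{r.q_bh:.3g}\t{r.q_storey:.3g}\t{int(r.significant)}\n"
                    )
        written["enrichment"] = enrich_path

        stage = "coverage"
        cov_path = out / "coverage.tsv"
        with open(cov_path, "w") as fh:
            fh.write("sample\ttotal_mb\tn_16s_reads\trrna_ratio\tratio_1_over\tn_otus\tcoverage\n")
            for s in config.samples:
                reads = reads_by_sample[s.sample_id]
                total_mb = sum(len(r) for r in reads.values()) / 1e6
                if s.rrna_hits is None or not Path(s.rrna_hits).exists():
                    continue
                rhits = parse_tabular_hits(s.rrna_hits, query_fasta=s.reads)
                ratio, over = rrna_ratio(rhits, total_reads=len(reads))
                rrna_read_ids = sorted({h.query_id for h in rhits})
                rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 7])
                if len(rrna_read_ids) > th.otu_max_reads:
                    pick = rng.choice(len(rrna_read_ids), th.otu_max_reads, replace=False)
                    rrna_read_ids = [rrna_read_ids[i] for i in sorted(pick)]
                otu_reads = {rid: reads[rid] for rid in rrna_read_ids if rid in reads}
                if otu_reads:
                    n_otus = greedy_cluster(
                        otu_reads, threshold=th.cluster_identity, family="16S"
                    ).n_clusters
                    cov = coverage_estimate(
                        total_mb, n_otus, genome_size_mb=th.genome_size_mb,
                        sample_id=s.sample_id,
                    ).coverage
                    fh.write(
                        f"{s.sample_id}\t{total_mb:.2f}\t{len(rrna_read_ids)}\t"
                        f"{ratio:.6f}\t{over if over else 'n.d.'}\t{n_otus}\t{cov:.2f}\n"
                    )
        written["coverage"] = cov_path

        stage = "richness"
        rich_path = out / "richness.tsv"
        rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 11])
        with open(rich_path, "w") as fh:
            fh.write("sample\tfamily\tn_reads\tn_clusters\trichness\n")
            for s in config.samples:
                assignments = assignments_by_sample[s.sample_id]
                per_family: dict[str, dict[str, str]] = {}
                reads = reads_by_sample[s.sample_id]
                for a in assignments:
                    if a.family not in DEFAULT_RICHNESS_FAMILIES:
                        continue
                    seq = reads.get(a.query_id)
                    if seq is None:
                        continue
                    if a.hit.reverse:
                        seq = seq.translate(_COMP)[::-1]
                    per_family.setdefault(a.family, {})[a.query_id] = seq
                for fam in sorted(per_family):
                    fam_reads = per_family[fam]
                    if len(fam_reads) > th.richness_max_reads:
                        ids = sorted(fam_reads)
                        pick = rng.choice(len(ids), th.richness_max_reads, replace=False)
                        fam_reads = {ids[i]: fam_reads[ids[i]] for i in sorted(pick)}
                    cs = greedy_cluster(fam_reads, threshold=th.cluster_identity, family=fam)
                    rv = richness(cs)
                    fh.write(
                        f"{s.sample_id}\t{fam}\t{rv.n_reads}\t{rv.n_clusters}\t"
                        f"{rv.richness:.3f}\n"
                    )
        written["richness"] = rich_path

        if config.taxonomy and config.subject_taxon:
            stage = "lca"
            tree = TaxonomyTree.from_tsv(config.taxonomy)
            taxon_map = _read_two_col(config.subject_taxon)
            lca_path = out / "taxon_counts.tsv"
            with open(lca_path, "w") as fh:
                fh.write("sample\tnode\tn_reads\n")
                for s in config.samples:
                    by_read: dict[str, list[AlignmentHit]] = {}
                    for h in hits_by_sample[s.sample_id]:
                        by_read.setdefault(h.query_id, []).append(h)
                    assigns = assign_reads(
                        by_read, taxon_map, tree, th.lca,
                        read_seqs=reads_by_sample[s.sample_id],
                    )
                    assigns = apply_min_support(assigns, tree, th.lca.min_support)
                    counts: dict[str, int] = {}
                    for a in assigns:
                        key = a.node_id if a.node_id else "unassigned"
                        counts[key] = counts.get(key, 0) + 1
                    for node in sorted(counts):
                        fh.write(f"{s.sample_id}\t{node}\t{counts[node]}\n")
            written["taxon_counts"] = lca_path

        if config.contigs and config.contig_annotations:
            stage = "hul"
            contigs = [
                ContigRecord(contig_id=k, sequence=v)
                for k, v in _read_fasta(config.contigs).items()
            ]
            annotations = []
            for line in Path(config.contig_annotations).read_text().splitlines():
                if not line or line.startswith("#") or line.startswith("contig_id\t"):
                    continue
                cid, start, end, strand, label = line.split("\t")[:5]
                annotations.append(
                    GeneAnnotation(cid, int(start), int(end), strand, label)
                )
            selected = select_gh_contigs(contigs, annotations)
            hotspots = select_hotspots(selected, annotations)
            refs = (
                _read_fasta(config.reference_genomes)
                if config.reference_genomes
                else {}
            )
            seq_of = {c.contig_id: c.sequence for c in contigs}
            hul_path = out / "hul.tsv"
            with open(hul_path, "w") as fh:
                fh.write(
                    "contig\tlength\tgc\tn_gh\trules\tbest_reference\tanib\tttnf_r\n"
                )
                for h in hotspots:
                    seq = seq_of[h.contig_id]
                    gc = gc_content([seq])[0]
                    if refs:
                        ref_id, ani, r = affiliate(seq, refs)
                        ani_s = "n.d." if ani is None else f"{ani:.1f}"
                        r_s = "n.d." if r is None else f"{r:.3f}"
                    else:
                        ref_id, ani_s, r_s = "n.d.", "n.d.", "n.d."
                    fh.write(
                        f"{h.contig_id}\t{len(seq)}\t{gc:.3f}\t{h.n_gh}\t"
                        f"{'+'.join(h.rules_fired)}\t{ref_id}\t{ani_s}\t{r_s}\n"
                    )
            written["hul"] = hul_path
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    log_path = out / "run_log.yaml"
    log = {
        "lignopipe_version": __version__,
        "seed": config.seed,
        "inoculum": inoc,
        "samples": [s.sample_id for s in config.samples],
        "thresholds": {
            **{
                k: v
                for k, v in dataclasses.asdict(th).items()
                if k != "lca"
            },
            "lca": dataclasses.asdict(th.lca),
        },
        "outputs": {k: str(v) for k, v in written.items()},
    }
    log_path.write_text(yaml.safe_dump(log, sort_keys=True))
    written["run_log"] = log_path
    return written
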