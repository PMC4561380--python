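"""Lowest-common-ancestor taxonomic binning of reads.

Reads carry protein-reference hits; after score/expected/top-percent/
max-matches filtering and a sequence-complexity gate, each read is placed at
the deepest taxonomy node shared by all retained hits. A min-support pass
then pushes weakly supported placements towards the root, preserving read
counts. Defaults mirror MEGAN's suggested parameters: max matches 10,
min support 5, min score 35, max expected 0.01, min complexity 0.3,
top percent 10.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .assign import AlignmentHit

__all__ = [
    "TaxonomyTree",
    "LcaParams",
    "TaxonAssignment",
    "sequence_complexity",
    "filter_hits",
    "lca",
    "apply_min_support",
    "assign_reads",
]


@dataclass(frozen=True)
class LcaParams:
    max_matches: int = 10
    min_support: int = 5
    min_score: float = 35.0
    max_expected: float = 0.01
    min_complexity: float = 0.3
    top_percent: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.top_percent <= 100:
            raise ValueError("top_percent must be in [0, 100]")
        for name in ("max_matches", "min_support", "min_score", "max_expected", "min_complexity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class TaxonAssignment:
    read_id: str
    node_id: str | None
    n_hits_used: int = 0

    @property
    def assigned(self) -> bool:
        return self.node_id is not None


class TaxonomyTree:
    """Rooted taxonomy: node -> (parent, rank, name), single root, acyclic."""

    def __init__(self, nodes: dict[str, tuple[str | None, str, str]]):
        roots = [n for n, (p, _, _) in nodes.items() if p is None or p == n]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {sorted(roots)}")
        self.root = roots[0]
        self.nodes = nodes
        for n in nodes:
            self.path_to_root(n)  # validates resolvability / acyclicity

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTree":
        """Load a 4-column TSV: node_id, parent_id, rank, name (header optional)."""
        nodes: dict[str, tuple[str | None, str, str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0] == "node_id":
                    continue
                if len(parts) != 4:
                    raise ValueError(f"taxonomy rows need 4 columns, got {len(parts)}")
                node, parent, rank, name = parts
                nodes[node] = (parent if parent and parent != node else None, rank, name)
        return cls(nodes)

    @classmethod
    def from_ncbi_dump(cls, nodes_dmp: str | Path, names_dmp: str | Path) -> "TaxonomyTree":
        """Convert NCBI-style nodes.dmp/names.dmp (pipe-delimited) to a tree."""
        names: dict[str, str] = {}
        with open(names_dmp) as fh:
            for line in fh:
                f = [x.strip() for x in line.split("|")]
                if len(f) >= 4 and f[3] == "scientific name":
                    names[f[0]] = f[1]
        nodes: dict[str, tuple[str | None, str, str]] = {}
        with open(nodes_dmp) as fh:
            for line in fh:
                f = [x.strip() for x in line.split("|")]
                node, parent, rank = f[0], f[1], f[2]
                nodes[node] = (None if parent == node else parent, rank, names.get(node, node))
        return cls(nodes)

    def parent(self, node: str) -> str | None:
        return self.nodes[node][0]

    def path_to_root(self, node: str) -> list[str]:
        """Node ids from the node up to the root, inclusive."""
        path = [node]
        seen = {node}
        while True:
            p = self.nodes[path[-1]][0]
            if p is None:
                return path
            if p not in self.nodes:
                raise ValueError(f"node {path[-1]!r} references unknown parent {p!r}")
            if p in seen:
                raise ValueError(f"cycle in taxonomy at {p!r}")
            seen.add(p)
            path.append(p)

    def depth(self, node: str) -> int:
        return len(self.path_to_root(node)) - 1


def sequence_complexity(read: str) -> float:
    """Trinucleotide Shannon entropy, normalized by its attainable maximum.

    Overlapping 3-mers are counted (windows containing ambiguous bases are
    skipped); the entropy in bits is divided by log2(min(64, n_windows)).
    0 for homopolymers, 1 for maximally mixed composition.
    """
    if len(read) < 3:
        warnings.warn("read shorter than 3 nt; complexity set to 0", stacklevel=2)
        return 0.0
    s = read.upper()
    counts: Counter[str] = Counter()
    for i in range(len(s) - 2):
        w = s[i : i + 3]
        if all(c in "ACGT" for c in w):
            counts[w] += 1
    n = sum(counts.values())
    if n == 0:
        return 0.0
    h = -sum((c / n) * math.log2(c / n) for c in counts.values())
    hmax = math.log2(min(64, n))
    if hmax == 0:
        return 0.0
    return h / hmax


def filter_hits(hits: list[AlignmentHit], params: LcaParams = LcaParams()) -> list[AlignmentHit]:
    """Score/expected floor, then top-percent band, then max-matches truncation."""
    kept = [h for h in hits if h.bitscore >= params.min_score and h.evalue <= params.max_expected]
    if not kept:
        return []
    best = max(h.bitscore for h in kept)
    floor = best * (100.0 - params.top_percent) / 100.0
    kept = [h for h in kept if h.bitscore >= floor]
    kept.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
    return kept[: params.max_matches]


def lca(node_ids, tree: TaxonomyTree) -> str | None:
    """Deepest node lying on the root-paths of every input node."""
    ids = list(node_ids)
    if not ids:
        return None
    paths = [tree.path_to_root(n)[::-1] for n in ids]  # root -> node
    deepest = tree.root
    for level in range(min(len(p) for p in paths)):
        cand = paths[0][level]
        if all(p[level] == cand for p in paths):
            deepest = cand
        else:
            break
    return deepest


def assign_reads(
    hits_by_read: dict[str, list[AlignmentHit]],
    subject_taxon_map: dict[str, str],
    tree: TaxonomyTree,
    params: LcaParams = LcaParams(),
    read_seqs: dict[str, str] | None = None,
) -> list[TaxonAssignment]:
    """LCA placement for each read (before the min-support pass).

    When ``read_seqs`` is given, reads below the complexity floor are left
    unassigned. Subjects missing from the taxon map raise.
    """
    out = []
    for rid in sorted(hits_by_read):
        if read_seqs is not None:
            seq = read_seqs.get(rid)
            if seq is None or sequence_complexity(seq) < params.min_complexity:
                out.append(TaxonAssignment(read_id=rid, node_id=None))
                continue
        kept = filter_hits(hits_by_read[rid], params)
        if not kept:
            out.append(TaxonAssignment(read_id=rid, node_id=None))
            continue
        taxa = []
        for h in kept:
            if h.subject_id not in subject_taxon_map:
                raise KeyError(f"subject {h.subject_id!r} missing from taxon map")
            taxa.append(subject_taxon_map[h.subject_id])
        node = lca(taxa, tree)
        out.append(TaxonAssignment(read_id=rid, node_id=node, n_hits_used=len(kept)))
    return out


def apply_min_support(
    assignments: list[TaxonAssignment],
    tree: TaxonomyTree,
    min_support: int = 5,
) -> list[TaxonAssignment]:
    """Push weakly supported placements towards the root until stable.

    A node whose direct read count (descendants excluded) is below
    ``min_support`` has its reads reassigned to its parent; iterated deepest
    node first. Reads still unsupported at the root become unassigned.
    """
    node_of = {a.read_id: a.node_id for a in assignments}
    hits_used = {a.read_id: a.n_hits_used for a in assignments}
    while True:
        counts: Counter[str] = Counter(n for n in node_of.values() if n is not None)
        weak = [n for n, c in counts.items() if c < min_support and n != tree.root]
        if not weak:
            break
        # deepest first so moved reads can accumulate support at the parent
        target = max(weak, key=lambda n: (tree.depth(n), n))
        parent = tree.parent(target)
        for rid, n in node_of.items():
            if n == target:
                node_of[rid] = parent
    root_count = sum(1 for n in node_of.values() if n == tree.root)
    drop_root = 0 < root_count < min_support
    out = []
    for a in assignments:
        n = node_of[a.read_id]
        if drop_root and n == tree.root:
            n = None
        out.append(TaxonAssignment(read_id=a.read_id, node_id=n, n_hits_used=hits_used[a.read_id]))
    return out
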