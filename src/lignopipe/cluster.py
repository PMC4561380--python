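"""Greedy 97%-identity clustering of reads within a CAZy family, and richness.

Richness is defined as the number of clusters at 97% nucleotide identity over
the total number of retrieved reads in a family — a cheap within-family
diversity proxy. The clustering follows the CD-HIT greedy-incremental rule:
reads are processed longest-first, and each read joins the first existing
cluster whose representative it matches at or above the identity threshold,
else it founds a new cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .align import pairwise_identity

__all__ = ["Cluster", "ClusterSet", "RichnessValue", "greedy_cluster", "richness"]


@dataclass
class Cluster:
    representative: str
    members: list[str] = field(default_factory=list)


@dataclass
class ClusterSet:
    family: str
    clusters: list[Cluster]
    threshold: float = 0.97

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_reads(self) -> int:
        return sum(len(c.members) for c in self.clusters)


@dataclass(frozen=True)
class RichnessValue:
    family: str
    n_clusters: int
    n_reads: int

    @property
    def richness(self) -> float:
        return self.n_clusters / self.n_reads


def greedy_cluster(
    reads: dict[str, str],
    threshold: float = 0.97,
    family: str = "",
    check_reverse_complement: bool = False,
) -> ClusterSet:
    """Cluster reads at a nucleotide-identity threshold.

    Identity is computed by exact global alignment, with the identical-column
    count divided by the shorter sequence length. Reads are visited by
    decreasing length (ties broken by read id), so each cluster's
    representative is its longest member.

    ``check_reverse_complement`` also tries the reverse complement of each
    incoming read against representatives (off by default: pipeline reads are
    orientation-normalized at extraction).
    """
    if not reads:
        raise ValueError("greedy_cluster requires at least one read")
    order = sorted(reads, key=lambda r: (-len(reads[r]), r))
    clusters: list[Cluster] = []
    for rid in order:
        seq = reads[rid]
        placed = False
        for cl in clusters:
            rep = reads[cl.representative]
            if _identity_reaches(seq, rep, threshold):
                cl.members.append(rid)
                placed = True
                break
            if check_reverse_complement and _identity_reaches(_revcomp(seq), rep, threshold):
                cl.members.append(rid)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=rid, members=[rid]))
    return ClusterSet(family=family, clusters=clusters, threshold=threshold)


def richness(cluster_set: ClusterSet) -> RichnessValue:
    """Clusters over reads for one family; in (0, 1] for non-empty input."""
    n_reads = cluster_set.n_reads
    if n_reads == 0:
        raise ValueError("richness is undefined for zero reads")
    return RichnessValue(
        family=cluster_set.family,
        n_clusters=cluster_set.n_clusters,
        n_reads=n_reads,
    )


def _identity_reaches(seq: str, rep: str, threshold: float) -> bool:
    """Exact check with a sound edit-distance prescreen.

    Any alignment with m matches yields an edit script of cost at most
    la + lb - 2m, so edit distance d bounds the matches of every alignment
    (the exact DP's included) by (la + lb - d) / 2. Pairs whose bound falls
    below the threshold are rejected without running the DP; candidates are
    then decided by the exact global alignment.
    """
    if seq == rep:
        return True
    la, lb = len(seq), len(rep)
    short = min(la, lb)
    k = int(la + lb - 2.0 * threshold * short)
    res = edlib.align(seq, rep, mode="NW", task="distance", k=k)
    if res["editDistance"] < 0:
        return False
    if (la + lb - res["editDistance"]) / 2.0 < threshold * short:
        return False
    return pairwise_identity(seq, rep) >= threshold


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
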