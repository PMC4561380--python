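"""(Hemi)cellulose utilization locus (HUL) detection and contig affiliation.

Contigs >= 5 kb carrying genes of the target glycosyl hydrolase families are
screened for GH "hotspots" by two rules: (1) length >= 10 kb with at least
two GH genes, or (2) length >= 35 kb with at least one. Selected loci are
affiliated to candidate reference genomes by fragment-based average
nucleotide identity (ANIb) and tetranucleotide-frequency (TTNF) correlation,
the alignment-free signal used to spot loci from as-yet-unsequenced genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np

from .align import align_pair
from .profiles import gc_content

__all__ = [
    "TARGET_GH_FAMILIES",
    "ContigRecord",
    "GeneAnnotation",
    "HULRecord",
    "select_gh_contigs",
    "select_hotspots",
    "tnf_vector",
    "ttnf_correlation",
    "anib",
    "affiliate",
    "contig_read_coverage",
]

#: GH families whose genes nominate a contig for HUL screening.
TARGET_GH_FAMILIES = frozenset({"GH2", "GH3", "GH29", "GH31", "GH43", "GH92", "GH95"})


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene on a contig; 0-based half-open bp coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str
    label: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad gene coordinates [{self.start}, {self.end})")

    @property
    def is_gh(self) -> bool:
        return self.label.startswith("GH")


@dataclass
class ContigRecord:
    contig_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_content([self.sequence])[0]


@dataclass
class HULRecord:
    contig_id: str
    gh_genes: list[GeneAnnotation]
    rules_fired: list[str] = field(default_factory=list)
    affiliation: tuple[str, float | None, float | None] | None = None

    @property
    def n_gh(self) -> int:
        return len(self.gh_genes)


def _genes_by_contig(annotations: list[GeneAnnotation]) -> dict[str, list[GeneAnnotation]]:
    out: dict[str, list[GeneAnnotation]] = {}
    for g in annotations:
        out.setdefault(g.contig_id, []).append(g)
    return out


def select_gh_contigs(
    contigs: list[ContigRecord],
    annotations: list[GeneAnnotation],
    min_len: int = 5000,
    families: frozenset[str] = TARGET_GH_FAMILIES,
) -> list[ContigRecord]:
    """Contigs >= min_len carrying at least one gene of the target families."""
    known = {c.contig_id for c in contigs}
    for g in annotations:
        if g.contig_id not in known:
            raise ValueError(f"annotation references unknown contig {g.contig_id!r}")
    genes = _genes_by_contig(annotations)
    return [
        c
        for c in contigs
        if c.length >= min_len
        and any(g.label in families for g in genes.get(c.contig_id, []))
    ]


def select_hotspots(
    selected_contigs: list[ContigRecord],
    annotations: list[GeneAnnotation],
) -> list[HULRecord]:
    """Apply the two hotspot rules; each record notes which rule(s) fired."""
    genes = _genes_by_contig(annotations)
    out = []
    for c in selected_contigs:
        gh = [g for g in genes.get(c.contig_id, []) if g.is_gh]
        rules = []
        if c.length >= 10_000 and len(gh) >= 2:
            rules.append("hotspot-10kb-2GH")
        if c.length >= 35_000 and len(gh) >= 1:
            rules.append("hotspot-35kb-1GH")
        if rules:
            out.append(HULRecord(contig_id=c.contig_id, gh_genes=gh, rules_fired=rules))
    return out


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


_TNF_CODE = np.full(256, -1, dtype=np.int64)
for _i, _c in enumerate(b"ACGT"):
    _TNF_CODE[_c] = _i
    _TNF_CODE[_c + 32] = _i


def _tnf_counts(seq: str) -> np.ndarray:
    codes = _TNF_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    c0, c1, c2, c3 = codes[:-3], codes[1:-2], codes[2:-1], codes[3:]
    valid = (c0 >= 0) & (c1 >= 0) & (c2 >= 0) & (c3 >= 0)
    idx = ((c0 * 64 + c1 * 16 + c2 * 4 + c3))[valid]
    return np.bincount(idx, minlength=256)


def tnf_vector(sequence: str) -> np.ndarray:
    """Strand-symmetric tetranucleotide frequency vector (256 components).

    Overlapping 4-mers are counted on the sequence and its reverse
    complement; windows containing ambiguous bases are skipped; the vector is
    normalized to sum to 1.
    """
    if len(sequence) < 4:
        raise ValueError("sequence must be at least 4 nt for TTNF")
    counts = _tnf_counts(sequence) + _tnf_counts(_revcomp(sequence))
    total = counts.sum()
    if total == 0:
        raise ValueError("no unambiguous 4-mer window in sequence")
    return counts / total


def ttnf_correlation(vec_a: np.ndarray, vec_b: np.ndarray) -> float | None:
    """Pearson correlation of two TTNF vectors; None if either is constant."""
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("TTNF vectors must have equal length")
    if a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def anib(
    query_contig: str,
    reference_genome: str,
    frag_len: int = 1020,
    min_id: float = 30.0,
    min_cov: float = 0.70,
) -> tuple[float | None, float]:
    """Fragment-based average nucleotide identity of a contig to a reference.

    The contig is cut into consecutive ``frag_len`` pieces (a trailing piece
    is kept if at least half-length). Each piece is placed on the reference
    at its best-matching locus and then re-scored there by exact local
    alignment; pieces aligning at >= ``min_id`` % identity over >=
    ``min_cov`` of their length are hits. Returns (mean hit identity in
    percent, hit fraction); identity is None when nothing qualifies.
    """
    if len(query_contig) < frag_len // 2:
        raise ValueError("contig shorter than half a fragment")
    frags = []
    for i in range(0, len(query_contig), frag_len):
        piece = query_contig[i : i + frag_len]
        if len(piece) >= frag_len // 2:
            frags.append(piece)
    identities = []
    hits = 0
    for piece in frags:
        ident, cov = _fragment_identity(piece, reference_genome)
        if ident is not None and ident >= min_id and cov >= min_cov:
            hits += 1
            identities.append(ident)
    if hits == 0:
        return None, 0.0
    return float(np.mean(identities)), hits / len(frags)


def _fragment_identity(piece: str, reference: str) -> tuple[float | None, float]:
    """Locate a fragment on the reference, then score it by exact local DP.

    Location search (both strands) uses bit-vector infix edit distance; the
    exact aligner then runs only on the located window, which keeps full-DP
    cost independent of reference length.
    """
    best = None
    for seq in (piece, _revcomp(piece)):
        res = edlib.align(seq.upper(), reference.upper(), mode="HW", task="locations")
        if res["editDistance"] >= 0 and (best is None or res["editDistance"] < best[0]):
            best = (res["editDistance"], res["locations"][0], seq)
    if best is None:
        return None, 0.0
    if best[0] == 0:  # verbatim match: the DP can only confirm it
        return 100.0, 1.0
    _, (lo, hi), oriented = best
    margin = len(piece) // 2
    window = reference[max(0, lo - margin) : hi + 1 + margin]
    if not window:
        return None, 0.0
    aln = align_pair(oriented, window, mode="local")
    if aln.aln_length == 0:
        return None, 0.0
    coverage = (aln.a_end - aln.a_start) / len(piece)
    return 100.0 * aln.identity, coverage


def affiliate(
    contig: str,
    reference_set: dict[str, str],
    frag_len: int = 1020,
) -> tuple[str, float | None, float | None]:
    """Best reference for a contig by ANIb, with TTNF correlation reported.

    Ties on ANIb fall to the higher TTNF correlation, then the smaller
    reference id. When no reference yields any ANIb hit, affiliation falls
    back to TTNF correlation alone (flagged by the None ANIb value).
    """
    if not reference_set:
        raise ValueError("reference_set must contain at least one genome")
    contig_tnf = tnf_vector(contig)
    scored = []
    for ref_id in sorted(reference_set):
        ani, _frac = anib(contig, reference_set[ref_id], frag_len=frag_len)
        r = ttnf_correlation(contig_tnf, tnf_vector(reference_set[ref_id]))
        scored.append((ref_id, ani, r))
    with_ani = [s for s in scored if s[1] is not None]
    if with_ani:
        return min(
            with_ani,
            key=lambda s: (-s[1], -(s[2] if s[2] is not None else -2.0), s[0]),
        )
    warnings.warn("no ANIb hit on any reference; affiliating by TTNF alone", stacklevel=2)
    return min(scored, key=lambda s: (-(s[2] if s[2] is not None else -2.0), s[0]))


def contig_read_coverage(contig_length: int, read_placements: list[tuple[int, int]]) -> float:
    """Mean read depth: summed covered bases over contig length.

    ``read_placements`` are (start, end) half-open read spans on the contig;
    spans are clipped to the contig.
    """
    if contig_length <= 0:
        raise ValueError("contig length must be positive")
    total = 0
    for start, end in read_placements:
        total += max(0, min(end, contig_length) - max(start, 0))
    return total / contig_length
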