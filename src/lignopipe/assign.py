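"""Read-level CAZy annotation from tabular alignments.

Consumes the 12/13-column blast-tab dialect (qseqid sseqid pident length
mismatch gapopen qstart qend sstart send evalue bitscore [qlen]), applies the
coverage-times-identity ratio filter, and assigns each read its best CAZy
family. Also implements the general protein-annotation filter and the 16S
rRNA read-ratio computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "AlignmentHit",
    "FamilyAssignment",
    "parse_tabular_hits",
    "ratio_filter",
    "hit_ratio",
    "assign_best_family",
    "general_functional_filter",
    "rrna_ratio",
    "family_class",
]

#: CAZy class prefixes, longest first so GH beats G etc.
_CLASSES = ("CBM", "GH", "GT", "CE", "PL", "AA")


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a tabular alignment.

    ``aln_length`` is in the units of the search (amino acids for translated
    searches, nucleotides otherwise); ``query_length_nt`` is always
    nucleotides of the read.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: float
    query_length_nt: int
    sstart: int = 0
    send: int = 0

    @property
    def reverse(self) -> bool:
        """Minus-orientation hit (blast convention: sstart > send)."""
        return self.sstart > self.send > 0

    def __post_init__(self) -> None:
        if self.aln_length < 1:
            raise ValueError(f"aln_length must be >= 1, got {self.aln_length}")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of [0, 100]: {self.pct_identity}")


@dataclass(frozen=True)
class FamilyAssignment:
    query_id: str
    family: str
    hit: AlignmentHit

    @property
    def cazy_class(self) -> str:
        return family_class(self.family)


def family_class(family: str) -> str:
    """CAZy class (AA/CBM/CE/GH/GT/PL) of a family tag, by prefix."""
    for cls in _CLASSES:
        if family.startswith(cls):
            return cls
    raise ValueError(f"{family!r} does not carry a CAZy class prefix")


def parse_tabular_hits(
    path: str | Path,
    query_fasta: str | Path | None = None,
) -> list[AlignmentHit]:
    """Parse a blast-tab file into hits.

    Rows may carry a 13th column with the query length in nucleotides; rows
    without it require ``query_fasta`` so the length can be looked up.
    Malformed rows raise with their line number.
    """
    qlens: dict[str, int] | None = None
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (12, 13):
                raise ValueError(
                    f"{path}:{lineno}: expected 12 or 13 columns, got {len(parts)}"
                )
            try:
                qid, sid = parts[0], parts[1]
                pident = float(parts[2])
                alen = int(parts[3])
                sstart = int(parts[8])
                send = int(parts[9])
                evalue = float(parts[10])
                bits = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed field ({exc})") from None
            if len(parts) == 13:
                qlen = int(parts[12])
            else:
                if qlens is None:
                    if query_fasta is None:
                        raise ValueError(
                            f"{path}:{lineno}: 12-column row for query {qid!r} "
                            "but no query FASTA given to supply its length"
                        )
                    qlens = {
                        rec.id: len(rec.seq) for rec in SeqIO.parse(str(query_fasta), "fasta")
                    }
                if qid not in qlens:
                    raise ValueError(
                        f"{path}:{lineno}: query {qid!r} absent from {query_fasta}"
                    )
                qlen = qlens[qid]
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=sid,
                    pct_identity=pident,
                    aln_length=alen,
                    evalue=evalue,
                    bitscore=bits,
                    query_length_nt=qlen,
                    sstart=sstart,
                    send=send,
                )
            )
    return hits


def hit_ratio(hit: AlignmentHit, translated: bool = True) -> float:
    """Coverage-times-identity statistic: aln_length x %identity / query length.

    For translated searches the nucleotide query length is converted to amino
    acids (floor(qlen/3)) so that a full-length perfect hit scores ~100.
    Returns inf-safe 0.0 when the converted query length is zero.
    """
    units = hit.query_length_nt // 3 if translated else hit.query_length_nt
    if units == 0:
        warnings.warn(
            f"query {hit.query_id!r}: query length {hit.query_length_nt} nt "
            "yields zero denominator units; hit fails the ratio filter",
            stacklevel=2,
        )
        return 0.0
    return hit.aln_length * hit.pct_identity / units


def ratio_filter(
    hit: AlignmentHit,
    threshold: float = 30.0,
    evalue_max: float = 1e-15,
    translated: bool = True,
) -> bool:
    """Retention rule for CAZy hits: e-value <= cutoff and ratio strictly > 30."""
    if hit.evalue > evalue_max:
        return False
    return hit_ratio(hit, translated=translated) > threshold


def assign_best_family(
    hits_for_read: list[AlignmentHit],
    subject_family_map: dict[str, str],
) -> FamilyAssignment | None:
    """Best-hit family for one read.

    The winner has the highest bitscore; ties fall to the lower e-value, then
    the lexicographically smallest subject id. All hits must share a query.
    """
    if not hits_for_read:
        return None
    qids = {h.query_id for h in hits_for_read}
    if len(qids) != 1:
        raise ValueError(f"hits span multiple queries: {sorted(qids)}")
    best = min(hits_for_read, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
    if best.subject_id not in subject_family_map:
        raise KeyError(f"subject {best.subject_id!r} missing from family map")
    return FamilyAssignment(
        query_id=best.query_id,
        family=subject_family_map[best.subject_id],
        hit=best,
    )


def general_functional_filter(
    hit: AlignmentHit,
    evalue_max: float = 1e-15,
    min_aln_aa: int = 50,
    min_identity: float = 50.0,
) -> bool:
    """General protein-annotation filter: e-value, >=50 aa alignment, >=50% id."""
    return (
        hit.evalue <= evalue_max
        and hit.aln_length >= min_aln_aa
        and hit.pct_identity >= min_identity
    )


def rrna_ratio(
    rrna_hits: list[AlignmentHit],
    total_reads: int,
    evalue_max: float = 1e-15,
    min_aln_nt: int = 200,
    min_identity: float = 90.0,
) -> tuple[float, int | None]:
    """16S read ratio: passing reads over total, plus the "1/N" denominator.

    A read passes with at least one nucleotide hit of >=200 bp alignment,
    >=90% identity and e-value <= 1e-15. Returns (ratio, N) with
    N = round(total/count), or (0.0, None) when nothing passes.
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    passing = {
        h.query_id
        for h in rrna_hits
        if h.evalue <= evalue_max
        and h.aln_length >= min_aln_nt
        and h.pct_identity >= min_identity
    }
    count = len(passing)
    if count == 0:
        return 0.0, None
    return count / total_reads, round(total_reads / count)


def assignments_from_table(
    hits: list[AlignmentHit],
    subject_family_map: dict[str, str],
    threshold: float = 30.0,
    evalue_max: float = 1e-15,
    translated: bool = True,
) -> list[FamilyAssignment]:
    """Filter hits by the ratio rule, group by read, pick each read's best family."""
    by_read: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        if ratio_filter(h, threshold=threshold, evalue_max=evalue_max, translated=translated):
            by_read.setdefault(h.query_id, []).append(h)
    out = []
    for qid in sorted(by_read):
        a = assign_best_family(by_read[qid], subject_family_map)
        if a is not None:
            out.append(a)
    return out
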