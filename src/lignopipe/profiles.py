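"""Per-sample CAZy family/class profiles and derived summaries.

Relative abundance (RA) of a family is its read count as a percentage of the
sample's total database-matched reads. Enrichment against the inoculum is the
RA ratio, log10-transformed; zero RAs propagate as an undefined flag ("n.d."),
never a pseudocount. Also here: the 16S-OTU-based metagenome coverage
estimate, profile r^2, sample G+C, and the top-k enrichment ranking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .assign import FamilyAssignment, family_class

__all__ = [
    "FamilyProfile",
    "FoldChange",
    "CoverageEstimate",
    "relative_abundance",
    "log_fold",
    "fold_table",
    "coverage_estimate",
    "profile_r2",
    "gc_content",
    "top_enriched",
]


@dataclass
class FamilyProfile:
    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)
    total_matched: int = 0

    @property
    def ra(self) -> dict[str, float]:
        """Relative abundance per family, in percent of matched reads."""
        if self.total_matched == 0:
            return {}
        return {f: 100.0 * c / self.total_matched for f, c in self.counts.items()}

    @property
    def class_ra(self) -> dict[str, float]:
        """RA rolled up to CAZy class (AA/CBM/CE/GH/GT/PL) by family prefix."""
        if self.total_matched == 0:
            return {}
        cls_counts: dict[str, int] = {}
        for f, c in self.counts.items():
            cls_counts[family_class(f)] = cls_counts.get(family_class(f), 0) + c
        return {k: 100.0 * v / self.total_matched for k, v in cls_counts.items()}


@dataclass(frozen=True)
class FoldChange:
    """log10 fold of one family's RA against the reference sample.

    ``log10_fold`` is None ("n.d.") when either RA is zero.
    """

    family: str
    ra_sample: float
    ra_reference: float
    log10_fold: float | None

    @property
    def defined(self) -> bool:
        return self.log10_fold is not None


@dataclass(frozen=True)
class CoverageEstimate:
    sample_id: str
    total_mb: float
    n_otus: int
    genome_size_mb: float
    coverage: float

    @property
    def rounded(self) -> float:
        return round(self.coverage, 2)


def relative_abundance(
    assignments: Iterable[FamilyAssignment],
    sample_id: str = "",
    total_matched: int | None = None,
) -> FamilyProfile:
    """Family profile from one sample's best-hit assignments.

    The RA denominator defaults to the number of assigned (database-matched)
    reads; pass ``total_matched`` to normalize against a different total
    (e.g. all quality reads).
    """
    counts: dict[str, int] = {}
    n = 0
    for a in assignments:
        counts[a.family] = counts.get(a.family, 0) + 1
        n += 1
    if total_matched is None:
        total_matched = n
    if total_matched == 0:
        warnings.warn(f"sample {sample_id!r}: no matched reads; empty profile", stacklevel=2)
    return FamilyProfile(sample_id=sample_id, counts=counts, total_matched=total_matched)


def log_fold(ra_sample: float, ra_reference: float, family: str = "") -> FoldChange:
    """log10(RA_sample / RA_reference); undefined when either side is zero."""
    if ra_sample < 0 or ra_reference < 0:
        raise ValueError("relative abundances must be non-negative")
    if ra_sample == 0 or ra_reference == 0:
        lf = None
    else:
        lf = math.log10(ra_sample / ra_reference)
    return FoldChange(family=family, ra_sample=ra_sample, ra_reference=ra_reference, log10_fold=lf)


def fold_table(profile: FamilyProfile, reference: FamilyProfile) -> list[FoldChange]:
    """Fold changes for the union of families in a sample and the reference."""
    ra_s = profile.ra
    ra_r = reference.ra
    return [
        log_fold(ra_s.get(f, 0.0), ra_r.get(f, 0.0), family=f)
        for f in sorted(set(ra_s) | set(ra_r))
    ]


def coverage_estimate(
    total_mb: float,
    n_otus: int,
    genome_size_mb: float = 4.0,
    sample_id: str = "",
) -> CoverageEstimate:
    """Metagenome coverage from sequenced megabases and 16S OTU richness.

    coverage = total_mb / (n_otus * genome_size_mb), with a reference genome
    size of 4 Mb per bacterium.
    """
    if n_otus < 1:
        raise ValueError("n_otus must be >= 1")
    if total_mb <= 0:
        raise ValueError("total_mb must be positive")
    cov = total_mb / (n_otus * genome_size_mb)
    return CoverageEstimate(
        sample_id=sample_id,
        total_mb=total_mb,
        n_otus=n_otus,
        genome_size_mb=genome_size_mb,
        coverage=cov,
    )


def profile_r2(
    profile_a: FamilyProfile,
    profile_b: FamilyProfile,
) -> tuple[float | None, int]:
    """Squared Pearson correlation of two RA vectors over the family union.

    Returns (r2, sign of r); (None, 0) when either vector has zero variance.
    """
    fams = sorted(set(profile_a.ra) | set(profile_b.ra))
    va = np.array([profile_a.ra.get(f, 0.0) for f in fams])
    vb = np.array([profile_b.ra.get(f, 0.0) for f in fams])
    if len(fams) < 2 or va.std() == 0 or vb.std() == 0:
        return None, 0
    r = float(np.corrcoef(va, vb)[0, 1])
    return r * r, int(np.sign(r))


def gc_content(sequences: Iterable[str]) -> tuple[float, float, float]:
    """Pooled G+C fraction over sequences, plus per-sequence mean and SD.

    Ambiguous bases are excluded from both numerator and denominator.
    Raises when no unambiguous base is present.
    """
    per_seq = []
    gc_tot = 0
    acgt_tot = 0
    for seq in sequences:
        s = seq.upper()
        gc = s.count("G") + s.count("C")
        acgt = gc + s.count("A") + s.count("T")
        if acgt:
            per_seq.append(gc / acgt)
        gc_tot += gc
        acgt_tot += acgt
    if acgt_tot == 0:
        raise ValueError("G+C undefined: no unambiguous bases in input")
    arr = np.array(per_seq)
    return gc_tot / acgt_tot, float(arr.mean()), float(arr.std())


def top_enriched(
    fold_changes: dict[str, Sequence[FoldChange]] | Sequence[FoldChange],
    k: int = 60,
) -> list[str]:
    """Top-k families by maximum log10 fold across samples, descending.

    Input is either one sample's fold list or a mapping sample -> fold list.
    Undefined folds rank last; ties break alphabetically by family.
    """
    if isinstance(fold_changes, dict):
        all_fc = [fc for fcs in fold_changes.values() for fc in fcs]
    else:
        all_fc = list(fold_changes)
    best: dict[str, float | None] = {}
    for fc in all_fc:
        cur = best.get(fc.family, None)
        if fc.log10_fold is not None and (cur is None or fc.log10_fold > cur):
            best[fc.family] = fc.log10_fold
        elif fc.family not in best:
            best[fc.family] = None
    ranked = sorted(
        best,
        key=lambda f: (0 if best[f] is not None else 1, -(best[f] or 0.0), f),
    )
    return ranked[:k]
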