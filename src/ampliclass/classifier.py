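"""k-mer containment classifier with bootstrap confidence.

The classifier compares a query amplicon Q against every reference R through
the containment similarity

    S(Q, R) = |Q_K ∩ R_K| / |Q_K|

where Q_K and R_K are the sets of distinct overlapping k-mers of the two
sequences. Scores live in [0, 1] and are asymmetric (normalised by the
query), which suits short amplicons queried against full-length genes: a
reference that fully contains the query's k-mer content scores 1 regardless
of how much longer it is.

Shared-k-mer counts are accumulated through an inverted index (k-mer →
posting list of reference ids), so a query touches only references that
share at least one k-mer with it. Both the forward sequence and its reverse
complement are searched and the better strand wins; strand comparison uses
exact integer cross-multiplication, never floating point, so ties are
detected exactly.

A taxonomic label is emitted at a level (genus, species, optional
*Clostridium* cluster) only when every top-scoring reference agrees at that
level; disagreement yields AMBIGUOUS rather than a forced call. Confidence
for assigned levels comes from a bootstrap: each trial draws, without
replacement, floor(|Q_K| / k) of the query's k-mers (at least 1), re-runs
the search on that subset, and counts a match when the trial's top set
unanimously carries the full-query label. Confidence is the fraction of
matching trials.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

from .errors import UndefinedScoreError
from .io_formats import (
    CLUSTER,
    GENUS,
    SPECIES,
    SequenceRecord,
    TaxonomyAnnotation,
    reverse_complement,
)

if TYPE_CHECKING:
    from .database import ReferenceDatabase

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")

DEFAULT_K = 8
DEFAULT_BOOTSTRAPS = 10


@dataclass(frozen=True)
class KmerSet:
    """Distinct overlapping k-mers of one sequence (only A/C/G/T windows)."""

    k: int
    kmers: frozenset[str]
    source_length: int

    def __len__(self) -> int:
        return len(self.kmers)


def extract_kmers(sequence: str, k: int) -> KmerSet:
    """Set of all overlapping length-k windows consisting solely of A/C/G/T.

    Windows containing any other character (IUPAC ambiguity codes, N) are
    skipped; duplicates collapse. A sequence shorter than k yields an empty
    set.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    kmers: set[str] = set()
    run = 0  # length of the current all-ACGT run
    for i, char in enumerate(sequence):
        run = run + 1 if char in _ACGT else 0
        if run >= k:
            kmers.add(sequence[i - k + 1 : i + 1])
    return KmerSet(k=k, kmers=frozenset(kmers), source_length=len(sequence))


def similarity_score(query_kmers: KmerSet, ref_kmers: KmerSet) -> float:
    """Containment score |Q_K ∩ R_K| / |Q_K| in [0, 1]."""
    if query_kmers.k != ref_kmers.k:
        raise ValueError(f"k mismatch: {query_kmers.k} vs {ref_kmers.k}")
    if not query_kmers.kmers:
        raise UndefinedScoreError("query has no valid k-mers; score undefined")
    return len(query_kmers.kmers & ref_kmers.kmers) / len(query_kmers.kmers)


class InvertedIndex:
    """Map from k-mer to the sorted list of reference ids containing it."""

    def __init__(self, k: int) -> None:
        self.k = k
        self.postings: dict[str, list[str]] = {}

    @classmethod
    def build(cls, records: Iterable[SequenceRecord], k: int) -> "InvertedIndex":
        index = cls(k)
        for rec in records:
            index.add(rec.id, rec.sequence)
        for ids in index.postings.values():
            ids.sort()
        return index

    def add(self, rec_id: str, sequence: str) -> None:
        for kmer in extract_kmers(sequence, self.k).kmers:
            self.postings.setdefault(kmer, []).append(rec_id)

    def shared_counts(self, kmers: Iterable[str]) -> dict[str, int]:
        """Per-reference count of k-mers shared with the given set.

        Equals |Q_K ∩ R_K| for every reference sharing at least one k-mer;
        references absent from the result share none.
        """
        counts: dict[str, int] = {}
        postings = self.postings
        for kmer in kmers:
            for rec_id in postings.get(kmer, ()):
                counts[rec_id] = counts.get(rec_id, 0) + 1
        return counts


class Strand(enum.Enum):
    FORWARD = "FORWARD"
    REVERSE = "REVERSE"
    BOTH = "BOTH"


class AssignmentStatus(enum.Enum):
    ASSIGNED = "ASSIGNED"
    AMBIGUOUS = "AMBIGUOUS"
    UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class LevelAssignment:
    """Outcome at one taxonomic level.

    ``confidence`` is defined only for ASSIGNED levels (None until the
    bootstrap fills it in, or when the level is not assigned).
    """

    level_name: str
    label: str
    status: AssignmentStatus
    confidence: float | None = None

    def with_confidence(self, confidence: float) -> "LevelAssignment":
        return LevelAssignment(self.level_name, self.label, self.status, confidence)


@dataclass
class ClassificationResult:
    query_id: str
    best_score: float
    strand: Strand | None
    hit_ids: frozenset[str]
    assignments: list[LevelAssignment]
    ambiguous_labels: dict[str, list[str]] = field(default_factory=dict)

    def assignment(self, level_name: str) -> LevelAssignment | None:
        for a in self.assignments:
            if a.level_name == level_name:
                return a
        return None

    @property
    def species(self) -> LevelAssignment | None:
        return self.assignment(SPECIES)


class _NoValidKmers(Exception):
    """Internal signal: no scorable k-mers on either strand."""


def _strand_best(index: InvertedIndex, kmers: KmerSet) -> tuple[int, frozenset[str]]:
    counts = index.shared_counts(kmers.kmers)
    if not counts:
        return 0, frozenset()
    best = max(counts.values())
    return best, frozenset(r for r, c in counts.items() if c == best)


def top_hits(
    query: SequenceRecord, db: "ReferenceDatabase"
) -> tuple[float, frozenset[str], Strand]:
    """Best containment score over both strands and all references.

    Returns the global maximum score, the set of ALL references attaining
    it, and the achieving strand (BOTH on an exact tie, with the hit sets
    unioned). Raises the internal no-k-mer signal through
    :exc:`UndefinedScoreError` when neither strand yields a valid k-mer.
    """
    k = db.k
    fwd = extract_kmers(query.sequence, k)
    rev = extract_kmers(reverse_complement(query.sequence), k)
    if not fwd.kmers and not rev.kmers:
        raise UndefinedScoreError(
            f"query {query.id!r} has no valid k-mers on either strand"
        )

    cf, hits_f = _strand_best(db.index, fwd) if fwd.kmers else (0, frozenset())
    cr, hits_r = _strand_best(db.index, rev) if rev.kmers else (0, frozenset())
    nf, nr = len(fwd), len(rev)

    # exact rational comparison: cf/nf vs cr/nr
    lhs = cf * nr if nf else -1
    rhs = cr * nf if nr else -1
    if lhs > rhs:
        return (cf / nf, hits_f, Strand.FORWARD)
    if rhs > lhs:
        return (cr / nr, hits_r, Strand.REVERSE)
    score = cf / nf if nf else cr / nr
    return (score, hits_f | hits_r, Strand.BOTH)


def assign_levels(
    hit_ids: Iterable[str],
    taxonomy: Mapping[str, TaxonomyAnnotation],
    level_names: Sequence[str] = (GENUS, SPECIES, CLUSTER),
) -> list[LevelAssignment]:
    """Per-level agreement rule over the top-hit set.

    A level is ASSIGNED when every hit carries the same non-empty label,
    AMBIGUOUS when at least two distinct labels occur, and UNASSIGNED when
    no hit (or only some hits) carry a label there — levels are independent,
    so species may be AMBIGUOUS while genus and cluster are ASSIGNED.
    """
    hits = list(hit_ids)
    if not hits:
        raise ValueError("assign_levels requires a non-empty hit set")
    out: list[LevelAssignment] = []
    for level in level_names:
        labels = [taxonomy[h].label(level) for h in hits]
        present = {lab for lab in labels if lab}
        if len(present) == 1 and all(labels):
            out.append(LevelAssignment(level, next(iter(present)), AssignmentStatus.ASSIGNED))
        elif len(present) >= 2:
            out.append(LevelAssignment(level, "", AssignmentStatus.AMBIGUOUS))
        else:
            out.append(LevelAssignment(level, "", AssignmentStatus.UNASSIGNED))
    return out


def bootstrap_subset_size(n_kmers: int, k: int) -> int:
    """|q_k| = floor(|Q_K| / k), floored at 1."""
    return max(1, n_kmers // k)


def bootstrap_confidence(
    query_kmers: KmerSet,
    db: "ReferenceDatabase",
    full_assignments: Sequence[LevelAssignment],
    n_boot: int = DEFAULT_BOOTSTRAPS,
    seed: int = 0,
) -> dict[str, float]:
    """Bootstrap confidence for each ASSIGNED level.

    Each trial samples, without replacement, ``floor(|Q_K|/k)`` (>= 1) of
    the query's k-mers, retrieves the top-scoring reference set for the
    subset, and counts a match at a level when that set unanimously carries
    the full-query label there. Confidence = matching trials / n_boot.

    The k-mer pool is sorted before sampling, so a given (query, seed) pair
    yields identical confidences regardless of reference input order.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    assigned = {
        a.level_name: a.label
        for a in full_assignments
        if a.status is AssignmentStatus.ASSIGNED
    }
    if not assigned:
        return {}
    pool = sorted(query_kmers.kmers)
    size = bootstrap_subset_size(len(pool), query_kmers.k)
    rng = np.random.default_rng(seed)
    matches = dict.fromkeys(assigned, 0)
    level_names = db.level_names
    all_ids = frozenset(db.records)
    for _ in range(n_boot):
        subset = rng.choice(pool, size=size, replace=False)
        counts = db.index.shared_counts(subset)
        if counts:
            best = max(counts.values())
            top: frozenset[str] = frozenset(r for r, c in counts.items() if c == best)
        else:
            # no reference shares a k-mer: every reference ties at zero
            top = all_ids
        trial = assign_levels(top, db.taxonomy, level_names)
        for a in trial:
            if (
                a.status is AssignmentStatus.ASSIGNED
                and a.level_name in assigned
                and a.label == assigned[a.level_name]
            ):
                matches[a.level_name] += 1
    return {level: matches[level] / n_boot for level in assigned}


def _unassigned_result(query: SequenceRecord, level_names: Sequence[str]) -> ClassificationResult:
    return ClassificationResult(
        query_id=query.id,
        best_score=0.0,
        strand=None,
        hit_ids=frozenset(),
        assignments=[
            LevelAssignment(level, "", AssignmentStatus.UNASSIGNED) for level in level_names
        ],
    )


def classify(
    query: SequenceRecord,
    db: "ReferenceDatabase",
    n_boot: int = DEFAULT_BOOTSTRAPS,
    seed: int = 0,
) -> ClassificationResult:
    """Full pipeline for one query: search, per-level agreement, bootstrap.

    Queries with no valid k-mers on either strand (too short, or all-
    ambiguity-code) come back all-UNASSIGNED with best_score 0. The
    bootstrap runs only when at least one level is ASSIGNED, sampling from
    the winning strand's k-mer set (forward on a strand tie).
    """
    level_names = db.level_names
    try:
        best_score, hit_ids, strand = top_hits(query, db)
    except UndefinedScoreError:
        logger.warning("query %r yields no valid k-mers; unassigned", query.id)
        return _unassigned_result(query, level_names)
    if best_score == 0.0 or not hit_ids:
        return _unassigned_result(query, level_names)

    assignments = assign_levels(hit_ids, db.taxonomy, level_names)
    ambiguous = {
        a.level_name: sorted({db.taxonomy[h].label(a.level_name) or "" for h in hit_ids} - {""})
        for a in assignments
        if a.status is AssignmentStatus.AMBIGUOUS
    }

    if any(a.status is AssignmentStatus.ASSIGNED for a in assignments):
        strand_seq = (
            query.sequence
            if strand in (Strand.FORWARD, Strand.BOTH)
            else reverse_complement(query.sequence)
        )
        kmers = extract_kmers(strand_seq, db.k)
        confidences = bootstrap_confidence(kmers, db, assignments, n_boot=n_boot, seed=seed)
        assignments = [
            a.with_confidence(confidences[a.level_name])
            if a.level_name in confidences
            else a
            for a in assignments
        ]

    return ClassificationResult(
        query_id=query.id,
        best_score=best_score,
        strand=strand,
        hit_ids=hit_ids,
        assignments=assignments,
        ambiguous_labels=ambiguous,
    )


def classify_many(
    queries: Iterable[SequenceRecord],
    db: "ReferenceDatabase",
    n_boot: int = DEFAULT_BOOTSTRAPS,
    seed: int = 0,
) -> Iterable[ClassificationResult]:
    """Classify queries independently; per-query seed = seed + ordinal.

    The seed derivation makes any concurrent execution bitwise-reproducible
    against this sequential reference.
    """
    for ordinal, query in enumerate(queries):
        yield classify(query, db, n_boot=n_boot, seed=seed + ordinal)
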