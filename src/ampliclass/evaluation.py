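"""Validation machinery: k-fold cross-validation, confidence-cutoff
sweeps, and mock-community panel scoring.

Cross-validation treats each fold of the reference database as held-out
queries: a database is rebuilt from the remaining folds, the held-out
sequences (optionally reduced to one variable region first) are classified
against it, and a call counts as a true positive when the species is
unambiguously assigned, matches the record's own label, and clears the
confidence cutoff. Ambiguous, unassigned and below-cutoff queries count as
unclassified, which is why two accuracy variants are reported: correct /
all queries (unassigned hurts) and correct / classified.

Rates follow TPR = TP/(TP+FP) and FPR = FP/(TP+FP); both are undefined
(None) when nothing is classified at a cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import (
    AssignmentStatus,
    ClassificationResult,
    DEFAULT_BOOTSTRAPS,
    classify,
)
from .database import ReferenceDatabase
from .io_formats import SPECIES, SequenceRecord
from .regions import PrimerPair, extract_region

logger = logging.getLogger(__name__)

DEFAULT_FOLDS = 10
DEFAULT_CUTOFFS = tuple(round(c * 0.1, 1) for c in range(10))


@dataclass(frozen=True)
class CutoffCounts:
    """TP/FP/unassigned tallies at one confidence cutoff."""

    cutoff: float
    tp: int
    fp: int
    unassigned: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.unassigned

    @property
    def classified(self) -> int:
        return self.tp + self.fp

    @property
    def tpr(self) -> float | None:
        return self.tp / self.classified if self.classified else None

    @property
    def fpr(self) -> float | None:
        return self.fp / self.classified if self.classified else None

    @property
    def accuracy(self) -> float | None:
        """Correct over ALL queries (unassigned counts against it)."""
        return self.tp / self.total if self.total else None

    @property
    def accuracy_classified(self) -> float | None:
        """Correct over classified queries only."""
        return self.tp / self.classified if self.classified else None


@dataclass
class EvaluationSummary:
    """Counts per confidence cutoff, with derived accuracy and rates."""

    rows: list[CutoffCounts]
    label: str = ""

    def at(self, cutoff: float) -> CutoffCounts:
        for row in self.rows:
            if row.cutoff == cutoff:
                return row
        raise KeyError(cutoff)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.label,
                "cutoff": r.cutoff,
                "TP": r.tp,
                "FP": r.fp,
                "unassigned": r.unassigned,
                "accuracy": r.accuracy,
                "accuracy_classified": r.accuracy_classified,
                "TPR": r.tpr,
                "FPR": r.fpr,
            }
            for r in self.rows
        )


def kfold_split(
    ids: Sequence[str] | ReferenceDatabase, n_folds: int = DEFAULT_FOLDS, seed: int = 0
) -> list[list[str]]:
    """Seeded random partition of reference ids into near-equal folds.

    Fold sizes differ by at most one; the same seed always yields the same
    partition. Accepts a database or a plain id sequence.
    """
    if isinstance(ids, ReferenceDatabase):
        ids = list(ids.records)
    ids = list(ids)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(ids) < n_folds:
        raise ValueError(f"cannot split {len(ids)} records into {n_folds} folds")
    order = np.random.default_rng(seed).permutation(len(ids))
    return [
        [ids[i] for i in chunk] for chunk in np.array_split(order, n_folds)
    ]


def _species_call(result: ClassificationResult) -> tuple[str, float] | None:
    """(label, confidence) when species is ASSIGNED, else None."""
    a = result.assignment(SPECIES)
    if a is None or a.status is not AssignmentStatus.ASSIGNED:
        return None
    return a.label, a.confidence if a.confidence is not None else 1.0


def sweep_cutoffs(
    results: Iterable[ClassificationResult],
    truth: Mapping[str, str],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> EvaluationSummary:
    """Score classifications against true species labels per cutoff.

    At cutoff c a query counts as classified only when species is ASSIGNED
    with confidence >= c; it is then TP if the label equals the truth and
    FP otherwise. Everything else (AMBIGUOUS, UNASSIGNED, below cutoff) is
    unassigned. Raising c can only shrink TP+FP.
    """
    calls = [( _species_call(r), truth[r.query_id]) for r in results]
    rows = []
    for cutoff in cutoffs:
        tp = fp = unassigned = 0
        for call, true_label in calls:
            if call is None or call[1] < cutoff:
                unassigned += 1
            elif call[0] == true_label:
                tp += 1
            else:
                fp += 1
        rows.append(CutoffCounts(cutoff, tp, fp, unassigned))
    return EvaluationSummary(rows)


def score_against_panel(
    results: Iterable[ClassificationResult],
    panel_species: Iterable[str],
    cutoff: float = 0.0,
) -> EvaluationSummary:
    """Mock-community rule: a call is correct iff the unambiguously
    assigned species is a known member of the panel."""
    panel = set(panel_species)
    if not panel:
        raise ValueError("panel_species must be non-empty")
    tp = fp = unassigned = 0
    for result in results:
        call = _species_call(result)
        if call is None or call[1] < cutoff:
            unassigned += 1
        elif call[0] in panel:
            tp += 1
        else:
            fp += 1
    return EvaluationSummary([CutoffCounts(cutoff, tp, fp, unassigned)], label="panel")


def cross_validate(
    db: ReferenceDatabase,
    n_folds: int = DEFAULT_FOLDS,
    n_boot: int = DEFAULT_BOOTSTRAPS,
    region: PrimerPair | None = None,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    seed: int = 0,
) -> EvaluationSummary:
    """k-fold cross-validation of species assignment accuracy.

    For every fold the training database is rebuilt (same k) from the other
    folds and the held-out records become queries — optionally reduced to
    the given variable region first. Records whose region cannot be
    extracted stay in the denominator as unassigned. Per-query bootstrap
    seeds derive from ``seed`` plus a global query ordinal.
    """
    folds = kfold_split(db, n_folds=n_folds, seed=seed)
    results: list[ClassificationResult] = []
    truth: dict[str, str] = {}
    n_unextractable = 0
    ordinal = 0
    for fold_idx, held_out in enumerate(folds):
        held = set(held_out)
        train_records = [r for i, r in db.records.items() if i not in held]
        if not train_records:
            raise ValueError(f"fold {fold_idx}: empty training partition")
        train_db = ReferenceDatabase.from_records(
            train_records, db.taxonomy, k=db.k
        )
        for rec_id in held_out:
            query = db.records[rec_id]
            truth[rec_id] = db.taxonomy[rec_id].species
            if region is not None:
                extracted = extract_region(query, region)
                if extracted is None:
                    n_unextractable += 1
                    results.append(
                        ClassificationResult(
                            query_id=rec_id,
                            best_score=0.0,
                            strand=None,
                            hit_ids=frozenset(),
                            assignments=[],
                        )
                    )
                    ordinal += 1
                    continue
                query = SequenceRecord(rec_id, extracted.sequence, query.description)
            results.append(classify(query, train_db, n_boot=n_boot, seed=seed + ordinal))
            ordinal += 1
    if n_unextractable:
        logger.info("%d held-out records had no extractable region", n_unextractable)
    summary = sweep_cutoffs(results, truth, cutoffs)
    summary.label = region.name if region is not None else "full-length"
    return summary
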