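"""Species reference database construction and persistence.

The reference set for species-level classification keeps only sequences
that can actually resolve a species: long enough to be full-length marker
genes, labelled with a complete binomial name, and non-redundant within a
species. Identical sequences labelled with *different* species are all
retained on purpose — they mark species the k-mer score cannot separate,
and their presence is what makes the classifier return AMBIGUOUS instead
of an arbitrary call.

Filters run in a fixed order (length → binomial → per-species dedup), drop
counts are recorded, and the inverted index is built over the survivors.
Databases serialise to a versioned JSON container (gzip when the path ends
in ``.gz``); the index is derived data and is rebuilt on load.
"""

from __future__ import annotations

import datetime
import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .classifier import DEFAULT_K, InvertedIndex
from .errors import DatabaseBuildError, DatabaseFormatError
from .io_formats import (
    CLUSTER,
    GENUS,
    SPECIES,
    SequenceRecord,
    TaxonomyAnnotation,
    is_binomial,
    read_fasta,
    read_taxonomy_map,
)

logger = logging.getLogger(__name__)

FORMAT_NAME = "ampliclass-db"
FORMAT_VERSION = "1.0"

DEFAULT_MIN_LENGTH = 1200

#: placeholder tokens that disqualify a species label (case-insensitive)
DEFAULT_BINOMIAL_DENYLIST = ("sp.", "uncultured", "unidentified", "unclassified")


@dataclass
class BuildMetadata:
    min_length: int
    dropped_length: int = 0
    dropped_binomial: int = 0
    dropped_duplicate: int = 0
    built_at: str = ""

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ReferenceDatabase:
    """Filtered, deduplicated references + taxonomy + inverted index."""

    records: dict[str, SequenceRecord]
    taxonomy: dict[str, TaxonomyAnnotation]
    k: int
    index: InvertedIndex
    metadata: BuildMetadata

    def __post_init__(self) -> None:
        if set(self.records) != set(self.taxonomy):
            orphans = sorted(set(self.records) ^ set(self.taxonomy))
            raise DatabaseBuildError(f"records/taxonomy mismatch for ids: {orphans}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def level_names(self) -> list[str]:
        """Genus and species always; cluster when any record carries one."""
        levels = [GENUS, SPECIES]
        if any(ann.cluster is not None for ann in self.taxonomy.values()):
            levels.append(CLUSTER)
        return levels

    @classmethod
    def from_records(
        cls,
        records: Sequence[SequenceRecord],
        taxonomy: Mapping[str, TaxonomyAnnotation] | Sequence[TaxonomyAnnotation],
        k: int = DEFAULT_K,
        metadata: BuildMetadata | None = None,
    ) -> "ReferenceDatabase":
        """Assemble a database from already-filtered records (index built here)."""
        if not isinstance(taxonomy, Mapping):
            taxonomy = {a.seq_id: a for a in taxonomy}
        rec_map = {r.id: r for r in records}
        tax_map = {i: taxonomy[i] for i in rec_map}
        return cls(
            records=rec_map,
            taxonomy=tax_map,
            k=k,
            index=InvertedIndex.build(records, k),
            metadata=metadata or BuildMetadata(min_length=0, built_at=_now()),
        )


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")


def filter_by_length(
    records: Iterable[SequenceRecord], min_length: int
) -> tuple[list[SequenceRecord], int]:
    """Keep records of length >= min_length; returns (kept, n_dropped)."""
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    kept, dropped = [], 0
    for rec in records:
        if len(rec.sequence) >= min_length:
            kept.append(rec)
        else:
            dropped += 1
    return kept, dropped


def filter_binomial(
    annotations: Iterable[TaxonomyAnnotation],
    denylist: Sequence[str] = DEFAULT_BINOMIAL_DENYLIST,
) -> tuple[list[TaxonomyAnnotation], int]:
    """Keep annotations whose species is a complete binomial.

    Drops labels that are missing, have fewer than two words, or contain a
    placeholder token from the (case-insensitive) denylist.
    """
    deny = {tok.lower() for tok in denylist}
    kept, dropped = [], 0
    for ann in annotations:
        words = ann.species.split()
        if len(words) < 2 or any(w.lower() in deny for w in words):
            dropped += 1
        else:
            kept.append(ann)
    return kept, dropped


def deduplicate(
    records: Sequence[SequenceRecord],
    annotations: Mapping[str, TaxonomyAnnotation],
) -> tuple[list[SequenceRecord], int]:
    """Remove identical sequences within a species, keeping the first seen.

    Identical sequences labelled with different species all survive: they
    flag species that are indistinguishable by sequence and must stay so
    the classifier can report them as ambiguous.
    """
    seen: set[tuple[str, str]] = set()
    kept, dropped = [], 0
    for rec in records:
        key = (annotations[rec.id].species, rec.sequence)
        if key in seen:
            dropped += 1
        else:
            seen.add(key)
            kept.append(rec)
    return kept, dropped


def attach_clusters(
    annotations: Iterable[TaxonomyAnnotation],
    cluster_lookup: Mapping[str, str],
) -> list[TaxonomyAnnotation]:
    """Attach a cluster level to annotations whose species is in the lookup."""
    return [
        ann.with_cluster(cluster_lookup[ann.species])
        if ann.species in cluster_lookup
        else ann
        for ann in annotations
    ]


def read_cluster_map(path: str | Path) -> dict[str, str]:
    """Parse a species → cluster lookup (TSV: species<TAB>cluster)."""
    from .errors import TaxonomyParseError

    lookup: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise TaxonomyParseError(f"{path}:{lineno}: expected species<TAB>cluster")
            species, cluster = cols[0].strip(), cols[1].strip()
            if species in lookup:
                raise TaxonomyParseError(f"{path}:{lineno}: duplicate species {species!r}")
            lookup[species] = cluster
    return lookup


def build_database(
    fasta_path: str | Path,
    taxonomy_path: str | Path,
    k: int = DEFAULT_K,
    min_length: int = DEFAULT_MIN_LENGTH,
    cluster_path: str | Path | None = None,
    length_filter: bool = True,
    denylist: Sequence[str] = DEFAULT_BINOMIAL_DENYLIST,
) -> ReferenceDatabase:
    """Build the reference database from FASTA + taxonomy TSV.

    Applies filters in order length → binomial → dedup, attaches cluster
    annotations when a lookup is supplied, and builds the inverted index at
    size k. Taxonomy rows skipped at parse time (non-binomial species)
    count as binomial-filter drops.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    records = list(read_fasta(fasta_path))
    table = read_taxonomy_map(taxonomy_path)
    annotations = table.as_dict()

    fasta_ids = {r.id for r in records}
    tax_ids = set(annotations) | set(table.skipped_ids)
    orphans = sorted(fasta_ids ^ tax_ids)
    if orphans:
        raise DatabaseBuildError(
            f"ids present in only one of FASTA/taxonomy: {orphans}"
        )

    meta = BuildMetadata(min_length=min_length if length_filter else 0, built_at=_now())

    if length_filter:
        records, meta.dropped_length = filter_by_length(records, min_length)

    # parse-time skips only count when their record survived the length filter
    skipped = set(table.skipped_ids)
    skipped_surviving = sum(1 for r in records if r.id in skipped)
    records = [r for r in records if r.id not in skipped]
    kept_anns, dropped_deny = filter_binomial(
        [annotations[r.id] for r in records], denylist=denylist
    )
    meta.dropped_binomial = dropped_deny + skipped_surviving
    kept_ids = {a.seq_id for a in kept_anns}
    records = [r for r in records if r.id in kept_ids]
    annotations = {a.seq_id: a for a in kept_anns}

    records, meta.dropped_duplicate = deduplicate(records, annotations)
    annotations = {r.id: annotations[r.id] for r in records}

    if cluster_path is not None:
        lookup = read_cluster_map(cluster_path)
        annotations = {
            a.seq_id: a for a in attach_clusters(annotations.values(), lookup)
        }

    if not records:
        raise DatabaseBuildError("no records survived filtering; database is empty")

    logger.info(
        "built database: %d records (%d length-dropped, %d binomial-dropped, "
        "%d duplicate-dropped), k=%d",
        len(records), meta.dropped_length, meta.dropped_binomial,
        meta.dropped_duplicate, k,
    )
    return ReferenceDatabase.from_records(records, annotations, k=k, metadata=meta)


def save_database(db: ReferenceDatabase, path: str | Path) -> None:
    """Serialise to versioned JSON (gzip when path ends in .gz)."""
    payload = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "k": db.k,
        "records": [
            {"id": r.id, "description": r.description, "sequence": r.sequence}
            for r in db.records.values()
        ],
        "taxonomy": [
            {"seq_id": a.seq_id, "genus": a.genus, "species": a.species, "cluster": a.cluster}
            for a in db.taxonomy.values()
        ],
        "metadata": db.metadata.to_dict(),
    }
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt", encoding="utf-8") as handle:
        json.dump(payload, handle)


def load_database(path: str | Path, k: int | None = None) -> ReferenceDatabase:
    """Load a saved database; the index is rebuilt (at the stored k, or at
    the requested k when it differs)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    try:
        with opener(path, "rt", encoding="utf-8") as handle:
            payload = json.load(handle)
    except (OSError, ValueError) as exc:
        raise DatabaseFormatError(f"{path}: corrupt or unreadable database: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != FORMAT_NAME:
        raise DatabaseFormatError(f"{path}: not an {FORMAT_NAME} file")
    version = str(payload.get("version", ""))
    if version.split(".")[0] != FORMAT_VERSION.split(".")[0]:
        raise DatabaseFormatError(
            f"{path}: incompatible version: expected {FORMAT_VERSION} "
            f"(major {FORMAT_VERSION.split('.')[0]}), found {version or '<missing>'}"
        )
    try:
        records = [
            SequenceRecord(r["id"], r["sequence"], r.get("description", ""))
            for r in payload["records"]
        ]
        taxonomy = {
            t["seq_id"]: TaxonomyAnnotation(
                t["seq_id"], t["genus"], t["species"], t.get("cluster")
            )
            for t in payload["taxonomy"]
        }
        meta = BuildMetadata(**payload["metadata"])
        stored_k = int(payload["k"])
    except (KeyError, TypeError) as exc:
        raise DatabaseFormatError(f"{path}: malformed database payload: {exc}") from exc
    use_k = k if k is not None else stored_k
    if k is not None and k != stored_k:
        logger.info("rebuilding index at k=%d (stored k=%d)", k, stored_k)
    return ReferenceDatabase.from_records(records, taxonomy, k=use_k, metadata=meta)
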