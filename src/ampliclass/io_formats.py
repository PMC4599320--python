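"""Sequence and taxonomy file input/output.

Reads FASTA (plain or gzip) references and FASTA/FASTQ queries into
:class:`SequenceRecord` objects, parses the tab-separated taxonomy mapping
file that links reference ids to a genus/species (and optional *Clostridium*
cluster) hierarchy, and provides IUPAC-aware reverse complementation.

Sequences are normalised on input: uppercased, and RNA-style ``U`` converted
to ``T`` (rRNA databases contain RNA-alphabet deposits). FASTQ qualities are
ignored — classification uses the nucleotide sequence only.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FastaParseError, TaxonomyParseError

logger = logging.getLogger(__name__)

#: canonical taxonomy level names, in rank order
GENUS = "genus"
SPECIES = "species"
CLUSTER = "cluster"

IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

_COMPLEMENT_TABLE = str.maketrans(IUPAC_COMPLEMENT)
_IUPAC_LETTERS = frozenset(IUPAC_COMPLEMENT)


@dataclass(frozen=True)
class SequenceRecord:
    """One identified nucleotide sequence (reference or query)."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TaxonomyAnnotation:
    """Genus/species (and optional cluster) labels for one reference id.

    The species label, when present, is a complete binomial
    (``"Genus species"``); enforcement happens at parse time and again in
    the database builder's binomial filter.
    """

    seq_id: str
    genus: str
    species: str
    cluster: str | None = None

    @property
    def levels(self) -> list[tuple[str, str]]:
        """Ordered (level_name, label) pairs; cluster only when annotated."""
        out = [(GENUS, self.genus), (SPECIES, self.species)]
        if self.cluster is not None:
            out.append((CLUSTER, self.cluster))
        return out

    def label(self, level_name: str) -> str | None:
        if level_name == GENUS:
            return self.genus
        if level_name == SPECIES:
            return self.species
        if level_name == CLUSTER:
            return self.cluster
        raise KeyError(level_name)

    def with_cluster(self, cluster: str | None) -> "TaxonomyAnnotation":
        return TaxonomyAnnotation(self.seq_id, self.genus, self.species, cluster)


@dataclass
class TaxonomyTable:
    """Parsed taxonomy mapping file: kept annotations plus skipped ids."""

    annotations: list[TaxonomyAnnotation] = field(default_factory=list)
    skipped_ids: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, TaxonomyAnnotation]:
        return {a.seq_id: a for a in self.annotations}

    def __len__(self) -> int:
        return len(self.annotations)


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8", newline=None)
    return open(path, "rt", encoding="utf-8", newline=None)


def _chain_lines(buffered: Sequence[str], rest: Iterator[str]) -> Iterator[str]:
    yield from buffered
    yield from rest


def _normalize(raw: str, record_name: str) -> str:
    seq = "".join(raw.split()).upper().replace("U", "T")
    if not seq:
        raise FastaParseError(f"record {record_name!r}: empty sequence")
    return seq


def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    """Yield records from a FASTA file (plain or gzip) in file order.

    Multi-line sequences are joined; the header token before the first
    whitespace becomes the id and the remainder the description. Lowercase
    letters are uppercased and ``U`` becomes ``T``.

    Raises
    ------
    FastaParseError
        On sequence data before any header, an empty sequence, or a
        duplicate id.
    """
    seen: set[str] = set()
    with _open_text(path) as handle:
        # Biopython tolerates leading junk before the first header; reject it
        lines = iter(handle)
        buffered: list[str] = []
        for line in lines:
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: sequence data before any FASTA header: {line.strip()[:40]!r}"
                    )
                buffered.append(line)
                break
        stream = _chain_lines(buffered, lines)
        try:
            for title, raw_seq in SimpleFastaParser(stream):
                parts = title.split(None, 1)
                if not parts:
                    raise FastaParseError(f"{path}: FASTA header with no id")
                rec_id = parts[0]
                desc = parts[1] if len(parts) == 2 else ""
                if rec_id in seen:
                    raise FastaParseError(f"{path}: duplicate sequence id {rec_id!r}")
                seen.add(rec_id)
                yield SequenceRecord(rec_id, _normalize(raw_seq, rec_id), desc)
        except ValueError as exc:  # Biopython: text before the first '>'
            raise FastaParseError(f"{path}: {exc}") from exc


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    """Yield records from a FASTQ file, discarding quality strings."""
    seen: set[str] = set()
    with _open_text(path) as handle:
        try:
            for title, raw_seq, _qual in FastqGeneralIterator(handle):
                rec_id = title.split(None, 1)[0]
                desc = title.split(None, 1)[1] if " " in title else ""
                if rec_id in seen:
                    raise FastaParseError(f"{path}: duplicate sequence id {rec_id!r}")
                seen.add(rec_id)
                yield SequenceRecord(rec_id, _normalize(raw_seq, rec_id), desc)
        except ValueError as exc:
            raise FastaParseError(f"{path}: {exc}") from exc


def read_sequences(path: str | Path) -> Iterator[SequenceRecord]:
    """Dispatch on extension: ``.fastq``/``.fq`` (optionally ``.gz``) vs FASTA."""
    name = Path(path).name.lower()
    stem = name[:-3] if name.endswith(".gz") else name
    if stem.endswith((".fastq", ".fq")):
        return read_fastq(path)
    return read_fasta(path)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> int:
    """Write records as FASTA; returns the number written."""
    n = 0
    with open(path, "wt", encoding="utf-8") as handle:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            handle.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")
            n += 1
    return n


def is_binomial(species: str) -> bool:
    """True when the label has at least two whitespace-separated words."""
    return len(species.split()) >= 2


def read_taxonomy_map(path: str | Path) -> TaxonomyTable:
    """Parse the taxonomy mapping file.

    Tab-separated, one row per reference: ``seq_id, genus, species[, cluster]``.
    Rows whose species label is not a binomial are skipped with a warning and
    recorded in :attr:`TaxonomyTable.skipped_ids`; duplicate seq_ids and rows
    with fewer than three columns are hard errors.
    """
    table = TaxonomyTable()
    seen: set[str] = set()
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise TaxonomyParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, got {len(cols)}"
                )
            seq_id, genus, species = cols[0].strip(), cols[1].strip(), cols[2].strip()
            cluster = cols[3].strip() if len(cols) >= 4 and cols[3].strip() else None
            if not seq_id:
                raise TaxonomyParseError(f"{path}:{lineno}: empty seq_id")
            if seq_id in seen:
                raise TaxonomyParseError(f"{path}:{lineno}: duplicate seq_id {seq_id!r}")
            seen.add(seq_id)
            if not is_binomial(species):
                logger.warning(
                    "%s:%d: species %r is not a binomial; record %r skipped",
                    path, lineno, species, seq_id,
                )
                table.skipped_ids.append(seq_id)
                continue
            table.annotations.append(TaxonomyAnnotation(seq_id, genus, species, cluster))
    return table


def write_taxonomy_map(annotations: Iterable[TaxonomyAnnotation], path: str | Path) -> int:
    n = 0
    with open(path, "wt", encoding="utf-8") as handle:
        for ann in annotations:
            cols = [ann.seq_id, ann.genus, ann.species]
            if ann.cluster is not None:
                cols.append(ann.cluster)
            handle.write("\t".join(cols) + "\n")
            n += 1
    return n


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the full IUPAC nucleotide alphabet.

    Raises
    ------
    ValueError
        Naming the character and 0-based position of the first non-IUPAC
        letter.
    """
    for pos, char in enumerate(sequence):
        if char not in _IUPAC_LETTERS:
            raise ValueError(
                f"non-IUPAC character {char!r} at position {pos}"
            )
    return sequence.translate(_COMPLEMENT_TABLE)[::-1]


def iupac_matches(primer_char: str, base: str) -> bool:
    """Does the IUPAC class of ``primer_char`` contain ``base``?

    ``base`` must be a concrete nucleotide; ambiguity codes in the
    *sequence* (including N) match nothing.
    """
    return base in IUPAC_SETS.get(primer_char, frozenset())


#: IUPAC code -> the set of concrete bases it stands for
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
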