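"""Variable-region extraction with degenerate primer pairs.

Validation of amplicon classifiers needs reads that cover the same
hypervariable stretch of the marker gene that a real PCR would amplify.
This module performs that in-silico PCR: it locates a degenerate forward
primer and, downstream of it, the reverse complement of the reverse
primer, and cuts out the region between the two footprints.

Primer matching is position-wise IUPAC class containment with a mismatch
budget — no indels inside primers. An ``N`` (or any ambiguity code) in the
*target* sequence matches nothing and counts as a mismatch. Among candidate
sites the fewest-mismatch match wins, ties broken leftmost; for the reverse
primer the leftmost valid downstream site wins, giving the shortest region
— deterministic and conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from .errors import TaxonomyParseError
from .io_formats import IUPAC_SETS, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_MAX_MISMATCHES = 2
MIN_PRIMER_LENGTH = 10


class PrimerMatch(NamedTuple):
    """Half-open window [start, end) and its mismatch count."""

    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class PrimerPair:
    """A named amplification region: forward and reverse primers, 5'→3'
    as written (the reverse primer on the opposite strand)."""

    name: str
    forward: str
    reverse: str
    max_mismatches: int = DEFAULT_MAX_MISMATCHES

    def __post_init__(self) -> None:
        for label, primer in (("forward", self.forward), ("reverse", self.reverse)):
            if len(primer) < MIN_PRIMER_LENGTH:
                raise ValueError(
                    f"{label} primer of pair {self.name!r} is shorter than "
                    f"{MIN_PRIMER_LENGTH} nt"
                )
            bad = [c for c in primer.upper() if c not in IUPAC_SETS]
            if bad:
                raise ValueError(
                    f"{label} primer of pair {self.name!r} has non-IUPAC characters {bad}"
                )
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


def match_primer(
    sequence: str, primer: str, max_mismatches: int = 0
) -> list[PrimerMatch]:
    """All windows where the primer matches with at most ``max_mismatches``.

    A primer position matches when its IUPAC class contains the sequence
    base; ambiguity codes in the sequence (including N) never match.
    Windows are 0-based half-open, returned left to right.
    """
    primer = primer.upper()
    classes = [IUPAC_SETS[c] for c in primer]
    m, n = len(primer), len(sequence)
    out: list[PrimerMatch] = []
    for start in range(n - m + 1):
        mism = 0
        for offset, cls in enumerate(classes):
            if sequence[start + offset] not in cls:
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            out.append(PrimerMatch(start, start + m, mism))
    return out


def _best(matches: Sequence[PrimerMatch]) -> PrimerMatch | None:
    return min(matches, key=lambda m: (m.mismatches, m.start)) if matches else None


def _extract_oriented(
    sequence: str, pair: PrimerPair, keep_primers: bool
) -> str | None:
    fwd = _best(match_primer(sequence, pair.forward, pair.max_mismatches))
    if fwd is None:
        return None
    rc_rev = reverse_complement(pair.reverse.upper())
    rev_candidates = [
        m
        for m in match_primer(sequence, rc_rev, pair.max_mismatches)
        if m.start >= fwd.end
    ]
    # leftmost valid downstream site (shortest region), mismatches second
    rev = min(rev_candidates, key=lambda m: (m.start, m.mismatches), default=None)
    if rev is None:
        return None
    region = (
        sequence[fwd.start : rev.end] if keep_primers else sequence[fwd.end : rev.start]
    )
    return region or None


def extract_region(
    record: SequenceRecord,
    pair: PrimerPair,
    keep_primers: bool = False,
    both_orientations: bool = True,
) -> SequenceRecord | None:
    """Cut the region between the primer footprints out of one record.

    Searches the record as given and, when ``both_orientations`` is set,
    its reverse complement; the result is always reported in the forward
    orientation of the primer pair, so a record and its reverse complement
    yield the same region. Returns None when either primer is absent or
    the region would be empty.
    """
    region = _extract_oriented(record.sequence, pair, keep_primers)
    if region is None and both_orientations:
        region = _extract_oriented(
            reverse_complement(record.sequence), pair, keep_primers
        )
    if region is None:
        return None
    return SequenceRecord(
        id=f"{record.id}|{pair.name}",
        sequence=region,
        description=record.description,
    )


@dataclass
class RipSummary:
    """Per-region extraction tallies."""

    extracted: dict[str, int] = field(default_factory=dict)
    missed: dict[str, int] = field(default_factory=dict)

    def rows(self) -> list[tuple[str, int, int]]:
        return [
            (name, self.extracted[name], self.missed[name])
            for name in self.extracted
        ]


def rip_all(
    records: Iterable[SequenceRecord],
    pairs: Sequence[PrimerPair],
    keep_primers: bool = False,
    both_orientations: bool = True,
) -> tuple[dict[str, list[SequenceRecord]], RipSummary]:
    """Extract every region from every record.

    Returns one record list per primer pair plus a summary of extracted
    and missed counts; extracted + missed equals the input count for each
    region. Pairs act independently — a record can appear in several
    region outputs.
    """
    records = list(records)
    regions: dict[str, list[SequenceRecord]] = {p.name: [] for p in pairs}
    summary = RipSummary(
        extracted={p.name: 0 for p in pairs}, missed={p.name: 0 for p in pairs}
    )
    for pair in pairs:
        for rec in records:
            region = extract_region(
                rec, pair, keep_primers=keep_primers, both_orientations=both_orientations
            )
            if region is None:
                summary.missed[pair.name] += 1
            else:
                regions[pair.name].append(region)
                summary.extracted[pair.name] += 1
    return regions, summary


def read_primer_config(
    path: str | Path, max_mismatches: int = DEFAULT_MAX_MISMATCHES
) -> list[PrimerPair]:
    """Parse a primer TSV (name, forward, reverse); names must be unique."""
    pairs: list[PrimerPair] = []
    seen: set[str] = set()
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise TaxonomyParseError(
                    f"{path}:{lineno}: expected name<TAB>forward<TAB>reverse"
                )
            name = cols[0].strip()
            if name in seen:
                raise TaxonomyParseError(f"{path}:{lineno}: duplicate region name {name!r}")
            seen.add(name)
            try:
                pairs.append(
                    PrimerPair(name, cols[1].strip(), cols[2].strip(), max_mismatches)
                )
            except ValueError as exc:
                raise TaxonomyParseError(f"{path}:{lineno}: {exc}") from exc
    return pairs
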