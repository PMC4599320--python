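"""Seeded synthetic reference sets and query reads.

The generator emulates the structure a marker-gene reference database and
its amplicon queries have for classification purposes: a star phylogeny of
genera, species radiating from each genus ancestor at a controlled
substitution divergence, near-identical sequence variants within each
species, and queries that are error-bearing (optionally sub-sampled) copies
of references on either strand. The mutation model is substitution-only
with uniform base composition; indels, chimeras, platform-specific error
profiles and GC skew are deliberately absent.

Everything is driven by one ``numpy`` Generator per call, so outputs are
bit-for-bit reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import SequenceRecord, TaxonomyAnnotation, reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic reference set.

    Divergences are per-base substitution probabilities: each species
    ancestor is the genus ancestor mutated at ``inter_species_divergence``,
    and each sequence is its species ancestor mutated at
    ``intra_species_divergence``.
    """

    n_genera: int = 4
    species_per_genus: int = 5
    seqs_per_species: int = 3
    seq_length: int = 1500
    inter_species_divergence: float = 0.03
    intra_species_divergence: float = 0.005
    query_error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genera", "species_per_genus", "seqs_per_species", "seq_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "inter_species_divergence",
            "intra_species_divergence",
            "query_error_rate",
        ):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")


def _random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability ``rate`` (always to a different base)."""
    out = codes.copy()
    hit = rng.random(len(codes)) < rate
    if hit.any():
        # shift by 1..3 mod 4 guarantees a different base
        out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def _to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def generate_reference_set(
    spec: FixtureSpec,
) -> tuple[list[SequenceRecord], list[TaxonomyAnnotation]]:
    """Reference FASTA records plus their taxonomy annotations.

    Names are ``Genus_<g>`` and ``Genus_<g> species_<s>``; record ids are
    ``G<g>_S<s>_R<r>`` (1-based).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    annotations: list[TaxonomyAnnotation] = []
    for g in range(1, spec.n_genera + 1):
        genus_name = f"Genus_{g}"
        ancestor = _random_sequence(spec.seq_length, rng)
        for s in range(1, spec.species_per_genus + 1):
            species_name = f"{genus_name} species_{s}"
            sp_ancestor = _mutate(ancestor, spec.inter_species_divergence, rng)
            for r in range(1, spec.seqs_per_species + 1):
                codes = _mutate(sp_ancestor, spec.intra_species_divergence, rng)
                rec_id = f"G{g}_S{s}_R{r}"
                records.append(SequenceRecord(rec_id, _to_str(codes), species_name))
                annotations.append(TaxonomyAnnotation(rec_id, genus_name, species_name))
    return records, annotations


def generate_queries(
    reference_records: Sequence[SequenceRecord],
    annotations: Mapping[str, TaxonomyAnnotation],
    n_per_ref: int = 1,
    error_rate: float = 0.005,
    read_length: int | None = None,
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[dict[str, str]]]:
    """Error-bearing reads from each reference plus a truth table.

    Reads are (optionally) random substrings of ``read_length`` with
    per-base substitutions at ``error_rate``; every other read is
    reverse-complemented. Truth rows map read id → true genus, species and
    strand. Row count is ``n_per_ref * len(reference_records)``.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    base_index = {b: i for i, b in enumerate("ACGT")}
    reads: list[SequenceRecord] = []
    truth: list[dict[str, str]] = []
    ordinal = 0
    for rec in reference_records:
        ann = annotations[rec.id]
        codes_full = np.array([base_index[b] for b in rec.sequence])
        for j in range(1, n_per_ref + 1):
            codes = codes_full
            if read_length is not None:
                if read_length > len(codes):
                    raise ValueError(
                        f"read_length {read_length} exceeds reference {rec.id} "
                        f"length {len(codes)}"
                    )
                start = int(rng.integers(0, len(codes) - read_length + 1))
                codes = codes[start : start + read_length]
            seq = _to_str(_mutate(codes, error_rate, rng))
            strand = "REVERSE" if ordinal % 2 else "FORWARD"
            if strand == "REVERSE":
                seq = reverse_complement(seq)
            read_id = f"{rec.id}_read{j}"
            reads.append(SequenceRecord(read_id, seq))
            truth.append(
                {
                    "read_id": read_id,
                    "source_id": rec.id,
                    "genus": ann.genus,
                    "species": ann.species,
                    "strand": strand,
                }
            )
            ordinal += 1
    return reads, truth


def instantiate_iupac(primer: str, rng: np.random.Generator) -> str:
    """Replace each IUPAC code with a concrete base drawn from its class."""
    from .io_formats import IUPAC_SETS

    out = []
    for char in primer.upper():
        options = sorted(IUPAC_SETS[char])
        out.append(options[int(rng.integers(0, len(options)))])
    return "".join(out)


def generate_ripper_fixture(
    primer_pair,
    insert: str,
    flank_lengths: tuple[int, int] = (50, 50),
    seed: int = 0,
) -> tuple[SequenceRecord, str]:
    """A record with a known extractable region.

    Concatenates random flank + instantiated forward primer + insert +
    revcomp(instantiated reverse primer) + random flank; returns the record
    and the expected extraction (the insert).
    """
    if not insert:
        raise ValueError("insert must be non-empty")
    rng = np.random.default_rng(seed)
    left = _to_str(_random_sequence(flank_lengths[0], rng))
    right = _to_str(_random_sequence(flank_lengths[1], rng))
    fwd = instantiate_iupac(primer_pair.forward, rng)
    rev = instantiate_iupac(primer_pair.reverse, rng)
    seq = left + fwd + insert.upper() + reverse_complement(rev) + right
    return SequenceRecord(f"synthetic_{primer_pair.name}", seq), insert.upper()
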