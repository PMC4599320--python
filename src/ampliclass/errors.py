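"""Exception hierarchy.

All data-level failures raise :class:`AmpliclassError` subclasses so the
command-line layer can map them to a uniform exit code (2) while usage
errors stay with the argument parser (exit 1).
"""


class AmpliclassError(Exception):
    """Base class for all data and processing errors."""


class FastaParseError(AmpliclassError):
    """Malformed FASTA/FASTQ input (empty sequence, duplicate id, junk before header)."""


class TaxonomyParseError(AmpliclassError):
    """Malformed taxonomy mapping or cluster lookup file."""


class DatabaseBuildError(AmpliclassError):
    """Reference-database construction failed (orphan ids, zero survivors)."""


class DatabaseFormatError(AmpliclassError):
    """Serialized database file is corrupt or has an incompatible version."""


class UndefinedScoreError(AmpliclassError):
    """Similarity score requested for a query with no valid k-mers."""
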