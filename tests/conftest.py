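import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ampliclass import (
    FixtureSpec,
    ReferenceDatabase,
    SequenceRecord,
    TaxonomyAnnotation,
    generate_reference_set,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_db(entries, k=4):
    """Build a small in-memory database from (id, genus, species, sequence[, cluster])."""
    records, taxonomy = [], {}
    for entry in entries:
        rec_id, genus, species, seq = entry[:4]
        cluster = entry[4] if len(entry) > 4 else None
        records.append(SequenceRecord(rec_id, seq))
        taxonomy[rec_id] = TaxonomyAnnotation(rec_id, genus, species, cluster)
    return ReferenceDatabase.from_records(records, taxonomy, k=k)


def random_db(rng, n_refs, max_len, k, n_genera=3, species_per_genus=3):
    """A random database of uniform-random sequences for oracle checks."""
    entries = []
    for i in range(n_refs):
        g = int(rng.integers(1, n_genera + 1))
        s = int(rng.integers(1, species_per_genus + 1))
        length = int(rng.integers(k, max_len + 1))
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
        entries.append((f"r{i}", f"Genus_{g}", f"Genus_{g} species_{s}", seq))
    return make_db(entries, k=k)


@pytest.fixture(scope="session")
def well_separated_db():
    """20 species, 3 sequences each, 3% inter / 0.5% intra divergence, k=8."""
    spec = FixtureSpec(
        n_genera=4,
        species_per_genus=5,
        seqs_per_species=3,
        seq_length=1500,
        inter_species_divergence=0.03,
        intra_species_divergence=0.005,
        seed=11,
    )
    records, annotations = generate_reference_set(spec)
    return ReferenceDatabase.from_records(records, annotations, k=8)
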