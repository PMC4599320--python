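"""Independent brute-force reimplementations used as test oracles.

These deliberately avoid the inverted index: scores come from direct
pairwise set intersections against every reference, so they validate the
index-accumulation path without sharing code with it.
"""

from fractions import Fraction

import numpy as np

from ampliclass import Strand, extract_kmers, reverse_complement
from ampliclass.classifier import bootstrap_subset_size


def brute_force_scores(query_seq, db, k):
    """Per-reference exact containment scores (Fractions) for one strand."""
    qk = extract_kmers(query_seq, k).kmers
    if not qk:
        return None
    return {
        rec_id: Fraction(len(qk & extract_kmers(rec.sequence, k).kmers), len(qk))
        for rec_id, rec in db.records.items()
    }


def brute_force_top_hits(query, db):
    """Both-strand best score/hit set by exhaustive pairwise scoring.

    A strand whose best score is zero contributes no hits, mirroring the
    contract that hit_ids is non-empty only when best_score > 0.
    """
    fwd = brute_force_scores(query.sequence, db, db.k)
    rev = brute_force_scores(reverse_complement(query.sequence), db, db.k)
    best_f = max(fwd.values()) if fwd else Fraction(-1)
    best_r = max(rev.values()) if rev else Fraction(-1)
    hits_f = frozenset(r for r, s in (fwd or {}).items() if s == best_f and s > 0)
    hits_r = frozenset(r for r, s in (rev or {}).items() if s == best_r and s > 0)
    if best_f > best_r:
        return float(best_f), hits_f, Strand.FORWARD
    if best_r > best_f:
        return float(best_r), hits_r, Strand.REVERSE
    return float(best_f), hits_f | hits_r, Strand.BOTH


def _agreed_labels(hit_ids, taxonomy, level_names):
    """Level -> label for levels where every hit agrees on a non-empty label."""
    agreed = {}
    for level in level_names:
        labels = [taxonomy[h].label(level) for h in hit_ids]
        if labels and all(labels) and len(set(labels)) == 1:
            agreed[level] = labels[0]
    return agreed


def brute_force_bootstrap(query_kmers, db, full_assignments, n_boot, seed):
    """Re-run the seeded bootstrap with pairwise scoring instead of the index.

    The sampling contract (sorted k-mer pool, numpy default_rng, choice
    without replacement, subset size floor(|Q_K|/k) >= 1) is part of the
    documented procedure and is therefore replicated; the scoring and
    label-agreement logic is independent.
    """
    from ampliclass import AssignmentStatus

    assigned = {
        a.level_name: a.label
        for a in full_assignments
        if a.status is AssignmentStatus.ASSIGNED
    }
    if not assigned:
        return {}
    ref_kmers = {
        rec_id: extract_kmers(rec.sequence, db.k).kmers
        for rec_id, rec in db.records.items()
    }
    pool = sorted(query_kmers.kmers)
    size = bootstrap_subset_size(len(pool), query_kmers.k)
    rng = np.random.default_rng(seed)
    matches = dict.fromkeys(assigned, 0)
    for _ in range(n_boot):
        subset = set(rng.choice(pool, size=size, replace=False))
        counts = {rid: len(subset & rk) for rid, rk in ref_kmers.items()}
        best = max(counts.values())
        top = [rid for rid, c in counts.items() if c == best]
        agreed = _agreed_labels(top, db.taxonomy, db.level_names)
        for level, label in assigned.items():
            if agreed.get(level) == label:
                matches[level] += 1
    return {level: matches[level] / n_boot for level in assigned}
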