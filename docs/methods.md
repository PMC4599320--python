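# Methods

## Model

A query read Q and a reference R are compared through the containment of
their k-mer sets: `S(Q,R) = |Q_K ∩ R_K| / |Q_K|`, where `Q_K` and `R_K`
are the sets of *distinct* overlapping k-mers. The score is asymmetric by
design — normalising by the query means a short amplicon wholly contained
in a full-length gene scores 1 — and it is a proxy for sequence identity
with known edge behaviour: interior substitutions are penalised roughly
k-fold (each destroys up to k windows), substitutions within k−1 bases of
an end are penalised less, and block rearrangements that would wreck an
alignment barely move the score. The classifier therefore suits short
reads whose deviation from the closest reference is small; a read riddled
with errors scores low everywhere and is left unassigned, which is the
intended behaviour when references for near-identical species differ by a
handful of bases.

Only A/C/G/T windows enter a k-mer set; windows containing IUPAC ambiguity
codes or N are skipped rather than expanded, keeping scores conservative
and the set semantics exact.

### Search

References are indexed k-mer → sorted posting list of reference ids.
Scoring a query accumulates, for each of its k-mers, a counter per posting
id; the count for reference R equals `|Q_K ∩ R_K|` exactly (an invariant
the test suite checks against direct set intersections). Both the read
and its reverse complement are searched; because the two strands can have
different numbers of valid k-mers, the strand comparison is done on
integer cross-products (`count_f · |Q_rev|` vs `count_r · |Q_fwd|`), so
equal rational scores are recognised exactly and reported as a strand tie
with the hit sets unioned. Reported scores are floats; all comparisons
that decide hits or strand are integer-exact.

### Assignment and ambiguity

The hit set (all references attaining the best score) is summarised per
taxonomic level. Unanimous non-empty label → ASSIGNED; two or more
distinct labels → AMBIGUOUS; no labels, or labels on only part of the hit
set (possible for the optional cluster level) → UNASSIGNED. Levels are
independent. Identical reference sequences under different species labels
are deliberately kept in the database so that queries matching them tie,
disagree at species level, and come out AMBIGUOUS rather than
arbitrarily called.

### Bootstrap confidence

For each of `n_boot` trials (default 10; 100 for slower, marginally
smoother estimates) a subset of `max(1, floor(|Q_K|/k))` k-mers is drawn
from the winning strand's k-mer set *without replacement*, the search is
re-run on the subset, and the trial counts as a match at a level when its
top set unanimously carries the full-query label there. Confidence is
matches / trials. Procedural details that the score definition leaves
open were fixed as follows:

- subset size rounds down, floored at one k-mer;
- a trial whose top set is ambiguous at a level is a non-match (per-trial
  counting; this coincides with pooled-reference counting whenever top
  sets are singletons);
- a trial whose subset shares no k-mer with any reference retrieves the
  entire reference set (everything ties at zero) — consequential only for
  databases with a single species, where such trials still match;
- the k-mer pool is sorted lexicographically before sampling with a
  `numpy` Generator seeded per query, making confidences independent of
  reference input order and reproducible bit-for-bit;
- batch classification derives per-query seeds as `seed + ordinal`, so
  any parallel execution must reproduce sequential output exactly.

## Reference database construction

Filters run in a fixed order and their drop counts are recorded:

1. **Length** (default ≥ 1200 bp): keeps full-length marker genes; can be
   disabled for short-marker databases such as *cpn60* Universal Target
   collections.
2. **Binomial names**: species labels must have ≥ 2 words and contain no
   placeholder token from a configurable, case-insensitive denylist
   (default `sp.`, `uncultured`, `unidentified`, `unclassified`). The
   denylist approximates common placeholder nomenclature and is editable
   because no canonical rule exists.
3. **Per-species deduplication**: within a species, one copy of each
   distinct sequence survives (first in input order, for deterministic
   builds); identical sequences across species all survive.

*Clostridium* cluster labels are attached from a user-supplied
species → cluster TSV, since the groupings are a curated convention rather
than derivable data. Databases serialise to a versioned JSON container
(major-version checked on load); the inverted index is derived data and
is rebuilt on load, also allowing a different k to be requested.

## Region extraction

In-silico PCR with degenerate primers: position-wise IUPAC-class
matching with a mismatch budget (default 2), no indels inside primers,
and ambiguity codes in the *target* counting as mismatches. The forward
site is the fewest-mismatch, leftmost window; the reverse site is the
leftmost valid window downstream of it (shortest region) matching the
reverse complement of the reverse primer. Primer footprints are excluded
by default (`keep_primers` reverses this). Records are searched in both
orientations and the region is always reported in the primer pair's
forward orientation, so a record and its reverse complement yield
identical regions. These tolerances and tie-breaks are this package's own
conventions, chosen to be deterministic and conservative.

## Evaluation harness

`kfold_split` partitions reference ids (sequences, not species) into
seeded near-equal folds. `cross_validate` rebuilds the database per fold,
optionally region-extracts the held-out records, classifies them, and
scores: TP = species ASSIGNED, equal to the record's label, confidence ≥
cutoff; FP = assigned but wrong; everything else unassigned. Two accuracy
variants are reported because the denominator is a genuine choice:
`accuracy` = TP / all held-out queries (an unassignable query counts
against the classifier) and `accuracy_classified` = TP / (TP+FP). Records
whose species has no other representative in the training folds stay in
the denominator. Panel scoring applies the mock-community rule: a call is
correct iff the unambiguously assigned species is a panel member.

## Synthetic fixtures

The generator emulates the *structure* that matters to a k-mer
classifier: a star phylogeny per genus, species ancestors at a controlled
per-base substitution divergence (default 3 %), near-identical
within-species variants (default 0.5 %), and reads that are error-bearing
copies (default 0.5 % substitutions, half reverse-complemented, optional
substring sampling). Defaults for the standard validation fixture are 4
genera × 5 species × 3 sequences of 1500 bp — 20 species and 60 records,
sized so a 10-fold cross-validation with 10 bootstraps completes in
seconds while every species retains same-species training representatives
in each fold. The model is substitution-only with uniform base
composition: no indels, chimeras, GC skew, platform error profiles, or
taxonomic mislabelling. Tests passing on these fixtures therefore
demonstrate the algorithmic contracts (exactness of the index, strand
handling, ambiguity semantics, bootstrap calibration under clean
separation) — not performance on real communities, where reference
incompleteness and mislabelled deposits dominate the error budget.

## Numerical and degenerate-input choices

- Scores are exact rationals internally (integer counts); text output
  rounds to 4 decimal places.
- Queries shorter than k, or with no A/C/G/T window on either strand,
  yield all-UNASSIGNED results with best score 0 (and a logged warning)
  rather than errors.
- `U` is converted to `T` and lowercase to uppercase on input; FASTQ
  qualities are ignored.
- Empty sequences, duplicate ids, sequence data before a FASTA header,
  short taxonomy rows and duplicate taxonomy ids are hard parse errors;
  non-binomial species labels in a taxonomy file are skipped with a
  warning and counted.

## Known limitations

- No gap-aware alignment: indel-heavy reads lose k-mers linearly and go
  unassigned sooner than an aligner would warrant.
- Confidence is relative to the database: a species with no close
  relatives in the references gets confidence 1 even from modest scores.
- The containment score ignores k-mer multiplicity and position; repeats
  and rearrangements can inflate similarity (see the block-swap example).
- Single-threaded execution; the seed-derivation contract is in place for
  parallel implementations but none is shipped.
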