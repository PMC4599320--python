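"""k-mer containment scores on tiny hand-checkable sequences.

The score S(Q,R) = |Q_K ∩ R_K| / |Q_K| counts the fraction of the query's
distinct k-mers found in the reference. The three cases below show its
character: swapping two blocks of a sequence barely changes the k-mer set
(a pairwise alignment would disagree), a substitution at the very first
base costs only one k-mer, and a substitution in the middle of a short
query destroys every window that spans it.
"""

from ampliclass import extract_kmers, similarity_score

a_block, b_block = "ATATTAAATT", "GCCGGGCGGC"
swap = similarity_score(
    extract_kmers(a_block + b_block, 4), extract_kmers(b_block + a_block, 4)
)
print(f"block swap        (k=4): {swap:.4f}  (= 14/17 shared 4-mers)")

print("4-mers of ATTTGCG:", " ".join(sorted(extract_kmers("ATTTGCG", 4).kmers)))
print("4-mers of GTTTGCG:", " ".join(sorted(extract_kmers("GTTTGCG", 4).kmers)))

start = similarity_score(extract_kmers("GTTTGCG", 4), extract_kmers("ATTTGCG", 4))
mid = similarity_score(extract_kmers("ATTCGCG", 4), extract_kmers("ATTTGCG", 4))
print(f"start substitution (k=4): {start:.4f}  (3 of 4 4-mers survive)")
print(f"mid substitution   (k=4): {mid:.4f}  (every 4-mer spans the change)")
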