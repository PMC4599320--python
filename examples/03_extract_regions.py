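"""Cut a variable region out of full-length sequences with degenerate primers.

A synthetic record is assembled as flank + forward primer + insert +
revcomp(reverse primer) + flank, then the extractor locates both primer
sites (IUPAC classes, up to 2 mismatches) and returns the sequence between
the footprints — an in-silico PCR of the amplified region.
"""

from ampliclass import PrimerPair, extract_region, generate_ripper_fixture, rip_all

pair = PrimerPair("V3V5", "ACRTACGWAC", "TTSGCCAAKG", max_mismatches=2)
record, expected = generate_ripper_fixture(
    pair, insert="GATTACAGATTACAGATTACA", flank_lengths=(60, 60), seed=4
)
region = extract_region(record, pair)
print(f"source record: {len(record.sequence)} bp")
print(f"extracted {region.id}: {region.sequence}")
print(f"matches the known insert: {region.sequence == expected}")

regions, summary = rip_all([record], [pair])
for name, extracted, missed in summary.rows():
    print(f"region {name}: {extracted} extracted, {missed} without both primers")
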