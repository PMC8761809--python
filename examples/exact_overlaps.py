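"""Find exact suffix-prefix overlaps in a tiny hand-made read set.

Three reads tile a short sequence; the exact pass recovers the two
dovetail adjacencies that an assembler would chain into a contig.
"""

from sufpref import (
    ReadSet,
    build_index,
    concatenate,
    derive_boundaries,
    find_overlaps_exact,
)

reads = ReadSet(
    reads=[
        "ACGTACGGTTCAGGCA",  # covers positions 0..15
        "TTCAGGCAGATCCGAT",  # covers positions 8..23  (8 bp overlap)
        "GATCCGATACCAGTTG",  # covers positions 16..31 (8 bp overlap)
    ],
    ids=["readA", "readB", "readC"],
)

ct = concatenate(reads)
si = build_index(ct)
b = derive_boundaries(si, ct)

for rec in find_overlaps_exact(si, b, k=3):
    print(
        f"{reads.ids[rec.source - 1]} -> {reads.ids[rec.target - 1]}: "
        f"{rec.overlap_len} bp (rank {rec.rank})"
    )

# Each line says: the source read's last <overlap_len> bases equal the
# target read's first <overlap_len> bases, so source precedes target in
# the assembly layout. Expect readA->readB and readB->readC at 8 bp.
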