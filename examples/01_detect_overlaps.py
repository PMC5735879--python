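"""Detect the overlap between two reads that share a genomic segment.

Two 5 kb reads are built from the same random genome so that they truly
overlap by 3 kb, one of them reverse-complemented.  The aligner reports
the boundary coordinates of the overlap (no base-level alignment), the
seed-covered score, and a seed-density identity estimate.
"""

import numpy as np

from hisea import find_overlaps, reverse_complement
from hisea.m4 import format_record
from hisea.seqio import reads_from_strings

rng = np.random.default_rng(0)
genome = "".join("ACGT"[i] for i in rng.integers(0, 4, size=7000))

read_a = genome[0:5000]                       # covers genome [0, 5000)
read_b = reverse_complement(genome[2000:7000])  # covers [2000, 7000), - strand

records, report = find_overlaps(reads_from_strings([read_a, read_b],
                                                   names=["a", "b"]))
print(f"pairs examined: {report['pairs_examined']}, "
      f"overlaps reported: {report['overlaps_reported']}")
for rec in records:
    print(format_record(rec, "a", "b"))
print("\ncolumns: qname tname score identity% qstrand qstart qend qlen "
      "tstrand tstart tend tlen")
print("The true overlap covers [2000, 5000) of read a and, after flipping "
      "to b's forward strand, [2000, 5000) of read b; tstrand=1 marks the "
      "reverse-complement match.")
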