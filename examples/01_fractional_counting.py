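"""Fractional assignment of multi-mapped reads to TEs.

A read aligning equally well to several loci is split 1/k across them,
so repetitive elements accumulate weighted rather than double-counted
evidence.
"""

from pollentx import GenomicInterval, ReadPlacement, fractional_counts

tes = [(f"te{k}", GenomicInterval("chr1", 10_000 * k, 10_000 * k + 900)) for k in range(1, 5)]

multi = ReadPlacement(
    "read_multi",
    tuple(GenomicInterval("chr1", 10_000 * k + 50, 10_000 * k + 149) for k in range(1, 5)),
)
unique = ReadPlacement("read_unique", (GenomicInterval("chr1", 10_100, 10_199),))

counts = fractional_counts([multi, unique], tes)
print(counts)
print(f"total assigned weight = {counts.sum():.2f} (2 reads in, mass conserved)")
# The 4-way multi-mapper contributes 0.25 to each TE; the unique read a
# full 1.0 to te1.
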