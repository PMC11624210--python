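"""Default genomic regions (hg38) for the genes of the KEAP1-NRF2 system.

These spans are configuration, not computation: copy-number calls and the
copy-number candidate filter only need an interval that contains the gene.
Override them for any other genome build or for synthetic data.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class GeneRegion:
    chrom: str
    start: int
    end: int

    def contains(self, start: int, end: int) -> bool:
        return start >= self.start and end <= self.end

    def padded(self, pad: int) -> "GeneRegion":
        return GeneRegion(self.chrom, max(1, self.start - pad), self.end + pad)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and start <= self.end and end >= self.start


# hg38 gene spans (UCSC); minus-strand genes, coordinates ascending.
NFE2L2_REGION = GeneRegion("chr2", 177_230_704, 177_265_062)
KEAP1_REGION = GeneRegion("chr19", 10_486_125, 10_503_356)
CUL3_REGION = GeneRegion("chr2", 224_470_150, 224_585_397)
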