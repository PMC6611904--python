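"""Scan promoters for the 7-bp core element and report TSS-relative hits.

Builds a two-gene toy genome with one element planted 989 bp upstream of a
+ strand gene's TSS (on the forward strand) and one planted in the promoter
of a - strand gene (so the match appears on the reverse genomic strand), then
scans both 2-kb promoters.  Chance occurrences of the 7-mer in the random
background sequence are reported too — a 2-kb promoter has roughly a
1-in-4 chance of containing any given 7-mer by luck alone.
"""

import numpy as np

import cismark as cm
from cismark.core_io import Annotation, GeneModel

rng = np.random.default_rng(0)
seq = list(rng.choice(list("ACGT"), size=12_000))

# + gene at 5000..6200: element 5'-most base 989 bp upstream of the TSS
seq[5000 - 989 : 5000 - 989 + 7] = list(cm.CORE_ELEMENT)
# - gene at 8000..9000: TSS at 8999; plant the reverse complement so the
# promoter (gene orientation) reads the element forward, 120 bp upstream
seq[9000 + 113 : 9000 + 120] = list(cm.revcomp(cm.CORE_ELEMENT))

genome = {"chr1": "".join(seq)}
genes = [
    GeneModel("gene_plus", "chr1", 5000, 6200, "+"),
    GeneModel("gene_minus", "chr1", 8000, 9000, "-"),
]
annotation = Annotation(genes, {"chr1": len(genome["chr1"])})

gene_set, hits = cm.genes_with_element(annotation, genome, pattern=cm.CORE_ELEMENT)

print(f"genes with >=1 element: {sorted(gene_set)}")
for h in hits:
    print(
        f"  {h.gene_id}: {h.matched_seq} at TSS-relative {h.tss_start}..{h.tss_end} "
        f"(match strand {h.strand_of_match}, genomic {h.genomic_start}-{h.genomic_end})"
    )
print(
    "\nCoordinates use the promoter convention: -1 is the base immediately "
    "5' of the TSS, so a span like -989..-983 is a 7-bp element ~1 kb upstream."
)
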