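"""Strand-aware promoter extraction and exact cis-element scanning.

Promoters are the 2 kb immediately 5' of the TSS (in gene orientation).
Element hits are reported in the TSS-relative convention used throughout the
plant-promoter literature: position +1 is the TSS base, the base immediately
upstream is -1, and there is no position 0.  A 7-bp element whose 5'-most
base sits 989 bp upstream of the TSS therefore spans -989..-983 inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .core_io import Annotation, GeneModel

__all__ = [
    "ElementHit",
    "Promoter",
    "revcomp",
    "extract_promoter",
    "scan_pattern",
    "genes_with_element",
    "hits_to_frame",
    "CORE_ELEMENT",
]

# 7-bp core element bound by the zinc-finger activator this pipeline targets
CORE_ELEMENT = "CGGAAAT"

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string (involution)."""
    bad = set(seq.upper()) - set(_IUPAC)
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Promoter:
    """A promoter sequence in gene 5'->3' orientation plus its genomic span."""

    gene_id: str
    chrom: str
    genomic_start: int  # 0-based half-open genomic interval
    genomic_end: int
    strand: str
    sequence: str
    truncated: bool  # True if clipped by a chromosome edge

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ElementHit:
    """One match of a pattern in a promoter, TSS-relative inclusive coords.

    ``strand_of_match`` is '+' if the promoter (gene-orientation) sequence
    matches the pattern itself, '-' if it matches the reverse complement.
    """

    gene_id: str
    pattern: str
    tss_start: int
    tss_end: int
    strand_of_match: str
    matched_seq: str
    chrom: Optional[str] = None
    genomic_start: Optional[int] = None
    genomic_end: Optional[int] = None


def extract_promoter(gene: GeneModel, genome: Mapping[str, str], upstream: int = 2000) -> Promoter:
    """Extract the ``upstream`` bp 5' of the TSS, oriented 5'->3' of the gene.

    For a + strand gene this is the genomic interval [start-upstream, start);
    for a - strand gene it is [end, end+upstream) reverse-complemented.
    Promoters are truncated at chromosome edges and flagged.
    """
    seq = genome.get(gene.chrom)
    if seq is None:
        raise KeyError(f"chromosome {gene.chrom!r} of gene {gene.gene_id} not in genome")
    chrom_len = len(seq)
    if gene.strand == "+":
        g_start = max(0, gene.start - upstream)
        g_end = gene.start
        sub = seq[g_start:g_end]
    else:
        g_start = gene.end
        g_end = min(chrom_len, gene.end + upstream)
        sub = revcomp(seq[g_start:g_end])
    return Promoter(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        genomic_start=g_start,
        genomic_end=g_end,
        strand=gene.strand,
        sequence=sub.upper(),
        truncated=(g_end - g_start) < upstream,
    )


def _pattern_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC pattern to an overlap-tolerant regex.

    Ambiguity codes in the pattern match their base expansions; ambiguity in
    the subject never matches (character classes contain only A/C/G/T).
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    parts = []
    for ch in pattern.upper():
        exp = _IUPAC.get(ch)
        if exp is None:
            raise ValueError(f"non-IUPAC pattern character {ch!r}")
        parts.append(exp if len(exp) == 1 else f"[{exp}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def _offset_to_tss(offset: int, promoter_len: int, pattern_len: int) -> tuple[int, int]:
    # promoter base at 0-based offset o lies (promoter_len - o) bp 5' of TSS
    start = offset - promoter_len
    end = start + pattern_len - 1
    return start, end


def scan_pattern(
    promoter_seq: str, pattern: str, both_strands: bool = True, gene_id: str = ""
) -> list[ElementHit]:
    """Find all (overlapping) occurrences of ``pattern`` in a promoter.

    Matches of the reverse complement are included when ``both_strands``.
    Coordinates are TSS-relative inclusive with no position 0.  A pattern
    longer than the sequence yields an empty list.
    """
    seq = promoter_seq.upper()
    plen = len(seq)
    n = len(pattern)
    hits: list[ElementHit] = []

    def _collect(pat: str, strand: str) -> None:
        rx = _pattern_regex(pat)
        for m in rx.finditer(seq):
            o = m.start()
            s, e = _offset_to_tss(o, plen, n)
            hits.append(
                ElementHit(
                    gene_id=gene_id,
                    pattern=pattern,
                    tss_start=s,
                    tss_end=e,
                    strand_of_match=strand,
                    matched_seq=seq[o : o + n],
                )
            )

    _collect(pattern, "+")
    rc = revcomp(pattern)
    if both_strands and rc.upper() != pattern.upper():
        _collect(rc, "-")
    hits.sort(key=lambda h: (h.tss_start, h.strand_of_match))
    return hits


def _with_genomic(hit: ElementHit, prom: Promoter) -> ElementHit:
    n = hit.tss_end - hit.tss_start + 1
    offset = hit.tss_start + prom.length  # 0-based offset in promoter sequence
    if prom.strand == "+":
        g_start = prom.genomic_start + offset
    else:
        g_start = prom.genomic_end - offset - n
    return ElementHit(
        gene_id=hit.gene_id,
        pattern=hit.pattern,
        tss_start=hit.tss_start,
        tss_end=hit.tss_end,
        strand_of_match=hit.strand_of_match,
        matched_seq=hit.matched_seq,
        chrom=prom.chrom,
        genomic_start=g_start,
        genomic_end=g_start + n,
    )


def genes_with_element(
    annotation: Annotation,
    genome: Mapping[str, str],
    pattern: str = CORE_ELEMENT,
    upstream: int = 2000,
    both_strands: bool = True,
) -> tuple[set[str], list[ElementHit]]:
    """Scan every promoter; return (gene ids with >=1 hit, full hit table).

    The hit table is sorted by (gene_id, tss_start, strand) so output is
    deterministic.
    """
    gene_set: set[str] = set()
    table: list[ElementHit] = []
    for gene in annotation:
        prom = extract_promoter(gene, genome, upstream=upstream)
        hits = scan_pattern(prom.sequence, pattern, both_strands=both_strands, gene_id=gene.gene_id)
        if hits:
            gene_set.add(gene.gene_id)
            table.extend(_with_genomic(h, prom) for h in hits)
    table.sort(key=lambda h: (h.gene_id, h.tss_start, h.strand_of_match))
    return gene_set, table


def hits_to_frame(hits: list[ElementHit]) -> pd.DataFrame:
    cols = [
        "gene_id", "chrom", "genomic_start", "genomic_end",
        "tss_start", "tss_end", "strand_of_match", "matched_seq",
    ]
    return pd.DataFrame([{c: getattr(h, c) for c in cols} for h in hits], columns=cols)
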