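"""Synthetic genomes, promoter elements, ChIP/input coverage and DEG tables.

The generator emulates the study conditions every downstream stage is tested
against: a multi-gene annotation on one chromosome with both strands, uniform
random promoter sequence with a 7-bp element planted at a configurable rate
(spontaneous promoter occurrences rejected-and-resampled so the element truth
set is exact), Poisson window coverage in which a subset of genes carries a
5'-biased ChIP enrichment of configurable fold over the first kilobase of the
gene body, and a differential-expression table in which the probability of
down-regulation depends on element presence.

Everything is deterministic under (config, seed); per-stage seeds are derived
from the master seed so stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import Annotation, CoverageTrack, DEGRecord, GeneModel
from .motifs import CORE_ELEMENT, extract_promoter, revcomp, scan_pattern

__all__ = [
    "SimConfig",
    "SimulationTruth",
    "stage_rng",
    "simulate_annotation",
    "simulate_sequences",
    "choose_enriched",
    "simulate_coverage",
    "simulate_deg",
    "simulate_dataset",
]

logger = logging.getLogger(__name__)

SIM_WINDOW = 200   # bp; granularity at which Poisson coverage is drawn
READ_LENGTH = 50   # bp; fixed for library-size bookkeeping


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 500
    chrom: str = "chr1"
    chrom_len: int = 2_000_000
    gene_len_min: int = 500
    gene_len_max: int = 2400
    intergenic_min: int = 2200
    intergenic_max: int = 2600
    element: str = CORE_ELEMENT
    element_rate: float = 0.1            # P(promoter carries a planted element)
    promoter_len: int = 2000
    enrichment_fold: float = 8.0         # ChIP over input inside the enriched region
    enrichment_len: int = 1000           # enriched region = [TSS, TSS + L)
    enrichment_profile: str = "five_prime"   # or "three_prime" (ends at the TES)
    p_enriched_given_element: float = 0.75
    p_enriched_background: float = 0.4
    background_depth: float = 20.0       # mean input reads per 200-bp window
    p_down_given_element: float = 0.35
    p_down_given_no_element: float = 0.15
    deg_q: float = 0.01                  # adjusted p assigned to true DEGs
    reject_spontaneous: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("element_rate", "p_enriched_given_element", "p_enriched_background",
                     "p_down_given_element", "p_down_given_no_element", "deg_q"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if self.background_depth <= 0:
            raise ValueError("background_depth must be > 0")
        if self.enrichment_profile not in ("five_prime", "three_prime"):
            raise ValueError("enrichment_profile must be 'five_prime' or 'three_prime'")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset, keyed by gene_id."""

    element_genes: set[str] = field(default_factory=set)
    enriched_genes: set[str] = field(default_factory=set)
    down_genes: set[str] = field(default_factory=set)
    seed: int = 0


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from a master seed."""
    key = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))


def simulate_annotation(cfg: SimConfig) -> Annotation:
    """Place non-overlapping genes with random strands along one chromosome."""
    rng = stage_rng(cfg.seed, "annotation")
    genes = []
    pos = int(rng.integers(cfg.intergenic_min, cfg.intergenic_max + 1))
    width = len(str(max(cfg.n_genes, 1)))
    for i in range(cfg.n_genes):
        glen = int(rng.integers(cfg.gene_len_min, cfg.gene_len_max + 1))
        if pos + glen > cfg.chrom_len:
            raise ValueError(
                f"gene {i} does not fit in chrom_len={cfg.chrom_len}; "
                "increase chrom_len or reduce n_genes/gene lengths"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i:0{width}d}", cfg.chrom, pos, pos + glen, strand))
        pos += glen + int(rng.integers(cfg.intergenic_min, cfg.intergenic_max + 1))
    return Annotation(genes, {cfg.chrom: cfg.chrom_len})


def _promoter_genomic_interval(gene: GeneModel, upstream: int, chrom_len: int) -> tuple[int, int]:
    if gene.strand == "+":
        return max(0, gene.start - upstream), gene.start
    return gene.end, min(chrom_len, gene.end + upstream)


def simulate_sequences(
    annotation: Annotation, cfg: SimConfig
) -> tuple[dict[str, str], set[str]]:
    """Random genome with planted promoter elements; returns (genome, truth set).

    With ``reject_spontaneous`` (default) every chance occurrence of the
    element (either orientation) inside any promoter window is resampled away
    before planting, so a promoter contains the element iff it was planted.
    Planted copies sit at a uniform TSS-relative offset in [-2000, -8] and are
    kept out of every other gene's promoter window so the truth set stays
    exact; a gene whose promoter is too truncated to host the element is
    skipped with a warning.
    """
    rng = stage_rng(cfg.seed, "sequences")
    chrom_len = annotation.chrom_sizes[cfg.chrom]
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seq = rng.choice(bases, size=chrom_len).astype("U1")
    pattern = cfg.element.upper()
    n = len(pattern)

    prom_ivs = {
        g.gene_id: _promoter_genomic_interval(g, cfg.promoter_len, chrom_len)
        for g in annotation
    }

    def genome_str() -> dict[str, str]:
        return {cfg.chrom: "".join(seq)}

    if cfg.reject_spontaneous:
        for _round in range(100):
            genome = genome_str()
            dirty = False
            for g in annotation:
                prom = extract_promoter(g, genome, upstream=cfg.promoter_len)
                hits = scan_pattern(prom.sequence, pattern, both_strands=True, gene_id=g.gene_id)
                for h in hits:
                    offset = h.tss_start + prom.length
                    if g.strand == "+":
                        gs = prom.genomic_start + offset
                    else:
                        gs = prom.genomic_end - offset - n
                    seq[gs : gs + n] = rng.choice(bases, size=n).astype("U1")
                    dirty = True
            if not dirty:
                break
        else:
            raise RuntimeError("spontaneous-element rejection did not converge")

    element_genes: set[str] = set()
    order = annotation.gene_ids()
    chosen = [gid for gid in order if rng.random() < cfg.element_rate]
    other_proms = {gid: [iv for g2, iv in prom_ivs.items() if g2 != gid] for gid in chosen}
    for gid in chosen:
        gene = annotation[gid]
        p_lo, p_hi = prom_ivs[gid]
        if p_hi - p_lo < n + 7:  # too truncated to host the element at t <= -8
            logger.warning("promoter of %s too short to plant element; skipped", gid)
            continue
        planted = False
        for _try in range(200):
            t = int(rng.integers(-cfg.promoter_len, -7))  # TSS-relative 5' offset, [-2000, -8]
            if gene.strand == "+":
                gs = gene.start + t
            else:
                gs = gene.end - t - n
            if gs < 0 or gs + n > chrom_len:
                continue
            if gene.strand == "+":
                if not (p_lo <= gs and gs + n <= p_hi):
                    continue
            else:
                if not (p_lo <= gs and gs + n <= p_hi):
                    continue
            if any(gs < e and gs + n > s for s, e in other_proms[gid]):
                continue
            word = pattern if gene.strand == "+" else revcomp(pattern)
            seq[gs : gs + n] = np.array(list(word), dtype="U1")
            planted = True
            break
        if planted:
            element_genes.add(gid)
        else:
            logger.warning("could not plant element for %s without touching another promoter", gid)
    return genome_str(), element_genes


def choose_enriched(annotation: Annotation, element_genes: set[str], cfg: SimConfig) -> set[str]:
    """Draw the H3K36me3-enriched gene set; the element raises the odds."""
    rng = stage_rng(cfg.seed, "enriched")
    out = set()
    for gid in annotation.gene_ids():
        p = cfg.p_enriched_given_element if gid in element_genes else cfg.p_enriched_background
        if rng.random() < p:
            out.add(gid)
    return out


def _enriched_region(gene: GeneModel, cfg: SimConfig) -> tuple[int, int]:
    """Genomic half-open span carrying the ChIP enrichment (strand-aware)."""
    L = cfg.enrichment_len
    if cfg.enrichment_profile == "five_prime":
        # [TSS, TSS + L) in gene orientation
        if gene.strand == "+":
            return gene.start, gene.start + L
        return gene.end - L, gene.end
    # three_prime: [TES - L, TES] in gene orientation
    if gene.strand == "+":
        return gene.end - L, gene.end
    return gene.start, gene.start + L


def simulate_coverage(
    annotation: Annotation, truth: SimulationTruth, cfg: SimConfig
) -> tuple[CoverageTrack, CoverageTrack]:
    """Poisson window coverage for ChIP and input.

    Input windows draw Poisson(d); ChIP windows draw Poisson(d * (1 +
    (fold - 1) * overlap_fraction)) where overlap_fraction is the part of the
    window inside an enriched region, so fully interior windows have mean
    fold * d.  Counts are emitted as bedGraph-style per-base values such that
    window mass / read_length recovers the counts exactly.
    """
    rng = stage_rng(cfg.seed, "coverage")
    chrom_len = annotation.chrom_sizes[cfg.chrom]
    W = SIM_WINDOW
    edges = np.arange(0, chrom_len + W, W, dtype=np.int64)
    edges[-1] = chrom_len
    if edges[-1] == edges[-2]:
        edges = edges[:-1]
    widths = np.diff(edges)
    n_win = len(widths)

    overlap = np.zeros(n_win)
    for gid in sorted(truth.enriched_genes):
        lo, hi = _enriched_region(annotation[gid], cfg)
        lo, hi = max(lo, 0), min(hi, chrom_len)
        o = np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo)
        overlap += np.clip(o, 0, None)
    frac = np.clip(overlap / widths, 0.0, 1.0)

    d = cfg.background_depth * widths / W  # partial last window scales down
    lam_input = d
    lam_chip = d * (1.0 + (cfg.enrichment_fold - 1.0) * frac)
    input_counts = rng.poisson(lam_input)
    chip_counts = rng.poisson(lam_chip)

    def to_track(counts: np.ndarray) -> CoverageTrack:
        vals = counts * READ_LENGTH / widths
        ivs = [
            (int(s), int(e), float(v))
            for s, e, v in zip(edges[:-1], edges[1:], vals)
            if v > 0
        ]
        return CoverageTrack({cfg.chrom: ivs}, annotation.chrom_sizes, read_length=READ_LENGTH)

    return to_track(chip_counts), to_track(input_counts)


def simulate_deg(
    annotation: Annotation, truth: SimulationTruth, cfg: SimConfig
) -> tuple[list[DEGRecord], set[str]]:
    """DEG table in which down-regulation probability depends on the element.

    True down-regulated genes get log2fc = -log2(U), U ~ Uniform(1.5, 4) and
    q = deg_q; the rest get log2fc ~ Normal(0, 0.2) and q ~ Uniform(0.05, 1),
    so the standard (>1.5-fold down, q < 0.05) filter recovers the truth set.
    """
    rng = stage_rng(cfg.seed, "deg")
    records: list[DEGRecord] = []
    down: set[str] = set()
    for gid in annotation.gene_ids():
        p = cfg.p_down_given_element if gid in truth.element_genes else cfg.p_down_given_no_element
        if rng.random() < p:
            u = rng.uniform(1.5, 4.0)
            records.append(DEGRecord(gid, -float(np.log2(u)), cfg.deg_q))
            down.add(gid)
        else:
            lfc = float(rng.normal(0.0, 0.2))
            records.append(DEGRecord(gid, lfc, float(rng.uniform(0.05, 1.0))))
    return records, down


def simulate_dataset(cfg: SimConfig):
    """Run all generator stages; returns (annotation, genome, chip, input,
    deg_records, truth)."""
    annotation = simulate_annotation(cfg)
    genome, element_genes = simulate_sequences(annotation, cfg)
    truth = SimulationTruth(element_genes=element_genes, seed=cfg.seed)
    truth.enriched_genes = choose_enriched(annotation, element_genes, cfg)
    chip, inp = simulate_coverage(annotation, truth, cfg)
    deg, down = simulate_deg(annotation, truth, cfg)
    truth.down_genes = down
    return annotation, genome, chip, inp, deg, truth
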