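"""Scaled TSS->TES metagene profiles, input calibration and group comparison.

Each gene is summarised as a 900-bin vector: 300 fixed 10-bp bins over the
3 kb upstream of the TSS, 300 equal-fraction bins over the gene body (every
body is "fitted" to the same axis regardless of its true length), and 300
fixed 10-bp bins over the 3 kb downstream of the TES, always ordered 5'->3'
in gene orientation.  Per bin the ChIP signal is RPKM-normalised and
calibrated to the input as a ratio with a pseudocount, so the null value is
1 everywhere.  Bins that fall outside the chromosome are missing (NaN) and
excluded from aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import special

from .core_io import Annotation, CoverageTrack, GeneModel

__all__ = [
    "BinScheme",
    "MetageneProfile",
    "rpkm",
    "body_bin_edges",
    "gene_profile",
    "profile_genes",
    "aggregate_and_matrix",
    "tss_downstream_signal",
    "ks_two_sample",
    "plot_profile",
]


@dataclass(frozen=True)
class BinScheme:
    upstream_bp: int = 3000
    upstream_bins: int = 300
    body_bins: int = 300
    downstream_bp: int = 3000
    downstream_bins: int = 300

    @property
    def total_bins(self) -> int:
        return self.upstream_bins + self.body_bins + self.downstream_bins


@dataclass
class MetageneProfile:
    """Per-gene bin matrix plus the per-bin mean aggregate curve."""

    matrix: np.ndarray            # genes x total_bins, NaN = missing
    aggregate: np.ndarray         # per-bin mean over genes, missing ignored
    gene_ids: list[str]
    scheme: BinScheme


def rpkm(count: float, region_len_bp: float, library_size_reads: float) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if region_len_bp <= 0:
        raise ValueError("region length must be > 0")
    if library_size_reads <= 0:
        raise ValueError("library size must be > 0")
    return count / ((region_len_bp / 1000.0) * (library_size_reads / 1e6))


def body_bin_edges(start: int, end: int, n_bins: int) -> np.ndarray:
    """Equal-fraction partition of [start, end) into n_bins via cumulative
    rounding: every base belongs to exactly one bin; short bodies yield empty
    bins (zero width)."""
    return start + np.rint(np.arange(n_bins + 1) * (end - start) / n_bins).astype(np.int64)


def _gene_edges(gene: GeneModel, scheme: BinScheme) -> np.ndarray:
    """Ascending genomic bin edges over [start - up, end + down)."""
    up_w = scheme.upstream_bp // scheme.upstream_bins
    down_w = scheme.downstream_bp // scheme.downstream_bins
    left = gene.start - scheme.upstream_bp + np.arange(scheme.upstream_bins) * up_w
    body = body_bin_edges(gene.start, gene.end, scheme.body_bins)
    right = gene.end + np.arange(1, scheme.downstream_bins + 1) * down_w
    return np.concatenate((left, body, right))


def gene_profile(
    chip: CoverageTrack,
    input_track: CoverageTrack,
    gene: GeneModel,
    scheme: BinScheme = BinScheme(),
    pseudocount: float = 1.0,
    log2: bool = False,
) -> np.ndarray:
    """One gene's input-calibrated profile as a total_bins vector.

    Per bin: (rpkm_chip + c) / (rpkm_input + c).  Minus-strand genes are
    orientation-flipped so bin 0 is always the far upstream edge.  Bins
    clipped by a chromosome edge are NaN.
    """
    chrom_len = chip.chrom_sizes.get(gene.chrom)
    if chrom_len is None:
        raise KeyError(f"chromosome {gene.chrom!r} missing from coverage track")
    if gene.length > chrom_len:
        raise ValueError(f"gene {gene.gene_id} longer than its chromosome")
    edges = _gene_edges(gene, scheme)
    widths = np.diff(edges).astype(float)
    chip_counts = chip.bin_masses(gene.chrom, edges) / chip.read_length
    input_counts = input_track.bin_masses(gene.chrom, edges) / input_track.read_length

    with np.errstate(divide="ignore", invalid="ignore"):
        chip_r = chip_counts / ((widths / 1000.0) * (chip.library_size / 1e6))
        input_r = input_counts / ((widths / 1000.0) * (input_track.library_size / 1e6))
        vals = (chip_r + pseudocount) / (input_r + pseudocount)
    vals[widths <= 0] = np.nan                       # empty body bins
    vals[(edges[:-1] < 0) | (edges[1:] > chrom_len)] = np.nan  # truncated flanks
    if gene.strand == "-":
        vals = vals[::-1]
    if log2:
        vals = np.log2(vals)
    return vals


def profile_genes(
    chip: CoverageTrack,
    input_track: CoverageTrack,
    annotation_or_genes: Iterable[GeneModel] | Annotation,
    scheme: BinScheme = BinScheme(),
    pseudocount: float = 1.0,
    log2: bool = False,
) -> MetageneProfile:
    genes = list(annotation_or_genes)
    rows = [gene_profile(chip, input_track, g, scheme, pseudocount, log2) for g in genes]
    return aggregate_and_matrix(rows, [g.gene_id for g in genes], scheme)


def aggregate_and_matrix(
    profiles: Sequence[np.ndarray], gene_ids: Sequence[str], scheme: BinScheme = BinScheme()
) -> MetageneProfile:
    """Stack per-gene vectors (input order preserved) and average per bin,
    ignoring missing bins."""
    if len(profiles) == 0:
        raise ValueError("need at least one gene profile")
    if len(profiles) != len(gene_ids):
        raise ValueError("profiles and gene_ids differ in length")
    matrix = np.vstack(profiles)
    with np.errstate(invalid="ignore"):
        aggregate = np.nanmean(matrix, axis=0)
    return MetageneProfile(matrix=matrix, aggregate=aggregate, gene_ids=list(gene_ids), scheme=scheme)


def tss_downstream_signal(profile_row: np.ndarray, scheme: BinScheme = BinScheme()) -> float:
    """Mean over the scaled gene-body bins: the per-gene scalar used to
    compare groups of genes by their signal downstream of the TSS."""
    lo = scheme.upstream_bins
    hi = lo + scheme.body_bins
    body = np.asarray(profile_row)[lo:hi]
    if np.all(np.isnan(body)):
        return float("nan")
    return float(np.nanmean(body))


def ks_two_sample(group_a, group_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the maximum |ECDF_A - ECDF_B| evaluated at the pooled sorted values
    (which handles ties exactly); the two-sided p comes from the asymptotic
    Kolmogorov distribution at sqrt(n*m/(n+m)) * D.
    """
    a = np.sort(np.asarray(group_a, dtype=float))
    b = np.sort(np.asarray(group_b, dtype=float))
    if len(a) < 2 or len(b) < 2 or np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise ValueError("each group needs >= 2 finite values")
    pooled = np.concatenate((a, b))
    cdf_a = np.searchsorted(a, pooled, side="right") / len(a)
    cdf_b = np.searchsorted(b, pooled, side="right") / len(b)
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    en = np.sqrt(len(a) * len(b) / (len(a) + len(b)))
    p = float(np.clip(special.kolmogorov(en * d), 0.0, 1.0))
    return d, p


def plot_profile(profile: MetageneProfile, path, label: str = "ChIP/input") -> None:
    """Write a simple aggregate-curve PNG (TSS/TES boundaries marked)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = profile.scheme
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(np.arange(s.total_bins), profile.aggregate, lw=1.5)
    ax.axvline(s.upstream_bins, color="grey", ls="--", lw=0.8)
    ax.axvline(s.upstream_bins + s.body_bins, color="grey", ls="--", lw=0.8)
    ax.set_xticks([0, s.upstream_bins, s.upstream_bins + s.body_bins, s.total_bins - 1])
    ax.set_xticklabels([f"-{s.upstream_bp/1000:g}kb", "TSS", "TES", f"+{s.downstream_bp/1000:g}kb"])
    ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
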