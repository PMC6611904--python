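"""Data model, coordinate conventions, and flat-file I/O.

All genomic intervals are 0-based half-open internally.  The user-facing
TSS-relative convention (used only at the reporting boundary, see
:mod:`cismark.motifs`) is 1-based with no position 0: the TSS base is +1 and
the base immediately 5' of it is -1.

A :class:`GeneModel` anchors the two reference points of every downstream
computation: the transcription start site (TSS) and the transcription end
site (TES; some literature calls the latter "TTS").  For a + strand gene the
TSS is ``start`` and the TES is ``end - 1``; for a - strand gene the TSS is
``end - 1`` and the TES is ``start``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO

__all__ = [
    "GeneModel",
    "Annotation",
    "CoverageTrack",
    "DEGRecord",
    "read_fasta",
    "write_fasta",
    "read_genes_bed",
    "write_genes_bed",
    "read_coverage_bedgraph",
    "write_coverage_bedgraph",
    "read_reads_bed",
    "read_deg_table",
    "write_deg_table",
]

DEFAULT_READ_LENGTH = 50


@dataclass(frozen=True)
class GeneModel:
    """One gene: identifier, 0-based half-open coordinates and strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: need 0 <= start < end, got "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        """Genomic 0-based position of the transcription start site base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Genomic 0-based position of the transcription end site base."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


class Annotation:
    """An ordered, validated collection of gene models.

    Genes are kept sorted by (chrom, start, gene_id) so iteration order is
    deterministic across runs and platforms.
    """

    def __init__(self, genes: Iterable[GeneModel], chrom_sizes: Mapping[str, int]):
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
        seen: set[str] = set()
        for g in genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom!r}")
            if g.end > size:
                raise ValueError(
                    f"gene {g.gene_id}: end {g.end} beyond chromosome {g.chrom} length {size}"
                )
        self.genes: list[GeneModel] = genes
        self._by_id = {g.gene_id: g for g in genes}

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Annotation):
            return NotImplemented
        return self.genes == other.genes and self.chrom_sizes == other.chrom_sizes

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


class _ChromCoverage:
    """Sorted non-overlapping intervals with values on one chromosome."""

    __slots__ = ("starts", "ends", "values", "cum_mass")

    def __init__(self, starts: np.ndarray, ends: np.ndarray, values: np.ndarray):
        self.starts = starts
        self.ends = ends
        self.values = values
        # cum_mass[i] = total value*length mass of intervals 0..i-1
        self.cum_mass = np.concatenate(([0.0], np.cumsum(values * (ends - starts))))

    def prefix_mass(self, x) -> np.ndarray:
        """Coverage mass (value x length) in [0, x) for scalar or array x."""
        x = np.asarray(x)
        if len(self.starts) == 0:
            return np.zeros(x.shape)
        j = np.searchsorted(self.starts, x, side="left")
        m = self.cum_mass[j]
        has_prev = j > 0
        jp = np.where(has_prev, j - 1, 0)
        overhang = np.where(has_prev, np.maximum(self.ends[jp] - x, 0), 0)
        return m - self.values[jp] * overhang * has_prev


class CoverageTrack:
    """Per-chromosome interval coverage with read-count bookkeeping.

    ``library_size`` is the total coverage mass divided by the read length:
    for a track built from N reads of the configured length it recovers N.
    """

    def __init__(
        self,
        intervals: Mapping[str, Iterable[tuple[int, int, float]]],
        chrom_sizes: Mapping[str, int],
        read_length: int = DEFAULT_READ_LENGTH,
    ):
        if read_length <= 0:
            raise ValueError("read_length must be positive")
        self.chrom_sizes = dict(chrom_sizes)
        self.read_length = read_length
        self._chroms: dict[str, _ChromCoverage] = {}
        for chrom, ivs in intervals.items():
            ivs = sorted(ivs)
            starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
            values = np.array([v for _, _, v in ivs], dtype=float)
            if np.any(values < 0):
                raise ValueError(f"negative coverage value on {chrom}")
            if np.any(ends <= starts):
                raise ValueError(f"empty or inverted interval on {chrom}")
            if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping coverage intervals on {chrom}")
            size = self.chrom_sizes.get(chrom)
            if size is not None and len(ends) and ends[-1] > size:
                raise ValueError(f"coverage beyond end of {chrom}")
            self._chroms[chrom] = _ChromCoverage(starts, ends, values)
        total = sum(float(c.cum_mass[-1]) for c in self._chroms.values())
        self.library_size = total / read_length
        if self.library_size <= 0:
            raise ValueError("coverage track is empty: library_size must be > 0")

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        c = self._chroms[chrom]
        return c.starts, c.ends, c.values

    def mass(self, chrom: str, start: int, end: int) -> float:
        """Total value x length mass overlapping [start, end)."""
        c = self._chroms.get(chrom)
        if c is None:
            return 0.0
        lo, hi = c.prefix_mass([max(start, 0), max(end, 0)])
        return float(hi - lo)

    def bin_masses(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Coverage mass in each [edges[i], edges[i+1]) bin (edges ascending)."""
        c = self._chroms.get(chrom)
        if c is None:
            return np.zeros(len(edges) - 1)
        p = c.prefix_mass(np.clip(edges, 0, None))
        return np.diff(p)


@dataclass(frozen=True)
class DEGRecord:
    """Differential-expression record: log2 fold change (mutant vs wild type)
    and a multiple-testing adjusted p-value."""

    gene_id: str
    log2fc: float
    q_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"{self.gene_id}: q_value must lie in [0, 1], got {self.q_value}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a multi-record FASTA into {id: uppercase sequence}.

    Record ids are taken up to the first whitespace; duplicate ids and empty
    files are errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def write_fasta(path, seqs: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w", newline="") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED6 gene models


def read_genes_bed(path, chrom_sizes: Mapping[str, int]) -> Annotation:
    """Parse a BED6 file (chrom, start, end, name, score, strand) of genes.

    The score column is ignored.  Malformed lines raise with their line
    number; genes extending beyond ``chrom_sizes`` are rejected.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                g = GeneModel(name, chrom, int(start), int(end), strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            genes.append(g)
    try:
        return Annotation(genes, chrom_sizes)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_genes_bed(path, annotation: Annotation) -> None:
    with open(path, "w", newline="") as fh:
        for g in annotation:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph coverage


def read_coverage_bedgraph(
    path, chrom_sizes: Mapping[str, int], read_length: int = DEFAULT_READ_LENGTH
) -> CoverageTrack:
    """Parse a 4-column bedGraph into a validated :class:`CoverageTrack`.

    ``library_size`` is computed as sum(value x interval length) / read_length.
    Overlapping intervals and negative values are errors.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = fields
            v = float(value)
            if v < 0:
                raise ValueError(f"{path}:{lineno}: negative value {v}")
            per_chrom.setdefault(chrom, []).append((int(start), int(end), v))
    try:
        return CoverageTrack(per_chrom, chrom_sizes, read_length=read_length)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_coverage_bedgraph(path, track: CoverageTrack) -> None:
    with open(path, "w", newline="") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.intervals(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_reads_bed(
    path, chrom_sizes: Mapping[str, int], read_length: int = DEFAULT_READ_LENGTH
) -> CoverageTrack:
    """Convert raw single-end read intervals (BED) to coverage.

    Each read is counted at its midpoint base, which makes downstream window
    counts unambiguous; the resulting single-base intervals carry a value of
    ``read_length`` so the value x length mass of one read equals one read.
    """
    mids: dict[str, dict[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            mid = (start + end) // 2
            mids.setdefault(chrom, {}).setdefault(mid, 0)
            mids[chrom][mid] += 1
    per_chrom = {
        chrom: [(pos, pos + 1, count * read_length) for pos, count in sorted(d.items())]
        for chrom, d in mids.items()
    }
    return CoverageTrack(per_chrom, chrom_sizes, read_length=read_length)


# ---------------------------------------------------------------------------
# DEG tables


def read_deg_table(path) -> list[DEGRecord]:
    """Read a TSV with header columns gene_id, log2fc, q_value."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "q_value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    return [
        DEGRecord(str(r.gene_id), float(r.log2fc), float(r.q_value))
        for r in df.itertuples(index=False)
    ]


def write_deg_table(path, records: Iterable[DEGRecord]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("gene_id\tlog2fc\tq_value\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.log2fc:.6g}\t{r.q_value:.6g}\n")
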