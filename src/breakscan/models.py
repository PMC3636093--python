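"""Shared genomic data model.

All internal coordinates are 0-based, half-open. Exons are kept in
*transcript* order: for a minus-strand gene the first exon is the one with
the largest genomic coordinates, so "proximal" always means 5' of the
transcript and "distal" means 3'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

FUSION_ROLES = frozenset({"five_prime", "three_prime", "either"})


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene model.

    ``exons`` (and ``cds``, when present) are ``(start, end)`` genomic
    intervals in transcript order. ``tx_length`` is the spliced length.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: Optional[tuple[tuple[int, int], ...]] = None
    tx_length: int = field(default=0)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError(f"{self.gene_id}: gene model needs >=1 exon")
        for s, e in exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon interval ({s},{e})")
        # transcript order: ascending genomic on +, descending on -
        starts = [s for s, _ in exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise ValueError(f"{self.gene_id}: exons not in transcript order")
        genomic = sorted(exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if self.cds is not None:
            cds = tuple((int(s), int(e)) for s, e in self.cds)
            object.__setattr__(self, "cds", cds)
            for cs, ce in cds:
                if not any(s <= cs and ce <= e for s, e in exons):
                    raise ValueError(f"{self.gene_id}: CDS interval ({cs},{ce}) not contained in an exon")
        length = sum(e - s for s, e in exons)
        object.__setattr__(self, "tx_length", length)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) of the whole gene body."""
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    def exon_tx_bounds(self) -> list[tuple[int, int]]:
        """Transcript-coordinate (start, end) of each exon, transcript order."""
        out, off = [], 0
        for s, e in self.exons:
            out.append((off, off + (e - s)))
            off += e - s
        return out

    def genomic_to_tx(self, pos: int) -> Optional[int]:
        """Map a genomic position to a transcript offset, or None if intronic."""
        off = 0
        for s, e in self.exons:
            if s <= pos < e:
                return off + (pos - s if self.strand == "+" else e - 1 - pos)
            off += e - s
        return None

    def cds_tx_interval(self) -> Optional[tuple[int, int]]:
        """CDS as a (start, end) transcript-coordinate interval."""
        if not self.cds:
            return None
        offs = []
        for cs, ce in self.cds:
            a = self.genomic_to_tx(cs if self.strand == "+" else ce - 1)
            b = self.genomic_to_tx(ce - 1 if self.strand == "+" else cs)
            offs.extend((a, b))
        return min(offs), max(offs) + 1


@dataclass
class ExonProfile:
    """Ordered exon-level log2 expression for one gene in one sample."""

    gene_id: str
    sample_id: str
    values: np.ndarray
    exon_indices: Optional[np.ndarray] = None  # kept when missing exons were dropped

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError(f"{self.gene_id}/{self.sample_id}: profile needs >=2 exon values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.gene_id}/{self.sample_id}: non-finite values after missing-value drop")

    @property
    def n_exons(self) -> int:
        return int(self.values.size)


@dataclass
class ProbeTrack:
    """Chromosome-ordered copy-number probes for one sample."""

    sample_id: str
    chrom: str
    positions: np.ndarray
    ratios: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.positions.shape != self.ratios.shape or self.positions.ndim != 1:
            raise ValueError("positions and ratios must be 1-D and equal length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly ascending")

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class CensusGene:
    """Cancer-gene-list entry with its allowed fusion orientation."""

    gene_id: str
    fusion_role: str
    notes: str = ""
    locus: Optional[GeneModel] = None

    def __post_init__(self):
        if self.fusion_role not in FUSION_ROLES:
            raise ValueError(f"{self.gene_id}: unknown fusion role {self.fusion_role!r}")


@dataclass(frozen=True)
class Read:
    """One aligned (or unaligned) read end."""

    chrom: str
    start: int
    end: int
    strand: str
    mapped: bool
    sequence: str = ""

    def __post_init__(self):
        if self.mapped and self.end <= self.start:
            raise ValueError("mapped read must have positive length")


@dataclass(frozen=True)
class MatePair:
    pair_id: str
    read1: Read
    read2: Read

    def __post_init__(self):
        if not (self.read1.mapped or self.read2.mapped):
            raise ValueError(f"{self.pair_id}: at least one read must be mapped")


@dataclass
class CnaSegment:
    """A smoothed copy-number alteration.

    Probe indices are 0-based half-open into the source ProbeTrack; genomic
    start/end positions cover [positions[start_probe], positions[end_probe-1]+1).
    """

    sample_id: str
    chrom: str
    start_probe: int
    end_probe: int
    start_pos: int
    end_pos: int
    mean_log2: float
    level: str  # standard | high
    sign: str  # gain | loss

    def __post_init__(self):
        n = self.end_probe - self.start_probe
        if self.level not in ("standard", "high"):
            raise ValueError(f"bad level {self.level!r}")
        if self.level == "standard" and (n < 50 or abs(self.mean_log2) < 0.3):
            raise ValueError("standard segment violates >=50 probes / |mean|>=0.3")
        if self.level == "high" and (n < 10 or abs(self.mean_log2) < 1.0):
            raise ValueError("high segment violates >=10 probes / |mean|>=1.0")
        if self.sign != ("gain" if self.mean_log2 > 0 else "loss"):
            raise ValueError("sign inconsistent with mean_log2")

    @property
    def n_probes(self) -> int:
        return self.end_probe - self.start_probe


@dataclass
class CnaBreakpoint:
    """A copy-number transition falling strictly inside a gene body."""

    gene_id: str
    sample_id: str
    boundary_pos: int
    boundary_side: str  # upper_5prime | lower_3prime: transcript end covered by the CNA
    transition: str  # gain_starts | gain_ends | loss_starts | loss_ends
    segment: CnaSegment
    focal: bool


@dataclass
class ChimericHit:
    """An unmapped read rescued onto an exon-exon junction sequence."""

    read_name: str
    exon5_index: int  # 1-based exon of the 5' gene ending at the junction
    exon3_index: int  # 1-based exon of the 3' gene starting at the junction
    mismatches: int
    truncated: bool = False


@dataclass
class FusionCandidate:
    gene5: str
    gene3: str
    support_pairs: list
    chimeric_reads: list
    junction: Optional[tuple[int, int]]  # (last exon of gene5, first exon of gene3), 1-based
    median_insert: Optional[float]
    frame: str = "unknown"
    ambiguous: bool = False
    notes: str = ""

    @property
    def support(self) -> int:
        return len(self.support_pairs) + len(self.chimeric_reads)
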