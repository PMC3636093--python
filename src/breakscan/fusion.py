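"""Paired-end fusion-partner nomination.

Given a candidate rearranged gene (from RBA/DBA), mine a paired-end
RNA-seq alignment for mate pairs with one read in that gene and the other
elsewhere; cluster the stray mates by the gene they hit; drop likely
readthrough artifacts (adjacent same-strand gene pairs); rescue unmapped
mates by ungapped alignment against candidate exon-exon junction
sequences; and keep candidates with >=2 supporting reads and a median
predicted fragment length between 100 and 400 nt. Finally, call the
reading-frame status of the chimeric coding sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pysam
from Bio import SeqIO

from .models import ChimericHit, FusionCandidate, GeneModel, MatePair, Read

logger = logging.getLogger(__name__)

INSERT_MIN, INSERT_MAX = 100, 400
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# SAM input
# ---------------------------------------------------------------------------

def read_mate_pairs(path: Union[str, Path], max_mismatches: Optional[int] = 2) -> list[MatePair]:
    """Load name-paired reads from SAM/BAM into MatePair records.

    Reads carrying an NM tag above ``max_mismatches`` are treated as
    unmapped (the mapping-stage mismatch rule); records with malformed
    pairing flags are skipped and counted.
    """
    ends: dict[str, dict[int, pysam.AlignedSegment]] = {}
    n_bad = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if not rec.is_paired or rec.is_secondary or rec.is_supplementary:
                n_bad += int(not rec.is_paired)
                continue
            if rec.is_read1 == rec.is_read2:
                n_bad += 1
                continue
            ends.setdefault(rec.query_name, {})[1 if rec.is_read1 else 2] = rec
    if n_bad:
        logger.warning("skipped %d records with malformed pairing flags", n_bad)

    def to_read(rec: pysam.AlignedSegment) -> Read:
        mapped = not rec.is_unmapped
        if mapped and max_mismatches is not None and rec.has_tag("NM"):
            mapped = rec.get_tag("NM") <= max_mismatches
        seq = rec.query_sequence or ""
        if rec.is_reverse and seq:
            seq = revcomp(seq)  # store in original read orientation
        if not mapped:
            return Read(chrom="*", start=0, end=0, strand="+", mapped=False, sequence=seq)
        return Read(
            chrom=rec.reference_name,
            start=rec.reference_start,
            end=rec.reference_end,
            strand="-" if rec.is_reverse else "+",
            mapped=True,
            sequence=seq,
        )

    pairs = []
    n_unanchored = 0
    for name, by_end in ends.items():
        if len(by_end) != 2:
            n_bad += 1
            continue
        r1, r2 = to_read(by_end[1]), to_read(by_end[2])
        if not (r1.mapped or r2.mapped):
            n_unanchored += 1  # no mapped end: cannot enter the pipeline
            continue
        pairs.append(MatePair(pair_id=name, read1=r1, read2=r2))
    if n_unanchored:
        logger.info("dropped %d pairs with no mapped end", n_unanchored)
    return pairs


def read_transcripts(path: Union[str, Path]) -> dict[str, str]:
    """Transcript FASTA -> {gene_id: sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# anchored-pair extraction and partner nomination
# ---------------------------------------------------------------------------

def _overlaps_exons(read: Read, gene: GeneModel) -> bool:
    if not read.mapped or read.chrom != gene.chrom:
        return False
    return any(read.start < e and s < read.end for s, e in gene.exons)


def extract_anchored_pairs(
    alignments: Union[str, Path, Iterable[MatePair]], anchor_gene: GeneModel
) -> list[MatePair]:
    """Pairs with exactly one read in the anchor gene's exons.

    The mate must map to a different locus (outside the anchor gene) or be
    unmapped (those are routed to chimeric-read rescue downstream). Pairs
    with both reads inside the anchor are concordant and excluded.
    """
    pairs = (
        read_mate_pairs(alignments)
        if isinstance(alignments, (str, Path))
        else list(alignments)
    )
    out = []
    for p in pairs:
        in1 = _overlaps_exons(p.read1, anchor_gene)
        in2 = _overlaps_exons(p.read2, anchor_gene)
        if in1 == in2:
            continue
        out.append(p)
    return out


@dataclass
class Nomination:
    """A candidate partner locus with its supporting pairs."""

    partner_id: str
    partner_model: Optional[GeneModel]
    pairs: list[MatePair] = field(default_factory=list)
    ambiguous: bool = False


def nominate_partners(
    pairs: Sequence[MatePair],
    models: Sequence[GeneModel],
    anchor_gene: GeneModel,
    min_cluster: int = 2,
    bin_size: int = 100_000,
) -> list[Nomination]:
    """Group stray mates by the annotated gene they overlap.

    Mates overlapping two genes are assigned to both and flagged ambiguous;
    intergenic mates are grouped into ``bin_size`` genomic bins and reported
    as unannotated loci. ``min_cluster`` is informational here — clusters
    below it are removed later by the support filter, not dropped now.
    """
    noms: dict[str, Nomination] = {}
    for p in pairs:
        mate = p.read2 if _overlaps_exons(p.read1, anchor_gene) else p.read1
        if not mate.mapped:
            continue  # unmapped mates enter via chimeric rescue
        hits = [
            m
            for m in models
            if m.gene_id != anchor_gene.gene_id and _overlaps_exons(mate, m)
        ]
        if hits:
            for m in hits:
                nom = noms.setdefault(m.gene_id, Nomination(m.gene_id, m))
                nom.pairs.append(p)
                if len(hits) > 1:
                    nom.ambiguous = True
        else:
            b = mate.start // bin_size
            key = f"{mate.chrom}:{b * bin_size}-{(b + 1) * bin_size}"
            noms.setdefault(key, Nomination(key, None)).pairs.append(p)
    out = sorted(noms.values(), key=lambda n: (-len(n.pairs), n.partner_id))
    return out


def _adjacent_same_strand(a: GeneModel, b: GeneModel, models: Sequence[GeneModel]) -> bool:
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    (s1, e1), (s2, e2) = sorted([a.span, b.span])
    gap_lo, gap_hi = e1, s2
    if gap_hi < gap_lo:  # overlapping genes: trivially adjacent
        return True
    for m in models:
        if m.gene_id in (a.gene_id, b.gene_id) or m.chrom != a.chrom:
            continue
        ms, me = m.span
        if ms < gap_hi and me > gap_lo:
            return False  # an intervening gene breaks adjacency
    return True


def readthrough_filter(
    nominations: Sequence[Nomination],
    models: Sequence[GeneModel],
    anchor_gene: GeneModel,
) -> list[Nomination]:
    """Drop partners immediately adjacent to the anchor on the same strand.

    Such pairs are likely transcriptional readthrough, not rearrangement.
    Same-strand genes with any intervening annotated gene (CEP85L/ROS1-like,
    ~1 Mb apart) are not adjacent and survive.
    """
    kept = []
    for nom in nominations:
        if nom.partner_model is not None and not _adjacent_same_strand(
            anchor_gene, nom.partner_model, models
        ):
            kept.append(nom)
        elif nom.partner_model is None:
            kept.append(nom)
    return kept


# ---------------------------------------------------------------------------
# chimeric junction-read rescue
# ---------------------------------------------------------------------------

def rescue_chimeric_reads(
    unmapped: Sequence[tuple[str, str]],
    gene5: GeneModel,
    gene3: GeneModel,
    transcripts: dict[str, str],
    max_mismatches: int = 2,
    try_revcomp: bool = True,
) -> list[ChimericHit]:
    """Ungapped alignment of unmapped reads to exon-exon junction sequences.

    For every ordered exon pair (exon i of ``gene5``, exon j of ``gene3``)
    the junction string is built from read_length-1 nt either side of the
    junction; each read is slid across every offset that leaves >=1 nt on
    both sides. A hit needs <= ``max_mismatches``; the best (fewest
    mismatches, then lowest (i, j)) junction per read is reported. Reads
    longer than the available context are evaluated on the truncated
    context and flagged.

    ``unmapped`` is a list of (read_name, sequence).
    """
    tx5, tx3 = transcripts[gene5.gene_id], transcripts[gene3.gene_id]
    bounds5 = gene5.exon_tx_bounds()
    bounds3 = gene3.exon_tx_bounds()
    hits: list[ChimericHit] = []
    for name, seq in unmapped:
        seq = seq.upper()
        L = len(seq)
        if L == 0:
            continue
        variants = [seq, revcomp(seq)] if try_revcomp else [seq]
        best: Optional[ChimericHit] = None
        for i, (_, e5) in enumerate(bounds5, start=1):
            left = tx5[max(0, e5 - (L - 1)) : e5]
            for j, (s3, _) in enumerate(bounds3, start=1):
                right = tx3[s3 : s3 + (L - 1)]
                junction = left + right
                truncated = len(left) < L - 1 or len(right) < L - 1
                mid = len(left)  # junction point index in `junction`
                for read in variants:
                    for off in range(max(0, mid - L + 1), min(mid, len(junction) - L) + 1):
                        mm = sum(a != b for a, b in zip(read, junction[off : off + L]))
                        if mm > max_mismatches:
                            continue
                        cand = ChimericHit(name, i, j, mm, truncated)
                        if best is None or (cand.mismatches, cand.exon5_index, cand.exon3_index) < (
                            best.mismatches,
                            best.exon5_index,
                            best.exon3_index,
                        ):
                            best = cand
        if best is not None:
            hits.append(best)
    return hits


# ---------------------------------------------------------------------------
# support / insert filtering and frame prediction
# ---------------------------------------------------------------------------

def _tx_interval(read: Read, gene: GeneModel) -> Optional[tuple[int, int]]:
    a = gene.genomic_to_tx(read.start)
    b = gene.genomic_to_tx(read.end - 1)
    if a is None or b is None:
        return None
    return (min(a, b), max(a, b) + 1)


def _estimate_junction_from_reads(
    pairs: Sequence[MatePair], gene5: GeneModel, gene3: GeneModel
) -> Optional[tuple[int, int]]:
    """Nearest exon boundaries compatible with every supporting pair."""
    max_end5, min_start3 = None, None
    for p in pairs:
        for read in (p.read1, p.read2):
            if _overlaps_exons(read, gene5):
                iv = _tx_interval(read, gene5)
                if iv:
                    max_end5 = iv[1] if max_end5 is None else max(max_end5, iv[1])
            elif _overlaps_exons(read, gene3):
                iv = _tx_interval(read, gene3)
                if iv:
                    min_start3 = iv[0] if min_start3 is None else min(min_start3, iv[0])
    if max_end5 is None or min_start3 is None:
        return None
    i5 = next((k for k, (_, e) in enumerate(gene5.exon_tx_bounds(), 1) if e >= max_end5), None)
    j3 = None
    for k, (s, _) in enumerate(gene3.exon_tx_bounds(), 1):
        if s <= min_start3:
            j3 = k
    if i5 is None or j3 is None:
        return None
    return (i5, j3)


def predicted_insert(
    pair: MatePair, gene5: GeneModel, gene3: GeneModel, junction: tuple[int, int]
) -> Optional[float]:
    """Fragment length of one discordant pair in fusion-transcript coordinates."""
    j5_tx = gene5.exon_tx_bounds()[junction[0] - 1][1]
    j3_tx = gene3.exon_tx_bounds()[junction[1] - 1][0]
    r5 = r3 = None
    for read in (pair.read1, pair.read2):
        if _overlaps_exons(read, gene5):
            r5 = _tx_interval(read, gene5)
        elif _overlaps_exons(read, gene3):
            r3 = _tx_interval(read, gene3)
    if r5 is None or r3 is None:
        return None
    len5, len3 = r5[1] - r5[0], r3[1] - r3[0]
    return float((j5_tx - r5[1]) + (r3[0] - j3_tx) + len5 + len3)


def support_and_insert_filter(
    nomination: Nomination,
    gene5: GeneModel,
    gene3: GeneModel,
    chimeric: Sequence[ChimericHit] = (),
    min_support: int = 2,
) -> Optional[FusionCandidate]:
    """Assemble one FusionCandidate; None when support/insert filters fail.

    The junction is taken from the chimeric reads when any exist (modal
    (i, j), lowest on ties), else the nearest exon boundaries compatible
    with all supporting pairs. Chimeric reads and discordant pairs pool
    toward the >=``min_support`` threshold. The candidate is removed unless
    the median predicted fragment length lies in [100, 400] nt; with no
    junction estimate the insert filter is skipped and the candidate
    flagged.
    """
    pairs = list(nomination.pairs)
    if len(pairs) + len(chimeric) < min_support:
        return None
    junction: Optional[tuple[int, int]] = None
    if chimeric:
        counts: dict[tuple[int, int], int] = {}
        for h in chimeric:
            counts[(h.exon5_index, h.exon3_index)] = counts.get((h.exon5_index, h.exon3_index), 0) + 1
        junction = min(counts, key=lambda k: (-counts[k], k))
    else:
        junction = _estimate_junction_from_reads(pairs, gene5, gene3)

    median_insert = None
    notes = ""
    if junction is None:
        notes = "no junction estimable; insert filter skipped"
    else:
        inserts = [
            ins
            for p in pairs
            if (ins := predicted_insert(p, gene5, gene3, junction)) is not None
        ]
        if inserts:
            median_insert = float(np.median(inserts))
            if not (INSERT_MIN <= median_insert <= INSERT_MAX):
                return None
        else:
            notes = "no pair spans both genes; insert filter skipped"
    return FusionCandidate(
        gene5=gene5.gene_id,
        gene3=gene3.gene_id,
        support_pairs=pairs,
        chimeric_reads=list(chimeric),
        junction=junction,
        median_insert=median_insert,
        ambiguous=nomination.ambiguous,
        notes=notes,
    )


def predict_frame(
    candidate: FusionCandidate, gene5: GeneModel, gene3: GeneModel
) -> str:
    """in_frame / out_of_frame / unknown for an exon-boundary junction.

    The fused CDS keeps the downstream gene's reading frame iff the coding
    length contributed by the 5' gene is congruent (mod 3) to the junction's
    offset within the 3' gene's codon structure. Junctions in either gene's
    UTR return "unknown" (a junction upstream of the 3' gene's start codon
    leaves translation to a possible internal ATG).
    """
    if candidate.junction is None:
        return "unknown"
    cds5, cds3 = gene5.cds_tx_interval(), gene3.cds_tx_interval()
    if cds5 is None or cds3 is None:
        return "unknown"
    j5_tx = gene5.exon_tx_bounds()[candidate.junction[0] - 1][1]
    j3_tx = gene3.exon_tx_bounds()[candidate.junction[1] - 1][0]
    if j5_tx <= cds5[0] or j5_tx > cds5[1]:
        return "unknown"
    if j3_tx < cds3[0]:
        candidate.notes = (candidate.notes + "; " if candidate.notes else "") + "internal ATG possible"
        return "unknown"
    if j3_tx >= cds3[1]:
        return "unknown"
    c5 = j5_tx - cds5[0]
    o3 = (j3_tx - cds3[0]) % 3
    return "in_frame" if c5 % 3 == o3 else "out_of_frame"


# ---------------------------------------------------------------------------
# full per-anchor pipeline
# ---------------------------------------------------------------------------

def nominate_fusions(
    alignments: Union[str, Path, Iterable[MatePair]],
    anchor_gene: GeneModel,
    models: Sequence[GeneModel],
    transcripts: dict[str, str],
    min_support: int = 2,
    max_mismatches: int = 2,
    allow_intragenic: bool = False,
) -> list[FusionCandidate]:
    """Run the whole nomination chain for one candidate rearranged gene.

    Orientation (which gene is the 5' partner) is resolved per nomination by
    trying both orders and keeping the one with more rescued chimeric reads
    (then higher support, then median insert closest to 300 nt). Candidates
    are returned ranked by (support, insert proximity to 300 nt).
    """
    all_pairs = (
        read_mate_pairs(alignments, max_mismatches)
        if isinstance(alignments, (str, Path))
        else list(alignments)
    )
    pairs = extract_anchored_pairs(all_pairs, anchor_gene)
    noms = nominate_partners(pairs, models, anchor_gene)
    noms = readthrough_filter(noms, models, anchor_gene)

    def rescue_fodder(partner: GeneModel) -> list[tuple[str, str]]:
        # pairs with one read in either fusion gene and an unmapped mate
        fodder = []
        for p in all_pairs:
            for mapped, mate in ((p.read1, p.read2), (p.read2, p.read1)):
                if (
                    not mate.mapped
                    and mate.sequence
                    and (_overlaps_exons(mapped, anchor_gene) or _overlaps_exons(mapped, partner))
                ):
                    fodder.append((p.pair_id, mate.sequence))
        return fodder

    candidates: list[FusionCandidate] = []
    for nom in noms:
        if nom.partner_model is None:
            continue  # unannotated bins are reported by nominate_partners only
        if not allow_intragenic and nom.partner_model.gene_id == anchor_gene.gene_id:
            continue
        best: Optional[FusionCandidate] = None
        best_key = None
        fodder = rescue_fodder(nom.partner_model)
        for g5, g3 in ((anchor_gene, nom.partner_model), (nom.partner_model, anchor_gene)):
            chim = (
                rescue_chimeric_reads(fodder, g5, g3, transcripts, max_mismatches)
                if fodder
                else []
            )
            cand = support_and_insert_filter(nom, g5, g3, chim, min_support)
            if cand is None:
                continue
            prox = -abs((cand.median_insert or 1e9) - 300.0)
            key = (len(cand.chimeric_reads), cand.support, prox)
            if best is None or key > best_key:
                best, best_key = cand, key
        if best is not None:
            best.frame = predict_frame(
                best,
                anchor_gene if best.gene5 == anchor_gene.gene_id else nom.partner_model,
                anchor_gene if best.gene3 == anchor_gene.gene_id else nom.partner_model,
            )
            candidates.append(best)
    candidates.sort(
        key=lambda c: (-c.support, abs((c.median_insert or 1e9) - 300.0), c.gene5, c.gene3)
    )
    return candidates
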