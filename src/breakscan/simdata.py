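"""Synthetic data with planted ground truth for all three input modalities.

Everything is a pure function of the configuration's seed: exon-level
expression matrices with a planted step at a chosen junction, piecewise-
constant copy-number tracks with Gaussian probe noise, and paired-end
reads sampled from planted chimeric transcripts over a random synthetic
genome. Truth tables accompany every generator so downstream calls can be
scored automatically.

Synthetic genes are intronless: exons abut back-to-back on the genome, so
genomic and transcript coordinates coincide up to the gene's offset and
SAM records stay a plain ``<len>M``. Exon boundaries remain as junction
landmarks, which is all the breakpoint machinery observes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fusion import revcomp
from .models import ExonProfile, GeneModel, ProbeTrack

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeConfig:
    n_transcripts: int = 6
    exons_range: tuple[int, int] = (8, 20)
    exon_len_range: tuple[int, int] = (100, 300)
    gap_range: tuple[int, int] = (500, 2000)
    utr_len: int = 30  # UTR on each end of the CDS


@dataclass(frozen=True)
class PlantedFusion:
    gene5: str
    exon_i: int  # last exon of gene5 in the fusion (1-based)
    gene3: str
    exon_j: int  # first exon of gene3 in the fusion (1-based)
    n_pairs: int = 30
    insert_mean: float = 250.0
    insert_sd: float = 30.0
    read_len: int = 50
    error_rate: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    # expression
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (8, 20)
    n_samples: int = 4
    exon_noise_sd: float = 0.3
    planted_expression_breaks: tuple = ()  # (gene, sample, junction, step)
    # copy number
    n_probes: int = 500
    probe_noise_sd: float = 0.15
    probe_spacing: int = 1000
    planted_cnas: tuple = ()  # (chrom, start_probe, length, mean_log2)
    # reads
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    planted_fusions: tuple[PlantedFusion, ...] = ()
    n_background_pairs: int = 50


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def make_exon_matrix(cfg: SimConfig) -> tuple[list[ExonProfile], pd.DataFrame]:
    """i.i.d. normal exon baseline plus planted steps distal to a junction.

    Gene g in the planted list gets ``step`` added to every exon distal to
    junction j (1-based: exons j+1..n) in the named sample. Returns the
    profiles and a truth table (gene, sample, junction, step, n_exons).
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.exons_per_gene
    genes = [f"G{k:03d}" for k in range(cfg.n_genes)]
    n_exons = {g: int(rng.integers(lo, hi + 1)) for g in genes}
    samples = [f"S{k:02d}" for k in range(cfg.n_samples)]
    values = {
        (g, s): rng.normal(0.0, cfg.exon_noise_sd, size=n_exons[g])
        for g in genes
        for s in samples
    }
    truth_rows = []
    for gene, sample, junction, step in cfg.planted_expression_breaks:
        if gene not in n_exons:
            raise ValueError(f"unknown planted gene {gene}")
        n = n_exons[gene]
        if not 1 <= junction <= n - 1:
            raise ValueError(f"junction {junction} out of range for {gene} ({n} exons)")
        values[(gene, sample)][junction:] += step
        truth_rows.append(
            {"gene_id": gene, "sample_id": sample, "junction": junction, "step": step, "n_exons": n}
        )
    profiles = [
        ExonProfile(gene_id=g, sample_id=s, values=values[(g, s)]) for g in genes for s in samples
    ]
    return profiles, pd.DataFrame(truth_rows, columns=["gene_id", "sample_id", "junction", "step", "n_exons"])


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

def make_probe_tracks(cfg: SimConfig) -> tuple[list[ProbeTrack], pd.DataFrame]:
    """Piecewise-constant means plus Gaussian probe noise, one track/sample.

    Planted CNAs (keyed by chromosome) appear in every sample. Overlapping
    planted CNAs on one chromosome are an error. Truth table lists
    chromosome, probe-index boundaries and the planted mean.
    """
    rng = np.random.default_rng(cfg.seed)
    chroms = sorted({c for c, *_ in cfg.planted_cnas}) or ["chr1"]
    by_chrom: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chroms}
    for chrom, start, length, mean in cfg.planted_cnas:
        if start < 0 or start + length > cfg.n_probes:
            raise ValueError(f"planted CNA out of bounds on {chrom}")
        by_chrom[chrom].append((int(start), int(start + length), float(mean)))
    truth_rows = []
    for chrom, events in by_chrom.items():
        events.sort()
        for (s1, e1, _), (s2, _, _) in zip(events, events[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping planted CNAs on {chrom}")
        for s, e, m in events:
            truth_rows.append({"chrom": chrom, "start_probe": s, "end_probe": e, "mean_log2": m})

    samples = [f"S{k:02d}" for k in range(cfg.n_samples)]
    positions = cfg.probe_spacing * (1 + np.arange(cfg.n_probes, dtype=np.int64))
    tracks = []
    for chrom in chroms:
        signal = np.zeros(cfg.n_probes)
        for s, e, m in by_chrom[chrom]:
            signal[s:e] = m
        for sample in samples:
            tracks.append(
                ProbeTrack(
                    sample_id=sample,
                    chrom=chrom,
                    positions=positions.copy(),
                    ratios=signal + rng.normal(0.0, cfg.probe_noise_sd, size=cfg.n_probes),
                )
            )
    return tracks, pd.DataFrame(truth_rows, columns=["chrom", "start_probe", "end_probe", "mean_log2"])


# ---------------------------------------------------------------------------
# synthetic genome / transcriptome
# ---------------------------------------------------------------------------

def make_gene_models(cfg: SimConfig) -> tuple[dict[str, str], list[GeneModel], dict[str, str]]:
    """Random genome with intronless multi-exon genes on one chromosome.

    Returns (genome {chrom: seq}, gene models, transcripts {gene_id: seq}).
    Gene T000 onward, all plus-strand, each with a CDS inset by the
    configured UTR length and trimmed to a codon multiple.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    g = cfg.genome
    chrom = "chrS"
    pieces: list[str] = []
    models: list[GeneModel] = []
    transcripts: dict[str, str] = {}
    cursor = 0
    for k in range(g.n_transcripts):
        gap = int(rng.integers(*g.gap_range))
        pieces.append("".join(rng.choice(_BASES, size=gap)))
        cursor += gap
        n_ex = int(rng.integers(g.exons_range[0], g.exons_range[1] + 1))
        lens = rng.integers(g.exon_len_range[0], g.exon_len_range[1] + 1, size=n_ex)
        exons = []
        start = cursor
        for L in lens:
            exons.append((cursor, cursor + int(L)))
            cursor += int(L)
        tx_len = cursor - start
        seq = "".join(rng.choice(_BASES, size=tx_len))
        pieces.append(seq)
        cds_start = start + g.utr_len
        cds_end = cds_start + ((tx_len - 2 * g.utr_len) // 3) * 3
        cds = tuple(
            (max(s, cds_start), min(e, cds_end))
            for s, e in exons
            if max(s, cds_start) < min(e, cds_end)
        )
        gid = f"T{k:03d}"
        models.append(
            GeneModel(gene_id=gid, chrom=chrom, strand="+", exons=tuple(exons), cds=cds)
        )
        transcripts[gid] = seq
    pieces.append("".join(rng.choice(_BASES, size=500)))
    return {chrom: "".join(pieces)}, models, transcripts


# ---------------------------------------------------------------------------
# paired-end reads
# ---------------------------------------------------------------------------

@dataclass
class _SamRecord:
    qname: str
    flag: int
    rname: str
    pos: int  # 0-based; -1 for unmapped
    cigar: str
    seq: str
    nm: Optional[int]


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> tuple[str, int]:
    if error_rate <= 0:
        return seq, 0
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < error_rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr), int(hit.sum())


def make_fusion_reads(
    cfg: SimConfig, out_dir: str | Path
) -> tuple[Path, Path, Path, list[GeneModel], pd.DataFrame]:
    """Simulate a paired-end library over the synthetic genome.

    Fragments from each planted chimeric transcript follow the stated
    insert distribution with per-base substitution errors; both reads of a
    fragment are written as SAM against the synthetic genome, except reads
    overlapping the fusion junction, which are left unmapped (with their
    sequence) to exercise chimeric rescue. Background concordant pairs are
    sampled from wildtype transcripts. Writes ``reads.sam``,
    ``genome.fa``, ``transcripts.fa`` and ``models.gff3`` under
    ``out_dir``; returns the SAM path, transcript FASTA path, model path,
    the models, and the truth table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 2)
    genome, models, transcripts = make_gene_models(cfg)
    by_id = {m.gene_id: m for m in models}

    records: list[_SamRecord] = []
    truth_rows = []

    def genomic_pos(gene: GeneModel, tx_off: int) -> int:
        return gene.span[0] + tx_off  # plus-strand intronless genes

    def emit_pair(qid: str, frag_seq: str, read_len: int, error_rate: float, placer) -> None:
        """placer(tx_interval) -> (gene, tx_offset) or None for junction reads."""
        frag = len(frag_seq)
        r1 = frag_seq[:read_len]
        r2 = revcomp(frag_seq[frag - read_len :])
        r1, e1 = _mutate(rng, r1, error_rate)
        r2, e2 = _mutate(rng, r2, error_rate)
        spots = [(0, read_len, r1, e1, True), (frag - read_len, frag, r2, e2, False)]
        placed = [placer(s, e) for s, e, *_ in spots]
        for (s, e, seq, nerr, is_r1), hit in zip(spots, placed):
            flag = 0x1 | (0x40 if is_r1 else 0x80)
            if hit is None:
                flag |= 0x4
                records.append(_SamRecord(qid, flag, "*", -1, "*", seq, None))
            else:
                gene, off = hit
                if not is_r1:
                    flag |= 0x10
                mate = placed[0] if not is_r1 else placed[1]
                if mate is None:
                    flag |= 0x8
                genome_fwd = seq if is_r1 else revcomp(seq)
                records.append(
                    _SamRecord(
                        qid,
                        flag,
                        gene.chrom,
                        genomic_pos(gene, off),
                        f"{len(seq)}M",
                        genome_fwd,
                        nerr,
                    )
                )

    for fi, pf in enumerate(cfg.planted_fusions):
        g5, g3 = by_id[pf.gene5], by_id[pf.gene3]
        j5 = g5.exon_tx_bounds()[pf.exon_i - 1][1]
        j3 = g3.exon_tx_bounds()[pf.exon_j - 1][0]
        fusion_tx = transcripts[pf.gene5][:j5] + transcripts[pf.gene3][j3:]
        if pf.insert_mean < 2 * pf.read_len:
            raise ValueError("insert shorter than 2x read length")
        for k in range(pf.n_pairs):
            frag = int(round(rng.normal(pf.insert_mean, pf.insert_sd)))
            frag = max(frag, 2 * pf.read_len)
            lo = max(0, j5 - frag + 1)
            hi = min(j5 - 1, len(fusion_tx) - frag)
            if hi < lo:
                continue
            start = int(rng.integers(lo, hi + 1))
            frag_seq = fusion_tx[start : start + frag]

            def place(s: int, e: int, start=start, j5=j5, g5=g5, g3=g3, j3=j3):
                a, b = start + s, start + e  # fusion-transcript coords
                if b <= j5:
                    return (g5, a)
                if a >= j5:
                    return (g3, j3 + (a - j5))
                return None  # junction-spanning: unmapped

            emit_pair(f"fus{fi}_{k}", frag_seq, pf.read_len, pf.error_rate, place)
        truth_rows.append(
            {
                "gene5": pf.gene5,
                "exon_i": pf.exon_i,
                "gene3": pf.gene3,
                "exon_j": pf.exon_j,
                "n_pairs": pf.n_pairs,
                "insert_mean": pf.insert_mean,
            }
        )

    read_len = cfg.planted_fusions[0].read_len if cfg.planted_fusions else 50
    gene_ids = sorted(transcripts)
    for k in range(cfg.n_background_pairs):
        gid = gene_ids[int(rng.integers(len(gene_ids)))]
        tx = transcripts[gid]
        frag = max(2 * read_len, int(round(rng.normal(250, 30))))
        if frag >= len(tx):
            continue
        start = int(rng.integers(0, len(tx) - frag + 1))

        def place(s: int, e: int, gene=by_id[gid], start=start):
            return (gene, start + s)

        emit_pair(f"bg_{k}", tx[start : start + frag], read_len, 0.005, place)

    sam_path = out / "reads.sam"
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, seq in genome.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(seq)}\n")
        for r in records:
            nm = f"\tNM:i:{r.nm}" if r.nm is not None else ""
            fh.write(
                f"{r.qname}\t{r.flag}\t{r.rname}\t{r.pos + 1 if r.pos >= 0 else 0}\t"
                f"{60 if r.pos >= 0 else 0}\t{r.cigar}\t*\t0\t0\t{r.seq}\t{'I' * len(r.seq)}{nm}\n"
            )

    fasta_path = out / "transcripts.fa"
    with open(fasta_path, "w") as fh:
        for gid in gene_ids:
            fh.write(f">{gid}\n{transcripts[gid]}\n")
    with open(out / "genome.fa", "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n{seq}\n")
    models_path = out / "models.gff3"
    from .io_formats import write_gff3

    write_gff3(models, models_path)
    truth = pd.DataFrame(
        truth_rows, columns=["gene5", "exon_i", "gene3", "exon_j", "n_pairs", "insert_mean"]
    )
    return sam_path, fasta_path, models_path, models, truth
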