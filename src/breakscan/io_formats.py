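"""Readers and writers for all on-disk formats.

Internal coordinates are 0-based half-open everywhere. On disk, BED stays
0-based half-open; GFF3 and SEG are 1-based inclusive. Conversions happen
only at the file boundary, in this module.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .models import CensusGene, CnaSegment, ExonProfile, GeneModel, ProbeTrack

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# exon expression matrices
# ---------------------------------------------------------------------------

def read_exon_matrix(
    path: PathLike,
    gene_models: Sequence[GeneModel],
    center: bool = False,
) -> list[ExonProfile]:
    """Read a gene x exon x sample TSV into per-(gene, sample) ExonProfiles.

    The file has columns ``gene_id``, ``exon_index`` (1-based, transcript
    order) followed by one column per sample. With ``center=True`` each exon
    row is mean-centered across samples before profiles are built. Missing
    values are dropped per profile, the surviving exon indices are kept on
    the profile. Genes absent from ``gene_models`` are skipped with a
    warning; an exon-count mismatch against the model is a hard error.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id" or df.columns[1] != "exon_index":
        raise ValueError("exon matrix must start with gene_id, exon_index columns")
    samples = list(df.columns[2:])
    if not samples:
        raise ValueError("exon matrix has no sample columns")
    models = {m.gene_id: m for m in gene_models}

    if center:
        vals = df[samples].to_numpy(dtype=float)
        df[samples] = vals - np.nanmean(vals, axis=1, keepdims=True)

    profiles: list[ExonProfile] = []
    n_skipped = 0
    for gene_id, block in df.groupby("gene_id", sort=False):
        model = models.get(gene_id)
        if model is None:
            n_skipped += 1
            logger.warning("gene %s absent from gene models; row block dropped", gene_id)
            continue
        block = block.sort_values("exon_index")
        idx = block["exon_index"].to_numpy(dtype=int)
        if len(idx) != model.n_exons or not np.array_equal(idx, np.arange(1, model.n_exons + 1)):
            raise ValueError(
                f"exon count mismatch for gene {gene_id}: matrix has exons "
                f"{idx.tolist()}, model has {model.n_exons} exons"
            )
        for sample in samples:
            v = block[sample].to_numpy(dtype=float)
            keep = np.isfinite(v)
            if keep.sum() < 2:
                logger.warning("%s/%s: <2 finite exon values, profile dropped", gene_id, sample)
                continue
            profiles.append(
                ExonProfile(gene_id=gene_id, sample_id=sample, values=v[keep], exon_indices=idx[keep])
            )
    if n_skipped:
        logger.warning("dropped %d gene blocks absent from models", n_skipped)
    return profiles


def write_exon_matrix(profiles: Iterable[ExonProfile], path: PathLike) -> None:
    """Inverse of :func:`read_exon_matrix` for complete (no-missing) profiles."""
    rows: dict[tuple[str, int], dict[str, float]] = {}
    for p in profiles:
        idx = p.exon_indices if p.exon_indices is not None else np.arange(1, p.n_exons + 1)
        for i, v in zip(idx, p.values):
            rows.setdefault((p.gene_id, int(i)), {})[p.sample_id] = float(v)
    recs = [{"gene_id": g, "exon_index": i, **vals} for (g, i), vals in sorted(rows.items())]
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# probe-level copy-number tracks
# ---------------------------------------------------------------------------

def read_probe_track(path: PathLike) -> list[ProbeTrack]:
    """Read a probe-track TSV (``chrom``, ``position``, one column/sample).

    Returns one ProbeTrack per (sample, chromosome). Unsorted input is
    sorted with a warning; duplicate positions keep the first occurrence.
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["chrom", "position"]:
        raise ValueError("probe track must start with chrom, position columns")
    samples = list(df.columns[2:])
    tracks: list[ProbeTrack] = []
    for chrom, block in df.groupby("chrom", sort=False):
        pos = block["position"].to_numpy(dtype=np.int64)
        if np.any(np.diff(pos) <= 0):
            if np.any(np.diff(pos) < 0):
                logger.warning("probe positions on %s unsorted; sorting", chrom)
            block = block.sort_values("position", kind="stable")
            pos = block["position"].to_numpy(dtype=np.int64)
            dup = np.concatenate([[False], np.diff(pos) == 0])
            if dup.any():
                logger.warning("%d duplicate probe positions on %s; keeping first", dup.sum(), chrom)
                block = block.loc[~dup]
                pos = block["position"].to_numpy(dtype=np.int64)
        for sample in samples:
            tracks.append(
                ProbeTrack(
                    sample_id=sample,
                    chrom=str(chrom),
                    positions=pos.copy(),
                    ratios=block[sample].to_numpy(dtype=float),
                )
            )
    return tracks


def write_probe_tracks(tracks: Sequence[ProbeTrack], path: PathLike) -> None:
    """Write tracks sharing a probe grid per chromosome back to TSV."""
    frames = []
    by_chrom: dict[str, list[ProbeTrack]] = {}
    for t in tracks:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, group in by_chrom.items():
        pos = group[0].positions
        for t in group[1:]:
            if not np.array_equal(t.positions, pos):
                raise ValueError(f"tracks on {chrom} do not share a probe grid")
        df = pd.DataFrame({"chrom": chrom, "position": pos})
        for t in group:
            df[t.sample_id] = t.ratios
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cancer gene census
# ---------------------------------------------------------------------------

def read_census(path: PathLike) -> list[CensusGene]:
    """Read the filtered cancer-gene list (``gene_id``, ``fusion_role``[, notes]).

    The upstream fragile-site/non-oncogenic-partner filtering is assumed
    already applied to this file. Duplicate gene symbols and unknown role
    tokens are hard errors. An empty file yields an empty list (downstream
    filters then pass everything through).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        return []
    if "gene_id" not in df.columns or "fusion_role" not in df.columns:
        raise ValueError("census file needs gene_id and fusion_role columns")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate census gene(s): {sorted(set(dup))}")
    out = []
    for rec in df.itertuples(index=False):
        notes = getattr(rec, "notes", "") or ""
        out.append(CensusGene(gene_id=rec.gene_id, fusion_role=rec.fusion_role, notes=notes))
    return out


def write_census(census: Sequence[CensusGene], path: PathLike) -> None:
    pd.DataFrame(
        [{"gene_id": c.gene_id, "fusion_role": c.fusion_role, "notes": c.notes} for c in census]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SEG segment files
# ---------------------------------------------------------------------------

SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_probes", "mean_log2"]


def write_segments(segments: Sequence[CnaSegment], path: PathLike) -> None:
    """Write segments as SEG (1-based inclusive genomic coordinates on disk)."""
    by_key: dict[tuple[str, str], list[CnaSegment]] = {}
    for s in segments:
        by_key.setdefault((s.sample_id, s.chrom), []).append(s)
    for (sample, chrom), group in by_key.items():
        group.sort(key=lambda s: s.start_pos)
        for a, b in zip(group, group[1:]):
            if b.start_pos < a.end_pos:
                raise ValueError(f"overlapping segments for {sample}/{chrom}")
    rows = [
        {
            "sample": s.sample_id,
            "chrom": s.chrom,
            "start": s.start_pos + 1,  # 0-based half-open -> 1-based inclusive
            "end": s.end_pos,
            "num_probes": s.n_probes,
            "mean_log2": s.mean_log2,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_segments(path: PathLike) -> pd.DataFrame:
    """Read a SEG file back into a frame with internal 0-based half-open coords."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != SEG_COLUMNS:
        raise ValueError(f"expected SEG columns {SEG_COLUMNS}, got {list(df.columns)}")
    df["start"] = df["start"] - 1
    return df


# ---------------------------------------------------------------------------
# gene models: GFF3 and BED12
# ---------------------------------------------------------------------------

def read_gene_models(path: PathLike) -> list[GeneModel]:
    """Dispatch on extension: .bed -> BED12, anything else -> GFF3."""
    p = Path(path)
    return read_bed12(p) if p.suffix.lower() == ".bed" else read_gff3(p)


def _attrs(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: PathLike) -> list[GeneModel]:
    """Parse flat gene/exon/CDS GFF3 into GeneModels (one transcript/gene)."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            start, end = int(start) - 1, int(end)  # 1-based inclusive -> 0-based half-open
            a = _attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID") or a.get("gene_id")
                if gid is None:
                    raise ValueError(f"gene feature without ID: {line!r}")
                genes[gid] = {"chrom": chrom, "strand": strand, "exons": [], "cds": []}
                order.append(gid)
            elif ftype in ("exon", "CDS"):
                gid = a.get("Parent") or a.get("gene_id")
                if gid not in genes:
                    raise ValueError(f"{ftype} with unknown Parent {gid!r}")
                genes[gid]["exons" if ftype == "exon" else "cds"].append((start, end))
    out = []
    for gid in order:
        g = genes[gid]
        rev = g["strand"] == "-"
        exons = tuple(sorted(g["exons"], reverse=rev))
        cds = tuple(sorted(g["cds"], reverse=rev)) or None
        out.append(GeneModel(gene_id=gid, chrom=g["chrom"], strand=g["strand"], exons=exons, cds=cds))
    return out


def write_gff3(models: Sequence[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gs, ge = m.span
            fh.write(
                f"{m.chrom}\tbreakscan\tgene\t{gs + 1}\t{ge}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            for s, e in sorted(m.exons):
                fh.write(f"{m.chrom}\tbreakscan\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\tParent={m.gene_id}\n")
            for s, e in sorted(m.cds or ()):
                fh.write(f"{m.chrom}\tbreakscan\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\tParent={m.gene_id}\n")


def read_bed12(path: PathLike) -> list[GeneModel]:
    """Parse BED12 (0-based half-open on disk; thick region = CDS)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 requires 12 columns, got {len(f)}")
            chrom, cstart, _, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            exons_genomic = [(cstart + o, cstart + o + sz) for o, sz in zip(offs, sizes)]
            cds = [
                (max(s, thick_s), min(e, thick_e))
                for s, e in exons_genomic
                if max(s, thick_s) < min(e, thick_e)
            ]
            rev = strand == "-"
            out.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(sorted(exons_genomic, reverse=rev)),
                    cds=tuple(sorted(cds, reverse=rev)) or None,
                )
            )
    return out


def write_bed12(models: Sequence[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        for m in models:
            gs, ge = m.span
            exons = sorted(m.exons)
            if m.cds:
                thick_s = min(s for s, _ in m.cds)
                thick_e = max(e for _, e in m.cds)
            else:
                thick_s = thick_e = gs
            sizes = ",".join(str(e - s) for s, e in exons)
            offs = ",".join(str(s - gs) for s, _ in exons)
            fh.write(
                f"{m.chrom}\t{gs}\t{ge}\t{m.gene_id}\t0\t{m.strand}\t"
                f"{thick_s}\t{thick_e}\t0\t{len(exons)}\t{sizes}\t{offs}\n"
            )
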