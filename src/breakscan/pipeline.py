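"""Top-level workflow: RBA and/or DBA, census/direction filters, merge.

Runs whichever arms the configuration provides inputs for, writes one TSV
per stage plus a merged candidate table flagging (gene, sample) pairs hit
by both arms, and stamps every report with a provenance header (config
hash, package version, seed) so identical configs reproduce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, dba, io_formats, rba

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str
    models: str
    census: Optional[str] = None
    exon_matrix: Optional[str] = None
    probe_tracks: Optional[str] = None
    alpha: float = 0.05
    min_group: int = 2
    center: bool = False
    theta: float = 0.3
    min_len: int = 50
    high_theta: float = 1.0
    high_min_len: int = 10
    fdr: float = 0.01
    focal_cap: int = 1000
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.exon_matrix is None and self.probe_tracks is None:
            raise ValueError("need at least one of exon_matrix / probe_tracks")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.theta <= 0 or self.high_theta <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_len < 1 or self.high_min_len < 1:
            raise ValueError("minimum lengths must be >= 1")
        for path in (self.models, self.census, self.exon_matrix, self.probe_tracks):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)

    def digest(self) -> str:
        payload = {k: v for k, v in sorted(vars(self).items())}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _header(cfg: RunConfig) -> str:
    return (
        f"# breakscan {__version__}\n"
        f"# config_hash {cfg.digest()}\n"
        f"# seed {cfg.seed}\n"
    )


def _write(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the configured arms and write per-stage and merged reports."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    models = io_formats.read_gene_models(cfg.models)
    census = io_formats.read_census(cfg.census) if cfg.census else []
    outputs: dict[str, Path] = {}

    rba_df = pd.DataFrame(
        columns=["gene_id", "sample_id", "junction_index", "t_stat", "p_value", "p_threshold", "direction", "n_tests_in_family"]
    )
    if cfg.exon_matrix:
        profiles = io_formats.read_exon_matrix(cfg.exon_matrix, models, center=cfg.center)
        calls = rba.call_expression_breakpoints(profiles, census or None, alpha=cfg.alpha, min_group=cfg.min_group)
        n_raw = len(calls)
        if census:
            calls = rba.direction_filter(calls, census)
        logger.info("RBA: %d significant breakpoints, %d after direction filter (avg %.2f/sample)",
                    n_raw, len(calls),
                    len(calls) / max(1, len({c.sample_id for c in calls})))
        rba_df = pd.DataFrame([vars(c) for c in calls], columns=rba_df.columns)
        path = out / "rba_calls.tsv"
        _write(rba_df, path, cfg)
        outputs["rba"] = path

    dba_df = pd.DataFrame(
        columns=["gene_id", "sample_id", "boundary_pos", "boundary_side", "transition", "mean_log2", "level", "focal"]
    )
    if cfg.probe_tracks:
        tracks = io_formats.read_probe_track(cfg.probe_tracks)
        segments, bp_calls = [], []
        for track in tracks:
            fitted = dba.segment_track(track, fdr=cfg.fdr, seed=cfg.seed)
            segs = dba.copy_number_smooth(
                fitted, track, theta=cfg.theta, min_len=cfg.min_len,
                high_theta=cfg.high_theta, high_min_len=cfg.high_min_len,
            )
            segments.extend(segs)
            bp_calls.extend(dba.call_intragenic_breakpoints(segs, models, focal_cap=cfg.focal_cap))
        n_raw = len(bp_calls)
        if census:
            bp_calls = dba.census_direction_filter(bp_calls, census)
        logger.info("DBA: %d segments, %d intragenic breakpoints, %d after census/direction filter",
                    len(segments), n_raw, len(bp_calls))
        seg_path = out / "segments.seg"
        io_formats.write_segments(segments, seg_path)
        outputs["segments"] = seg_path
        dba_df = pd.DataFrame(
            [
                {
                    "gene_id": c.gene_id,
                    "sample_id": c.sample_id,
                    "boundary_pos": c.boundary_pos,
                    "boundary_side": c.boundary_side,
                    "transition": c.transition,
                    "mean_log2": c.segment.mean_log2,
                    "level": c.segment.level,
                    "focal": c.focal,
                }
                for c in bp_calls
            ],
            columns=dba_df.columns,
        )
        path = out / "dba_breakpoints.tsv"
        _write(dba_df, path, cfg)
        outputs["dba"] = path

    rba_keys = set(zip(rba_df["gene_id"], rba_df["sample_id"])) if len(rba_df) else set()
    dba_keys = set(zip(dba_df["gene_id"], dba_df["sample_id"])) if len(dba_df) else set()
    merged_rows = [
        {
            "gene_id": g,
            "sample_id": s,
            "evidence": "both" if (g, s) in rba_keys and (g, s) in dba_keys
            else ("rba" if (g, s) in rba_keys else "dba"),
        }
        for g, s in sorted(rba_keys | dba_keys)
    ]
    merged = pd.DataFrame(merged_rows, columns=["gene_id", "sample_id", "evidence"])
    merged_path = out / "candidates.tsv"
    _write(merged, merged_path, cfg)
    outputs["merged"] = merged_path
    logger.info("merged: %d candidates (%d supported by both arms)",
                len(merged), int((merged["evidence"] == "both").sum()) if len(merged) else 0)
    return outputs
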