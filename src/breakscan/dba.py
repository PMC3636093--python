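"""DNA breakpoint analysis (DBA).

An unbalanced rearrangement leaves a copy-number transition inside the
gene it disrupts. The pipeline here: (1) fit a piecewise-constant signal
to probe-level log2 ratios with a total-variation (fused) penalty whose
strength is calibrated so the expected fraction of probes called
non-neutral on permuted (spatially scrambled) data stays below a target
FDR; neutral probes are shrunk to exactly 0 by soft-thresholding.
(2) "Copy-number smoothing": walk each chromosome, accept well-defined
CNAs by amplitude/length gates (|log2|>=0.3 over >=50 probes, or
|log2|>=1.0 over >=10 probes for high-level events) and place their lower
boundary where 95% of a look-ahead window of fitted values turns neutral,
flips sign, or shifts in mean by >=0.3. (3) Report transitions falling
strictly inside annotated genes, oriented against the cancer-gene list.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .models import CensusGene, CnaBreakpoint, CnaSegment, GeneModel, ProbeTrack


# ---------------------------------------------------------------------------
# exact 1-D total-variation denoising (Condat's direct non-iterative method)
# ---------------------------------------------------------------------------

def tv_denoise(y: np.ndarray, lam: float) -> np.ndarray:
    """Exact minimiser of 0.5*||y - x||^2 + lam * sum|x[i+1] - x[i]|."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n == 0:
        return y.copy()
    if lam <= 0:
        return y.copy()
    x = np.empty(n)
    k = k0 = kminus = kplus = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        if k == n - 1:
            if umin < 0.0:
                x[k0 : kminus + 1] = vmin
                k = k0 = kminus = kminus + 1
                vmin = y[k]
                umin = lam
                umax = y[k] + lam - vmax
            elif umax > 0.0:
                x[k0 : kplus + 1] = vmax
                k = k0 = kplus = kplus + 1
                vmax = y[k]
                umax = -lam
                umin = y[k] - lam - vmin
            else:
                x[k0:n] = vmin + umin / (k - k0 + 1)
                return x
            if k == n - 1:
                x[k] = vmin + umin  # single trailing point
                return x
            continue
        if y[k + 1] + umin < vmin - lam:  # negative jump forced
            x[k0 : kminus + 1] = vmin
            k = k0 = kminus = kplus = kminus + 1
            vmin = y[k]
            vmax = y[k] + 2 * lam
            umin = lam
            umax = -lam
        elif y[k + 1] + umax > vmax + lam:  # positive jump forced
            x[k0 : kplus + 1] = vmax
            k = k0 = kminus = kplus = kplus + 1
            vmin = y[k] - 2 * lam
            vmax = y[k]
            umin = lam
            umax = -lam
        else:  # no jump yet; extend the current segment
            k += 1
            umin += y[k] - vmin
            umax += y[k] - vmax
            if umin >= lam:
                vmin += (umin - lam) / (k - k0 + 1)
                umin = lam
                kminus = k
            if umax <= -lam:
                vmax += (umax + lam) / (k - k0 + 1)
                umax = -lam
                kplus = k


def soft_threshold(x: np.ndarray, lam: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


def robust_sigma(ratios: np.ndarray) -> float:
    """Noise scale from the median absolute first difference (MAD-based)."""
    y = np.asarray(ratios, dtype=float)
    return max(float(np.median(np.abs(np.diff(y)))) / (np.sqrt(2) * 0.6745), 1e-6)


def calibrate_threshold(
    ratios: np.ndarray,
    penalty: float,
    fdr: float = 0.01,
    n_perm: int = 20,
    seed: int = 0,
) -> float:
    """Sparsity threshold with permutation-null non-neutral rate <= fdr.

    Probe ratios are permuted within the chromosome (destroying spatial
    structure, preserving the marginal distribution), TV-fitted at the
    fusion penalty, and the (1 - fdr) quantile of the pooled |fitted|
    values is returned: the smallest soft-threshold for which the expected
    fraction of probes called non-neutral under the null stays below fdr.
    """
    y = np.asarray(ratios, dtype=float)
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate(
        [np.abs(tv_denoise(rng.permutation(y), penalty)) for _ in range(n_perm)]
    )
    return float(np.quantile(pooled, 1.0 - fdr, method="higher"))


def segment_track(
    track: ProbeTrack,
    fdr: float = 0.01,
    penalty: Optional[float] = None,
    threshold: Optional[float] = None,
    n_perm: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Piecewise-constant fit of one chromosome's ratios; neutral probes are 0.

    The fusion (total-variation) penalty gives the piecewise structure; a
    separate sparsity soft-threshold shrinks the fitted levels so probes
    outside any alteration come back exactly 0. ``penalty`` defaults to the
    universal-threshold analogue sigma * sqrt(2 ln n) on the robust noise
    scale; ``threshold=None`` triggers permutation calibration at the
    requested FDR. A whole-chromosome constant offset is indistinguishable
    from neutral under the permutation null and is shrunk away.
    """
    y = np.asarray(track.ratios, dtype=float)
    if y.size < 2:
        raise ValueError("track must have >= 2 probes")
    if not np.any(np.isfinite(y)):
        raise ValueError("all-missing track")
    if penalty is None:
        penalty = robust_sigma(y) * np.sqrt(2.0 * np.log(y.size))
    if threshold is None:
        threshold = calibrate_threshold(y, penalty, fdr=fdr, n_perm=n_perm, seed=seed)
    return soft_threshold(tv_denoise(y, penalty), threshold)


# ---------------------------------------------------------------------------
# copy number smoothing
# ---------------------------------------------------------------------------

def _window_vote(
    window: np.ndarray, sign: float, cna_mean: float, theta: float, mode: str
) -> float:
    """Fraction of a look-ahead window supporting CNA termination."""
    neutral = window == 0.0
    flipped = (window != 0.0) & (np.sign(window) != sign)
    if mode == "window" and abs(window.mean() - cna_mean) >= theta:
        return 1.0
    sat = neutral | flipped
    if mode == "probe":
        sat |= np.abs(window - cna_mean) >= theta
    return float(np.mean(sat))


def copy_number_smooth(
    fitted: np.ndarray,
    raw: ProbeTrack,
    theta: float = 0.3,
    min_len: int = 50,
    high_theta: float = 1.0,
    high_min_len: int = 10,
    frac: float = 0.95,
    window: int = 100,
    high_window: int = 50,
    level_change_mode: str = "window",
) -> list[CnaSegment]:
    """Boundary-refinement walk over the fitted values of one chromosome.

    Each iteration finds the next candidate CNA (maximal same-sign non-zero
    run of the fit), gates it on amplitude/length (raw-ratio mean >= theta
    over >= min_len probes, or >= high_theta over >= high_min_len), then
    walks downstream for the lower boundary: the first probe that is itself
    neutral, sign-flipped, or level-shifted by >= theta from the running CNA
    mean, and where >= ``frac`` of the next ``window`` fitted values (the
    shorter ``high_window`` for high-level CNAs) vote the same way. The
    boundary sits at the first probe of that terminating window and the
    segment mean is then recomputed from the raw ratios.

    ``level_change_mode`` selects how the mean-shift criterion enters the
    window vote: ``"window"`` compares the window mean against the CNA mean
    (one shifted window satisfies wholesale), ``"probe"`` compares each
    fitted value individually. The boundary probe itself is always tested
    per-probe, which keeps clean boundaries exact.
    """
    f = np.asarray(fitted, dtype=float)
    y = np.asarray(raw.ratios, dtype=float)
    pos = raw.positions
    n = f.size
    if f.shape != y.shape:
        raise ValueError("fitted vector and raw track are not aligned")
    if level_change_mode not in ("window", "probe"):
        raise ValueError("level_change_mode must be 'window' or 'probe'")

    segments: list[CnaSegment] = []
    i = 0
    while i < n:
        nz = np.flatnonzero(f[i:] != 0.0)
        if nz.size == 0:
            break
        start = i + int(nz[0])
        sign = np.sign(f[start])
        run_end = start
        while run_end < n and f[run_end] != 0.0 and np.sign(f[run_end]) == sign:
            run_end += 1
        run_mean_raw = float(np.mean(y[start:run_end]))
        run_len = run_end - start
        is_high = abs(run_mean_raw) >= high_theta and run_len >= high_min_len
        is_standard = abs(run_mean_raw) >= theta and run_len >= min_len
        if not (is_high or is_standard):
            i = run_end
            continue

        w = high_window if is_high else window
        lower = n
        csum = float(f[start])  # running sum of fitted values inside the CNA
        for p in range(start + 1, n):
            cna_mean = csum / (p - start)
            fp = f[p]
            probe_sat = (
                fp == 0.0
                or np.sign(fp) != sign
                or abs(fp - cna_mean) >= theta
            )
            if probe_sat and _window_vote(f[p : p + w], sign, cna_mean, theta, level_change_mode) >= frac:
                lower = p
                break
            csum += fp

        mean_log2 = float(np.mean(y[start:lower]))
        length = lower - start
        if abs(mean_log2) >= high_theta and length >= high_min_len:
            level = "high"
        elif abs(mean_log2) >= theta and length >= min_len:
            level = "standard"
        else:  # recomputed mean slipped under the gate
            i = lower
            continue
        segments.append(
            CnaSegment(
                sample_id=raw.sample_id,
                chrom=raw.chrom,
                start_probe=start,
                end_probe=lower,
                start_pos=int(pos[start]),
                end_pos=int(pos[lower - 1]) + 1,
                mean_log2=mean_log2,
                level=level,
                sign="gain" if mean_log2 > 0 else "loss",
            )
        )
        i = lower  # the walk may stop inside the run (level shift): rescan from there
    return segments


# ---------------------------------------------------------------------------
# intragenic breakpoint calling and directional filtering
# ---------------------------------------------------------------------------

def call_intragenic_breakpoints(
    segments: Sequence[CnaSegment],
    models: Sequence[GeneModel],
    focal_cap: int = 1000,
) -> list[CnaBreakpoint]:
    """Emit a breakpoint for every segment boundary strictly inside a gene.

    ``boundary_side`` records, in transcript orientation, which end of the
    gene lies inside the alteration (``upper_5prime`` when the CNA covers
    the transcript-5' portion). Segments spanning fewer than ``focal_cap``
    probes are flagged focal (used for prioritisation, never exclusion).
    """
    calls: list[CnaBreakpoint] = []
    for seg in segments:
        for boundary_pos, which in ((seg.start_pos, "start"), (seg.end_pos, "end")):
            for m in models:
                if m.chrom != seg.chrom:
                    continue
                gs, ge = m.span
                if not (gs < boundary_pos < ge):
                    continue
                # the gene portion covered by the CNA is genomic-right of a
                # start boundary and genomic-left of an end boundary
                covered_right = which == "start"
                covered_end = (
                    "three_prime"
                    if (covered_right == (m.strand == "+"))
                    else "five_prime"
                )
                calls.append(
                    CnaBreakpoint(
                        gene_id=m.gene_id,
                        sample_id=seg.sample_id,
                        boundary_pos=boundary_pos,
                        boundary_side="upper_5prime" if covered_end == "five_prime" else "lower_3prime",
                        transition=f"{seg.sign}_{'starts' if which == 'start' else 'ends'}",
                        segment=seg,
                        focal=seg.n_probes < focal_cap,
                    )
                )
    return calls


def covered_transcript_end(call: CnaBreakpoint) -> str:
    return "five_prime" if call.boundary_side == "upper_5prime" else "three_prime"


def census_direction_filter(
    calls: Sequence[CnaBreakpoint], census: Optional[Sequence[CensusGene]]
) -> list[CnaBreakpoint]:
    """Keep breakpoints consistent with the gene's known fusion orientation.

    A 3'-partner gene (ABL1-like) must show amplification of its 3' end or
    deletion of its 5' end; a 5'-partner gene the mirror image; ``either``
    passes both. An empty census disables the filter.
    """
    if not census:
        return list(calls)
    roles = {c.gene_id: c.fusion_role for c in census}
    kept = []
    for call in calls:
        role = roles.get(call.gene_id)
        if role is None:
            continue
        end = covered_transcript_end(call)
        sign = call.segment.sign
        three_ok = (sign == "gain" and end == "three_prime") or (sign == "loss" and end == "five_prime")
        five_ok = (sign == "gain" and end == "five_prime") or (sign == "loss" and end == "three_prime")
        if role == "either" or (role == "three_prime" and three_ok) or (role == "five_prime" and five_ok):
            kept.append(call)
    return kept
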