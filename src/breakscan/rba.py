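"""RNA breakpoint analysis (RBA).

A rearrangement that fuses a gene mid-transcript leaves a step in its
exon-level expression profile: exons 3' of the junction of a 3' fusion
partner are driven by the partner's promoter and sit above the 5' exons
(and mirror-image for 5' partners). The scan below slides a two-sample
Student's t-test along every exon-exon junction of a transcript
("walking" t-test), comparing all proximal (5') against all distal (3')
exon values, and controls the per-sample family of tests by Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .models import CensusGene, ExonProfile

DISTAL = "distal_elevated"
PROXIMAL = "proximal_elevated"


@dataclass
class JunctionTest:
    """One walking t-test at junction ``j`` (between exon j and j+1, 1-based)."""

    junction_index: int
    t_stat: float
    p_value: float
    degenerate: bool = False  # zero pooled variance with unequal means


@dataclass
class ExpressionBreakpoint:
    gene_id: str
    sample_id: str
    junction_index: int
    t_stat: float
    p_value: float
    p_threshold: float
    direction: str
    n_tests_in_family: int


def walking_ttest(profile: ExonProfile | np.ndarray, min_group: int = 2) -> list[JunctionTest]:
    """Pooled-variance two-sided t-test at every admissible exon junction.

    Junction ``j`` (1-based) splits the profile into proximal exons
    ``1..j`` and distal exons ``j+1..n``; only junctions with at least
    ``min_group`` exons on each side are tested. The statistic is signed as
    mean(distal) - mean(proximal), so t > 0 means the 3' exons are elevated.

    Degenerate variance is resolved as: both sides constant and equal
    -> t=0, p=1; zero pooled variance with unequal means -> p set to the
    smallest positive float and the test flagged.
    """
    v = profile.values if isinstance(profile, ExonProfile) else np.asarray(profile, dtype=float)
    n = v.size
    if min_group < 1:
        raise ValueError("min_group must be >= 1")
    out: list[JunctionTest] = []
    if n < 2 * min_group:
        return out

    vc = v - v.mean()  # shift-invariant; reduces cancellation in the sums below
    cs = np.cumsum(vc)
    css = np.cumsum(vc * vc)
    total, total_sq = cs[-1], css[-1]
    js = np.arange(min_group, n - min_group + 1)
    n1 = js.astype(float)
    n2 = n - n1
    s1, q1 = cs[js - 1], css[js - 1]
    m1 = s1 / n1
    m2 = (total - s1) / n2
    ss1 = q1 - s1 * s1 / n1
    ss2 = (total_sq - q1) - (total - s1) ** 2 / n2
    # the one-pass sums cancel catastrophically when one side is near-constant
    # but far from the overall mean; redo those junctions with two-pass sums
    scale = total_sq + 1.0
    for k in np.flatnonzero((ss1 < 1e-7 * scale) | (ss2 < 1e-7 * scale)):
        j = int(js[k])
        ss1[k] = float(np.sum((vc[:j] - vc[:j].mean()) ** 2))
        ss2[k] = float(np.sum((vc[j:] - vc[j:].mean()) ** 2))
    df = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = (ss1 + ss2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        t = (m2 - m1) / se
        p = 2.0 * stats.t.sf(np.abs(t), df)

    tiny = np.finfo(float).tiny
    for k, j in enumerate(js):
        tk, pk, degenerate = t[k], p[k], False
        if not np.isfinite(tk):  # zero pooled variance
            if np.isclose(m1[k], m2[k]):
                tk, pk = 0.0, 1.0
            else:
                tk = np.inf if m2[k] > m1[k] else -np.inf
                pk, degenerate = tiny, True
        out.append(JunctionTest(int(j), float(tk), float(pk), degenerate))
    return out


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance level alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def call_expression_breakpoints(
    profiles: Iterable[ExonProfile],
    census: Optional[Sequence[CensusGene]],
    alpha: float = 0.05,
    min_group: int = 2,
) -> list[ExpressionBreakpoint]:
    """Scan census-gene profiles per sample; emit Bonferroni-significant minima.

    The Bonferroni family is the number of junction tests actually performed
    in one sample across the census genes (recorded on every call). A gene
    contributes one candidate per sample: the junction of minimum P, most-5'
    junction on ties, kept when P < alpha / family_size. When ``census`` is
    None or empty, no gene filter is applied (the family then spans all genes).
    """
    census_ids = {c.gene_id for c in census} if census else None
    by_sample: dict[str, list[tuple[ExonProfile, list[JunctionTest]]]] = {}
    for prof in profiles:
        if census_ids is not None and prof.gene_id not in census_ids:
            continue
        tests = walking_ttest(prof, min_group=min_group)
        if tests:
            by_sample.setdefault(prof.sample_id, []).append((prof, tests))

    calls: list[ExpressionBreakpoint] = []
    for sample_id, entries in by_sample.items():
        family = sum(len(tests) for _, tests in entries)
        threshold = bonferroni_threshold(alpha, family)
        for prof, tests in entries:
            best = min(tests, key=lambda jt: (jt.p_value, jt.junction_index))
            if best.p_value < threshold:
                calls.append(
                    ExpressionBreakpoint(
                        gene_id=prof.gene_id,
                        sample_id=sample_id,
                        junction_index=best.junction_index,
                        t_stat=best.t_stat,
                        p_value=best.p_value,
                        p_threshold=threshold,
                        direction=DISTAL if best.t_stat > 0 else PROXIMAL,
                        n_tests_in_family=family,
                    )
                )
    calls.sort(key=lambda c: (c.sample_id, c.gene_id))
    return calls


def direction_filter(
    calls: Sequence[ExpressionBreakpoint], census: Sequence[CensusGene]
) -> list[ExpressionBreakpoint]:
    """Keep calls whose step direction matches the gene's known fusion role.

    A 3' partner is overexpressed distal to the junction (distal_elevated);
    a 5' partner proximal. ``either`` passes both directions.
    """
    roles = {c.gene_id: c.fusion_role for c in census}
    kept = []
    for call in calls:
        role = roles.get(call.gene_id)
        if role is None:
            continue
        if role == "either":
            kept.append(call)
        elif role == "three_prime" and call.direction == DISTAL:
            kept.append(call)
        elif role == "five_prime" and call.direction == PROXIMAL:
            kept.append(call)
    return kept
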