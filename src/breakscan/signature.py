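"""Supervised two-class gene signature with permutation FDR.

A gene enters the signature when (1) its expression correlates with the
binary class label (Pearson |R| >= 0.5), (2) the two-class difference is
significant by a two-tailed pooled-variance Student's t-test (P < 0.001),
and (3) the classes differ by >= 2-fold in average (linear-scale)
expression. The false-discovery rate is estimated globally by comparing
the observed pass count with the mean count over label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SignatureResult:
    gene_id: str
    pearson_r: float
    t_p: float
    fold_change: float
    passes: bool
    elevated_in_class1: bool


@dataclass
class SignatureAnalysis:
    results: list[SignatureResult]
    n_passing: int
    fdr_estimate: float
    perm_mean_passing: float


def _pass_counts(
    x: np.ndarray, labels: np.ndarray, r_min: float, p_max: float, fold_min: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene criteria for one labelling. x: genes x samples, log2 scale."""
    g1 = x[:, labels == 1]
    g0 = x[:, labels == 0]
    n1, n0 = g1.shape[1], g0.shape[1]
    m1, m0 = g1.mean(axis=1), g0.mean(axis=1)
    # point-biserial Pearson correlation of expression with the 0/1 label
    xc = x - x.mean(axis=1, keepdims=True)
    lc = labels - labels.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (lc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ lc) / denom
    r = np.nan_to_num(r)

    ss = (g1.var(axis=1, ddof=1) * (n1 - 1)) + (g0.var(axis=1, ddof=1) * (n0 - 1))
    df = n1 + n0 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(ss / df * (1.0 / n1 + 1.0 / n0))
        t = (m1 - m0) / se
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), df), 1.0)
    fold = 2.0 ** np.abs(m1 - m0)
    passes = (np.abs(r) >= r_min) & (p < p_max) & (fold >= fold_min)
    return r, p, fold, passes


def supervised_signature(
    matrix: pd.DataFrame,
    labels,
    r_min: float = 0.5,
    p_max: float = 0.001,
    fold_min: float = 2.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> SignatureAnalysis:
    """Two-class signature on a gene x sample log2 matrix.

    ``labels`` is a binary vector over the matrix columns (1 = class of
    interest). Fold change is computed from log2 means as 2**|dmean|. The
    global FDR estimate is mean permutation pass count / observed pass
    count, capped at 1; with zero observed passes it is reported as 0 (no
    discoveries). Permutations shuffle labels preserving class sizes and
    are driven by ``seed`` (re-runs are bit-identical).
    """
    labels = np.asarray(labels, dtype=int)
    x = matrix.to_numpy(dtype=float)
    if labels.size != x.shape[1]:
        raise ValueError("labels length must match the number of samples")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError("each class needs >= 2 samples")

    r, p, fold, passes = _pass_counts(x, labels, r_min, p_max, fold_min)
    m1 = x[:, labels == 1].mean(axis=1)
    m0 = x[:, labels == 0].mean(axis=1)
    results = [
        SignatureResult(
            gene_id=str(g),
            pearson_r=float(r[k]),
            t_p=float(p[k]),
            fold_change=float(fold[k]),
            passes=bool(passes[k]),
            elevated_in_class1=bool(m1[k] > m0[k]),
        )
        for k, g in enumerate(matrix.index)
    ]
    observed = int(passes.sum())

    rng = np.random.default_rng(seed)
    perm_counts = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(labels)
        perm_counts[b] = _pass_counts(x, perm, r_min, p_max, fold_min)[3].sum()
    perm_mean = float(perm_counts.mean())
    fdr = 0.0 if observed == 0 else min(1.0, perm_mean / observed)
    return SignatureAnalysis(
        results=results, n_passing=observed, fdr_estimate=fdr, perm_mean_passing=perm_mean
    )
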