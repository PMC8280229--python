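"""Liver-background estimation, regression removal, and sample QC.

The per-sample background score is the sum, over hepatocyte marker genes,
of the gene-wise mean-centered expression; the normalized proportion is
its min-max rescaling across samples. Removal fits, per gene, an
ordinary-least-squares regression on the proportion (with intercept) and
keeps the residuals, then shifts the whole matrix so its minimum is 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from metacms.core_io import ExpressionMatrix, MarkerGeneList


class DegenerateBackgroundError(ValueError):
    """All samples have identical marker scores; adjustment is undefined."""


@dataclass
class BackgroundEstimate:
    """Per-sample liver-background scores.

    Attributes
    ----------
    sample_ids : list of str
    raw_scores : ndarray
        Marker-sum scores p_i (one per sample).
    proportions : ndarray
        Min-max normalized scores P_i in [0, 1]; all zero when degenerate.
    p_min, p_max : float
        Extremes of the raw scores across samples.
    degenerate : bool
        True when p_max == p_min.
    markers_used : list of str
        Marker genes found in the expression matrix.
    """

    sample_ids: list[str]
    raw_scores: np.ndarray
    proportions: np.ndarray
    p_min: float
    p_max: float
    degenerate: bool
    markers_used: list[str]


def estimate_background(
    x: ExpressionMatrix, markers: MarkerGeneList
) -> BackgroundEstimate:
    """Estimate the per-sample liver-background proportion.

    ``z`` is the gene-wise mean-centered matrix; the raw score of sample
    ``i`` is ``p_i = sum_j z_ij`` over marker genes ``j``, and the
    proportion is ``P_i = (p_i - p_min) / (p_max - p_min)``.

    Raises
    ------
    ValueError
        If fewer than 2 samples, or no marker gene is present in ``x``.
    """
    if x.n_samples < 2:
        raise ValueError("background estimation requires >=2 samples (min-max undefined)")
    present = [g for g in markers if g in set(x.gene_ids)]
    if not present:
        raise ValueError(
            "no marker gene found in expression matrix; missing: "
            + ", ".join(list(markers)[:10])
        )
    if len(present) < 0.5 * len(markers):
        warnings.warn(
            f"only {len(present)}/{len(markers)} marker genes found in matrix",
            stacklevel=2,
        )
    z = x.values - x.values.mean(axis=1, keepdims=True)
    idx = x.gene_index(present)
    p = z[idx].sum(axis=0)
    p_min, p_max = float(p.min()), float(p.max())
    degenerate = p_max == p_min
    if degenerate:
        proportions = np.zeros_like(p)
    else:
        proportions = (p - p_min) / (p_max - p_min)
    return BackgroundEstimate(
        sample_ids=list(x.sample_ids),
        raw_scores=p,
        proportions=proportions,
        p_min=p_min,
        p_max=p_max,
        degenerate=bool(degenerate),
        markers_used=present,
    )


def regress_out_background(
    x: ExpressionMatrix,
    est: BackgroundEstimate,
    literal_shift: bool = False,
) -> ExpressionMatrix:
    """Remove the background axis by per-gene OLS on the proportion.

    Each gene's expression across samples is regressed on ``P`` with an
    intercept; the residual matrix is then shifted by a single global
    scalar so its minimum is exactly 0. By default the shift is
    ``max(0, -min(residuals))``; with ``literal_shift=True`` the shift is
    ``abs(min(residuals))`` regardless of sign (compatibility mode).

    Raises
    ------
    DegenerateBackgroundError
        If the estimate is degenerate (constant P).
    ValueError
        If the estimate was computed on different samples.
    """
    if est.degenerate:
        raise DegenerateBackgroundError(
            "background estimate is degenerate (constant marker score); "
            "skip adjustment for this cohort"
        )
    if est.sample_ids != list(x.sample_ids):
        raise ValueError("background estimate does not match matrix samples")
    P = est.proportions
    # per-gene OLS with intercept, vectorized over genes:
    # residual = centered(y) - beta * centered(P)
    Pc = P - P.mean()
    denom = float(Pc @ Pc)
    Y = x.values
    Yc = Y - Y.mean(axis=1, keepdims=True)
    beta = (Yc @ Pc) / denom
    residuals = Yc - np.outer(beta, Pc)
    mn = float(residuals.min())
    shift = abs(mn) if literal_shift else max(0.0, -mn)
    adjusted = residuals + shift
    return ExpressionMatrix(list(x.gene_ids), list(x.sample_ids), adjusted)


def filter_contaminated_samples(
    x: ExpressionMatrix,
    est: BackgroundEstimate,
    normal_liver_scores: np.ndarray,
) -> tuple[list[str], list[str]]:
    """Discard samples whose raw marker score reaches normal-liver levels.

    A tumor sample is discarded when its raw score meets or exceeds the
    10th percentile (linear interpolation) of the reference scores from
    normal liver samples.

    Returns
    -------
    (kept, discarded) : lists of sample ids, in input order.
    """
    ref = np.asarray(normal_liver_scores, dtype=float)
    if ref.size == 0:
        raise ValueError("empty normal-liver reference")
    if ref.size < 2:
        raise ValueError("need >=2 normal-liver reference scores")
    if est.sample_ids != list(x.sample_ids):
        raise ValueError("background estimate does not match matrix samples")
    threshold = float(np.percentile(ref, 10.0))  # type-7 linear interpolation
    kept, discarded = [], []
    for sid, p in zip(est.sample_ids, est.raw_scores):
        (discarded if p >= threshold else kept).append(sid)
    return kept, discarded
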