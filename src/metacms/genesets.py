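"""Single-sample gene-set scoring by a normalized mean-rank statistic.

For each sample, genes are ranked by expression within the sample
(average ranks on ties). The score of a set is

    (mean rank of set genes - (G + 1) / 2) / (G / 2)

with ``G`` the number of genes in the matrix — a signed enrichment in
[-1, 1], invariant under any strictly monotone per-sample transform.
This deliberately replaces kernel-density KS-type scoring with an
exactly testable statistic; scores are used comparatively only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from metacms.core_io import ExpressionMatrix, GeneSetCollection

MIN_OVERLAP = 3


def score_gene_sets(
    x: ExpressionMatrix, sets: GeneSetCollection, min_overlap: int = MIN_OVERLAP
) -> pd.DataFrame:
    """Score every gene set in every sample.

    Returns a samples x sets table. Sets overlapping the matrix by fewer
    than ``min_overlap`` genes yield an all-NaN column with a warning;
    set genes absent from the matrix are dropped (with a warning).
    """
    if len(sets) == 0:
        raise ValueError("empty gene-set collection")
    G = x.n_genes
    ranks = rankdata(x.values, axis=0)  # (G, n), average ranks on ties
    center = (G + 1) / 2.0
    half = G / 2.0
    universe = set(x.gene_ids)
    out = pd.DataFrame(index=list(x.sample_ids), columns=sets.names, dtype=float)
    out.index.name = "sample_id"
    for name, genes in sets:
        present = [g for g in genes if g in universe]
        if len(present) < len(genes):
            warnings.warn(
                f"set {name!r}: {len(genes) - len(present)} gene(s) absent "
                "from matrix, dropped",
                stacklevel=2,
            )
        if len(present) < min_overlap:
            warnings.warn(
                f"set {name!r}: overlap {len(present)} < {min_overlap}, scored NA",
                stacklevel=2,
            )
            out[name] = np.nan
            continue
        idx = x.gene_index(present)
        out[name] = (ranks[idx].mean(axis=0) - center) / half
    return out
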