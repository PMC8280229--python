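"""Heuristic selection of cancer-cell-intrinsic feature genes.

Applied to microenvironment-free reference profiles (cell lines or
organoids). Two sequential filters: (i) the gene's maximum expression
must exceed the first tertile of the pooled value distribution of the
whole matrix; (ii) its 10th-90th inter-percentile range across samples
must lie in the top 10% of the IPR distribution of genes passing (i).
All percentiles use linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from metacms.core_io import ExpressionMatrix


class NoFeaturesError(ValueError):
    """Raised when the filters leave no genes."""


@dataclass
class FeatureSet:
    """Selected feature genes plus the cutoffs that produced them."""

    genes: list[str]
    tertile_cutoff: float
    ipr_cutoff: float

    def __post_init__(self) -> None:
        if not self.genes:
            raise NoFeaturesError("feature set is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# tertile_cutoff={self.tertile_cutoff:.10g}\n")
            fh.write(f"# ipr_cutoff={self.ipr_cutoff:.10g}\n")
            for g in self.genes:
                fh.write(g + "\n")


def select_intrinsic_features(ref: ExpressionMatrix) -> FeatureSet:
    """Select robustly expressed, high-dispersion genes from a reference panel.

    Raises
    ------
    ValueError
        If the panel has fewer than 3 samples.
    NoFeaturesError
        If no gene survives both filters (e.g. constant matrix).
    """
    if ref.n_samples < 3:
        raise ValueError("feature selection requires >=3 reference samples")
    values = ref.values
    tertile = float(np.percentile(values, 100.0 / 3.0))
    gene_max = values.max(axis=1)
    pass1 = gene_max > tertile
    if not pass1.any():
        raise NoFeaturesError(
            "no features: no gene exceeds the first tertile of the data set"
        )
    q10, q90 = np.percentile(values[pass1], [10.0, 90.0], axis=1)
    ipr = q90 - q10
    ipr_cutoff = float(np.percentile(ipr, 90.0))
    pass2 = ipr >= ipr_cutoff
    genes = [g for g, keep in zip(np.array(ref.gene_ids)[pass1], pass2) if keep]
    if not genes:
        raise NoFeaturesError("no features: empty after dispersion filter")
    return FeatureSet(genes=genes, tertile_cutoff=tertile, ipr_cutoff=ipr_cutoff)
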