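"""PCA on primary tumors and projection of new samples.

Components are fitted on the genes with the largest cross-sample
variance (default 5000), gene-centered but not scaled, via singular
value decomposition. New cohorts are projected by subtracting the
*training* gene means and multiplying by the stored loadings. Signs are
fixed deterministically: each loading's largest-magnitude entry is
positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from metacms.core_io import ExpressionMatrix

DEFAULT_N_GENES = 5000
DEFAULT_N_COMPONENTS = 5


@dataclass
class PCAModel:
    """Fitted principal components.

    Attributes
    ----------
    genes : list of str
        Gene subset used (top-variance genes of the training matrix).
    means : ndarray of shape (p,)
        Training per-gene means.
    loadings : ndarray of shape (p, k)
        Orthonormal loading vectors (columns).
    explained : ndarray of shape (k,)
        Fraction of (retained-gene) variance explained per component.
    """

    genes: list[str]
    means: np.ndarray
    loadings: np.ndarray
    explained: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.explained = np.asarray(self.explained, dtype=float)
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("loading vectors are not orthonormal")
        if (np.diff(self.explained) > 1e-12).any() or self.explained.sum() > 1 + 1e-9:
            raise ValueError("explained fractions must be non-increasing, sum <= 1")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_dict(self) -> dict:
        return {
            "genes": self.genes,
            "means": self.means.tolist(),
            "loadings": self.loadings.tolist(),
            "explained": self.explained.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAModel":
        return cls(
            genes=list(d["genes"]),
            means=np.array(d["means"]),
            loadings=np.array(d["loadings"]),
            explained=np.array(d["explained"]),
        )


def fit_pca(
    x: ExpressionMatrix,
    n_genes: int = DEFAULT_N_GENES,
    n_components: int = DEFAULT_N_COMPONENTS,
) -> PCAModel:
    """Fit PCA on the top-variance genes of a training cohort.

    ``n_genes`` caps at the number of available genes; ``n_components``
    caps at the data rank (``n_samples - 1``).
    """
    if x.n_samples < 2:
        raise ValueError("PCA requires >=2 samples")
    if n_genes < 2:
        raise ValueError("n_genes must be >=2")
    variances = x.values.var(axis=1, ddof=1)
    n_keep = min(n_genes, x.n_genes)
    order = np.argsort(-variances, kind="stable")[:n_keep]
    order = np.sort(order)  # keep original gene order for determinism
    genes = [x.gene_ids[i] for i in order]
    sub = x.values[order]
    means = sub.mean(axis=1)
    centered = (sub - means[:, None]).T  # samples x genes
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, int((s > s.max() * 1e-12).sum()) if s.size else 0)
    k = max(k, 1)
    loadings = vt[:k].T  # (p, k)
    # deterministic sign: largest-magnitude loading entry positive
    for j in range(k):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    total_ss = float((centered**2).sum())
    explained = (s[:k] ** 2) / total_ss if total_ss > 0 else np.zeros(k)
    return PCAModel(genes=genes, means=means, loadings=loadings, explained=explained)


def project(model: PCAModel, x: ExpressionMatrix) -> pd.DataFrame:
    """Project samples onto fitted components.

    Returns a samples x components table with columns PC1..PCk.
    """
    sub = x.subset_genes(model.genes)  # KeyError lists missing genes
    centered = sub.values - model.means[:, None]
    scores = centered.T @ model.loadings
    cols = [f"PC{i + 1}" for i in range(model.n_components)]
    out = pd.DataFrame(scores, index=list(x.sample_ids), columns=cols)
    out.index.name = "sample_id"
    return out


def correlate_scores(scores: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between each component and each numeric covariate.

    Missing pairs are dropped pairwise; correlations with fewer than 3
    paired observations or zero variance are reported as NaN.
    """
    common = scores.index.intersection(covariates.index)
    out = pd.DataFrame(index=scores.columns, columns=covariates.columns, dtype=float)
    for comp in scores.columns:
        a_all = scores.loc[common, comp]
        for cov in covariates.columns:
            b_all = pd.to_numeric(covariates.loc[common, cov], errors="coerce")
            mask = a_all.notna() & b_all.notna()
            a, b = a_all[mask].to_numpy(float), b_all[mask].to_numpy(float)
            if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
                out.loc[comp, cov] = np.nan
            else:
                out.loc[comp, cov] = float(np.corrcoef(a, b)[0, 1])
    return out
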