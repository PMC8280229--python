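"""Nearest-shrunken-centroids CMS classifier.

Training soft-thresholds the standardized class-centroid deviations

    d_kj = (xbar_kj - xbar_j) / (m_k * (s_j + s0)),   m_k = sqrt(1/n_k - 1/n)

by a tuning parameter ``t`` and rebuilds shrunken centroids
``xbar'_kj = xbar_j + m_k * (s_j + s0) * d'_kj``. ``s_j`` is the pooled
within-class standard deviation, ``s0`` the median of the ``s_j``.

Prediction uses the discriminant

    delta_k(s) = sum_j (x_js - xbar'_kj)^2 / (s_j + s0)^2 - 2 log pi_k

with posteriors proportional to ``exp(-delta_k / 2)``; calls with
maximum posterior below the confidence cutoff are reported as "NA"
(the nearest class is always reported alongside).

The shrinkage ``t`` is tuned by leave-one-out cross-validation with the
confidence gate disabled; ties are broken toward the largest (sparsest)
``t``. A random forest can be distilled from the confident calls so that
new cohorts can be classified without background adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from metacms.core_io import CMS_CLASSES, ExpressionMatrix
from metacms.features import FeatureSet

DEFAULT_SHRINKAGE = 1.5  # operating point of the published metastasis classifier
DEFAULT_CUTOFF = 0.5


@dataclass
class CentroidModel:
    """Trained nearest-shrunken-centroids model."""

    classes: list[str]
    feature_genes: list[str]
    overall_centroid: np.ndarray  # (p,)
    shrunken_centroids: np.ndarray  # (K, p)
    raw_centroids: np.ndarray  # (K, p)
    pooled_sd: np.ndarray  # (p,) s_j
    s0: float
    priors: np.ndarray  # (K,)
    threshold: float
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        self.overall_centroid = np.asarray(self.overall_centroid, dtype=float)
        self.shrunken_centroids = np.asarray(self.shrunken_centroids, dtype=float)
        self.raw_centroids = np.asarray(self.raw_centroids, dtype=float)
        self.pooled_sd = np.asarray(self.pooled_sd, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("class priors must sum to 1")

    @property
    def n_active_genes(self) -> int:
        """Genes whose shrunken centroid differs from the overall centroid."""
        dev = self.shrunken_centroids - self.overall_centroid
        return int(np.any(dev != 0.0, axis=0).sum())

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "feature_genes": self.feature_genes,
            "overall_centroid": self.overall_centroid.tolist(),
            "shrunken_centroids": self.shrunken_centroids.tolist(),
            "raw_centroids": self.raw_centroids.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "s0": self.s0,
            "priors": self.priors.tolist(),
            "threshold": self.threshold,
            "cutoff": self.cutoff,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CentroidModel":
        return cls(
            classes=list(d["classes"]),
            feature_genes=list(d["feature_genes"]),
            overall_centroid=np.array(d["overall_centroid"]),
            shrunken_centroids=np.array(d["shrunken_centroids"]),
            raw_centroids=np.array(d["raw_centroids"]),
            pooled_sd=np.array(d["pooled_sd"]),
            s0=float(d["s0"]),
            priors=np.array(d["priors"]),
            threshold=float(d["threshold"]),
            cutoff=float(d["cutoff"]),
        )


@dataclass
class TuningCurve:
    """LOOCV accuracy over a grid of shrinkage values."""

    t_grid: np.ndarray
    accuracies: np.ndarray
    chosen_t: float

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if ((self.accuracies < 0) | (self.accuracies > 1)).any():
            raise ValueError("accuracies must lie in [0, 1]")


def _class_statistics(values: np.ndarray, y: np.ndarray, classes: list[str]):
    """Per-class means, pooled within-class sd, counts. values: (p, n)."""
    p, n = values.shape
    K = len(classes)
    centroids = np.empty((K, p))
    ss = np.zeros(p)
    counts = np.empty(K, dtype=int)
    for k, cls in enumerate(classes):
        mask = y == cls
        counts[k] = int(mask.sum())
        sub = values[:, mask]
        centroids[k] = sub.mean(axis=1)
        ss += ((sub - centroids[k][:, None]) ** 2).sum(axis=1)
    pooled_sd = np.sqrt(ss / (n - K))
    return centroids, pooled_sd, counts


def _fit(values: np.ndarray, y: np.ndarray, classes: list[str], t: float):
    """Core NSC fit on a (p, n) matrix; returns all model arrays."""
    n = values.shape[1]
    centroids, pooled_sd, counts = _class_statistics(values, y, classes)
    overall = values.mean(axis=1)
    s0 = float(np.median(pooled_sd))
    m = np.sqrt(1.0 / counts - 1.0 / n)  # (K,)
    scale = m[:, None] * (pooled_sd + s0)[None, :]  # (K, p)
    d = (centroids - overall[None, :]) / scale
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - t, 0.0)
    shrunken = overall[None, :] + scale * d_shrunk
    # entries the threshold left untouched keep their raw centroid exactly
    # (avoids 1-ulp drift from the divide/multiply round trip at t = 0)
    shrunken = np.where(d_shrunk == d, centroids, shrunken)
    priors = counts / n
    return overall, centroids, shrunken, pooled_sd, s0, priors, d


def train_nsc(
    x: ExpressionMatrix,
    labels: pd.Series | dict,
    features: FeatureSet,
    t: float = DEFAULT_SHRINKAGE,
    cutoff: float = DEFAULT_CUTOFF,
) -> CentroidModel:
    """Train the shrunken-centroids classifier on labeled samples.

    Parameters
    ----------
    x : ExpressionMatrix
        Training expression (typically primary tumors).
    labels : mapping sample_id -> class
        Confident class labels; "NA" / missing labels are not allowed.
    features : FeatureSet
        Predictor genes; all must be present in ``x``.
    t : float
        Shrinkage threshold (>= 0).
    cutoff : float
        Posterior confidence cutoff stored with the model.
    """
    if t < 0:
        raise ValueError("shrinkage t must be non-negative")
    labels = pd.Series(labels)
    y = labels.reindex(x.sample_ids)
    if y.isna().any() or (y == "NA").any():
        bad = [s for s, v in zip(x.sample_ids, y) if pd.isna(v) or v == "NA"]
        raise ValueError(f"samples without a confident label: {bad[:10]}")
    classes = [c for c in CMS_CLASSES if c in set(y)]
    if len(classes) < 2:
        raise ValueError("need >=2 classes to train")
    counts = y.value_counts()
    small = [c for c in classes if counts[c] < 2]
    if small:
        raise ValueError(f"classes with <2 samples: {small}")
    sub = x.subset_genes(list(features))  # raises listing missing genes
    overall, raw, shrunken, pooled_sd, s0, priors, _ = _fit(
        sub.values, y.to_numpy(), classes, t
    )
    return CentroidModel(
        classes=classes,
        feature_genes=list(features),
        overall_centroid=overall,
        shrunken_centroids=shrunken,
        raw_centroids=raw,
        pooled_sd=pooled_sd,
        s0=s0,
        priors=priors,
        threshold=float(t),
        cutoff=float(cutoff),
    )


def _discriminants(model: CentroidModel, values: np.ndarray) -> np.ndarray:
    """delta_k(s) for a (p, n) matrix; returns (n, K)."""
    denom = (model.pooled_sd + model.s0) ** 2  # (p,)
    diff = values[None, :, :] - model.shrunken_centroids[:, :, None]  # (K, p, n)
    delta = (diff**2 / denom[None, :, None]).sum(axis=1)  # (K, n)
    delta -= 2.0 * np.log(model.priors)[:, None]
    return delta.T


def posteriors_from_discriminants(delta: np.ndarray) -> np.ndarray:
    """Normalized ``exp(-delta/2)`` rows, computed stably."""
    z = -0.5 * (delta - delta.min(axis=1, keepdims=True))
    w = np.exp(z)
    return w / w.sum(axis=1, keepdims=True)


def predict_nsc(
    model: CentroidModel,
    x: ExpressionMatrix,
    cutoff: float | None = None,
) -> pd.DataFrame:
    """Classify samples; returns a table indexed by sample id.

    Columns: one posterior per class, ``nearest`` (argmax class, never
    NA) and ``call`` (the confident label, "NA" below the cutoff).
    """
    c = model.cutoff if cutoff is None else float(cutoff)
    sub = x.subset_genes(model.feature_genes)
    if not np.all(np.isfinite(sub.values)):
        j = int(np.argwhere(~np.isfinite(sub.values))[0][1])
        raise ValueError(f"non-finite expression value in sample {x.sample_ids[j]!r}")
    delta = _discriminants(model, sub.values)
    post = posteriors_from_discriminants(delta)
    nearest_idx = np.argmax(post, axis=1)
    nearest = [model.classes[i] for i in nearest_idx]
    maxpost = post[np.arange(len(nearest)), nearest_idx]
    call = [nl if mp >= c else "NA" for nl, mp in zip(nearest, maxpost)]
    out = pd.DataFrame(post, index=list(x.sample_ids), columns=model.classes)
    out.index.name = "sample_id"
    out["nearest"] = nearest
    out["call"] = call
    return out


def tune_loocv(
    x: ExpressionMatrix,
    labels: pd.Series | dict,
    features: FeatureSet,
    t_grid: np.ndarray | list | None = None,
) -> TuningCurve:
    """Leave-one-out accuracy over a shrinkage grid.

    Each sample is predicted (by nearest class, no confidence gate) from
    a model fitted on the remaining samples. The chosen ``t`` maximizes
    accuracy; ties are broken toward the largest value.
    """
    labels = pd.Series(labels)
    y = labels.reindex(x.sample_ids).to_numpy()
    classes = [c for c in CMS_CLASSES if c in set(y)]
    sub = x.subset_genes(list(features))
    values = sub.values
    n = values.shape[1]
    if t_grid is None:
        *_, d_full = _fit(values, y, classes, 0.0)
        t_grid = np.linspace(0.0, float(np.abs(d_full).max()), 30)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("t_grid is empty")
    if (t_grid < 0).any():
        raise ValueError("t_grid contains negative values")

    correct = np.zeros(t_grid.size, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        vals_tr, y_tr = values[:, mask], y[mask]
        # class statistics are t-independent: compute once, threshold per t
        n_tr = n - 1
        centroids, pooled_sd, counts = _class_statistics(vals_tr, y_tr, classes)
        if (counts < 1).any():
            raise ValueError("a class vanishes in LOOCV; need >=2 samples per class")
        overall = vals_tr.mean(axis=1)
        s0 = float(np.median(pooled_sd))
        m = np.sqrt(1.0 / counts - 1.0 / n_tr)
        scale = m[:, None] * (pooled_sd + s0)[None, :]
        d = (centroids - overall[None, :]) / scale
        priors = counts / n_tr
        denom = (pooled_sd + s0) ** 2
        xi = values[:, i]
        for g, t in enumerate(t_grid):
            d_shrunk = np.sign(d) * np.maximum(np.abs(d) - t, 0.0)
            shrunken = overall[None, :] + scale * d_shrunk
            delta = ((xi[None, :] - shrunken) ** 2 / denom[None, :]).sum(
                axis=1
            ) - 2.0 * np.log(priors)
            if classes[int(np.argmin(delta))] == y[i]:
                correct[g] += 1
    acc = correct / n
    best = float(t_grid[np.max(np.flatnonzero(acc == acc.max()))])
    return TuningCurve(t_grid=t_grid, accuracies=acc, chosen_t=best)


def solve_confidence_cutoff(predictions: pd.DataFrame, target_na_fraction: float) -> float:
    """Cutoff yielding approximately the target NA fraction on a cohort.

    Returns the smallest cutoff such that the fraction of samples whose
    maximum posterior falls below it is >= ``target_na_fraction``.
    """
    if not 0.0 <= target_na_fraction <= 1.0:
        raise ValueError("target NA fraction must be in [0, 1]")
    classes = [c for c in CMS_CLASSES if c in predictions.columns]
    maxpost = np.sort(predictions[classes].to_numpy().max(axis=1))
    n = maxpost.size
    k = int(np.ceil(target_na_fraction * n))
    if k == 0:
        return 0.0
    # gate is "call if maxpost >= c": c just above the k-th smallest maxpost
    return float(np.nextafter(maxpost[k - 1], np.inf))


@dataclass
class DistilledForest:
    """Random forest distilled from confident NSC calls on raw expression."""

    classes: list[str]
    feature_genes: list[str]
    cutoff: float
    seed: int
    forest: RandomForestClassifier = field(repr=False)

    def predict(self, x: ExpressionMatrix, cutoff: float | None = None) -> pd.DataFrame:
        """Same output contract as :func:`predict_nsc`; posterior = vote share."""
        c = self.cutoff if cutoff is None else float(cutoff)
        sub = x.subset_genes(self.feature_genes)
        proba = self.forest.predict_proba(sub.values.T)
        # align sklearn's class order with ours
        order = [list(self.forest.classes_).index(cl) for cl in self.classes]
        post = proba[:, order]
        nearest_idx = np.argmax(post, axis=1)
        nearest = [self.classes[i] for i in nearest_idx]
        maxpost = post[np.arange(len(nearest)), nearest_idx]
        call = [nl if mp >= c else "NA" for nl, mp in zip(nearest, maxpost)]
        out = pd.DataFrame(post, index=list(x.sample_ids), columns=self.classes)
        out.index.name = "sample_id"
        out["nearest"] = nearest
        out["call"] = call
        return out


def distill_random_forest(
    nsc_calls: pd.DataFrame,
    x_raw: ExpressionMatrix,
    features: FeatureSet,
    n_trees: int = 500,
    seed: int = 0,
    cutoff: float = DEFAULT_CUTOFF,
) -> DistilledForest:
    """Train a forest on raw (unadjusted) expression against NSC calls.

    Samples with an "NA" call are excluded from training. The resulting
    model is applied directly to new cohorts without background
    adjustment; posteriors are tree-vote fractions gated at ``cutoff``.
    """
    confident = nsc_calls[nsc_calls["call"] != "NA"]
    labels = confident["call"]
    if labels.nunique() < 2:
        raise ValueError("need >=2 distinct confident labels to distill")
    sub = x_raw.subset_genes(list(features)).subset_samples(list(confident.index))
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
    )
    forest.fit(sub.values.T, labels.to_numpy())
    classes = [c for c in CMS_CLASSES if c in set(labels)]
    return DistilledForest(
        classes=classes,
        feature_genes=list(features),
        cutoff=float(cutoff),
        seed=int(seed),
        forest=forest,
    )
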