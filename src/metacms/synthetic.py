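"""Synthetic cohorts with known subtype structure and liver contamination.

Expression is generated in log2 space as baseline + class-block effects
+ Gaussian noise. Four 50-gene signature blocks carry the class signals
(CMS1 immune/MSI-like, CMS2 canonical, CMS3 metabolic, CMS4
mesenchymal); a fifth block holds hepatocyte markers that are silent in
tumors and highly expressed in the liver profile. Metastasis samples are
mixed as ``(1 - w) * tumor + w * liver`` at a controlled per-sample
weight ``w``; the liver profile also elevates the metabolic block, so
unadjusted contamination confounds classification. Metastasis class
frequencies follow configurable enrichment weights. Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from metacms.core_io import (
    CMS_CLASSES,
    ExpressionMatrix,
    GeneSetCollection,
    MarkerGeneList,
    SampleAnnotation,
)

# the 14 bundled gene-set names, mapped to sub-ranges of the class blocks
GENE_SET_BLOCKS: dict[str, tuple[str, float, float]] = {
    # name: (class block, start fraction, end fraction)
    "MSI": ("CMS1", 0.0, 0.5),
    "IMMUNE": ("CMS1", 0.5, 1.0),
    "MYC": ("CMS2", 0.0, 0.25),
    "CELL_CYCLE": ("CMS2", 0.25, 0.5),
    "WNT": ("CMS2", 0.5, 0.75),
    "DNA_REPAIR": ("CMS2", 0.75, 1.0),
    "HNF4A": ("CMS3", 0.0, 0.25),
    "GLYCOLYSIS": ("CMS3", 0.25, 0.5),
    "DIFFERENTIATION": ("CMS3", 0.5, 0.75),
    "LGR5_STEM": ("CMS3", 0.75, 1.0),
    "EMT": ("CMS4", 0.0, 0.34),
    "TGFB": ("CMS4", 0.34, 0.67),
    "STROMAL": ("CMS4", 0.67, 1.0),
}


@dataclass
class SyntheticConfig:
    """Generator parameters; ``seed`` is mandatory."""

    seed: int
    n_genes: int = 2000
    block_size: int = 50
    n_hepatocyte_markers: int = 50
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_range: tuple[float, float] = (4.0, 9.0)
    n_primaries_per_class: int = 60
    n_metastases: int = 120
    met_class_weights: tuple[float, float, float, float] = (0.05, 0.40, 0.05, 0.50)
    contamination_range: tuple[float, float] = (0.2, 0.5)
    contamination_weights: Sequence[float] | None = None  # overrides the range
    liver_marker_level: float = 10.0
    liver_metabolic_level: float = 3.0
    n_normal_liver: int = 10
    max_lesions_per_patient: int = 4
    n_reference_per_class: int = 15
    reference_effect_size: float = 3.0
    reference_noise_sd: float = 0.5
    mix_linear_space: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_genes < 4 * self.block_size + self.n_hepatocyte_markers:
            raise ValueError(
                "n_genes must accommodate 4 class blocks plus the marker block"
            )
        for name in ("n_primaries_per_class", "n_metastases", "block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.contamination_weights is not None:
            w = np.asarray(self.contamination_weights, dtype=float)
            if len(w) != self.n_metastases:
                raise ValueError("contamination_weights length != n_metastases")
            if ((w < 0) | (w > 1)).any():
                raise ValueError("contamination weights must lie in [0, 1]")
        lo, hi = self.contamination_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("contamination_range must satisfy 0 <= lo <= hi <= 1")
        if abs(sum(self.met_class_weights) - 1.0) > 1e-9:
            raise ValueError("met_class_weights must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("baseline_range", "met_class_weights", "contamination_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    # -- gene-block geometry -------------------------------------------------

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    def class_block(self, cms: str) -> slice:
        k = CMS_CLASSES.index(cms)
        return slice(k * self.block_size, (k + 1) * self.block_size)

    def marker_block(self) -> slice:
        start = 4 * self.block_size
        return slice(start, start + self.n_hepatocyte_markers)


@dataclass
class SyntheticCohort:
    """A generated cohort with complete ground truth."""

    expression: ExpressionMatrix
    truth: pd.DataFrame  # sample_id, sample_type, true_class, contamination
    annotation: SampleAnnotation
    gene_sets: GeneSetCollection
    markers: MarkerGeneList
    config: SyntheticConfig

    def _samples_of_type(self, sample_type: str) -> list[str]:
        t = self.truth
        return list(t.loc[t["sample_type"] == sample_type, "sample_id"])

    def primaries(self) -> ExpressionMatrix:
        return self.expression.subset_samples(self._samples_of_type("primary"))

    def metastases(self) -> ExpressionMatrix:
        return self.expression.subset_samples(self._samples_of_type("metastasis"))

    def normal_liver(self) -> ExpressionMatrix:
        return self.expression.subset_samples(self._samples_of_type("normal_liver"))

    def true_labels(self) -> pd.Series:
        return self.truth.set_index("sample_id")["true_class"]

    def contamination(self) -> pd.Series:
        return self.truth.set_index("sample_id")["contamination"]


def _liver_profile(config: SyntheticConfig, baseline: np.ndarray) -> np.ndarray:
    profile = baseline.copy()
    profile[config.marker_block()] += config.liver_marker_level
    # hepatocyte metabolic programs overlap the CMS3-metabolic block
    profile[config.class_block("CMS3")] += config.liver_metabolic_level
    return profile


def _tumor_sample(
    config: SyntheticConfig, baseline: np.ndarray, cms: str, rng: np.random.Generator
) -> np.ndarray:
    x = baseline + rng.normal(0.0, config.noise_sd, config.n_genes)
    x[config.class_block(cms)] += config.effect_size
    return x


def _mix(config: SyntheticConfig, tumor: np.ndarray, liver: np.ndarray, w: float):
    if config.mix_linear_space:
        return np.log2((1.0 - w) * 2.0**tumor + w * 2.0**liver)
    return (1.0 - w) * tumor + w * liver


def build_gene_sets(config: SyntheticConfig) -> GeneSetCollection:
    """The 14 bundled gene sets wired to the generator's blocks."""
    ids = np.array(config.gene_ids())
    sets: dict[str, list[str]] = {}
    for name, (cms, f0, f1) in GENE_SET_BLOCKS.items():
        block = ids[config.class_block(cms)]
        i0, i1 = int(round(f0 * len(block))), int(round(f1 * len(block)))
        sets[name] = list(block[i0:i1])
    # MSS mirrors the microsatellite-stable subtypes (CMS2 + CMS4 blocks)
    sets["MSS"] = list(ids[config.class_block("CMS2")]) + list(
        ids[config.class_block("CMS4")]
    )
    return GeneSetCollection(sets, {n: "synthetic block" for n in sets})


def build_marker_list(config: SyntheticConfig) -> MarkerGeneList:
    ids = config.gene_ids()
    return MarkerGeneList(ids[config.marker_block()])


def _lesion_structure(
    config: SyntheticConfig, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """(patient_id, lesion_id) per metastasis sample."""
    pairs: list[tuple[str, str]] = []
    pat = 0
    while len(pairs) < config.n_metastases:
        pat += 1
        n_lesions = int(rng.integers(1, config.max_lesions_per_patient + 1))
        for les in range(1, n_lesions + 1):
            n_samples = int(rng.integers(1, 3))  # 1 or 2 samples per lesion
            for _ in range(n_samples):
                pairs.append((f"p{pat:03d}", f"p{pat:03d}_l{les}"))
                if len(pairs) == config.n_metastases:
                    return pairs
    return pairs


def generate(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a full cohort: primaries, metastases, normal liver.

    Primaries carry balanced class labels with no contamination.
    Metastasis classes are drawn lesion-wise from the configured
    enrichment weights; every metastasis sample is mixed with the liver
    profile at its contamination weight. Normal-liver samples are pure
    liver profile plus noise.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = config.gene_ids()
    baseline = rng.uniform(*config.baseline_range, config.n_genes)
    liver = _liver_profile(config, baseline)

    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    truth_rows: list[dict] = []
    annot_rows: list[dict] = []

    # primary tumors: balanced classes, one lesion each
    for cms in CMS_CLASSES:
        for i in range(config.n_primaries_per_class):
            sid = f"P_{cms}_{i:03d}"
            columns.append(_tumor_sample(config, baseline, cms, rng))
            sample_ids.append(sid)
            truth_rows.append(
                {
                    "sample_id": sid,
                    "sample_type": "primary",
                    "true_class": cms,
                    "contamination": 0.0,
                }
            )
            annot_rows.append(
                {
                    "sample_id": sid,
                    "patient_id": f"pp_{cms}_{i:03d}",
                    "lesion_id": f"pp_{cms}_{i:03d}_l1",
                    "sample_type": "primary",
                    "treated": False,
                }
            )

    # metastases: lesion-wise classes, per-sample contamination
    structure = _lesion_structure(config, rng)
    lesion_class: dict[str, str] = {}
    if config.contamination_weights is not None:
        weights = np.asarray(config.contamination_weights, dtype=float)
    else:
        weights = rng.uniform(*config.contamination_range, config.n_metastases)
    for i, (patient, lesion) in enumerate(structure):
        if lesion not in lesion_class:
            lesion_class[lesion] = CMS_CLASSES[
                rng.choice(4, p=np.asarray(config.met_class_weights))
            ]
        cms = lesion_class[lesion]
        w = float(weights[i])
        sid = f"M_{i:03d}"
        tumor = _tumor_sample(config, baseline, cms, rng)
        liver_noisy = liver + rng.normal(0.0, config.noise_sd, config.n_genes)
        columns.append(_mix(config, tumor, liver_noisy, w))
        sample_ids.append(sid)
        truth_rows.append(
            {
                "sample_id": sid,
                "sample_type": "metastasis",
                "true_class": cms,
                "contamination": w,
            }
        )
        annot_rows.append(
            {
                "sample_id": sid,
                "patient_id": patient,
                "lesion_id": lesion,
                "sample_type": "metastasis",
                "treated": bool(rng.random() < 0.75),
            }
        )

    # normal liver reference samples
    for i in range(config.n_normal_liver):
        sid = f"N_{i:03d}"
        columns.append(liver + rng.normal(0.0, config.noise_sd, config.n_genes))
        sample_ids.append(sid)
        truth_rows.append(
            {
                "sample_id": sid,
                "sample_type": "normal_liver",
                "true_class": "NA",
                "contamination": 1.0,
            }
        )
        annot_rows.append(
            {
                "sample_id": sid,
                "patient_id": f"np_{i:03d}",
                "lesion_id": f"np_{i:03d}_l1",
                "sample_type": "normal_liver",
                "treated": False,
            }
        )

    # survival: poorer-prognosis classes die earlier, capped follow-up
    hazard_scale = {"CMS1": 24.0, "CMS3": 28.0, "CMS4": 40.0, "CMS2": 52.0, "NA": 48.0}
    annot = pd.DataFrame(annot_rows)
    truth = pd.DataFrame(truth_rows)
    per_patient = truth.merge(annot[["sample_id", "patient_id"]], on="sample_id")
    surv_time, surv_event = {}, {}
    for patient, grp in per_patient.groupby("patient_id", sort=False):
        worst = min(
            grp["true_class"],
            key=lambda c: ["CMS1", "CMS3", "CMS4", "CMS2", "NA"].index(c),
        )
        t = float(rng.exponential(hazard_scale[worst]))
        censor = float(rng.uniform(6.0, 90.0))
        surv_time[patient] = round(min(t, censor), 2)
        surv_event[patient] = int(t <= censor)
    annot["survival_time"] = annot["patient_id"].map(surv_time)
    annot["event"] = annot["patient_id"].map(surv_event)

    expr = ExpressionMatrix(gene_ids, sample_ids, np.column_stack(columns))
    return SyntheticCohort(
        expression=expr,
        truth=truth,
        annotation=SampleAnnotation(annot),
        gene_sets=build_gene_sets(config),
        markers=build_marker_list(config),
        config=config,
    )


def generate_reference_panel(config: SyntheticConfig) -> ExpressionMatrix:
    """Microenvironment-free reference profiles (cell lines/organoids).

    Class-intrinsic blocks at high expression, no hepatocyte signal, low
    noise — the intended input for feature selection. Uses an
    independent stream derived from the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    gene_ids = config.gene_ids()
    baseline = rng.uniform(*config.baseline_range, config.n_genes)
    columns, sample_ids = [], []
    for cms in CMS_CLASSES:
        for i in range(config.n_reference_per_class):
            x = baseline + rng.normal(0.0, config.reference_noise_sd, config.n_genes)
            x[config.class_block(cms)] += config.reference_effect_size
            columns.append(x)
            sample_ids.append(f"REF_{cms}_{i:02d}")
    return ExpressionMatrix(gene_ids, sample_ids, np.column_stack(columns))
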