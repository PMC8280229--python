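"""Intra-patient inter-lesion subtype heterogeneity and worst-subtype rule.

A patient is heterogeneous when at least two confidently classified
lesions carry different labels (unclassified lesions are excluded from
the determination). Multi-sample lesions are collapsed by majority vote
before comparison (ties give NA). Transcriptomic spread is summarized as
the maximum pairwise Euclidean distance over all of the patient's
samples in PC1-PC3 score space.

The worst-subtype stratification assigns, per patient: "CMS1/3" if any
lesion is CMS1 or CMS3; otherwise "CMS4" if any lesion is CMS4;
otherwise "CMS2" if any lesion is CMS2; otherwise "NA".
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
import pandas as pd

from metacms.core_io import SampleAnnotation

PC_COLUMNS = ("PC1", "PC2", "PC3")
REQUIRED_COLUMNS = ("patient_id", "lesion_id", "sample_id", "nearest", "call")


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"patient-lesion table missing columns: {missing}")
    trip = table[["patient_id", "lesion_id", "sample_id"]]
    if trip.duplicated().any():
        raise ValueError("duplicate (patient, lesion, sample) triples")


def _majority(labels: list[str]) -> str:
    """Majority label; NA on ties or when nothing usable remains."""
    usable = [l for l in labels if l not in (None, "NA") and not pd.isna(l)]
    if not usable:
        return "NA"
    counts = Counter(usable).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return "NA"
    return counts[0][0]


def collapse_lesions(table: pd.DataFrame, use_nearest: bool = False) -> pd.DataFrame:
    """One row per (patient, lesion) with a majority-vote label.

    With ``use_nearest`` the vote is over nearest labels (never NA
    per sample, though ties still yield NA); otherwise over confident
    calls only.
    """
    _validate_table(table)
    col = "nearest" if use_nearest else "call"
    rows = []
    for (pat, les), grp in table.groupby(["patient_id", "lesion_id"], sort=False):
        rows.append(
            {"patient_id": pat, "lesion_id": les, "label": _majority(list(grp[col]))}
        )
    return pd.DataFrame(rows)


def assess_heterogeneity(table: pd.DataFrame) -> pd.DataFrame:
    """Per-patient heterogeneity summary.

    Input columns: patient_id, lesion_id, sample_id, nearest, call, and
    optionally PC1-PC3. Returns one row per patient with sample/lesion
    counts, the set of distinct confident lesion labels, a heterogeneity
    flag, and the maximum pairwise PC1-PC3 distance (NaN when scores are
    missing).
    """
    _validate_table(table)
    lesions = collapse_lesions(table, use_nearest=False)
    rows = []
    for pat, grp in table.groupby("patient_id", sort=False):
        les = lesions[lesions["patient_id"] == pat]
        confident = [l for l in les["label"] if l != "NA"]
        distinct = sorted(set(confident))
        heterogeneous = len(confident) >= 2 and len(distinct) > 1
        max_dist = np.nan
        if all(c in grp.columns for c in PC_COLUMNS):
            pcs = grp[list(PC_COLUMNS)].apply(pd.to_numeric, errors="coerce")
            if not pcs.isna().any().any():
                pts = pcs.to_numpy(float)
                if len(pts) >= 2:
                    diff = pts[:, None, :] - pts[None, :, :]
                    max_dist = float(np.sqrt((diff**2).sum(axis=2)).max())
                else:
                    max_dist = 0.0
        rows.append(
            {
                "patient_id": pat,
                "n_samples": len(grp),
                "n_lesions": len(les),
                "n_confident_lesions": len(confident),
                "distinct_subtypes": ",".join(distinct) if distinct else "NA",
                "heterogeneous": heterogeneous,
                "max_pc_distance": max_dist,
            }
        )
    return pd.DataFrame(rows)


def worst_subtype_stratify(
    table: pd.DataFrame, use_nearest: bool = True
) -> pd.Series:
    """Patient stratum in {"CMS1/3", "CMS4", "CMS2", "NA"}.

    Applies the worst-subtype rule over lesion-level labels. With
    ``use_nearest`` (the survival-analysis convention) every sample
    contributes its nearest class, so NA strata cannot arise from
    unconfident calls.
    """
    lesions = collapse_lesions(table, use_nearest=use_nearest)
    strata = {}
    for pat, grp in lesions.groupby("patient_id", sort=False):
        labels = set(grp["label"]) - {"NA"}
        if labels & {"CMS1", "CMS3"}:
            strata[pat] = "CMS1/3"
        elif "CMS4" in labels:
            strata[pat] = "CMS4"
        elif "CMS2" in labels:
            strata[pat] = "CMS2"
        else:
            strata[pat] = "NA"
    out = pd.Series(strata, name="stratum")
    out.index.name = "patient_id"
    return out


def export_survival_table(
    strata: pd.Series,
    annotations: SampleAnnotation,
    cap_months: float = 60.0,
) -> pd.DataFrame:
    """Per-patient (stratum, time, event) table for survival tooling.

    Times beyond ``cap_months`` are censored at the cap (event set to
    0). Patients without survival data are omitted with a warning.
    """
    tab = annotations.table
    if "survival_time" not in tab.columns or "event" not in tab.columns:
        raise ValueError("annotations lack survival_time/event columns")
    per_patient = (
        tab[["patient_id", "survival_time", "event"]]
        .drop_duplicates(subset="patient_id")
        .set_index("patient_id")
    )
    rows = []
    for pat, stratum in strata.items():
        if pat not in per_patient.index:
            warnings.warn(f"patient {pat!r}: no annotation row, omitted", stacklevel=2)
            continue
        t = pd.to_numeric(per_patient.loc[pat, "survival_time"], errors="coerce")
        e = pd.to_numeric(per_patient.loc[pat, "event"], errors="coerce")
        if pd.isna(t) or pd.isna(e):
            warnings.warn(
                f"patient {pat!r}: missing survival fields, omitted", stacklevel=2
            )
            continue
        t, e = float(t), int(e)
        if t > cap_months:
            t, e = cap_months, 0
        rows.append({"patient_id": pat, "stratum": stratum, "time": t, "event": e})
    return pd.DataFrame(rows)
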