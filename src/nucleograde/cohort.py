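"""Patient-level aggregation.

Each patient is represented by the per-feature arithmetic mean over all
defined nucleus values, pooling nuclei across the patient's 4-5 images
(nucleus-level pooling, not image-level means of means).  A patient
entry is missing only when the feature was missing for every nucleus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .features import FEATURE_NAMES

log = logging.getLogger(__name__)

GROUP_LABELS = {"low": 0, "high": 1}


def _normalize_group(group) -> int:
    if isinstance(group, str):
        try:
            return GROUP_LABELS[group.lower()]
        except KeyError:
            raise ValueError(f"unknown group {group!r}; expected 'low' or 'high'")
    if group in (0, 1):
        return int(group)
    raise ValueError(f"group must be low/high or 0/1, got {group!r}")


@dataclass
class PatientProfile:
    """Mean 63-feature vector of one patient."""

    patient_id: str
    group: int  # low = 0, high = 1
    mean_vector: pd.Series
    n_images: int = 0
    n_nuclei: int = 0


def patient_mean(vectors, patient_id: str, group, n_images: int = 0) -> PatientProfile:
    """Average a patient's per-nucleus vectors feature-by-feature,
    skipping missing values (an entry stays missing only when every
    nucleus missed that feature)."""
    if isinstance(vectors, pd.DataFrame):
        frame = vectors
    else:
        frame = pd.DataFrame(list(vectors))
    if frame.empty:
        raise ValueError(f"patient {patient_id!r} has no nucleus vectors")
    missing_cols = set(FEATURE_NAMES) - set(frame.columns)
    if missing_cols:
        raise ValueError(f"vectors lack features: {sorted(missing_cols)[:3]}...")
    sub = frame[list(FEATURE_NAMES)].astype(float)
    n_missing = int(sub.isna().sum().sum())
    if n_missing:
        log.info("patient %s: %d missing nucleus feature values skipped", patient_id, n_missing)
    mean_vec = sub.mean(axis=0, skipna=True)
    return PatientProfile(
        patient_id=str(patient_id), group=_normalize_group(group),
        mean_vector=mean_vec, n_images=n_images, n_nuclei=len(sub),
    )


@dataclass
class CohortTable:
    """Patients-by-63 feature matrix with 0/1 group labels, ordered by
    (group, patient id)."""

    X: pd.DataFrame = field(repr=False)
    y: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.X.index.has_duplicates:
            dupes = self.X.index[self.X.index.duplicated()].tolist()
            raise ValueError(f"duplicate patient ids: {dupes}")
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y indices differ")

    @property
    def group_sizes(self) -> tuple[int, int]:
        return int((self.y == 0).sum()), int((self.y == 1).sum())

    def __len__(self) -> int:
        return len(self.X)

    def to_frame(self) -> pd.DataFrame:
        out = self.X.copy()
        out.insert(0, "group", self.y)
        return out.reset_index(names="patient_id")


def build_cohort(profiles: list[PatientProfile]) -> CohortTable:
    """Assemble patient profiles into a :class:`CohortTable`."""
    if not profiles:
        raise ValueError("no patient profiles")
    profiles = sorted(profiles, key=lambda p: (p.group, p.patient_id))
    X = pd.DataFrame(
        [p.mean_vector.reindex(FEATURE_NAMES) for p in profiles],
        index=pd.Index([p.patient_id for p in profiles], name="patient_id"),
    )
    y = pd.Series([p.group for p in profiles], index=X.index, name="group")
    return CohortTable(X=X, y=y)


def aggregate_features(features: pd.DataFrame, manifest: pd.DataFrame | None = None) -> CohortTable:
    """Cohort table from a per-nucleus feature table.

    ``features`` needs ``patient_id`` plus the 63 feature columns and
    either a ``group`` column or a manifest (patient_id, group) to join.
    """
    feats = features.copy()
    if "group" not in feats.columns:
        if manifest is None:
            raise ValueError("need a 'group' column or a manifest")
        mapping = manifest.drop_duplicates("patient_id").set_index("patient_id")["group"]
        feats["group"] = feats["patient_id"].map(mapping)
    profiles = []
    for (pid, grp), sub in feats.groupby(["patient_id", "group"], sort=True):
        n_images = sub["image_path"].nunique() if "image_path" in sub.columns else 0
        profiles.append(patient_mean(sub, pid, grp, n_images=n_images))
    return build_cohort(profiles)
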