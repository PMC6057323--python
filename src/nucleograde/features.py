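"""The 63-value per-nucleus feature vector.

Fixed canonical order: 54 textural features (histogram 1-4,
co-occurrence 5-17, run-length 18-22, wavelet 23-46, Tamura 47-52,
LBP 53-54) followed by the 9 morphological features (55-63).  Column
names are the lower-snake-cased feature names and this order is shared
by every table the package writes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .morphology import MORPHOLOGY_NAMES, morphology_vector
from .regions import NucleusRegion
from .texture import TEXTURE_NAMES, texture_vector

#: Canonical 63 feature names, items 1-63.
FEATURE_NAMES: tuple[str, ...] = TEXTURE_NAMES + MORPHOLOGY_NAMES
assert len(FEATURE_NAMES) == 63


def combine_vectors(texture: dict[str, float], shape: dict[str, float]) -> dict[str, float]:
    """Merge a 54-value texture dict and a 9-value shape dict into one
    ordered 63-value record, preserving missing (NaN) flags."""
    missing = (set(TEXTURE_NAMES) - set(texture)) | (set(MORPHOLOGY_NAMES) - set(shape))
    if missing:
        raise ValueError(f"incomplete feature families, missing {sorted(missing)[:3]}...")
    merged = {**texture, **shape}
    return {name: float(merged[name]) for name in FEATURE_NAMES}


def nucleus_features(region: NucleusRegion) -> dict[str, float]:
    """Full 63-value feature vector of one segmented nucleus."""
    return combine_vectors(texture_vector(region), morphology_vector(region.mask))


def features_frame(regions: list[NucleusRegion], **meta) -> pd.DataFrame:
    """One row per nucleus, columns = metadata + the 63 features."""
    rows = []
    for reg in regions:
        row = {"nucleus_label": reg.label, **meta}
        row.update(nucleus_features(reg))
        rows.append(row)
    cols = ["nucleus_label", *meta, *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=cols)


class NucleusFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer mapping a list of :class:`NucleusRegion` (or a list
    of such lists) to a DataFrame of 63-feature rows."""

    def fit(self, X=None, y=None):
        self.feature_names_out_ = list(FEATURE_NAMES)
        return self

    def transform(self, X) -> pd.DataFrame:
        if len(X) and isinstance(X[0], NucleusRegion):
            return features_frame(X)
        frames = [features_frame(regions, image_index=i) for i, regions in enumerate(X)]
        if not frames:
            return pd.DataFrame(columns=["nucleus_label", "image_index", *FEATURE_NAMES])
        return pd.concat(frames, ignore_index=True)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
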