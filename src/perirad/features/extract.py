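"""Feature-vector assembly over image types, masks, and families.

The bookkeeping that the default configuration must honor:
14 shape features on the original mask, plus 93 non-shape features
(18 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM) on
each of the 14 image types, i.e. 14 + 93 x 14 = 1,316 features per ROI.
Names follow ``<imageType>_<family>_<feature>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..filters import FilterConfig, derive_images
from ..image import RoiMask, Volume
from .firstorder import firstorder_features
from .shape import shape_features
from .texture import (DiscretizedRoi, discretize, glcm_features,
                      gldm_features, glrlm_features, glszm_features,
                      ngtdm_features)

DEFAULT_BIN_WIDTH = 25.0

NONSHAPE_FAMILIES = ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")


@dataclass(frozen=True)
class ExtractionConfig:
    """Extraction settings: discretization and the derived-image bank."""

    bin_width: float = DEFAULT_BIN_WIDTH
    filters: FilterConfig = field(default_factory=FilterConfig)
    include_shape: bool = True

    def image_type_names(self) -> list[str]:
        return self.filters.image_type_names()

    def expected_count(self) -> int:
        n_types = len(self.image_type_names())
        return (14 if self.include_shape else 0) + 93 * n_types


@dataclass(frozen=True)
class FeatureVector:
    """Ordered feature-name -> value map with provenance."""

    values: dict[str, float]
    case_id: str = ""
    mask_role: str = "intratumoral"
    ring_distance: float | None = None

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.case_id)


def _nonshape_block(volume: Volume, mask: RoiMask, image_type: str,
                    bin_width: float) -> dict[str, float]:
    droi = discretize(volume.values, mask.values, bin_width)
    vv = float(np.prod(volume.spacing))
    out: dict[str, float] = {}
    for fam, fn in (("firstorder", lambda d: firstorder_features(d, vv)),
                    ("glcm", glcm_features),
                    ("glrlm", glrlm_features),
                    ("glszm", glszm_features),
                    ("gldm", gldm_features),
                    ("ngtdm", ngtdm_features)):
        try:
            feats = fn(droi)
        except Exception as exc:  # pragma: no cover - defensive contract
            raise RuntimeError(
                f"{fam} extraction failed on image type {image_type!r}") from exc
        for name, val in feats.items():
            out[f"{image_type}_{fam}_{name}"] = val
    return out


def extract_feature_vector(volume: Volume, mask: RoiMask,
                           config: ExtractionConfig = ExtractionConfig(),
                           derived: dict[str, Volume] | None = None,
                           case_id: str = "") -> FeatureVector:
    """Full radiomics vector for one (volume, mask) pair.

    ``derived`` allows reuse of precomputed filter outputs when several
    masks share one volume (the intratumoral + four ring masks of a case).
    """
    if volume.shape != mask.shape:
        raise ValueError("volume and mask grids differ")
    if mask.is_empty():
        raise ValueError("empty ROI mask")
    values: dict[str, float] = {}
    if config.include_shape:
        for name, val in shape_features(mask.values, volume.spacing).items():
            values[f"original_shape_{name}"] = val
    if derived is None:
        derived = derive_images(volume, config.filters)
    for image_type in config.image_type_names():
        values.update(_nonshape_block(derived[image_type], mask, image_type,
                                      config.bin_width))
    bad = [k for k, v in values.items() if not np.isfinite(v)]
    if bad:
        raise RuntimeError(f"non-finite feature values: {bad[:5]}")
    return FeatureVector(values=values, case_id=case_id, mask_role=mask.role,
                         ring_distance=mask.ring_distance)


def extract_case_features(volume: Volume, masks: dict[str, RoiMask],
                          config: ExtractionConfig = ExtractionConfig(),
                          case_id: str = "") -> dict[str, FeatureVector]:
    """Vectors for several masks of one case, sharing the filter bank."""
    derived = derive_images(volume, config.filters)
    return {key: extract_feature_vector(volume, m, config, derived, case_id)
            for key, m in masks.items()}


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack vectors into a cases x features DataFrame with provenance columns."""
    rows = []
    for v in vectors:
        row = {"case_id": v.case_id, "mask_role": v.mask_role,
               "ring_distance": v.ring_distance}
        row.update(v.values)
        rows.append(row)
    return pd.DataFrame(rows)
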