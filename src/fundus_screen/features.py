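"""Six scalar lesion features for maculopathy classification.

For each of the exudate mask and its macula-region restriction: the total
on-pixel area, and the mean and sample standard deviation of the areas of
its 8-connected components.  The triple is (0, 0, 0) for an empty mask and
the SD is 0 when there are fewer than two components.

An alternative reading of the "mean of on pixels" — the mean intensity of
the on pixels in a grey image — is available via ``on_pixel_intensity_stats``
but is not part of the default feature vector.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import FEATURE_NAMES, FeatureVector, LesionMaps, validate_gray, validate_mask

_EIGHT = np.ones((3, 3), dtype=int)


def _mask_triple(mask: np.ndarray) -> tuple[float, float, float]:
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return 0.0, 0.0, 0.0
    areas = np.bincount(labels.ravel())[1:].astype(float)
    sd = float(areas.std(ddof=1)) if n >= 2 else 0.0
    return float(areas.sum()), float(areas.mean()), sd


def extract_features(maps: LesionMaps) -> FeatureVector:
    """Compute the six-feature vector from a pair of lesion masks."""
    ex_area, ex_mean, ex_sd = _mask_triple(maps.exudates)
    mac_area, mac_mean, mac_sd = _mask_triple(maps.maculopathy)
    return FeatureVector(ex_area, ex_mean, ex_sd, mac_area, mac_mean, mac_sd)


def on_pixel_intensity_stats(img: np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    """Area, mean and sample SD of the *intensities* under the mask
    (documented variant of the component-area statistics)."""
    a = validate_gray(img)
    m = validate_mask(mask, a.shape)
    vals = a[m].astype(float)
    if vals.size == 0:
        return 0.0, 0.0, 0.0
    sd = float(vals.std(ddof=1)) if vals.size >= 2 else 0.0
    return float(vals.size), float(vals.mean()), sd


def feature_table(
    image_ids: Sequence[str],
    vectors: Iterable[FeatureVector],
    labels: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Assemble per-image feature vectors into a tidy table."""
    rows = [fv.as_array() for fv in vectors]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    df.insert(0, "image_id", list(image_ids))
    if labels is not None:
        df["label"] = [bool(x) for x in labels]
    return df


def write_feature_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
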