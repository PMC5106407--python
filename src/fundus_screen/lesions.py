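"""Exudate segmentation and exudative-maculopathy identification.

Exudates — bright lipid deposits — are segmented from the contrast-enhanced
green channel by a fixed global threshold (default 135), after masking out
the optic disc (the only other comparably bright structure) and the vessel
network.  Exudates falling inside the macula region constitute exudative
maculopathy, the sight-threatening form of the disease.
"""

from __future__ import annotations

import numpy as np

from .types import Circle, LesionMaps, MaculaRegion, OpticDisc, validate_gray, validate_mask

DEFAULT_EXUDATE_THRESHOLD = 135
"""Default global grey-level threshold separating exudates from background
on the equalised green channel."""

OD_EXCLUSION_DD_FRACTION = 0.1
"""The optic-disc exclusion circle is dilated by this fraction of DD to
suppress bright rim bleed-through."""


def detect_exudates(
    img: np.ndarray,
    od: OpticDisc | None,
    vessels: np.ndarray | None,
    t: float = DEFAULT_EXUDATE_THRESHOLD,
) -> np.ndarray:
    """Global-threshold exudate segmentation.

    Pixels strictly brighter than ``t`` are exudate candidates; the optic
    disc (dilated by 10% of DD) and the vessel mask are removed.  ``od`` and
    ``vessels`` may be ``None`` to skip the respective masking step.
    """
    a = validate_gray(img)
    if not 0 <= t <= 255:
        raise ValueError(f"threshold must lie in [0, 255], got {t}")
    mask = a > t
    if od is not None:
        excl = Circle(od.row, od.col, od.radius + OD_EXCLUSION_DD_FRACTION * od.dd)
        mask &= ~excl.mask(a.shape)
    if vessels is not None:
        mask &= ~validate_mask(vessels, a.shape)
    return mask


def detect_maculopathy(exudates: np.ndarray, macula: MaculaRegion) -> LesionMaps:
    """Restrict the exudate mask to the macula region.

    The maculopathy mask is the intersection of the exudate mask with the
    1.3 DD macula circle; maculopathy is present iff that intersection is
    non-empty.
    """
    ex = validate_mask(exudates)
    mac = ex & macula.circle.mask(ex.shape)
    return LesionMaps(ex, mac, bool(mac.any()))
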