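"""End-to-end screening of a single colour fundus photograph.

The pipeline enhances the green channel twice: once directly (optic disc,
macula and exudates are bright/dark structures of the green channel) and
once after intensity complement (vessels become the bright thin structures
a white tophat isolates).  It then localises the optic disc and macula,
segments vessels, applies the global exudate threshold with disc and
vessel masking, restricts exudates to the macula region, and extracts the
six-feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import lesions, preprocess, structures
from .features import extract_features
from .preprocess import BpdfheParams, FsmParams
from .structures import VesselParams
from .types import FeatureVector, FundusImage, LesionMaps, MaculaRegion, OpticDisc


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable parameters of the full screening pipeline."""

    fsm: FsmParams = field(default_factory=FsmParams)
    bpdfhe: BpdfheParams = field(default_factory=BpdfheParams)
    vessels: VesselParams = field(default_factory=VesselParams)
    rmin_frac: float = 0.03
    rmax_frac: float = 0.08
    exudate_threshold: float = lesions.DEFAULT_EXUDATE_THRESHOLD
    macula_method: str = "geometric"
    macula_side: str = "auto"
    centre_radius_frac: float = 0.12  # macula radius as a width fraction (centre method)

    def __post_init__(self) -> None:
        if self.macula_method not in ("geometric", "centre"):
            raise ValueError(f"macula_method must be geometric or centre, got {self.macula_method!r}")


@dataclass(frozen=True)
class ScreenResult:
    """All intermediate and final products of screening one image."""

    green: np.ndarray
    enhanced: np.ndarray
    enhanced_complement: np.ndarray
    od: OpticDisc
    macula: MaculaRegion
    vessels: np.ndarray
    lesions: LesionMaps
    features: FeatureVector

    @property
    def maculopathy_present(self) -> bool:
        return self.lesions.maculopathy_present


def field_of_view_mask(img: FundusImage | np.ndarray, green: np.ndarray) -> np.ndarray:
    """The circular field of view: the recorded mask if present, otherwise the
    non-black region of the green channel."""
    if isinstance(img, FundusImage) and img.fov_mask is not None:
        return img.fov_mask
    return green > 8


def screen_image(img: FundusImage | np.ndarray, config: ScreenConfig = ScreenConfig()) -> ScreenResult:
    """Run the full screening chain on one RGB fundus image."""
    green = preprocess.extract_green_channel(img)
    fov = field_of_view_mask(img, green)
    enhanced = preprocess.enhance(green, config.fsm, config.bpdfhe, mask=fov)
    comp = preprocess.enhance(preprocess.complement(green), config.fsm, config.bpdfhe, mask=fov)

    od = structures.detect_optic_disc(enhanced, config.rmin_frac, config.rmax_frac)
    vessel_mask = structures.segment_vessels(comp, config.vessels) & fov
    if config.macula_method == "geometric":
        vessel_free = structures.remove_vessels(enhanced, vessel_mask)
        macula = structures.locate_macula_geometric(vessel_free, od, side=config.macula_side)
    else:
        radius = config.centre_radius_frac * green.shape[1]
        macula = structures.locate_macula_image_centre(enhanced, radius)

    exudates = lesions.detect_exudates(enhanced, od, vessel_mask, config.exudate_threshold) & fov
    maps = lesions.detect_maculopathy(exudates, macula)
    return ScreenResult(
        green=green,
        enhanced=enhanced,
        enhanced_complement=comp,
        od=od,
        macula=macula,
        vessels=vessel_mask,
        lesions=maps,
        features=extract_features(maps),
    )
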