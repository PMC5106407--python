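"""Core value types shared across the screening pipeline.

Conventions used throughout the package:

* images are 2-D (grey) or 3-D ``(H, W, 3)`` (RGB) ``uint8`` numpy arrays,
  intensities in ``[0, 255]``;
* coordinates are ``(row, col)``, 0-based, origin at the top-left corner;
* circle membership is closed: a pixel belongs to a circle iff its centre
  distance is ``<= radius``;
* binary masks are 2-D boolean arrays of the same shape as the image they
  refer to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class ScreeningError(Exception):
    """Base class for domain errors raised by the pipeline."""


class NoDiscFoundError(ScreeningError):
    """Raised when no credible optic-disc circle is found in an image."""


class MaculaOutOfFrameError(ScreeningError):
    """Raised when the macula search region lies entirely outside the image."""


def validate_gray(img: np.ndarray) -> np.ndarray:
    """Validate and return a grey image as a ``uint8`` array.

    Accepts any integer or float array with values in ``[0, 255]``.
    """
    a = np.asarray(img)
    if a.ndim != 2:
        raise ValueError(f"grey image must be 2-D, got shape {a.shape}")
    if a.size == 0:
        raise ValueError("grey image must be non-empty")
    if a.dtype != np.uint8:
        if np.any(a < 0) or np.any(a > 255):
            raise ValueError("grey image values must lie in [0, 255]")
        a = a.astype(np.uint8)
    return a


def validate_mask(mask: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Validate a binary mask, optionally against an expected shape."""
    m = np.asarray(mask)
    if m.dtype != bool:
        m = m.astype(bool)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    if shape is not None and m.shape != tuple(shape):
        raise ValueError(f"mask shape {m.shape} does not match image shape {tuple(shape)}")
    return m


@dataclass(frozen=True)
class Circle:
    """A circle in image coordinates: centre ``(row, col)`` and radius, in pixels."""

    row: float
    col: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"circle radius must be positive, got {self.radius}")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean membership mask on a raster of the given shape (closed disc)."""
        h, w = shape
        rr, cc = np.ogrid[:h, :w]
        return (rr - self.row) ** 2 + (cc - self.col) ** 2 <= self.radius**2


@dataclass(frozen=True)
class OpticDisc:
    """Optic-disc localisation: a circle plus the disc diameter DD = 2 * radius.

    DD is the clinical unit of retinal distance used for macula geometry
    (the fovea sits roughly 2 DD temporal to the disc centre).
    """

    circle: Circle

    @property
    def dd(self) -> float:
        return 2.0 * self.circle.radius

    @property
    def row(self) -> float:
        return self.circle.row

    @property
    def col(self) -> float:
        return self.circle.col

    @property
    def radius(self) -> float:
        return self.circle.radius


@dataclass(frozen=True)
class MaculaRegion:
    """Macula region: a 1.3 DD-diameter circle centred on the fovea.

    ``angle_deg`` is the signed angle (positive = up) of the fovea from the
    horizontal line through the optic-disc centre; anatomically it stays
    within +/-37 degrees.
    """

    circle: Circle
    fovea: tuple[float, float]
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.angle_deg) > 37.0 + 1e-9:
            raise ValueError(f"macula angle {self.angle_deg} outside +/-37 degrees")
        fr, fc = self.fovea
        if abs(fr - self.circle.row) > 1e-6 or abs(fc - self.circle.col) > 1e-6:
            raise ValueError("fovea must coincide with the macula circle centre")


@dataclass(frozen=True)
class LesionMaps:
    """Exudate mask, its restriction to the macula region, and the presence flag."""

    exudates: np.ndarray
    maculopathy: np.ndarray
    maculopathy_present: bool

    def __post_init__(self) -> None:
        ex = validate_mask(self.exudates)
        mac = validate_mask(self.maculopathy, ex.shape)
        if np.any(mac & ~ex):
            raise ValueError("maculopathy mask must be a subset of the exudate mask")
        if bool(mac.any()) != bool(self.maculopathy_present):
            raise ValueError("maculopathy_present inconsistent with the maculopathy mask")
        object.__setattr__(self, "exudates", ex)
        object.__setattr__(self, "maculopathy", mac)

    @classmethod
    def from_masks(cls, exudates: np.ndarray, maculopathy: np.ndarray) -> "LesionMaps":
        mac = validate_mask(maculopathy)
        return cls(exudates, mac, bool(mac.any()))


FEATURE_NAMES = ("ex_area", "ex_mean", "ex_sd", "mac_area", "mac_mean", "mac_sd")


@dataclass(frozen=True)
class FeatureVector:
    """The six scalar lesion features.

    ``*_area`` is the total on-pixel count of a mask; ``*_mean`` / ``*_sd``
    are the mean and sample standard deviation of its 8-connected
    component areas (0 when the mask has fewer than two components).
    """

    ex_area: float
    ex_mean: float
    ex_sd: float
    mac_area: float
    mac_mean: float
    mac_sd: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals < 0):
            raise ValueError("features must be non-negative")
        if self.mac_area > self.ex_area:
            raise ValueError("maculopathy area cannot exceed exudate area")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.ex_area, self.ex_mean, self.ex_sd, self.mac_area, self.mac_mean, self.mac_sd],
            dtype=float,
        )


@dataclass(frozen=True)
class FundusImage:
    """An 8-bit RGB colour fundus photograph with its circular field-of-view mask."""

    rgb: np.ndarray
    fov_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.rgb)
        if a.ndim != 3 or a.shape[2] != 3:
            raise ValueError(f"fundus image must be (H, W, 3) RGB, got shape {a.shape}")
        if a.dtype != np.uint8:
            if np.any(a < 0) or np.any(a > 255):
                raise ValueError("RGB values must lie in [0, 255]")
            a = a.astype(np.uint8)
        object.__setattr__(self, "rgb", a)
        if self.fov_mask is not None:
            object.__setattr__(self, "fov_mask", validate_mask(self.fov_mask, a.shape[:2]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]


def warn(message: str) -> None:
    warnings.warn(message, UserWarning, stacklevel=3)
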