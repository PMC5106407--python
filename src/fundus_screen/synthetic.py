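"""Seeded synthetic fundus-image generator with full ground truth.

The generator emulates the image properties the detectors rely on: a dark
circular field of view on black, a bright circular optic disc, a darker
macula about two disc diameters (DD) temporal to the disc within +/-37
degrees of the horizontal, a branching vessel tree growing out of the
disc, a smooth illumination gradient, optional salt-and-pepper noise, and
planted bright exudate blobs with soft (Gaussian-profile) edges so that
behaviour near the global exudate threshold is testable.  Every planted
structure is returned as ground truth, so each pipeline stage can be
scored against a known answer without any external image data.

It does not attempt photorealism: there is no texture of the nerve-fibre
layer, no haemorrhages or microaneurysms, no colour calibration, and blob
shapes are circular.  Conclusions drawn from it concern the geometry and
contrast logic of the pipeline, not performance on clinical photographs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .types import Circle, FundusImage, MaculaRegion, OpticDisc

MACULA_REGION_DD = 1.3  # macula-region diameter in DD units


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic fundus image.

    Geometry defaults follow a 600 x 900 optic-disc-centred view with a
    45 px disc; ``exudate_blobs`` is a tuple of ``(row, col, radius,
    intensity)`` bright lesions.  All randomness (vessel tree, noise,
    texture) is driven by ``seed`` alone, so equal specs yield bit-equal
    images.
    """

    height: int = 600
    width: int = 900
    od_row: float = 300.0
    od_col: float = 650.0
    od_radius: float = 45.0
    od_intensity: int = 200
    background_intensity: int = 92
    macula_depth: int = 45
    macula_angle_deg: float = 0.0
    macula_dist_dd: float = 2.0
    n_vessel_branches: int = 7
    vessel_intensity: int = 60
    exudate_blobs: tuple[tuple[float, float, float, float], ...] = ()
    noise_density: float = 0.0
    illumination_gradient: float = 14.0
    blob_mode: str = "soft"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.od_radius <= 0:
            raise ValueError("od_radius must be positive")
        if self.macula_depth <= 0:
            raise ValueError("macula_depth must be positive")
        if abs(self.macula_angle_deg) > 37:
            raise ValueError("macula_angle_deg must lie in [-37, 37]")
        if not 0 <= self.noise_density <= 1:
            raise ValueError("noise_density must lie in [0, 1]")
        if self.blob_mode not in ("soft", "hard"):
            raise ValueError(f"blob_mode must be soft or hard, got {self.blob_mode!r}")
        for _, _, rad, inten in self.exudate_blobs:
            if inten <= self.background_intensity:
                raise ValueError("exudate intensity must exceed the background")
            if rad <= 0:
                raise ValueError("exudate radius must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structures of a synthetic image."""

    od: OpticDisc
    macula: MaculaRegion
    vessels: np.ndarray
    exudate_truth: np.ndarray
    maculopathy_label: bool


def _fov_geometry(spec: SyntheticSpec) -> tuple[float, float, float]:
    h, w = spec.height, spec.width
    return h / 2.0, w / 2.0, min(h, w) / 2.0 - 4.0


def _macula_position(spec: SyntheticSpec) -> tuple[float, float]:
    # temporal side: towards the image's vertical midline
    sign = 1.0 if spec.od_col <= spec.width / 2 else -1.0
    dd = 2.0 * spec.od_radius
    rad = math.radians(spec.macula_angle_deg)
    r = spec.od_row - spec.macula_dist_dd * dd * math.sin(rad)
    c = spec.od_col + sign * spec.macula_dist_dd * dd * math.cos(rad)
    return r, c


def _stamp_disk(mask: np.ndarray, row: float, col: float, radius: float) -> None:
    h, w = mask.shape
    r0, r1 = max(0, int(row - radius) - 1), min(h, int(row + radius) + 2)
    c0, c1 = max(0, int(col - radius) - 1), min(w, int(col + radius) + 2)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.ogrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] |= (rr - row) ** 2 + (cc - col) ** 2 <= radius**2


def _grow_vessels(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Random-walk vessel tree emanating from the optic disc."""
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=bool)
    fr, fc, fov_r = _fov_geometry(spec)
    n_steps = int(0.55 * w)
    for _ in range(spec.n_vessel_branches):
        ang = rng.uniform(0, 2 * math.pi)
        r, c = spec.od_row, spec.od_col
        width0 = rng.uniform(1.5, 2.5)
        for step in range(n_steps):
            ang += rng.normal(0.0, 0.12)
            r -= math.sin(ang) * 2.0
            c += math.cos(ang) * 2.0
            if (r - fr) ** 2 + (c - fc) ** 2 > (fov_r - 3) ** 2:
                break
            width = max(0.8, width0 * (1.0 - 0.6 * step / n_steps))
            _stamp_disk(mask, r, c, width)
            if rng.random() < 0.01 and step > 20:  # occasional bifurcation kink
                ang += rng.choice([-1.0, 1.0]) * rng.uniform(0.3, 0.7)
    return mask


def generate(spec: SyntheticSpec = SyntheticSpec()) -> tuple[FundusImage, GroundTruth]:
    """Render one synthetic fundus photograph and its ground truth.

    Raises ``ValueError`` when the optic disc or macula falls outside the
    circular field of view.
    """
    h, w = spec.height, spec.width
    fr, fc, fov_r = _fov_geometry(spec)
    rr, cc = np.mgrid[0:h, 0:w]
    fov = (rr - fr) ** 2 + (cc - fc) ** 2 <= fov_r**2

    dd = 2.0 * spec.od_radius
    if math.hypot(spec.od_row - fr, spec.od_col - fc) + spec.od_radius > fov_r:
        raise ValueError("optic disc falls outside the field of view")
    mac_r, mac_c = _macula_position(spec)
    mac_radius = 0.5 * MACULA_REGION_DD * dd
    if math.hypot(mac_r - fr, mac_c - fc) + mac_radius > fov_r:
        raise ValueError("macula falls outside the field of view")

    rng = np.random.default_rng(spec.seed)

    green = np.full((h, w), float(spec.background_intensity))
    # smooth horizontal illumination gradient plus spatially correlated
    # texture (retinal background varies smoothly, not pixel-to-pixel)
    green += spec.illumination_gradient * (cc - w / 2.0) / w
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), sigma=10.0)
    sd = texture.std()
    if sd > 0:
        green += texture * (1.5 / sd)

    # macula: soft dark pit centred on the fovea
    d_mac = np.hypot(rr - mac_r, cc - mac_c)
    green -= spec.macula_depth * np.exp(-0.5 * (d_mac / (0.45 * mac_radius)) ** 2)

    # vessels: dark tree from the disc
    vessels = _grow_vessels(spec, rng)
    green[vessels] = spec.vessel_intensity + rng.normal(0.0, 1.0, size=int(vessels.sum()))

    # optic disc: bright plateau with a soft rim
    d_od = np.hypot(rr - spec.od_row, cc - spec.od_col)
    od_profile = np.clip((spec.od_radius + 2.0 - d_od) / 4.0, 0.0, 1.0)
    green = green + (spec.od_intensity - green) * od_profile

    # exudates: bright blobs, solid core with optional Gaussian skirt
    exudate_truth = np.zeros((h, w), dtype=bool)
    for br, bc, brad, binten in spec.exudate_blobs:
        d = np.hypot(rr - br, cc - bc)
        core = d <= brad
        exudate_truth |= core
        if spec.blob_mode == "soft":
            profile = np.where(core, 1.0, np.exp(-0.5 * ((d - brad) / 2.0) ** 2))
        else:
            profile = core.astype(float)
        green = np.maximum(green, green + (binten - green) * profile)

    green = np.clip(green, 0, 255)
    green[~fov] = 0.0

    if spec.noise_density > 0:
        noisy = rng.random((h, w)) < spec.noise_density
        noisy &= fov
        salt = rng.random((h, w)) < 0.5
        green[noisy & salt] = 255.0
        green[noisy & ~salt] = 0.0

    g8 = green.astype(np.uint8)
    rgb = np.stack(
        [
            np.clip(green * 1.35 + 20.0, 0, 255).astype(np.uint8),
            g8,
            np.clip(green * 0.35, 0, 255).astype(np.uint8),
        ],
        axis=-1,
    )
    rgb[~fov] = 0

    sign = 1.0 if spec.od_col <= w / 2 else -1.0
    angle = math.degrees(
        math.atan2(-(mac_r - spec.od_row), sign * (mac_c - spec.od_col))
    )
    macula = MaculaRegion(
        Circle(mac_r, mac_c, mac_radius), fovea=(mac_r, mac_c), angle_deg=angle
    )
    od = OpticDisc(Circle(spec.od_row, spec.od_col, spec.od_radius))
    label = bool((exudate_truth & macula.circle.mask((h, w))).any())
    truth = GroundTruth(od, macula, vessels, exudate_truth, label)
    return FundusImage(rgb, fov_mask=fov), truth


def _random_blobs(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    n_inside: int,
    n_outside: int,
) -> tuple[tuple[float, float, float, float], ...]:
    """Place exudate blobs inside and/or safely outside the macula circle."""
    mac_r, mac_c = _macula_position(spec)
    dd = 2.0 * spec.od_radius
    mac_radius = 0.5 * MACULA_REGION_DD * dd
    fr, fc, fov_r = _fov_geometry(spec)
    blobs: list[tuple[float, float, float, float]] = []
    for _ in range(n_inside):
        rad = rng.uniform(0.06, 0.12) * dd
        dist = rng.uniform(0.0, mac_radius - rad - 2.0)
        ang = rng.uniform(0, 2 * math.pi)
        blobs.append(
            (
                mac_r - dist * math.sin(ang),
                mac_c + dist * math.cos(ang),
                rad,
                rng.uniform(195.0, 220.0),
            )
        )
    attempts = 0
    while n_outside > 0 and attempts < 200:
        attempts += 1
        rad = rng.uniform(0.06, 0.12) * dd
        r = rng.uniform(fr - 0.6 * fov_r, fr + 0.6 * fov_r)
        c = rng.uniform(fc - 0.6 * fov_r, fc + 0.6 * fov_r)
        if math.hypot(r - fr, c - fc) + rad > fov_r - 5:
            continue
        if math.hypot(r - mac_r, c - mac_c) < mac_radius + rad + 6:
            continue  # must stay clear of the macula circle
        if math.hypot(r - spec.od_row, c - spec.od_col) < spec.od_radius + 0.2 * dd + rad + 4:
            continue  # the disc exclusion zone would swallow it
        blobs.append((r, c, rad, rng.uniform(195.0, 220.0)))
        n_outside -= 1
    return tuple(blobs)


def cohort_spec(seed: int, positive: bool, *, height: int = 320, width: int = 480) -> SyntheticSpec:
    """Randomised per-image spec used by :func:`generate_cohort`."""
    rng = np.random.default_rng(seed)
    od_radius = 0.05 * width * rng.uniform(0.9, 1.1)
    left_eye = rng.random() < 0.5
    od_col = (0.30 if left_eye else 0.70) * width + rng.normal(0.0, 4.0)
    base = SyntheticSpec(
        height=height,
        width=width,
        od_row=height / 2.0 + rng.normal(0.0, 6.0),
        od_col=od_col,
        od_radius=od_radius,
        macula_angle_deg=float(rng.uniform(-25.0, 25.0)),
        macula_dist_dd=float(rng.uniform(1.85, 2.15)),
        noise_density=0.01,
        seed=seed,
    )
    n_inside = int(rng.integers(1, 4)) if positive else 0
    n_outside = int(rng.integers(0, 3))
    blobs = _random_blobs(rng, base, n_inside, n_outside)
    return replace(base, exudate_blobs=blobs)


def generate_cohort(
    n: int,
    pos_fraction: float,
    seed: int = 0,
    *,
    height: int = 320,
    width: int = 480,
) -> tuple[list[FundusImage], list[GroundTruth]]:
    """Generate a seeded cohort with a fixed fraction of maculopathy-positive eyes.

    Exactly ``round(n * pos_fraction)`` images carry at least one exudate
    blob inside the macula circle; the rest carry exudates (if any) only
    outside it.  Per-image seeds derive deterministically from the master
    seed.
    """
    if n < 2:
        raise ValueError("cohort needs at least 2 images")
    if not 0.0 < pos_fraction < 1.0:
        raise ValueError("pos_fraction must lie strictly between 0 and 1")
    n_pos = int(round(n * pos_fraction))
    if n_pos == 0 or n_pos == n:
        raise ValueError("pos_fraction leaves one class empty for this n")
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)
    flags = np.zeros(n, dtype=bool)
    flags[:n_pos] = True
    np.random.default_rng(seed).shuffle(flags)
    images: list[FundusImage] = []
    truths: list[GroundTruth] = []
    for i in range(n):
        spec = cohort_spec(int(child_seeds[i]), bool(flags[i]), height=height, width=width)
        img, truth = generate(spec)
        if truth.maculopathy_label != bool(flags[i]):
            raise RuntimeError("blob placement violated the intended label")
        images.append(img)
        truths.append(truth)
    return images, truths
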