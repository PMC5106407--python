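"""Fuzzy image-quality enhancement for colour fundus photographs.

The enhancement chain is: green-channel extraction, optional intensity
complement, fuzzy switching median (FSM) noise filtering, and brightness
preserving dynamic fuzzy histogram equalisation (BPDFHE).

The green channel carries most of the structural contrast of a fundus
photograph (the red channel is near-saturated, the blue channel noisy),
so all downstream detectors operate on it.  The FSM filter removes
salt-and-pepper acquisition noise while leaving uncorrupted detail
untouched; BPDFHE stretches contrast without shifting mean brightness,
which keeps a fixed exudate threshold meaningful across images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import FundusImage, validate_gray


@dataclass(frozen=True)
class FsmParams:
    """Fuzzy switching median filter parameters.

    ``t1`` and ``t2`` are the lower and upper thresholds (grey levels) of the
    fuzzy noise-membership ramp applied to the local maximum absolute
    intensity difference; ``window`` is the odd side length of the median
    neighbourhood.
    """

    t1: float = 10.0
    t2: float = 30.0
    window: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.t1 < self.t2 <= 255):
            raise ValueError(f"need 0 <= t1 < t2 <= 255, got t1={self.t1}, t2={self.t2}")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")


@dataclass(frozen=True)
class BpdfheParams:
    """BPDFHE parameters.

    ``fuzz_radius`` is the half-width (grey levels) of the triangular fuzzy
    membership that spreads each pixel over neighbouring histogram bins;
    ``smoothing_width`` is the odd moving-average width used when locating
    histogram local maxima; ``range_rule`` selects how the output dynamic
    range is allocated across histogram partitions: ``"span"`` (proportional
    to input span) or ``"span_log_count"`` (span times log10(count + 1)).
    """

    fuzz_radius: int = 4
    smoothing_width: int = 5
    range_rule: str = "span_log_count"

    def __post_init__(self) -> None:
        if self.fuzz_radius < 1:
            raise ValueError(f"fuzz_radius must be >= 1, got {self.fuzz_radius}")
        if self.smoothing_width < 1 or self.smoothing_width % 2 == 0:
            raise ValueError(f"smoothing_width must be odd, got {self.smoothing_width}")
        if self.range_rule not in ("span", "span_log_count"):
            raise ValueError(f"unknown range_rule {self.range_rule!r}")


def _as_rgb(img: FundusImage | np.ndarray) -> np.ndarray:
    a = img.rgb if isinstance(img, FundusImage) else np.asarray(img)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError(f"expected an RGB image with 3 channels, got shape {a.shape}")
    return a


def extract_green_channel(img: FundusImage | np.ndarray) -> np.ndarray:
    """Return the green channel of an RGB fundus image, values unchanged."""
    return validate_gray(_as_rgb(img)[:, :, 1])


def to_greyscale(img: FundusImage | np.ndarray) -> np.ndarray:
    """ITU-R BT.601 weighted-luma greyscale conversion (0.299 R + 0.587 G + 0.114 B)."""
    a = _as_rgb(img).astype(float)
    luma = 0.299 * a[:, :, 0] + 0.587 * a[:, :, 1] + 0.114 * a[:, :, 2]
    return np.clip(np.floor(luma + 0.5), 0, 255).astype(np.uint8)


def complement(img: np.ndarray) -> np.ndarray:
    """Intensity complement ``255 - x`` (an involution)."""
    return (255 - validate_gray(img)).astype(np.uint8)


def fsm_filter(img: np.ndarray, p: FsmParams = FsmParams()) -> np.ndarray:
    """Fuzzy switching median filter for salt-and-pepper noise.

    For every pixel ``x`` the filter computes the window median ``m`` and the
    noise evidence ``d`` = maximum absolute difference between ``x`` and its
    window neighbours.  A fuzzy membership ``f`` ramps linearly from 0 at
    ``t1`` to 1 at ``t2``; the output is ``round((1 - f) x + f m)``.  Pixels
    in locally flat regions (``d < t1``) pass through unchanged, so the
    filter does not blur noise-free detail the way a plain median does.
    """
    a = validate_gray(img)
    if p.window > min(a.shape):
        raise ValueError(f"window {p.window} exceeds image extent {a.shape}")
    f = a.astype(float)
    med = ndimage.median_filter(f, size=p.window, mode="reflect")
    hi = ndimage.maximum_filter(f, size=p.window, mode="reflect")
    lo = ndimage.minimum_filter(f, size=p.window, mode="reflect")
    d = np.maximum(hi - f, f - lo)
    memb = np.clip((d - p.t1) / (p.t2 - p.t1), 0.0, 1.0)
    out = np.floor((1.0 - memb) * f + memb * med + 0.5)
    return np.clip(out, 0, 255).astype(np.uint8)


def _fuzzy_histogram(a: np.ndarray, fuzz_radius: int) -> np.ndarray:
    # integer grey levels: the fuzzy histogram is the crisp histogram
    # convolved with a triangular membership kernel of half-width fuzz_radius
    hist = np.bincount(a.ravel(), minlength=256).astype(float)
    offsets = np.arange(-(fuzz_radius - 1), fuzz_radius)
    kernel = 1.0 - np.abs(offsets) / fuzz_radius
    return np.convolve(hist, kernel, mode="same")


def bpdfhe(
    img: np.ndarray,
    p: BpdfheParams = BpdfheParams(),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Brightness preserving dynamic fuzzy histogram equalisation.

    Four steps: (1) build the fuzzy (triangular-membership) histogram;
    (2) partition it at the local maxima of a moving-average-smoothed copy;
    (3) equalise each partition into an output sub-range allocated over the
    full display range according to ``range_rule``; (4) rescale the result
    multiplicatively so the output mean matches the input mean, rounding
    half-up and clipping to ``[0, 255]``.

    The per-partition mapping is monotone non-decreasing, so intensity order
    is preserved within partitions.  A constant image is returned unchanged.

    ``mask`` (e.g. the circular field-of-view of a fundus photograph)
    restricts the histogram, the mapping and the brightness normalisation to
    the masked pixels; pixels outside it are returned unchanged.  Without it
    the black surround of a fundus image would dominate the histogram.
    """
    a = validate_gray(img)
    if mask is not None:
        from .types import validate_mask

        m = validate_mask(mask, a.shape)
        if not m.any():
            return a.copy()
        out = a.copy()
        out[m] = bpdfhe_values(a[m], p)
        return out
    return _bpdfhe_full(a, p)


def bpdfhe_values(values: np.ndarray, p: BpdfheParams = BpdfheParams()) -> np.ndarray:
    """BPDFHE applied to a flat array of grey values (helper for masked use)."""
    return _bpdfhe_full(np.atleast_2d(values), p).reshape(values.shape)


def _bpdfhe_full(a: np.ndarray, p: BpdfheParams) -> np.ndarray:
    lo, hi = int(a.min()), int(a.max())
    if lo == hi:
        return a.copy()

    fh = _fuzzy_histogram(a, p.fuzz_radius)
    sw = p.smoothing_width
    smooth = np.convolve(fh, np.ones(sw) / sw, mode="same")

    # local maxima strictly inside the occupied grey range partition it
    maxima = [
        i
        for i in range(lo + 1, hi)
        if smooth[i] > 0 and smooth[i] > smooth[i - 1] and smooth[i] >= smooth[i + 1]
    ]
    edges = [lo] + maxima + [hi]

    spans = []
    counts = []
    sub_bins = []
    for k in range(len(edges) - 1):
        start = edges[k] + (1 if k > 0 else 0)
        stop = edges[k + 1]
        bins = np.arange(start, stop + 1)
        sub_bins.append(bins)
        spans.append(max(edges[k + 1] - edges[k], 1))
        counts.append(fh[bins].sum())

    spans = np.asarray(spans, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if p.range_rule == "span":
        factors = spans
    else:
        factors = spans * np.log10(counts + 1.0)
    if factors.sum() <= 0:
        factors = spans
    ranges = 255.0 * factors / factors.sum()
    starts = np.concatenate([[0.0], np.cumsum(ranges)[:-1]])

    mapping = np.arange(256, dtype=float)
    for bins, rng, start, cnt in zip(sub_bins, ranges, starts, counts):
        if cnt <= 0:
            mapping[bins] = start
            continue
        cdf = np.cumsum(fh[bins]) / cnt
        mapping[bins] = start + rng * cdf

    out = mapping[a]
    out_mean = out.mean()
    if out_mean > 0:
        out = out * (a.mean() / out_mean)
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def enhance(
    green: np.ndarray,
    fsm: FsmParams = FsmParams(),
    bp: BpdfheParams = BpdfheParams(),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """FSM noise filtering followed by BPDFHE contrast enhancement."""
    return bpdfhe(fsm_filter(green, fsm), bp, mask=mask)
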