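"""Background estimation and the baseline ratio methods.

Three background-subtraction baselines for ratiometric imaging:

* distant (mean) background — a scalar per channel from a box far from
  any cell, subtracted from both channels before division (MBS);
* halfway background — a scalar midway between the distant value and the
  mask threshold, emulating deliberate over-subtraction;
* nonuniform background — a per-pixel field built by sampling intensity
  just outside the cell edge, Gaussian-smoothing it along the contour and
  interpolating inward by inverse-distance weighting.

All three leave the denominator noise-dominated near the cell edge, which
is the artifact the NCF method (see :mod:`ncfratio.ncf`) removes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import EdgeContour

__all__ = [
    "RatioResult",
    "box_background",
    "mbs_ratio",
    "halfway_background",
    "sample_edge_intensity",
    "smooth_contour_gaussian",
    "interpolate_background",
    "nonuniform_ratio",
    "estimate_nonuniform_background",
]

log = logging.getLogger(__name__)


@dataclass
class RatioResult:
    """A per-pixel ratio map with its validity mask and full provenance.

    ``invalid`` flags pixels where the denominator after subtraction was
    <= 0 or either input was non-finite; the ratio is NaN there and such
    pixels are excluded from every downstream statistic.
    """

    ratio: np.ndarray
    method: str  # MBS | halfway | nonuniform | NCF
    invalid: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def valid(self) -> np.ndarray:
        return ~self.invalid


def box_background(
    image: np.ndarray,
    box: tuple[int, int, int, int],
    mask: np.ndarray | None = None,
    min_area: int = 100,
) -> tuple[float, float]:
    """Mean and sample standard deviation over a rectangular background box.

    ``box`` is (row0, col0, height, width); it must lie inside the image,
    be disjoint from ``mask`` (if given) and cover at least ``min_area`` px.
    """
    image = np.asarray(image, dtype=float)
    r0, c0, h, w = box
    if r0 < 0 or c0 < 0 or r0 + h > image.shape[0] or c0 + w > image.shape[1]:
        raise ValueError(f"box {box} exceeds image bounds {image.shape}")
    if h * w < min_area:
        raise ValueError(f"box area {h * w} px below minimum {min_area} px")
    if mask is not None and np.asarray(mask, bool)[r0 : r0 + h, c0 : c0 + w].any():
        raise ValueError(f"background box {box} overlaps the cell mask")
    patch = image[r0 : r0 + h, c0 : c0 + w]
    return float(patch.mean()), float(patch.std(ddof=1))


def _ratio(
    num: np.ndarray, den: np.ndarray, method: str, params: dict
) -> RatioResult:
    invalid = (den <= 0) | ~np.isfinite(num) | ~np.isfinite(den)
    ratio = np.full(num.shape, np.nan)
    ok = ~invalid
    ratio[ok] = num[ok] / den[ok]
    n_invalid = int(invalid.sum())
    params = dict(params, n_invalid=n_invalid)
    if n_invalid == invalid.size:
        log.warning("%s ratio: every pixel invalid (denominator <= 0)", method)
    elif n_invalid:
        log.info("%s ratio: %d invalid pixels", method, n_invalid)
    return RatioResult(ratio=ratio, method=method, invalid=invalid, params=params)


def mbs_ratio(
    img1: np.ndarray, img2: np.ndarray, bg1: float, bg2: float,
    method: str = "MBS",
) -> RatioResult:
    """Mean background subtraction: (img1 - bg1) / (img2 - bg2)."""
    img1 = np.asarray(img1, dtype=float)
    img2 = np.asarray(img2, dtype=float)
    if img1.shape != img2.shape:
        raise ValueError(f"shape mismatch: {img1.shape} vs {img2.shape}")
    return _ratio(
        img1 - bg1, img2 - bg2, method, {"bg1": float(bg1), "bg2": float(bg2)}
    )


def halfway_background(distant_mean: float, mask_threshold_value: float) -> float:
    """Background value halfway between the distant-box mean and the mask
    threshold (the intensity right at the cell edge)."""
    if mask_threshold_value < distant_mean:
        raise ValueError(
            f"mask threshold {mask_threshold_value} below distant background "
            f"{distant_mean}: inconsistent segmentation"
        )
    return 0.5 * (distant_mean + mask_threshold_value)


def sample_edge_intensity(image: np.ndarray, contour: EdgeContour) -> EdgeContour:
    """Fill ``contour.raw_intensity`` with image values in traversal order.

    Only outer-side contours are accepted: the local background must be
    sampled just outside the cell, never on biosensor-bearing pixels.
    """
    if contour.side != "outer":
        raise ValueError("background must be sampled on an outer-side contour")
    image = np.asarray(image, dtype=float)
    rows, cols = contour.pixels[:, 0], contour.pixels[:, 1]
    return EdgeContour(
        pixels=contour.pixels,
        side=contour.side,
        component_id=contour.component_id,
        closed=contour.closed,
        raw_intensity=image[rows, cols],
        smoothed_intensity=contour.smoothed_intensity,
    )


def smooth_contour_gaussian(
    intensity: np.ndarray, sigma: float, closed: bool = True
) -> np.ndarray:
    """Gaussian smoothing along the contour, kernel truncated at +/-3 sigma
    with weights renormalized to sum to 1.

    Closed contours are treated as periodic; open contours use reflective
    padding.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    intensity = np.asarray(intensity, dtype=float)
    if intensity.ndim != 1 or intensity.size < 3:
        raise ValueError("contour intensity must be 1-D with length >= 3")
    mode = "wrap" if closed else "reflect"
    return ndimage.gaussian_filter1d(intensity, sigma, mode=mode, truncate=3.0)


def interpolate_background(
    contour: EdgeContour,
    domain: np.ndarray,
    m: float = 2.0,
    subsample: int = 1,
    _chunk: int = 8192,
) -> np.ndarray:
    """Inverse-distance-power interpolation of the smoothed edge intensity.

    BG(x, y) = sum_i Ibar(i) / d_i^m / sum_i 1 / d_i^m over contour pixels,
    with d_i the Euclidean distance from contour pixel i to (x, y); a pixel
    coinciding with contour pixel i gets exactly Ibar(i).  ``subsample``
    keeps every k-th contour pixel to bound the O(domain x contour) cost.
    """
    if contour.smoothed_intensity is None:
        raise ValueError("contour has no smoothed intensity; smooth it first")
    if m <= 0:
        raise ValueError(f"exponent m must be > 0, got {m}")
    pts = np.asarray(contour.pixels, dtype=float)[::subsample]
    vals = np.asarray(contour.smoothed_intensity, dtype=float)[::subsample]
    if pts.shape[0] == 0:
        raise ValueError("empty contour")
    domain = np.asarray(domain, dtype=bool)
    rows, cols = np.nonzero(domain)
    out = np.full(domain.shape, np.nan)
    coords = np.stack([rows, cols], axis=1).astype(float)
    for lo in range(0, coords.shape[0], _chunk):
        block = coords[lo : lo + _chunk]
        d2 = (
            (block[:, None, 0] - pts[None, :, 0]) ** 2
            + (block[:, None, 1] - pts[None, :, 1]) ** 2
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            wgt = d2 ** (-0.5 * m)
            wsum = wgt.sum(axis=1)
            bg = (wgt * vals[None, :]).sum(axis=1) / wsum
        # pixels coinciding with a contour point take its value exactly
        hits = d2 == 0.0
        any_hit = hits.any(axis=1)
        if any_hit.any():
            first_hit = hits[any_hit].argmax(axis=1)
            bg[any_hit] = vals[first_hit]
        out[rows[lo : lo + _chunk], cols[lo : lo + _chunk]] = bg
    return out


def nonuniform_ratio(
    img1: np.ndarray,
    img2: np.ndarray,
    bg1_field: np.ndarray,
    bg2_field: np.ndarray,
    params: dict | None = None,
) -> RatioResult:
    """Per-pixel background subtraction: (img1 - BG1(x,y)) / (img2 - BG2(x,y))."""
    img1 = np.asarray(img1, dtype=float)
    img2 = np.asarray(img2, dtype=float)
    bg1_field = np.asarray(bg1_field, dtype=float)
    bg2_field = np.asarray(bg2_field, dtype=float)
    shapes = {img1.shape, img2.shape, bg1_field.shape, bg2_field.shape}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch among inputs: {shapes}")
    return _ratio(
        img1 - bg1_field, img2 - bg2_field, "nonuniform", dict(params or {})
    )


def estimate_nonuniform_background(
    image: np.ndarray,
    mask: np.ndarray,
    sigma: float = 10.0,
    m: float = 2.0,
    subsample: int = 1,
    domain: np.ndarray | None = None,
) -> np.ndarray:
    """Edge-sampled, contour-smoothed, inverse-distance-interpolated
    background field for one channel.

    Samples the intensity on the outer contour of every component of
    ``mask``, smooths along each contour (sigma in contour-pixel units) and
    interpolates over ``domain`` (default: whole image).  With several
    components the per-component contour samples are pooled into one
    interpolation, matching the per-pixel formula.
    """
    from .geometry import extract_edge_contour

    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if domain is None:
        domain = np.ones_like(mask)
    contours = extract_edge_contour(mask, side="outer")
    pixels, smoothed = [], []
    for c in contours:
        c = sample_edge_intensity(image, c)
        sm = smooth_contour_gaussian(c.raw_intensity, sigma, closed=c.closed)
        pixels.append(c.pixels)
        smoothed.append(sm)
    pooled = EdgeContour(
        pixels=np.concatenate(pixels, axis=0),
        side="outer",
        component_id=0,
        closed=False,
        smoothed_intensity=np.concatenate(smoothed),
    )
    return interpolate_background(pooled, domain, m=m, subsample=subsample)
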