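"""Edge-artifact diagnostics for ratio maps.

Distance profiles (mean ratio vs distance from the cell edge), the
relative-range flatness metric, per-band edge statistics with Welch
t-tests, the 3-sigma pixel classification and display composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .background import RatioResult

__all__ = [
    "DistanceProfile",
    "BandStats",
    "distance_profile",
    "relative_range",
    "edge_band_stats",
    "classify_pixels",
    "render_ratio_map",
]


@dataclass
class DistanceProfile:
    """Per-integer-distance-bin statistics of a ratio map.

    Bin d collects valid in-mask pixels with ceil(distance) == d, so bin 1
    is the innermost contour layer.  Bins with fewer than ``min_bin_count``
    pixels are dropped.
    """

    bins: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    n: np.ndarray


@dataclass
class BandStats:
    """Statistics of one contour-parallel band of pixels.

    ``band_offset`` counts pixel layers from the cell edge: +1 is the
    innermost in-cell layer, -1 the first background layer outside; the
    geometric edge itself (offset 0) lies between the two and holds no
    pixels.  ``p_adjacent`` is the two-sided Welch t-test against the next
    band inward (offset + 1); ``p_bonferroni`` multiplies it by the number
    of adjacent-band tests performed.
    """

    band_offset: int
    mean: float
    se: float
    n: int
    p_adjacent: float | None
    p_bonferroni: float | None


def _ratio_and_valid(ratio) -> tuple[np.ndarray, np.ndarray, str | None]:
    if isinstance(ratio, RatioResult):
        return ratio.ratio, ratio.valid, ratio.method
    arr = np.asarray(ratio, dtype=float)
    return arr, np.isfinite(arr), None


def distance_profile(
    ratio,
    distmap: np.ndarray,
    max_d: int | None = None,
    min_bin_count: int = 50,
) -> DistanceProfile:
    """Bin valid in-mask ratio pixels by ceil(distance-from-edge)."""
    values, valid, _ = _ratio_and_valid(ratio)
    distmap = np.asarray(distmap, dtype=float)
    if values.shape != distmap.shape:
        raise ValueError("ratio and distance map shapes differ")
    sel = (distmap > 0) & valid
    if max_d is not None:
        sel &= distmap <= max_d
    if not sel.any():
        raise ValueError("no valid in-mask pixel to profile")
    bins = np.ceil(distmap[sel]).astype(int)
    vals = values[sel]
    n = np.bincount(bins)
    s1 = np.bincount(bins, weights=vals)
    s2 = np.bincount(bins, weights=vals**2)
    keep = n >= max(min_bin_count, 1)
    keep[0] = False
    if not keep.any():
        raise ValueError(
            f"no distance bin reaches min_bin_count={min_bin_count}"
        )
    d = np.flatnonzero(keep)
    mean = s1[keep] / n[keep]
    var = (s2[keep] - n[keep] * mean**2) / np.maximum(n[keep] - 1, 1)
    return DistanceProfile(
        bins=d, mean=mean, std=np.sqrt(np.maximum(var, 0.0)), n=n[keep]
    )


def relative_range(
    profile: DistanceProfile,
    d_range: tuple[float, float] | None = None,
) -> float:
    """Flatness metric (max_d<I> - min_d<I>) / min_d<I> over reported bins."""
    means = profile.mean
    if d_range is not None:
        sel = (profile.bins >= d_range[0]) & (profile.bins <= d_range[1])
        means = means[sel]
    if means.size < 2:
        raise ValueError("relative range needs >= 2 distance bins")
    mn = float(means.min())
    if mn <= 0:
        raise ValueError(f"minimum bin mean {mn:g} <= 0: metric undefined")
    return (float(means.max()) - mn) / mn


def band_offset_map(mask: np.ndarray) -> np.ndarray:
    """Signed integer layer index for every pixel: ceil of the Euclidean
    distance, positive inside the mask, negative outside."""
    mask = np.asarray(mask, dtype=bool)
    d_in = ndimage.distance_transform_edt(mask)
    d_out = ndimage.distance_transform_edt(~mask)
    out = np.where(mask, np.ceil(d_in), -np.ceil(d_out))
    return out.astype(int)


def edge_band_stats(
    ratio,
    mask: np.ndarray,
    offsets,
) -> list[BandStats]:
    """Mean, SE and adjacent-band Welch t-tests per contour-parallel band.

    Negative offsets (bands outside the cell) require an NCF-method ratio:
    background-subtracted methods are noise-over-noise there and carry no
    usable signal.
    """
    offsets = [int(o) for o in offsets]
    if sorted(offsets) != list(range(min(offsets), max(offsets) + 1)):
        raise ValueError("offsets must form a contiguous integer range")
    values, valid, method = _ratio_and_valid(ratio)
    if method is not None and method != "NCF" and any(o < 0 for o in offsets):
        raise ValueError(
            f"negative band offsets are undefined for the {method} method; "
            "use the NCF ratio"
        )
    layer = band_offset_map(mask)
    samples: dict[int, np.ndarray] = {}
    for off in range(min(offsets), max(offsets) + 2):
        sel = (layer == off) & valid
        samples[off] = values[sel]

    def _inward(off: int) -> np.ndarray:
        # offset 0 is the geometric edge line and holds no pixels: the
        # band just outside (-1) is adjacent to the band just inside (+1)
        nxt = off + 1 if off != -1 else 1
        return samples.get(nxt, np.empty(0))

    n_tests = sum(
        1
        for off in offsets
        if samples[off].size >= 2 and _inward(off).size >= 2
    )
    out: list[BandStats] = []
    for off in offsets:
        v = samples[off]
        if v.size == 0:
            out.append(BandStats(off, np.nan, np.nan, 0, None, None))
            continue
        mean = float(v.mean())
        se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan
        inward = _inward(off)
        if v.size >= 2 and inward.size >= 2:
            p = float(stats.ttest_ind(v, inward, equal_var=False).pvalue)
            p_adj = min(1.0, p * max(n_tests, 1))
        else:
            p = p_adj = None
        out.append(BandStats(off, mean, se, int(v.size), p, p_adj))
    return out


def classify_pixels(
    image: np.ndarray,
    mask_threshold: float,
    bg_mean: float,
    bg_std: float,
) -> np.ndarray:
    """Three-way pixel classification from the background-box statistics.

    Labels: 2 = in_cell (>= mask threshold), 0 = background
    (< bg_mean + 3*bg_std), 1 = near_edge_bg (in between; a pixel exactly
    at bg_mean + 3*bg_std falls in this middle class).
    """
    if bg_std < 0:
        raise ValueError("bg_std must be >= 0")
    image = np.asarray(image, dtype=float)
    cut = bg_mean + 3.0 * bg_std
    labels = np.ones(image.shape, dtype=np.uint8)
    labels[image < cut] = 0
    labels[image >= mask_threshold] = 2
    if mask_threshold < cut:
        warnings.warn(
            "mask threshold below bg_mean + 3*std: near_edge_bg class is "
            "empty by construction"
        )
    return labels


def render_ratio_map(
    ratio,
    mask: np.ndarray,
    mode: str = "bg_to_mean",
) -> tuple[np.ndarray, tuple[float, float]]:
    """Compose a ratio map for display.

    ``bg_to_mean`` replaces out-of-mask (and invalid) pixels with the mean
    valid in-mask ratio — a display convention only, never fed back into
    statistics.  ``raw`` passes values through.  Scale bounds are the
    in-mask 1st/99th percentiles.
    """
    if mode not in ("raw", "bg_to_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    values, valid, _ = _ratio_and_valid(ratio)
    mask = np.asarray(mask, dtype=bool)
    in_ok = mask & valid
    if not in_ok.any():
        raise ValueError("no valid in-mask pixel to render")
    lo, hi = np.percentile(values[in_ok], [1.0, 99.0])
    if mode == "raw":
        return values.copy(), (float(lo), float(hi))
    display = values.copy()
    display[~in_ok] = values[in_ok].mean()
    return display, (float(lo), float(hi))
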