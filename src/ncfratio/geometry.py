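"""Cell masks and the spatial structures derived from them.

Everything downstream of segmentation — edge contours, distance-from-edge
maps, the eroded interior used for high-SNR statistics and the dilated
near-edge background ring used for NCF calibration — is built here.

Conventions: 0-based (row, col) indexing, row-major; distances in pixel
units; foreground is 8-connected, background 4-connected.  An optional
``pixel_size_um`` tag travels with images read from disk but never enters
any computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "EmptyMaskError",
    "EdgeContour",
    "RegionSet",
    "threshold_mask",
    "extract_edge_contour",
    "distance_from_edge",
    "build_region_set",
    "line_scan",
]

# 8-connectivity structuring element for foreground labelling
_STRUCT8 = np.ones((3, 3), dtype=bool)

# Moore neighbourhood in clockwise order starting straight up (row, col offsets)
_CLOCKWISE = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)
_CLOCKWISE_INDEX = {d: k for k, d in enumerate(_CLOCKWISE)}


class EmptyMaskError(ValueError):
    """Raised when a mask operation produces no foreground pixels."""


@dataclass
class EdgeContour:
    """An ordered traversal of the boundary of one connected component.

    ``pixels`` is an (n, 2) integer array of (row, col) coordinates.  For
    ``side='inner'`` these are mask pixels adjacent to background, traced
    clockwise by Moore boundary following from the topmost-then-leftmost
    boundary pixel.  For ``side='outer'`` they are background pixels
    8-adjacent to the mask, ordered by projection onto the inner traversal.
    """

    pixels: np.ndarray
    side: str
    component_id: int
    closed: bool
    raw_intensity: np.ndarray | None = None
    smoothed_intensity: np.ndarray | None = None

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.pixels)


@dataclass
class RegionSet:
    """A mask plus its derived analysis regions.

    interior
        mask pixels deeper than ``depth_in`` from the edge (Euclidean).
    bg_ring
        background pixels within ``depth_out`` of the mask, excluding
        every cell mask in the scene and an optional border margin.
    bg_box
        (row0, col0, height, width) of the distant background rectangle.
    """

    mask: np.ndarray
    interior: np.ndarray
    bg_ring: np.ndarray
    bg_box: tuple[int, int, int, int] | None = None
    params: dict = field(default_factory=dict)


def threshold_mask(
    image: np.ndarray,
    threshold: float,
    min_area: int = 1,
) -> np.ndarray:
    """Global-threshold segmentation: keep 8-connected components of
    ``image >= threshold`` with at least ``min_area`` pixels, holes filled.
    """
    image = np.asarray(image, dtype=float)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    fg = image >= threshold
    labels, n = ndimage.label(fg, structure=_STRUCT8)
    if n == 0:
        raise EmptyMaskError(
            f"no pixel reaches threshold {threshold!r}: empty mask"
        )
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_area)
    keep = keep[keep != 0]
    if keep.size == 0:
        raise EmptyMaskError(
            f"no component of >= {min_area} px at threshold {threshold!r}: empty mask"
        )
    mask = np.isin(labels, keep)
    # fill holes with 4-connected background (dual of 8-connected foreground)
    return ndimage.binary_fill_holes(mask)


def _trace_moore(comp: np.ndarray) -> list[tuple[int, int]]:
    """Clockwise Moore boundary trace of a padded component (Jacob's stop)."""
    rows, cols = np.nonzero(comp)
    order = np.lexsort((cols, rows))  # topmost, then leftmost
    start = (int(rows[order[0]]), int(cols[order[0]]))
    # single isolated pixel
    if not any(
        comp[start[0] + dr, start[1] + dc] for dr, dc in _CLOCKWISE
    ):
        return [start]
    contour = [start]
    cur = start
    backtrack = (start[0] - 1, start[1])  # above the topmost pixel: background
    first_move: tuple | None = None
    limit = 8 * int(comp.sum()) + 8
    while True:
        d0 = _CLOCKWISE_INDEX[(backtrack[0] - cur[0], backtrack[1] - cur[1])]
        for k in range(1, 9):
            dr, dc = _CLOCKWISE[(d0 + k) % 8]
            cand = (cur[0] + dr, cur[1] + dc)
            if comp[cand]:
                nxt = cand
                pr, pc = _CLOCKWISE[(d0 + k - 1) % 8]
                new_backtrack = (cur[0] + pr, cur[1] + pc)
                break
        move = (cur, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:
            # the directed traversal repeats: full cycle completed
            break
        contour.append(nxt)
        cur, backtrack = nxt, new_backtrack
        if len(contour) > limit:  # pragma: no cover - defensive
            raise RuntimeError("Moore trace failed to terminate")
    if len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    return contour


def _is_closed(pixels: np.ndarray) -> bool:
    if len(pixels) <= 1:
        return True
    steps = np.abs(np.diff(pixels, axis=0))
    if np.any(steps.max(axis=1) > 1):
        return False
    wrap = np.abs(pixels[0] - pixels[-1])
    return int(wrap.max()) <= 1


def extract_edge_contour(mask: np.ndarray, side: str = "inner") -> list[EdgeContour]:
    """Trace the boundary of each 8-connected component of ``mask``.

    ``side='inner'`` returns mask pixels adjacent to background; ``'outer'``
    returns background pixels 8-adjacent to the mask, ordered by the inner
    traversal they touch.  Pixels on the image border count as boundary only
    when 8-adjacent to true in-image background, so border-clipped contours
    may be open.
    """
    mask = np.asarray(mask, dtype=bool)
    if side not in ("inner", "outer"):
        raise ValueError(f"side must be 'inner' or 'outer', got {side!r}")
    if not mask.any():
        raise EmptyMaskError("cannot trace contours of an empty mask")
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    background = ~mask
    out: list[EdgeContour] = []
    for cid in range(1, n + 1):
        comp = labels == cid
        padded = np.pad(comp, 1)
        traced = np.array(_trace_moore(padded), dtype=int) - 1
        touches_border = (
            traced[:, 0].min() == 0
            or traced[:, 1].min() == 0
            or traced[:, 0].max() == mask.shape[0] - 1
            or traced[:, 1].max() == mask.shape[1] - 1
        )
        if touches_border:
            keep = [
                i
                for i, (r, c) in enumerate(traced)
                if _has_bg_neighbor(background, r, c)
            ]
            traced = traced[keep]
            if len(traced) == 0:
                # component fills a border-to-border strip with no in-image
                # background contact; fall back to the full trace
                traced = np.array(_trace_moore(padded), dtype=int) - 1
        inner = EdgeContour(
            pixels=traced,
            side="inner",
            component_id=cid,
            closed=_is_closed(traced),
        )
        if side == "inner":
            out.append(inner)
        else:
            out.append(_outer_from_inner(inner, mask))
    return out


def _has_bg_neighbor(background: np.ndarray, r: int, c: int) -> bool:
    h, w = background.shape
    for dr, dc in _CLOCKWISE:
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w and background[rr, cc]:
            return True
    return False


def _outer_from_inner(inner: EdgeContour, mask: np.ndarray) -> EdgeContour:
    h, w = mask.shape
    seen: set[tuple[int, int]] = set()
    pixels: list[tuple[int, int]] = []
    for r, c in inner.pixels:
        for dr, dc in _CLOCKWISE:
            rr, cc = int(r) + dr, int(c) + dc
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc]:
                if (rr, cc) not in seen:
                    seen.add((rr, cc))
                    pixels.append((rr, cc))
    arr = np.array(pixels, dtype=int).reshape(-1, 2)
    return EdgeContour(
        pixels=arr,
        side="outer",
        component_id=inner.component_id,
        closed=inner.closed,
    )


def distance_from_edge(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance from each mask pixel to the nearest
    background pixel centre; 0 outside the mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("distance map of an empty mask is undefined")
    return ndimage.distance_transform_edt(mask)


def build_region_set(
    mask: np.ndarray,
    depth_in: float = 10,
    depth_out: float = 50,
    bg_box: tuple[int, int, int, int] | None = None,
    scene_mask: np.ndarray | None = None,
    border_margin: int = 0,
) -> RegionSet:
    """Derive interior and near-edge background ring from a cell mask.

    ``scene_mask`` (default: ``mask``) is the union of every cell in the
    scene; the ring excludes all of them so neighbouring cells never leak
    into each other's background statistics.
    """
    mask = np.asarray(mask, dtype=bool)
    if scene_mask is None:
        scene_mask = mask
    scene_mask = np.asarray(scene_mask, dtype=bool) | mask

    if depth_in > 0:
        interior = distance_from_edge(mask) > depth_in
    else:
        interior = mask.copy()
    if not interior.any():
        raise EmptyMaskError(
            f"erosion by depth_in={depth_in} leaves no interior; "
            "use a smaller depth_in"
        )

    if depth_out <= 0:
        warnings.warn("depth_out <= 0 produces an empty background ring")
        bg_ring = np.zeros_like(mask)
    else:
        d_out = ndimage.distance_transform_edt(~scene_mask)
        bg_ring = (d_out > 0) & (d_out <= depth_out)
        if border_margin > 0:
            bg_ring[:border_margin, :] = False
            bg_ring[-border_margin:, :] = False
            bg_ring[:, :border_margin] = False
            bg_ring[:, -border_margin:] = False

    if bg_box is not None:
        r0, c0, hh, ww = bg_box
        if r0 < 0 or c0 < 0 or r0 + hh > mask.shape[0] or c0 + ww > mask.shape[1]:
            raise ValueError(f"bg_box {bg_box} exceeds image bounds {mask.shape}")
        if scene_mask[r0 : r0 + hh, c0 : c0 + ww].any():
            raise ValueError(f"bg_box {bg_box} overlaps a cell mask")

    return RegionSet(
        mask=mask,
        interior=interior,
        bg_ring=bg_ring,
        bg_box=bg_box,
        params={
            "depth_in": depth_in,
            "depth_out": depth_out,
            "border_margin": border_margin,
        },
    )


def line_scan(
    image: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``image`` at unit-spaced points along the segment p0→p1 by
    nearest-pixel lookup.  Returns (positions_px, values)."""
    image = np.asarray(image)
    h, w = image.shape
    for p in (p0, p1):
        if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
            raise ValueError(f"endpoint {p} outside image of shape {image.shape}")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    pos = np.arange(0.0, length, 1.0)
    if pos.size == 0 or pos[-1] < length:
        pos = np.append(pos, length)
    if length == 0.0:
        pos = np.array([0.0])
        coords = p0[None, :]
    else:
        coords = p0[None, :] + (pos / length)[:, None] * (p1 - p0)[None, :]
    rows = np.clip(np.rint(coords[:, 0]).astype(int), 0, h - 1)
    cols = np.clip(np.rint(coords[:, 1]).astype(int), 0, w - 1)
    return pos, image[rows, cols]
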