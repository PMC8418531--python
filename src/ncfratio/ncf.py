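"""Noise-correction-factor (NCF) ratio and NCF estimation.

For two channels that share a proportional pure signal,

    img1 = a0*S2 + B1 + N1,      img2 = S2 + B2 + N2,

the raw ratio can be rewritten as

    img1 / img2 = (a0*(S2 + B2) + (B1 - a0*B2) + N1) / ((S2 + B2) + N2),

so subtracting the single constant NCF = B1 - a0*B2 from the numerator
*only* gives a ratio whose denominator keeps its background offset B2:

    Ratio_NCF = (img1 - NCF) / img2.

Because B2 dominates the noise N2, the denominator is never
noise-dominated, even where the cell signal S2 -> 0 at the edge — the
division-by-small-numbers artifact of background-subtracted ratios
vanishes, and the ratio is well defined over the whole image, background
included (where it equals a0 on average).

The NCF constant is estimated by five mutually consistent routes:

* theoretical: B1 - a0*B2 from measured backgrounds and the fitted slope;
* fit intercept: intercept of the pixelwise img1-vs-img2 linear fit;
* Dev_in: minimize mean (Ratio_NCF - Ratio_MBS)^2 over the cell interior
  (away from the edge, where MBS is trustworthy);
* Dev_out: minimize mean (Ratio_NCF - a0)^2 over the background ring just
  outside the edge (flattens the background to the basal ratio) — the
  route of choice for dual-chain biosensors with no strong channel
  proportionality;
* flatness: minimize the relative range of the mean ratio as a function
  of distance from the cell edge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .background import RatioResult, mbs_ratio, _ratio

__all__ = [
    "ProportionalityFit",
    "NCFFit",
    "ncf_ratio",
    "fit_proportionality",
    "theoretical_ncf",
    "dev_in",
    "dev_out",
    "flatness_objective",
    "optimize_ncf",
    "calibrate",
]

log = logging.getLogger(__name__)


@dataclass
class ProportionalityFit:
    """OLS fit of the numerator on the denominator over in-cell pixels.

    Under the generative model the slope is a0 and the intercept is
    B1 - a0*B2, i.e. the intercept is itself an NCF estimate.
    """

    a0: float
    intercept: float
    n_pixels: int
    residual_rms: float


@dataclass
class NCFFit:
    """Result of a grid search over NCF candidates for one objective."""

    ncf: float
    objective: str
    grid: np.ndarray
    dev_curve: np.ndarray
    a0_used: float | None = None
    params: dict = field(default_factory=dict)


def ncf_ratio(img1: np.ndarray, img2: np.ndarray, ncf: float) -> RatioResult:
    """(img1 - NCF) / img2 over the whole image, no background subtraction
    in the denominator.  ncf = 0 reduces to the raw ratio img1/img2."""
    img1 = np.asarray(img1, dtype=float)
    img2 = np.asarray(img2, dtype=float)
    if img1.shape != img2.shape:
        raise ValueError(f"shape mismatch: {img1.shape} vs {img2.shape}")
    return _ratio(img1 - ncf, img2, "NCF", {"ncf": float(ncf)})


def fit_proportionality(
    img1: np.ndarray, img2: np.ndarray, region: np.ndarray
) -> ProportionalityFit:
    """Least-squares line img1 = a0*img2 + intercept over region pixels."""
    region = np.asarray(region, dtype=bool)
    x = np.asarray(img2, dtype=float)[region]
    y = np.asarray(img1, dtype=float)[region]
    if x.size < 2:
        raise ValueError("proportionality fit needs >= 2 region pixels")
    if np.ptp(x) == 0:
        raise ValueError("degenerate region: denominator constant, slope undefined")
    design = np.stack([x, np.ones_like(x)], axis=1)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return ProportionalityFit(
        a0=float(coef[0]),
        intercept=float(coef[1]),
        n_pixels=int(x.size),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def theoretical_ncf(bg1: float, a0: float, bg2: float) -> float:
    """NCF = B1 - a0*B2."""
    return float(bg1) - float(a0) * float(bg2)


def dev_in(
    ncf: float,
    img1: np.ndarray,
    img2: np.ndarray,
    bg1: float,
    bg2: float,
    interior: np.ndarray,
    min_valid: int = 100,
) -> float:
    """Mean squared NCF-vs-MBS ratio difference over the cell interior."""
    interior = np.asarray(interior, dtype=bool)
    if not interior.any():
        raise ValueError("interior region is empty")
    x1 = np.asarray(img1, dtype=float)[interior]
    x2 = np.asarray(img2, dtype=float)[interior]
    valid = (x2 - bg2 > 0) & (x2 > 0) & np.isfinite(x1) & np.isfinite(x2)
    n = int(valid.sum())
    if n < min_valid:
        raise ValueError(
            f"only {n} interior pixels valid under both methods (< {min_valid})"
        )
    r_mbs = (x1[valid] - bg1) / (x2[valid] - bg2)
    r_ncf = (x1[valid] - ncf) / x2[valid]
    return float(np.mean((r_ncf - r_mbs) ** 2))


def dev_out(
    ncf: float,
    img1: np.ndarray,
    img2: np.ndarray,
    a0_ref: float,
    bg_ring: np.ndarray,
) -> float:
    """Mean squared deviation of the NCF ratio from the basal ratio a0 over
    the near-edge background ring."""
    bg_ring = np.asarray(bg_ring, dtype=bool)
    if not bg_ring.any():
        raise ValueError("background ring is empty")
    x1 = np.asarray(img1, dtype=float)[bg_ring]
    x2 = np.asarray(img2, dtype=float)[bg_ring]
    valid = (x2 > 0) & np.isfinite(x1) & np.isfinite(x2)
    if not valid.any():
        raise ValueError("no valid ring pixel (denominator <= 0 everywhere)")
    r = (x1[valid] - ncf) / x2[valid]
    return float(np.mean((r - a0_ref) ** 2))


def flatness_objective(
    ncf: float,
    img1: np.ndarray,
    img2: np.ndarray,
    distmap: np.ndarray,
    d_range: tuple[float, float] | None = None,
    min_bin_count: int = 50,
) -> float:
    """Relative range (max-min)/min of the mean NCF ratio per integer
    distance-from-edge bin, over d_range."""
    from .diagnostics import distance_profile, relative_range

    result = ncf_ratio(img1, img2, ncf)
    prof = distance_profile(result, distmap, min_bin_count=min_bin_count)
    return relative_range(prof, d_range=d_range)


def optimize_ncf(
    objective,
    grid_spec: tuple[float, float, int],
    *,
    img1: np.ndarray | None = None,
    img2: np.ndarray | None = None,
    bg1: float | None = None,
    bg2: float | None = None,
    interior: np.ndarray | None = None,
    a0_ref: float | None = None,
    bg_ring: np.ndarray | None = None,
    distmap: np.ndarray | None = None,
    d_range: tuple[float, float] | None = None,
    min_bin_count: int = 50,
) -> NCFFit:
    """Exhaustive 1-D grid search for the NCF minimizing an objective.

    ``objective`` is 'dev_in', 'dev_out', 'flatness' or any callable
    f(ncf) -> float.  The full dev curve is returned for auditing; ties
    break toward the smallest candidate and an argmin on the grid boundary
    triggers a warning (the interval is probably too narrow).  Candidates
    where the objective is undefined (e.g. a non-positive flatness
    denominator) are recorded as +inf and skipped.
    """
    lo, hi, n_steps = grid_spec
    if n_steps < 2:
        raise ValueError("grid needs at least 2 candidates")
    if not lo < hi:
        raise ValueError(f"grid bounds must satisfy lo < hi, got {lo}, {hi}")
    grid = np.linspace(lo, hi, int(n_steps))

    if callable(objective):
        fn, name = objective, getattr(objective, "__name__", "custom")
        curve = _evaluate(fn, grid)
        a0_used = None
    elif objective == "dev_in":
        _require(img1=img1, img2=img2, bg1=bg1, bg2=bg2, interior=interior)
        x1 = np.asarray(img1, float)[interior]
        x2 = np.asarray(img2, float)[interior]
        valid = (x2 - bg2 > 0) & (x2 > 0) & np.isfinite(x1) & np.isfinite(x2)
        x1, x2 = x1[valid], x2[valid]
        if x1.size < 2:
            raise ValueError("objective undefined: no valid interior pixels")
        r_mbs = (x1 - bg1) / (x2 - bg2)
        curve = _evaluate(
            lambda c: float(np.mean(((x1 - c) / x2 - r_mbs) ** 2)), grid
        )
        fn, name, a0_used = None, "dev_in", None
    elif objective == "dev_out":
        _require(img1=img1, img2=img2, a0_ref=a0_ref, bg_ring=bg_ring)
        x1 = np.asarray(img1, float)[bg_ring]
        x2 = np.asarray(img2, float)[bg_ring]
        valid = (x2 > 0) & np.isfinite(x1) & np.isfinite(x2)
        x1, x2 = x1[valid], x2[valid]
        if x1.size == 0:
            raise ValueError("objective undefined: no valid ring pixels")
        curve = _evaluate(
            lambda c: float(np.mean(((x1 - c) / x2 - a0_ref) ** 2)), grid
        )
        fn, name, a0_used = None, "dev_out", float(a0_ref)
    elif objective == "flatness":
        _require(img1=img1, img2=img2, distmap=distmap)
        curve = _flatness_curve(
            grid, img1, img2, distmap, d_range, min_bin_count
        )
        fn, name, a0_used = None, "flatness", None
    else:
        raise ValueError(f"unknown objective {objective!r}")

    if not np.isfinite(curve).any():
        raise ValueError(f"objective {name!r} undefined at every grid point")
    best = int(np.nanargmin(np.where(np.isfinite(curve), curve, np.inf)))
    n_ties = int(np.sum(curve == curve[best]))
    if n_ties > 1:
        warnings.warn(
            f"{n_ties} grid candidates tie at the minimum; "
            "returning the smallest"
        )
    if best in (0, len(grid) - 1):
        warnings.warn(
            f"argmin of {name} lies on the grid boundary ({grid[best]:g}); "
            "widen the search interval"
        )
    return NCFFit(
        ncf=float(grid[best]),
        objective=name,
        grid=grid,
        dev_curve=curve,
        a0_used=a0_used,
        params={"grid_spec": (float(lo), float(hi), int(n_steps))},
    )


def _require(**kw):
    missing = [k for k, v in kw.items() if v is None]
    if missing:
        raise ValueError(f"objective requires arguments: {', '.join(missing)}")


def _evaluate(fn, grid: np.ndarray) -> np.ndarray:
    out = np.empty(grid.size)
    for i, c in enumerate(grid):
        try:
            out[i] = fn(float(c))
        except ValueError:
            out[i] = np.inf
    return out


def _flatness_curve(
    grid: np.ndarray,
    img1: np.ndarray,
    img2: np.ndarray,
    distmap: np.ndarray,
    d_range: tuple[float, float] | None,
    min_bin_count: int,
) -> np.ndarray:
    """Fast flatness evaluation over the grid.

    The NCF ratio is affine in the candidate, so each bin mean is
    mean(img1/img2) - c*mean(1/img2) and one binning pass serves the whole
    grid.  The validity mask (img2 > 0) does not depend on the candidate.
    """
    img1 = np.asarray(img1, float)
    img2 = np.asarray(img2, float)
    distmap = np.asarray(distmap, float)
    inside = distmap > 0
    valid = inside & (img2 > 0) & np.isfinite(img1) & np.isfinite(img2)
    bins = np.ceil(distmap[valid]).astype(int)
    if bins.size == 0:
        raise ValueError("no valid in-mask pixel for the flatness objective")
    n = np.bincount(bins)
    sum_r = np.bincount(bins, weights=img1[valid] / img2[valid])
    sum_inv = np.bincount(bins, weights=1.0 / img2[valid])
    keep = n >= min_bin_count
    keep[0] = False
    d = np.arange(n.size)
    if d_range is not None:
        keep &= (d >= d_range[0]) & (d <= d_range[1])
    if keep.sum() < 2:
        raise ValueError("fewer than 2 populated distance bins for flatness")
    with np.errstate(invalid="ignore"):
        mean_r = sum_r[keep] / n[keep]
        mean_inv = sum_inv[keep] / n[keep]
    curve = np.empty(grid.size)
    for i, c in enumerate(grid):
        means = mean_r - c * mean_inv
        mn = means.min()
        curve[i] = (means.max() - mn) / mn if mn > 0 else np.inf
    return curve


def calibrate(
    img1: np.ndarray,
    img2: np.ndarray,
    regions,
    bg1: float,
    bg2: float,
    grid_spec: tuple[float, float, int] | None = None,
    d_range: tuple[float, float] | None = None,
    min_bin_count: int = 50,
    advisory_rms_ratio: float = 0.5,
) -> dict:
    """Estimate the NCF by all five routes on one cell's regions.

    ``regions`` is a :class:`~ncfratio.geometry.RegionSet`; ``bg1``/``bg2``
    are the distant-box background means.  Returns a dict with the
    proportionality fit, every estimate, the dev curves and the a0
    reference used by Dev_out.  When the fit residual RMS is large
    relative to the fitted signal span (weak proportionality, as for
    dual-chain biosensors) an advisory recommending Dev_out is logged;
    the objective is never switched silently.
    """
    from .geometry import distance_from_edge

    img1 = np.asarray(img1, float)
    img2 = np.asarray(img2, float)
    fit = fit_proportionality(img1, img2, regions.mask)
    span = float(np.ptp(img1[regions.mask]))
    if span > 0 and fit.residual_rms > advisory_rms_ratio * span:
        log.warning(
            "weak channel proportionality (residual RMS %.3g vs span %.3g): "
            "prefer the dev_out estimate for this (likely dual-chain) sensor",
            fit.residual_rms,
            span,
        )
    if grid_spec is None:
        hi = 2.0 * max(bg1, 1.0)
        grid_spec = (0.0, hi, 1001)

    mbs = mbs_ratio(img1, img2, bg1, bg2)
    a0_ref = float(np.nanmean(mbs.ratio[regions.interior & mbs.valid]))
    distmap = distance_from_edge(regions.mask)

    fit_in = optimize_ncf(
        "dev_in", grid_spec, img1=img1, img2=img2, bg1=bg1, bg2=bg2,
        interior=regions.interior,
    )
    fit_out = optimize_ncf(
        "dev_out", grid_spec, img1=img1, img2=img2, a0_ref=a0_ref,
        bg_ring=regions.bg_ring,
    )
    fit_flat = optimize_ncf(
        "flatness", grid_spec, img1=img1, img2=img2, distmap=distmap,
        d_range=d_range, min_bin_count=min_bin_count,
    )
    return {
        "fit": fit,
        "a0": fit.a0,
        "a0_ref": a0_ref,
        "ncf": {
            "theoretical": theoretical_ncf(bg1, fit.a0, bg2),
            "fit_intercept": fit.intercept,
            "dev_in": fit_in.ncf,
            "dev_out": fit_out.ncf,
            "flatness": fit_flat.ncf,
        },
        "fits": {"dev_in": fit_in, "dev_out": fit_out, "flatness": fit_flat},
        "bg": {"bg1": float(bg1), "bg2": float(bg2)},
        "grid_spec": grid_spec,
    }
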