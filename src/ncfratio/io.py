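"""Image I/O, preprocessing corrections and the full pipeline.

Channels are read from single-plane TIFF (uint8/uint16/float32) into
64-bit floats; masks from TIFF or PNG (nonzero = foreground).  The two
acquisition corrections applied before any ratio work are dark-current
subtraction and flat-field (shading) normalization.  ``run_pipeline``
ties preprocessing, masking, region construction, background estimation,
NCF calibration, ratio maps and diagnostics together and writes every
parameter used into JSON sidecars for full provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import background as bgm
from . import diagnostics as diag
from . import geometry as geo
from . import ncf as ncfm

__all__ = [
    "ChannelImage",
    "PipelineConfig",
    "read_channel",
    "write_channel",
    "read_mask",
    "write_mask",
    "dark_current_correct",
    "shading_correct",
    "run_pipeline",
]

log = logging.getLogger(__name__)


@dataclass
class ChannelImage:
    """A single fluorescence channel as float64 with source metadata."""

    data: np.ndarray
    source_dtype: str | None = None
    pixel_size_um: float | None = None
    path: str | None = None


def read_channel(path, page: int | None = None) -> ChannelImage:
    """Read one TIFF plane as float64; stacks need an explicit page."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        if "S" in series.axes:  # samples per pixel > 1
            raise ValueError(f"{path}: RGB/multisample TIFFs are not supported")
        n_pages = len(tif.pages)
        if n_pages > 1:
            if page is None:
                raise ValueError(
                    f"{path} has {n_pages} pages; pass an explicit page index"
                )
            plane = tif.pages[page].asarray()
        else:
            plane = series.asarray()
            if plane.ndim == 3:
                if page is None:
                    raise ValueError(
                        f"{path} has {plane.shape[0]} planes; "
                        "pass an explicit page index"
                    )
                plane = plane[page]
    if plane.ndim != 2:
        raise ValueError(f"{path}: expected a single 2-D plane")
    return ChannelImage(
        data=plane.astype(np.float64),
        source_dtype=str(plane.dtype),
        path=str(path),
    )


def write_channel(path, data: np.ndarray, dtype=np.float32) -> None:
    tifffile.imwrite(Path(path), np.asarray(data, dtype=dtype))


def read_mask(path) -> np.ndarray:
    """Binary mask from single-plane TIFF or PNG; nonzero = foreground."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:
            arr = arr[..., 0]
    else:
        arr = tifffile.imread(path)
    return np.asarray(arr) != 0


def write_mask(path, mask: np.ndarray) -> None:
    write_channel(path, np.asarray(mask, dtype=np.uint8) * 255, dtype=np.uint8)


def dark_current_correct(image: np.ndarray, dark: np.ndarray) -> np.ndarray:
    """Subtract the camera dark-current frame; negatives are kept (the
    pipeline is floating point throughout)."""
    image = np.asarray(image, dtype=float)
    dark = np.asarray(dark, dtype=float)
    if image.shape != dark.shape:
        raise ValueError(f"shape mismatch: {image.shape} vs {dark.shape}")
    return image - dark


def shading_correct(image: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flat-field correction: normalize the shading reference to mean 1,
    then divide the (dark-corrected) image by it pixelwise."""
    image = np.asarray(image, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if image.shape != reference.shape:
        raise ValueError(f"shape mismatch: {image.shape} vs {reference.shape}")
    if np.any(reference <= 0):
        raise ValueError("shading reference must be strictly positive")
    return image / (reference / reference.mean())


@dataclass
class PipelineConfig:
    """Every knob the pipeline consumes; echoed into all output sidecars."""

    numerator: str = ""
    denominator: str = ""
    dark: str | None = None
    shading1: str | None = None
    shading2: str | None = None
    mask: str | None = None
    bg_box: tuple[int, int, int, int] | None = None
    mask_threshold: float | None = None  # None -> bg mean + 3*std policy
    min_area: int = 50
    depth_in: float = 10.0
    depth_out: float = 50.0
    sigma: float = 10.0
    m: float = 2.0
    subsample: int = 1
    grid: tuple[float, float, int] | None = None
    methods: tuple[str, ...] = ("MBS", "NCF")
    objective: str = "dev_in"
    max_d: int | None = None
    min_bin_count: int = 50
    band_offsets: tuple[int, int] = (-2, 4)
    seed: int = 0
    outdir: str = "ncfratio_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def merged(self, **overrides) -> "PipelineConfig":
        clean = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **clean)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Preprocess -> mask -> regions -> backgrounds -> calibrate ->
    ratio maps -> diagnostics, writing everything under config.outdir."""
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    if not cfg.numerator or not cfg.denominator:
        raise ValueError("pipeline config needs numerator and denominator paths")
    if cfg.mask_threshold is None and cfg.bg_box is None:
        raise ValueError(
            "default mask-threshold policy (bg mean + 3*std) requires bg_box"
        )

    img1 = read_channel(cfg.numerator).data
    img2 = read_channel(cfg.denominator).data
    if cfg.dark:
        dark = read_channel(cfg.dark).data
        img1 = dark_current_correct(img1, dark)
        img2 = dark_current_correct(img2, dark)
    if cfg.shading1:
        img1 = shading_correct(img1, read_channel(cfg.shading1).data)
    if cfg.shading2:
        img2 = shading_correct(img2, read_channel(cfg.shading2).data)

    if cfg.bg_box is not None:
        bg1, bg1_std = bgm.box_background(img1, tuple(cfg.bg_box))
        bg2, bg2_std = bgm.box_background(img2, tuple(cfg.bg_box))
    else:
        bg1 = bg2 = bg1_std = bg2_std = None

    if cfg.mask is not None:
        mask = read_mask(cfg.mask)
    else:
        threshold = (
            cfg.mask_threshold
            if cfg.mask_threshold is not None
            else bg2 + 3.0 * bg2_std
        )
        mask = geo.threshold_mask(img2, threshold, min_area=cfg.min_area)
    regions = geo.build_region_set(
        mask,
        depth_in=cfg.depth_in,
        depth_out=cfg.depth_out,
        bg_box=tuple(cfg.bg_box) if cfg.bg_box else None,
    )
    distmap = geo.distance_from_edge(mask)

    report: dict = {"config": cfg.to_dict(), "bg": None, "ncf": None}
    if bg1 is not None:
        report["bg"] = {
            "bg1_mean": bg1, "bg1_std": bg1_std,
            "bg2_mean": bg2, "bg2_std": bg2_std,
        }
        cal = ncfm.calibrate(
            img1, img2, regions, bg1, bg2,
            grid_spec=cfg.grid, min_bin_count=cfg.min_bin_count,
        )
        report["ncf"] = {
            "estimates": cal["ncf"], "a0": cal["a0"], "a0_ref": cal["a0_ref"],
        }
        chosen = cal["ncf"][cfg.objective if cfg.objective in cal["ncf"] else "dev_in"]
        curve = cal["fits"]["dev_in"]
        import pandas as pd

        pd.DataFrame(
            {"ncf_candidate": curve.grid, "objective_value": curve.dev_curve}
        ).to_csv(out / "dev_curve.csv", index=False)
    else:
        chosen = 0.0

    results = {}
    for method in cfg.methods:
        if method == "MBS":
            if bg1 is None:
                raise ValueError("MBS method requires bg_box")
            res = bgm.mbs_ratio(img1, img2, bg1, bg2)
        elif method == "NCF":
            res = ncfm.ncf_ratio(img1, img2, chosen)
        elif method == "nonuniform":
            f1 = bgm.estimate_nonuniform_background(
                img1, mask, sigma=cfg.sigma, m=cfg.m, subsample=cfg.subsample
            )
            f2 = bgm.estimate_nonuniform_background(
                img2, mask, sigma=cfg.sigma, m=cfg.m, subsample=cfg.subsample
            )
            res = bgm.nonuniform_ratio(
                img1, img2, f1, f2, params={"sigma": cfg.sigma, "m": cfg.m}
            )
        elif method == "halfway":
            thr = cfg.mask_threshold if cfg.mask_threshold is not None else bg2 + 3 * bg2_std
            res = bgm.mbs_ratio(
                img1, img2,
                bgm.halfway_background(bg1, max(bg1, thr)),
                bgm.halfway_background(bg2, max(bg2, thr)),
                method="halfway",
            )
        else:
            raise ValueError(f"unknown ratio method {method!r}")
        results[method] = res
        write_channel(out / f"ratio_{method}.tif", res.ratio)
        write_mask(out / f"invalid_{method}.tif", res.invalid)
        _dump_json(out / f"ratio_{method}.json", res.params | {"method": method})

        prof = diag.distance_profile(
            res, distmap, max_d=cfg.max_d, min_bin_count=cfg.min_bin_count
        )
        import pandas as pd

        pd.DataFrame(
            {"distance_px": prof.bins, "mean": prof.mean,
             "std": prof.std, "n": prof.n}
        ).to_csv(out / f"profile_{method}.csv", index=False)
        report.setdefault("flatness", {})[method] = diag.relative_range(prof)

    if "NCF" in results:
        lo, hi = cfg.band_offsets
        bands = diag.edge_band_stats(
            results["NCF"], mask, range(int(lo), int(hi) + 1)
        )
        import pandas as pd

        pd.DataFrame(
            [dataclasses.asdict(b) for b in bands]
        ).to_csv(out / "band_stats.csv", index=False)

    write_mask(out / "mask.tif", mask)
    write_mask(out / "interior.tif", regions.interior)
    write_mask(out / "bg_ring.tif", regions.bg_ring)
    _dump_json(out / "report.json", report)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    log.info("pipeline outputs written to %s", out)
    return report
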