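"""Ground-truthed synthetic two-channel biosensor scenes.

The generator implements the wedge (hypothetical-cell) model: cell
thickness — hence pure denominator signal S2 — rises linearly from zero
at the edge to a plateau over ``ramp_width`` pixels.  Channels are
assembled from the exact generative identity

    img1 = (a0 + a1(x,y)) * S2 + B1 + shade1 + noise1
    img2 =             S2 + B2 + shade2 + noise2

with per-channel additive background constants B1, B2, optional linear
"shade" gradients, optional per-pixel activity a1 (including a narrow
edge band), and zero-mean Gaussian noise that is deliberately *not*
clipped at zero so the algebraic identities above hold bit-exactly on the
emitted floating-point images.  The true NCF of a cell is B1 - a0*B2.

Defaults (256x256 scene, disc radius 80 px, ramp 20 px, S2 plateau 2000,
B1 = 120, B2 = 100, a0 = 0.7, noise sigma 8) put the interior at high SNR
while leaving the edge artifact clearly visible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "CellGeometry",
    "SceneSpec",
    "SceneGroundTruth",
    "Scene",
    "make_wedge_scene",
    "make_two_cell_scene",
    "add_shade_gradient",
    "add_edge_band_activity",
]


@dataclass(frozen=True)
class CellGeometry:
    """A disc-shaped cell footprint: centre (row, col) and radius in px."""

    center: tuple[float, float]
    radius: float


def _default_cells() -> list[CellGeometry]:
    return [CellGeometry(center=(128.0, 128.0), radius=80.0)]


@dataclass(frozen=True)
class SceneSpec:
    """Generative parameters of a synthetic scene.

    ``a0`` may be a scalar (shared) or a per-cell sequence.  ``shade`` is
    ((dr, dc), amplitude, channels) for a linear background gradient;
    ``edge_band`` is (width_px, amplitude) of an activity band at the
    cell edge.  All randomness comes from ``seed``.
    """

    shape: tuple[int, int] = (256, 256)
    cells: list[CellGeometry] = field(default_factory=_default_cells)
    ramp_width: float = 20.0
    s2_plateau: float = 2000.0
    a0: float | tuple[float, ...] = 0.7
    edge_band: tuple[float, float] | None = None
    B1: float = 120.0
    B2: float = 100.0
    shade: tuple[tuple[float, float], float, str] | None = None
    noise_sigma1: float = 8.0
    noise_sigma2: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.s2_plateau <= 0:
            raise ValueError("s2_plateau must be > 0")
        if self.B1 < 0 or self.B2 < 0:
            raise ValueError("backgrounds must be >= 0")
        if self.noise_sigma1 < 0 or self.noise_sigma2 < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.ramp_width < 1:
            raise ValueError("ramp_width must be >= 1")


@dataclass
class SceneGroundTruth:
    """Everything needed to reconstruct the emitted images bit-exactly."""

    S2_field: np.ndarray
    a0_field: np.ndarray
    a1_field: np.ndarray
    true_a0: list[float]
    true_ncf: list[float]
    mask_true: np.ndarray
    cell_masks: list[np.ndarray]
    noise1: np.ndarray
    noise2: np.ndarray
    shade1: np.ndarray
    shade2: np.ndarray
    spec: SceneSpec

    def reconstruct(self) -> tuple[np.ndarray, np.ndarray]:
        img1 = (
            (self.a0_field + self.a1_field) * self.S2_field
            + self.spec.B1
            + self.shade1
            + self.noise1
        )
        img2 = self.S2_field + self.spec.B2 + self.shade2 + self.noise2
        return img1, img2

    @property
    def edge_snr(self) -> float:
        """SNR of the denominator signal at the first in-mask pixel layer:
        (s2_plateau / ramp_width) / noise_sigma2."""
        if self.spec.noise_sigma2 == 0:
            return np.inf
        return (self.spec.s2_plateau / self.spec.ramp_width) / self.spec.noise_sigma2


@dataclass
class Scene:
    """An emitted two-channel scene plus its ground truth."""

    img1: np.ndarray
    img2: np.ndarray
    truth: SceneGroundTruth


def _disc_mask(shape, cell: CellGeometry) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - cell.center[0]) ** 2 + (cc - cell.center[1]) ** 2 <= cell.radius**2


def make_wedge_scene(spec: SceneSpec) -> Scene:
    """Build a wedge-model scene from its spec; deterministic in the seed."""
    shape = spec.shape
    cell_masks = []
    for cell in spec.cells:
        r, c = cell.center
        if (
            r - cell.radius < 0
            or c - cell.radius < 0
            or r + cell.radius > shape[0] - 1
            or c + cell.radius > shape[1] - 1
        ):
            raise ValueError(f"cell {cell} exceeds image bounds {shape}")
        cell_masks.append(_disc_mask(shape, cell))
    for i in range(len(cell_masks)):
        for j in range(i + 1, len(cell_masks)):
            if (cell_masks[i] & cell_masks[j]).any():
                raise ValueError(f"cells {i} and {j} overlap")

    a0s = spec.a0 if isinstance(spec.a0, (tuple, list)) else [spec.a0] * len(
        spec.cells
    )
    if len(a0s) != len(spec.cells):
        raise ValueError("need one a0 per cell")

    S2 = np.zeros(shape)
    a0_field = np.zeros(shape)
    for m, a0 in zip(cell_masks, a0s):
        d = ndimage.distance_transform_edt(m)
        S2 += spec.s2_plateau * np.minimum(1.0, d / spec.ramp_width)
        a0_field[m] = a0
    mask_true = S2 > 0

    a1 = np.zeros(shape)
    rng = np.random.default_rng(spec.seed)
    noise1 = rng.normal(0.0, spec.noise_sigma1, shape) if spec.noise_sigma1 else np.zeros(shape)
    noise2 = rng.normal(0.0, spec.noise_sigma2, shape) if spec.noise_sigma2 else np.zeros(shape)

    truth = SceneGroundTruth(
        S2_field=S2,
        a0_field=a0_field,
        a1_field=a1,
        true_a0=[float(a) for a in a0s],
        true_ncf=[float(spec.B1 - a * spec.B2) for a in a0s],
        mask_true=mask_true,
        cell_masks=cell_masks,
        noise1=noise1,
        noise2=noise2,
        shade1=np.zeros(shape),
        shade2=np.zeros(shape),
        spec=spec,
    )
    scene = Scene(*truth.reconstruct(), truth)
    if spec.shade is not None:
        direction, amplitude, channels = spec.shade
        scene = add_shade_gradient(scene, direction, amplitude, channels)
    if spec.edge_band is not None:
        width, amplitude = spec.edge_band
        scene = add_edge_band_activity(scene, width, amplitude)
    return scene


def make_two_cell_scene(spec: SceneSpec | None = None) -> Scene:
    """Two disjoint wedge cells with distinct a0 (defaults 0.63 and 0.72),
    shared backgrounds and noise model."""
    if spec is None:
        spec = SceneSpec(
            shape=(256, 384),
            cells=[
                CellGeometry(center=(128.0, 100.0), radius=70.0),
                CellGeometry(center=(128.0, 284.0), radius=70.0),
            ],
            a0=(0.63, 0.72),
        )
    if len(spec.cells) != 2:
        raise ValueError("two-cell scene needs exactly two cells")
    return make_wedge_scene(spec)


def _shade_field(shape, direction, amplitude) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    norm = np.hypot(*d)
    if norm == 0:
        raise ValueError("shade direction must be a non-zero vector")
    d = d / norm
    rr, cc = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), indexing="ij"
    )
    proj = rr * d[0] + cc * d[1]
    span = proj.max() - proj.min()
    if span == 0:
        return np.zeros(shape)
    return amplitude * (proj - proj.min()) / span


def add_shade_gradient(
    scene: Scene,
    direction: tuple[float, float],
    amplitude: float,
    channels: str = "both",
) -> Scene:
    """Add a linear background gradient (a shade-like artifact) to the
    stated channel(s); ``amplitude`` is the full corner-to-corner change
    along ``direction``, normalized over the image extent."""
    if not np.isfinite(amplitude):
        raise ValueError("shade amplitude must be finite")
    if channels not in ("1", "2", "both"):
        raise ValueError("channels must be '1', '2' or 'both'")
    truth = copy.deepcopy(scene.truth)
    fld = _shade_field(truth.S2_field.shape, direction, amplitude)
    if channels in ("1", "both"):
        truth.shade1 = truth.shade1 + fld
    if channels in ("2", "both"):
        truth.shade2 = truth.shade2 + fld
    img1, img2 = truth.reconstruct()
    return Scene(img1, img2, truth)


def add_edge_band_activity(
    scene: Scene, width_px: float, amplitude: float
) -> Scene:
    """Add a uniform activity increment a1 += amplitude to in-mask pixels
    within ``width_px`` of the cell edge; the numerator is rebuilt from the
    generative identity (activity scales with S2)."""
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    truth = copy.deepcopy(scene.truth)
    d = ndimage.distance_transform_edt(truth.mask_true)
    band = (d > 0) & (d <= width_px)
    truth.a1_field = truth.a1_field + amplitude * band
    img1, img2 = truth.reconstruct()
    return Scene(img1, img2, truth)
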