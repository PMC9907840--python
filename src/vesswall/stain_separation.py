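"""Color deconvolution of H-DAB brightfield images.

Brightfield immunohistochemistry images mix a blue hematoxylin counterstain
with the brown DAB chromogen. Stain amounts are additive in optical density
(Beer-Lambert), so an RGB image is converted to OD and unmixed with a 3x3
linear system whose columns are the per-stain OD unit vectors. The DAB
concentration map is then thresholded inside the vessel-wall mask to yield
the binary "stained" mask that all downstream quantification consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "StainImage",
    "StainVectors",
    "ConcentrationMaps",
    "StainedMask",
    "HDAB_VECTORS",
    "rgb_to_optical_density",
    "separate_stains",
    "threshold_stained",
]

MIN_IMAGE_SIDE = 32


@dataclass
class StainImage:
    """8-bit RGB raster plus identity metadata.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3)
        Integer channel values in [0, 255].
    id : str
        Identifier (typically vessel id) carried through the pipeline.
    pixel_size_um : float, optional
        Physical pixel edge length; informational only.
    """

    pixels: np.ndarray
    id: str = ""
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an (H, W, 3) RGB raster, got shape {px.shape}")
        if px.shape[0] < MIN_IMAGE_SIDE or px.shape[1] < MIN_IMAGE_SIDE:
            raise ValueError(
                f"image must be at least {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}, got {px.shape[:2]}"
            )
        if px.min() < 0 or px.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("stain vector must be non-zero")
    return v / n


@dataclass(frozen=True)
class StainVectors:
    """Per-stain unit vectors in 3-channel optical-density space.

    The columns of :attr:`matrix` are (hematoxylin, dab, residual); a pixel's
    OD vector equals ``matrix @ concentrations``.
    """

    hematoxylin: np.ndarray
    dab: np.ndarray
    residual: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "hematoxylin", _unit(self.hematoxylin))
        object.__setattr__(self, "dab", _unit(self.dab))
        object.__setattr__(self, "residual", _unit(self.residual))
        if abs(np.linalg.det(self.matrix)) < 1e-8:
            raise ValueError("stain vectors are linearly dependent (singular basis)")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 matrix with stain vectors as columns."""
        return np.column_stack([self.hematoxylin, self.dab, self.residual])

    @classmethod
    def from_matrix(cls, m) -> "StainVectors":
        m = np.asarray(m, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {m.shape}")
        return cls(m[:, 0], m[:, 1], m[:, 2])


def _hdab_default() -> StainVectors:
    # Standard published H-DAB basis (Ruifrok & Johnston); residual is the
    # normalized cross product, completing an independent basis.
    h = _unit([0.650, 0.704, 0.286])
    d = _unit([0.268, 0.570, 0.776])
    return StainVectors(h, d, np.cross(h, d))


HDAB_VECTORS: StainVectors = _hdab_default()


@dataclass
class ConcentrationMaps:
    """Non-negative per-stain concentration rasters in OD units."""

    hematoxylin: np.ndarray
    dab: np.ndarray
    residual: np.ndarray
    vectors: StainVectors = field(default_factory=lambda: HDAB_VECTORS)

    @property
    def shape(self) -> tuple[int, int]:
        return self.hematoxylin.shape


@dataclass
class StainedMask:
    mask: np.ndarray
    threshold_value: float
    method: str  # "fixed" | "otsu"

    @property
    def n_stained(self) -> int:
        return int(self.mask.sum())


def rgb_to_optical_density(image, i0: float = 255.0, floor: float = 1.0) -> np.ndarray:
    """Convert an RGB image to optical density via Beer-Lambert.

    ``OD = -log10(clip(I, floor, i0) / i0)`` per channel. Intensities are
    clipped to ``floor`` (>= 1) before the log so fully absorbing pixels map
    to the finite bound ``log10(i0 / floor)`` instead of infinity.
    """
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    if floor < 1:
        raise ValueError("floor must be >= 1")
    px = image.pixels if isinstance(image, StainImage) else np.asarray(image)
    if px.ndim != 3 or px.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB raster, got shape {px.shape}")
    clipped = np.clip(px.astype(float), floor, i0)
    return -np.log10(clipped / i0)


def separate_stains(od: np.ndarray, vectors: StainVectors = HDAB_VECTORS) -> ConcentrationMaps:
    """Unmix a 3-channel OD raster into per-stain concentration maps.

    Solves ``OD = M c`` per pixel with M the stain-vector matrix, then clips
    negative concentrations to zero (concentrations are physical amounts;
    small negatives arise from noise outside the stain simplex).
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) OD raster, got shape {od.shape}")
    m = vectors.matrix
    if abs(np.linalg.det(m)) < 1e-8:
        raise ValueError("stain matrix is singular; cannot unmix")
    flat = od.reshape(-1, 3).T  # (3, N)
    conc = np.linalg.solve(m, flat).T.reshape(od.shape)
    conc = np.clip(conc, 0.0, None)
    return ConcentrationMaps(conc[..., 0], conc[..., 1], conc[..., 2], vectors)


def threshold_stained(
    dab: np.ndarray,
    wall: np.ndarray,
    method: str = "otsu",
    level: float | None = None,
) -> StainedMask:
    """Binarize the DAB concentration map inside the vessel wall.

    ``method="otsu"`` computes Otsu's threshold from DAB values restricted to
    wall pixels; ``method="fixed"`` uses the supplied ``level``. The returned
    mask is always a subset of ``wall``.
    """
    dab = np.asarray(dab, dtype=float)
    wall = np.asarray(wall, dtype=bool)
    if dab.shape != wall.shape:
        raise ValueError(f"shape mismatch: dab {dab.shape} vs wall {wall.shape}")
    if not wall.any():
        raise ValueError("wall mask is empty")
    inside = dab[wall]
    if method == "fixed":
        if level is None:
            raise ValueError("method='fixed' requires a threshold level")
        thr = float(level)
    elif method == "otsu":
        if np.ptp(inside) == 0:
            raise ValueError("all DAB values inside the wall are equal; Otsu threshold undefined")
        thr = float(threshold_otsu(inside))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return StainedMask(mask=(dab >= thr) & wall, threshold_value=thr, method=method)
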