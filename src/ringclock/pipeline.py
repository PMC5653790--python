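"""From colony photograph to clean 1-D radial profile.

The chain mirrors standard band-image preprocessing: read the image,
extract a rectangle whose long axis runs radially from the seed to the
colony edge, smooth with a Gaussian blur (sigma = 3) to suppress
high-frequency noise, apply a pseudo flat-field correction to remove
smooth illumination gradients, and average each row of pixels sharing
the same radial coordinate into one intensity value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .profiles import RadialProfile
from .synthetic import ColonyImage

__all__ = [
    "ROI",
    "read_image",
    "extract_roi",
    "gaussian_blur",
    "pseudo_flat_field",
    "collapse_profile",
    "image_to_profile",
]

log = logging.getLogger(__name__)

# Rec. 601 luminance weights for RGB -> gray
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ROI:
    """A rotated rectangle whose first axis points radially outward.

    ``anchor`` is the (x, y) pixel of the seed-side corner; the radial
    axis extends ``length`` pixels from it at ``angle`` degrees
    (counter-clockwise from +x), and the rectangle is ``width`` pixels
    across.
    """

    anchor: tuple[float, float]
    length: int
    width: int
    angle: float = 0.0

    def __post_init__(self) -> None:
        if self.length < 32:
            raise ValueError("ROI length must be >= 32 px")
        if self.width < 4:
            raise ValueError("ROI width must be >= 4 px")

    def sample_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """(ys, xs) arrays of shape (length, width) to sample the patch."""
        theta = np.deg2rad(self.angle)
        u = np.array([np.cos(theta), np.sin(theta)])  # radial direction (x, y)
        v = np.array([-np.sin(theta), np.cos(theta)])  # across-band direction
        i = np.arange(self.length, dtype=float)[:, None]
        j = np.arange(self.width, dtype=float)[None, :]
        xs = self.anchor[0] + i * u[0] + j * v[0]
        ys = self.anchor[1] + i * u[1] + j * v[1]
        return ys, xs


def read_image(path: str | Path) -> ColonyImage:
    """Read a PNG or TIFF photograph as floating-point grayscale.

    RGB(A) input is converted to Rec. 601 luminance; a sidecar
    ``<name>.yaml`` next to the image, if present, populates metadata.
    Multi-page TIFFs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        raise ValueError(f"unsupported image format {suffix!r}")
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3].astype(float) @ _LUMA
    elif arr.ndim != 2:
        raise ValueError("multi-page TIFFs are not supported; export a single page")
    dtype = arr.dtype
    if dtype == np.uint8:
        depth: int | str = 8
    elif dtype == np.uint16:
        depth = 16
    else:
        depth = "float"
    metadata: dict = {}
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        metadata = yaml.safe_load(sidecar.read_text()) or {}
    return ColonyImage(pixels=arr.astype(float), bit_depth=depth, metadata=metadata)


def extract_roi(image: ColonyImage, roi: ROI) -> np.ndarray:
    """Sample the rotated ROI with bilinear interpolation.

    Returns a ``(length, width)`` patch whose first axis increases away
    from the seed.
    """
    ys, xs = roi.sample_coordinates()
    h, w = image.shape
    eps = 1e-9
    if xs.min() < -eps or ys.min() < -eps or xs.max() > w - 1 + eps or ys.max() > h - 1 + eps:
        raise ValueError("ROI extends outside the image after rotation")
    return ndimage.map_coordinates(image.pixels, [ys, xs], order=1, mode="nearest")


def gaussian_blur(patch: np.ndarray, sigma: float = 3.0) -> np.ndarray:
    """2-D Gaussian smoothing with reflective boundaries; sigma=0 is identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return np.array(patch, dtype=float, copy=True)
    return ndimage.gaussian_filter(np.asarray(patch, dtype=float), sigma, mode="reflect")


def pseudo_flat_field(
    patch: np.ndarray,
    background_sigma: float,
    expected_spacing: float | None = None,
) -> np.ndarray:
    """Divide by a heavily blurred copy to remove smooth illumination.

    ``output = patch / blur(patch, background_sigma) * mean(blur)``, so
    the overall intensity scale is preserved.  ``background_sigma``
    should dwarf the ring spacing; passing ``expected_spacing`` enables
    a warning when it is less than 5x that spacing.  Non-positive
    input is offset to be strictly positive before dividing.
    """
    patch = np.asarray(patch, dtype=float)
    if not np.any(patch):
        raise ValueError("degenerate all-zero patch")
    if expected_spacing is not None and background_sigma < 5 * expected_spacing:
        warnings.warn(
            f"background_sigma={background_sigma:g} is < 5x the expected ring "
            f"spacing ({expected_spacing:g} px); the background estimate may "
            "absorb band signal",
            stacklevel=2,
        )
    lo = patch.min()
    if lo <= 0:
        offset = -lo + 1e-6 * max(np.ptp(patch), 1.0)
        log.info("pseudo_flat_field: offsetting patch by %+g to keep it positive", offset)
        patch = patch + offset
    background = ndimage.gaussian_filter(patch, background_sigma, mode="reflect")
    return patch / background * background.mean()


def collapse_profile(patch: np.ndarray, provenance: list[str] | None = None) -> RadialProfile:
    """Average each radial row into a single intensity value."""
    patch = np.asarray(patch, dtype=float)
    if patch.ndim == 1:
        patch = patch[:, None]
    if patch.ndim != 2:
        raise ValueError("patch must be 2-D (length x width)")
    intensities = patch.mean(axis=1)
    return RadialProfile(
        positions=np.arange(patch.shape[0], dtype=float),
        intensities=intensities,
        provenance=[*(provenance or []), f"collapse_profile (width={patch.shape[1]})"],
    )


def image_to_profile(
    image: ColonyImage,
    roi: ROI,
    blur_sigma: float = 3.0,
    background_sigma: float | None = None,
    expected_spacing: float | None = None,
) -> RadialProfile:
    """Full preprocessing chain: extract -> blur -> flat-field -> collapse.

    ``background_sigma`` defaults to a quarter of the ROI length.
    Every stage is recorded in the profile's provenance log.
    """
    if background_sigma is None:
        background_sigma = roi.length / 4.0
    steps = [f"extract_roi (anchor={roi.anchor}, length={roi.length}, "
             f"width={roi.width}, angle={roi.angle})"]
    patch = extract_roi(image, roi)
    patch = gaussian_blur(patch, blur_sigma)
    steps.append(f"gaussian_blur (sigma={blur_sigma})")
    patch = pseudo_flat_field(patch, background_sigma, expected_spacing)
    steps.append(f"pseudo_flat_field (background_sigma={background_sigma:g})")
    return collapse_profile(patch, provenance=steps)
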