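"""Image container, grayscale conversion, wavelet denoising and fidelity metrics.

Ultrasound frames arrive as 8-bit grayscale or RGB rasters (or DICOM with
pixel-spacing metadata).  Everything downstream works on a single-channel
float image in [0, 1] with an optional millimetre-per-pixel calibration, so
this module owns the conversion, the speckle-suppression step (wavelet soft
thresholding) and the PSNR/SSIM metrics used to judge it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pywt
from skimage import restoration
from skimage.metrics import structural_similarity

__all__ = [
    "Image2D",
    "load_image",
    "save_image",
    "to_grayscale",
    "denoise_wavelet",
    "psnr",
    "ssim",
]

#: BT.601 luma weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class Image2D:
    """A 2-D intensity raster in [0, 1] with optional physical calibration.

    Parameters
    ----------
    pixels : ndarray of float, shape (H, W)
        Intensities in [0, 1].
    mm_per_pixel : float, optional
        Isotropic pixel size in millimetres.  Required for any measurement
        reported in mm; irrelevant for purely pictorial operations.
    """

    pixels: np.ndarray
    mm_per_pixel: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a 2-D array, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        if self.mm_per_pixel is not None and not self.mm_per_pixel > 0:
            raise ValueError("mm_per_pixel must be positive when present")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def from_array(cls, arr: np.ndarray, mm_per_pixel: float | None = None) -> "Image2D":
        """Build from an integer (0–255) or float array, normalizing to [0, 1]."""
        arr = np.asarray(arr)
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(float) / 255.0
        return cls(np.asarray(arr, dtype=float), mm_per_pixel)

    def with_pixels(self, pixels: np.ndarray) -> "Image2D":
        return replace(self, pixels=pixels)


def _as_pixels(image: "Image2D | np.ndarray") -> np.ndarray:
    return image.pixels if isinstance(image, Image2D) else np.asarray(image, dtype=float)


def to_grayscale(image: "Image2D | np.ndarray", mm_per_pixel: float | None = None) -> Image2D:
    """Convert a 1- or 3-channel raster to a single-channel :class:`Image2D`.

    RGB input is collapsed with BT.601 luma weights (0.299, 0.587, 0.114);
    already-grayscale input passes through unchanged.  Integer input is
    normalized from 0–255 to [0, 1].
    """
    if isinstance(image, Image2D):
        return image if mm_per_pixel is None else replace(image, mm_per_pixel=mm_per_pixel)
    arr = np.asarray(image)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / 255.0
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        return Image2D(arr, mm_per_pixel)
    if arr.ndim == 3 and arr.shape[2] == 1:
        return Image2D(arr[:, :, 0], mm_per_pixel)
    if arr.ndim == 3 and arr.shape[2] == 3:
        gray = arr @ np.array(LUMA_WEIGHTS)
        return Image2D(gray, mm_per_pixel)
    raise ValueError(
        f"expected 1 or 3 channels, got array of shape {arr.shape}"
    )


def denoise_wavelet(
    image: Image2D,
    wavelet: str = "db4",
    level: int = 3,
    threshold_rule: str = "universal",
) -> Image2D:
    """Soft-threshold wavelet denoising.

    ``threshold_rule='universal'`` is VisuShrink: detail coefficients are
    shrunk toward zero by sigma * sqrt(2 ln n), with the noise scale sigma
    estimated from the median absolute deviation of the finest diagonal
    detail band.  ``'bayes'`` selects BayesShrink instead.  Output is clipped
    back to [0, 1]; shape and calibration are preserved.
    """
    if level < 1:
        raise ValueError("decomposition level must be >= 1")
    max_level = pywt.dwtn_max_level(image.pixels.shape, wavelet)
    if level > max_level:
        raise ValueError(
            f"level {level} too deep for image of shape {image.pixels.shape} "
            f"with wavelet '{wavelet}' (max {max_level})"
        )
    rule = threshold_rule.lower()
    if rule in ("universal", "visushrink"):
        # noise scale from the MAD of the finest diagonal detail band
        _, (_, _, diag) = pywt.dwt2(image.pixels, wavelet)
        sigma = float(np.median(np.abs(diag))) / 0.6745
        if sigma == 0.0:  # (near-)noise-free input is a fixed point
            return image.with_pixels(np.clip(image.pixels, 0.0, 1.0))
        den = restoration.denoise_wavelet(
            image.pixels,
            sigma=sigma,
            wavelet=wavelet,
            mode="soft",
            wavelet_levels=level,
            method="VisuShrink",
        )
    elif rule in ("bayes", "bayesshrink"):
        den = restoration.denoise_wavelet(
            image.pixels,
            wavelet=wavelet,
            mode="soft",
            wavelet_levels=level,
            method="BayesShrink",
        )
    else:
        raise ValueError(f"unknown threshold_rule {threshold_rule!r}")
    return image.with_pixels(np.clip(den, 0.0, 1.0))


def psnr(reference: "Image2D | np.ndarray", test: "Image2D | np.ndarray", data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB: 10 log10(data_range^2 / MSE).

    Identical inputs have zero MSE; ``inf`` is returned rather than raising,
    since comparing an image with itself is a legitimate degenerate case.
    """
    ref = _as_pixels(reference)
    tst = _as_pixels(test)
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    if not data_range > 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((ref - tst) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(data_range**2 / mse)


def ssim(
    reference: "Image2D | np.ndarray",
    test: "Image2D | np.ndarray",
    data_range: float = 1.0,
    win_size: int = 7,
) -> float:
    """Mean local structural similarity with the standard constants.

    Uses a 7x7 uniform window and stabilizers K1=0.01, K2=0.03 on the data
    range.  Raises if shapes differ or either image is smaller than the
    window.
    """
    ref = _as_pixels(reference)
    tst = _as_pixels(test)
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    if min(ref.shape) < win_size:
        raise ValueError(
            f"image of shape {ref.shape} smaller than SSIM window ({win_size})"
        )
    return float(
        structural_similarity(
            ref, tst, win_size=win_size, data_range=data_range, K1=0.01, K2=0.03
        )
    )


def load_image(path: "str | Path", mm_per_pixel: float | None = None) -> Image2D:
    """Read PNG/TIFF/JPEG (or DICOM, if pydicom is installed) into an Image2D.

    DICOM pixel-spacing metadata, when present, populates ``mm_per_pixel``
    unless an explicit value is given.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        return _load_dicom(path, mm_per_pixel)
    import imageio.v3 as iio

    arr = iio.imread(path)
    return to_grayscale(arr, mm_per_pixel)


def _load_dicom(path: Path, mm_per_pixel: float | None) -> Image2D:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading DICOM requires the 'pydicom' extra") from exc
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    if mm_per_pixel is None:
        spacing = getattr(ds, "PixelSpacing", None)
        if spacing is not None:
            mm_per_pixel = float(spacing[0])
    if arr.ndim == 3:
        return to_grayscale(arr, mm_per_pixel)
    return Image2D(arr, mm_per_pixel)


def save_image(image: Image2D, path: "str | Path") -> None:
    """Write the image as an 8-bit raster."""
    import imageio.v3 as iio

    arr = np.clip(image.pixels, 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255.0 + 0.5).astype(np.uint8))
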