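"""Image enhancement and lung-field segmentation.

The segmentation recipe is maximum between-class variance (Otsu) thresholding
followed by morphological cleanup based on grayscale/binary reconstruction:
opening-by-reconstruction with a disc structuring element, hole filling by
reconstruction from the border, and retention of the two largest connected
components (the two lung fields).

Clinical radiographs have radiolucent (dark) lungs while the synthetic
convention renders lung fields bright; ``polarity`` selects which side of the
threshold is foreground.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import exposure, morphology

__all__ = [
    "SegmentationError",
    "enhance",
    "otsu_threshold",
    "segment_lung_fields",
    "apply_mask",
    "read_image",
    "write_mask",
]


class SegmentationError(RuntimeError):
    """Raised when no plausible lung-field foreground survives cleanup."""


def _validate_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2D grayscale image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def enhance(img: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Global histogram equalization onto [0, 1].

    Rank-preserving: pixels keep their relative order.  A constant image has
    no contrast to equalize and is returned unchanged.
    """
    img = _validate_image(img)
    if img.max() == img.min():
        return img.copy()
    return exposure.equalize_hist(img, nbins=n_bins)


def otsu_threshold(img: np.ndarray, n_bins: int = 256) -> float:
    """Maximum between-class variance threshold.

    The intensity range is split into ``n_bins`` histogram bins; every bin
    edge is a candidate cut t, and the returned edge maximizes

        sigma_B^2(t) = w0(t) * w1(t) * (mu0(t) - mu1(t))^2

    with ties broken toward the lower threshold.

    Raises
    ------
    ValueError
        For a constant image (no between-class variance to maximize).
    """
    img = _validate_image(img)
    vmin, vmax = float(img.min()), float(img.max())
    if vmin == vmax:
        raise ValueError("cannot threshold a constant image")
    counts, edges = np.histogram(img, bins=n_bins, range=(vmin, vmax))
    sums, _ = np.histogram(img, bins=n_bins, range=(vmin, vmax), weights=img)
    w0 = np.cumsum(counts)[:-1].astype(float)            # pixels below the cut edge
    w1 = img.size - w0
    csum = np.cumsum(sums)[:-1]
    total = img.sum()
    mu0 = np.divide(csum, w0, out=np.zeros_like(csum), where=w0 > 0)
    mu1 = np.divide(total - csum, w1, out=np.zeros_like(csum), where=w1 > 0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    best = int(np.argmax(sigma_b))                       # argmax takes the first (lowest) tie
    return float(edges[best + 1])


def segment_lung_fields(img: np.ndarray, *, polarity: str = "bright",
                        disc_radius: int = 5, n_bins: int = 256,
                        keep: int = 2) -> np.ndarray:
    """Extract the lung fields as a boolean mask.

    Binarizes at the Otsu threshold (``polarity`` picks the bright or dark
    side as lung), cleans the result by opening-by-reconstruction with a disc
    of ``disc_radius`` pixels, fills holes by reconstruction from the border,
    and keeps the ``keep`` largest 8-connected components.

    Raises
    ------
    SegmentationError
        If nothing survives cleanup (e.g. structure-free noise images).
    """
    img = _validate_image(img)
    if polarity not in ("bright", "dark"):
        raise ValueError("polarity must be 'bright' or 'dark'")
    t = otsu_threshold(img, n_bins=n_bins)
    binary = img > t if polarity == "bright" else img < t

    selem = morphology.disk(disc_radius)
    eroded = morphology.erosion(binary, selem)
    # opening-by-reconstruction: geodesic dilation of the eroded marker
    opened = morphology.reconstruction(eroded, binary, method="dilation").astype(bool)
    filled = ndimage.binary_fill_holes(opened)

    labels, n_comp = ndimage.label(filled, structure=np.ones((3, 3), dtype=int))
    if n_comp == 0:
        raise SegmentationError("no foreground component survived morphological cleanup")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_comp + 1))
    keep_labels = 1 + np.argsort(sizes)[::-1][:keep]
    return np.isin(labels, keep_labels)


def apply_mask(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero out pixels outside the mask; inside pixels are unchanged."""
    img = _validate_image(img)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {img.shape}")
    if not mask.any():
        raise ValueError("mask is empty; refusing to zero the whole image")
    return np.where(mask, img, 0.0)


def read_image(path: str | Path) -> np.ndarray:
    """Read PNG/TIFF (or DICOM, if pydicom is installed) as float in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        try:
            import pydicom
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError("reading DICOM requires the 'pydicom' extra") from exc
        arr = pydicom.dcmread(path).pixel_array.astype(float)
        lo, hi = arr.min(), arr.max()
        return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float)
    return arr / 255.0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as a 0/255 PNG."""
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8), mode="L").save(path)
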