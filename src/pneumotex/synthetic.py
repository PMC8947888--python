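"""Seeded synthetic chest-image cohorts with stage-dependent nodular texture.

Real pneumoconiosis screening cohorts are rarely shareable, so this module
renders chest-like test images: two bright elliptical lung fields on a darker
thorax background with spatially correlated noise, plus — for "patient"
images — diffuse small circular opacities whose expected count and contrast
grow with disease stage (I < II < III).  Every render is a pure function of
its arguments, which makes the whole downstream pipeline testable bit-for-bit.

Images are processed as float arrays in [0, 1] and written to disk as 8-bit
PNG (or TIFF).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "STAGES",
    "StageSpec",
    "DEFAULT_STAGE_SPECS",
    "MIN_IMAGE_SIZE",
    "lung_field_mask",
    "generate_image",
    "generate_cohort",
    "MANIFEST_COLUMNS",
]

#: Ordered stage labels; "normal" is disease-free, I–III increasing severity.
STAGES = ("normal", "I", "II", "III")

#: Minimum image side so that an 8-level dyadic wavelet decomposition fits.
MIN_IMAGE_SIZE = 256

MANIFEST_COLUMNS = ["image_id", "path", "label", "stage", "seed"]


@dataclasses.dataclass(frozen=True)
class StageSpec:
    """Texture parameters of one disease stage.

    Parameters
    ----------
    stage : str
        One of ``"normal"``, ``"I"``, ``"II"``, ``"III"``.
    nodule_rate : float
        Expected number of nodular opacities per image (Poisson mean).
        Zero for the normal stage.
    radius_range : tuple of float
        ``(min, max)`` nodule radius in pixels, both >= 1.
    contrast : float
        Peak nodule amplitude as a fraction of the [0, 1] intensity range.
    """

    stage: str
    nodule_rate: float
    radius_range: tuple[float, float] = (2.0, 6.0)
    contrast: float = 0.1

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.nodule_rate < 0:
            raise ValueError("nodule_rate must be >= 0")
        if self.stage == "normal" and self.nodule_rate != 0:
            raise ValueError("normal stage must have nodule_rate == 0")
        lo, hi = self.radius_range
        if not (1.0 <= lo <= hi):
            raise ValueError("radius_range must satisfy 1 <= min <= max")
        if not (0.0 <= self.contrast <= 1.0):
            raise ValueError("contrast must lie in [0, 1]")


#: Default per-stage texture model.  Counts/contrast rise monotonically with
#: stage, emulating the increasing profusion and density of small shadows.
DEFAULT_STAGE_SPECS: dict[str, StageSpec] = {
    "normal": StageSpec("normal", nodule_rate=0, contrast=0.0),
    "I": StageSpec("I", nodule_rate=60, contrast=0.10),
    "II": StageSpec("II", nodule_rate=150, contrast=0.15),
    "III": StageSpec("III", nodule_rate=300, contrast=0.20),
}


def lung_field_mask(height: int, width: int) -> np.ndarray:
    """Ground-truth boolean mask of the two elliptical lung fields.

    The same geometry is used by :func:`generate_image`, so segmentation code
    can be scored against this mask directly.
    """
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    a = 0.14 * width   # semi-axis along x
    b = 0.30 * height  # semi-axis along y
    cy = 0.52 * height
    mask = np.zeros((height, width), dtype=bool)
    for cx in (0.28 * width, 0.72 * width):
        mask |= ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    return mask


def _correlated_noise(shape: tuple[int, int], sigma: float, corr_length: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Gaussian white noise smoothed to the given correlation length.

    The smoothing kernel shrinks the pointwise variance, so the field is
    rescaled back to standard deviation ``sigma``.
    """
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, corr_length, mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth *= sigma / sd
    return smooth


def _render_nodules(shape: tuple[int, int], lung: np.ndarray, spec: StageSpec,
                    rng: np.random.Generator) -> np.ndarray:
    """Additive field of cosine-tapered circular opacities inside the lungs."""
    field = np.zeros(shape, dtype=float)
    n = int(rng.poisson(spec.nodule_rate))
    if n == 0:
        return field
    lung_idx = np.flatnonzero(lung)
    centers = rng.choice(lung_idx, size=n, replace=True)
    radii = rng.uniform(*spec.radius_range, size=n)
    h, w = shape
    for flat, r in zip(centers, radii):
        cy, cx = divmod(int(flat), w)
        ri = int(np.ceil(r))
        y0, y1 = max(cy - ri, 0), min(cy + ri + 1, h)
        x0, x1 = max(cx - ri, 0), min(cx + ri + 1, w)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(yy - cy, xx - cx)
        # cosine profile: full amplitude at the centre, zero at radius r
        profile = np.where(d < r, np.cos(0.5 * np.pi * d / r), 0.0)
        field[y0:y1, x0:x1] += spec.contrast * profile
    # opacities are clipped at the lung-field boundary
    field *= lung
    return field


def generate_image(spec: StageSpec, width: int = 256, height: int = 256,
                   seed: int = 0, *, background_level: float = 0.30,
                   lung_level: float = 0.62, noise_sigma: float = 0.04,
                   correlation_length: float = 1.0) -> np.ndarray:
    """Render one synthetic chest image.

    Returns a ``(height, width)`` float array in [0, 1].  Identical arguments
    always produce bit-identical pixels.

    Raises
    ------
    ValueError
        If either side is below :data:`MIN_IMAGE_SIZE` (the 8-level
        decomposition downstream needs dyadic room).
    """
    if min(width, height) < MIN_IMAGE_SIZE:
        raise ValueError(
            f"image size {width}x{height} below minimum {MIN_IMAGE_SIZE}"
        )
    rng = np.random.default_rng(seed)
    lung = lung_field_mask(height, width)
    img = np.full((height, width), background_level, dtype=float)
    img[lung] = lung_level
    img += _correlated_noise((height, width), noise_sigma, correlation_length, rng)
    img += _render_nodules((height, width), lung, spec, rng)
    return np.clip(img, 0.0, 1.0)


def save_image(img: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG/TIFF."""
    arr = np.round(np.clip(img, 0.0, 1.0) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def _derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-image seeds from one master seed (each < 2**31)."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return (state & 0x7FFFFFFF).astype(np.int64)


def generate_cohort(out_dir: str | Path, n_normal: int,
                    stage_counts: Mapping[str, int], width: int = 256,
                    height: int = 256, seed: int = 0,
                    stage_specs: Mapping[str, StageSpec] | None = None,
                    image_format: str = "png") -> pd.DataFrame:
    """Generate a labelled cohort of images plus a manifest CSV.

    Parameters
    ----------
    out_dir : path
        Output directory (created if missing); images land in
        ``out_dir/images`` and the manifest in ``out_dir/manifest.csv``.
    n_normal : int
        Number of disease-free images (label 0).
    stage_counts : mapping
        Patient counts per stage, e.g. ``{"I": 40, "II": 12, "III": 8}``.
    seed : int
        Master seed; per-image seeds are derived from it and recorded in the
        manifest, so any single image can be regenerated.

    Returns
    -------
    pandas.DataFrame
        The manifest, with columns ``image_id,path,label,stage,seed``.
    """
    if stage_specs is None:
        stage_specs = DEFAULT_STAGE_SPECS
    if n_normal < 0 or any(c < 0 for c in stage_counts.values()):
        raise ValueError("counts must be >= 0")
    for stage in stage_counts:
        if stage not in ("I", "II", "III"):
            raise ValueError(f"unknown patient stage {stage!r}")
    total = n_normal + sum(stage_counts.values())
    if total < 2:
        raise ValueError(f"cohort needs at least 2 images, got {total}")

    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    plan: list[tuple[str, int]] = [("normal", 0)] * n_normal
    for stage in ("I", "II", "III"):
        plan += [(stage, 1)] * stage_counts.get(stage, 0)
    seeds = _derive_seeds(seed, total)

    records = []
    for idx, ((stage, label), img_seed) in enumerate(zip(plan, seeds)):
        image_id = f"img{idx:04d}_{stage}"
        path = img_dir / f"{image_id}.{image_format}"
        img = generate_image(stage_specs[stage], width, height, int(img_seed))
        save_image(img, path)
        records.append((image_id, str(path), label, stage, int(img_seed)))

    manifest = pd.DataFrame(records, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
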