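"""Multi-level wavelet-entropy texture features.

An image is decomposed with an N-level 2D discrete wavelet transform
(Daubechies db7 by default, N = 8).  For level i (1 = finest) the detail
coefficients of all three orientation subbands form one sequence {S_ik};
the level-N approximation band is kept separate and enters no sequence.
Per level the features are

    E_i = sum_k S_ik^2                (energy)
    p_i = E_i / sum_j E_j             (relative energy; the approximation
                                       band is excluded from the total)
    H_i = -p_i ln p_i                 (wavelet entropy, nats)
    T_i = ln(max(H_i, eps))           (log feature, eps = 1e-12)

H_i lies in [0, 1/e]; p and hence H, T are invariant to a global intensity
rescaling of the image.  With an orthogonal basis and periodization boundary
handling the transform is energy preserving (Parseval), which the tests
exploit.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DecompositionSpec",
    "WaveletDecomposition",
    "EntropyFeatureVector",
    "LOG_EPS",
    "decompose",
    "level_energy",
    "relative_energies",
    "wavelet_entropy",
    "entropy_vector",
    "log_transform",
    "crop_and_pad",
    "WaveletEntropyExtractor",
]

#: Floor used before taking ln of an entropy value; blank levels have H = 0
#: and must map to a finite sentinel rather than -inf.
LOG_EPS = 1e-12

_PYWT_MODES = {"periodization": "periodization", "symmetric": "symmetric"}


@dataclasses.dataclass(frozen=True)
class DecompositionSpec:
    """Wavelet basis, number of levels, and boundary handling."""

    basis: str = "db7"
    levels: int = 8
    boundary_mode: str = "periodization"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.boundary_mode not in _PYWT_MODES:
            raise ValueError("boundary_mode must be 'periodization' or 'symmetric'")
        pywt.Wavelet(self.basis)  # raises on unknown basis


@dataclasses.dataclass(frozen=True)
class WaveletDecomposition:
    """Per-level detail sequences plus the final approximation band.

    ``details[i - 1]`` is the flattened concatenation of the horizontal,
    vertical and diagonal subbands of level i (level 1 = finest).
    """

    details: tuple[np.ndarray, ...]
    approx: np.ndarray

    @property
    def levels(self) -> int:
        return len(self.details)


@dataclasses.dataclass(frozen=True)
class EntropyFeatureVector:
    """All per-level features of one image."""

    energies: np.ndarray          # E_i, length N
    total_energy: float           # E = sum E_i
    relative_energies: np.ndarray  # p_i
    entropies: np.ndarray         # H_i (nats)
    log_features: np.ndarray      # T_i = ln(max(H_i, eps))


def crop_and_pad(img: np.ndarray, mask: np.ndarray | None = None,
                 levels: int = 8) -> np.ndarray:
    """Crop to the mask bounding box and zero-pad to a multiple of 2**levels.

    With no mask the image is only padded.  Padding is appended on the
    bottom/right so pixel positions stay stable.
    """
    img = np.asarray(img, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != img.shape:
            raise ValueError("mask shape does not match image shape")
        if not mask.any():
            raise ValueError("mask is empty")
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        img = img[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    block = 2 ** levels
    pad_r = (-img.shape[0]) % block
    pad_c = (-img.shape[1]) % block
    if pad_r or pad_c:
        img = np.pad(img, ((0, pad_r), (0, pad_c)))
    return img


def decompose(img: np.ndarray, spec: DecompositionSpec = DecompositionSpec()
              ) -> WaveletDecomposition:
    """N-level 2D multiresolution analysis of an image.

    Raises
    ------
    ValueError
        If the image is too small for ``spec.levels`` dyadic halvings; the
        message names the maximum feasible level count.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    short = min(img.shape)
    max_levels = int(np.floor(np.log2(short))) if short > 1 else 0
    if spec.levels > max_levels:
        raise ValueError(
            f"image of shape {img.shape} supports at most {max_levels} "
            f"decomposition levels, requested {spec.levels}"
        )
    import warnings as _warnings
    with _warnings.catch_warnings():
        # pywt warns when levels exceed its filter-length heuristic; with
        # periodization the transform stays exact, which is what we rely on
        _warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(img, spec.basis,
                               mode=_PYWT_MODES[spec.boundary_mode],
                               level=spec.levels)
    approx = coeffs[0]
    # wavedec2 orders detail tuples coarse -> fine; level 1 is the finest
    details = tuple(
        np.concatenate([band.ravel() for band in coeffs[-i]])
        for i in range(1, spec.levels + 1)
    )
    return WaveletDecomposition(details=details, approx=approx)


def level_energy(coeffs: np.ndarray) -> float:
    """E_i: sum of squared detail coefficients of one level."""
    coeffs = np.asarray(coeffs, dtype=float)
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("non-finite wavelet coefficients")
    return float(np.sum(coeffs * coeffs))


def relative_energies(energies: np.ndarray) -> np.ndarray:
    """p_i = E_i / E.  Requires positive total detail energy."""
    energies = np.asarray(energies, dtype=float)
    if np.any(energies < 0):
        raise ValueError("energies must be nonnegative")
    total = energies.sum()
    if total <= 0:
        raise ValueError("zero total detail energy (blank image)")
    return energies / total


def wavelet_entropy(p: np.ndarray | float) -> np.ndarray | float:
    """H = -p ln p with the limit convention H(0) = 0 (and H(1) = 0)."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("relative energies must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(p_arr > 0, -p_arr * np.log(p_arr), 0.0)
    return float(h) if np.isscalar(p) else h


def log_transform(entropies: np.ndarray, eps: float = LOG_EPS) -> np.ndarray:
    """T_i = ln(max(H_i, eps)); monotone in H_i, finite for blank levels."""
    h = np.asarray(entropies, dtype=float)
    if np.any(h < 0):
        raise ValueError("entropies must be nonnegative")
    return np.log(np.maximum(h, eps))


def entropy_vector(img: np.ndarray,
                   spec: DecompositionSpec = DecompositionSpec(),
                   mask: np.ndarray | None = None) -> EntropyFeatureVector:
    """Full feature computation: decompose -> E -> p -> H -> T.

    If ``mask`` is given the image is cropped to the mask bounding box (and
    zero-padded back to dyadic size) first, so features describe the lung
    fields rather than the whole frame.
    """
    prepared = crop_and_pad(img, mask=mask, levels=spec.levels)
    dec = decompose(prepared, spec)
    energies = np.array([level_energy(d) for d in dec.details])
    p = relative_energies(energies)
    h = wavelet_entropy(p)
    return EntropyFeatureVector(
        energies=energies,
        total_energy=float(energies.sum()),
        relative_energies=p,
        entropies=h,
        log_features=log_transform(h),
    )


class WaveletEntropyExtractor(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: images -> (n, levels) feature matrix.

    Parameters
    ----------
    basis, levels, boundary_mode :
        Decomposition parameters, see :class:`DecompositionSpec`.
    output : {"T", "H", "p"}
        Which per-level quantity to emit: log features (default), raw
        entropies, or relative energies.
    """

    def __init__(self, basis: str = "db7", levels: int = 8,
                 boundary_mode: str = "periodization", output: str = "T"):
        self.basis = basis
        self.levels = levels
        self.boundary_mode = boundary_mode
        self.output = output

    def fit(self, X, y=None):  # noqa: D102 - nothing to learn
        if self.output not in ("T", "H", "p"):
            raise ValueError("output must be 'T', 'H' or 'p'")
        self.spec_ = DecompositionSpec(self.basis, self.levels, self.boundary_mode)
        self.n_features_in_ = self.levels
        return self

    def transform(self, X) -> np.ndarray:
        """X is a sequence of 2D arrays (or one (n, h, w) stack)."""
        if not hasattr(self, "spec_"):
            self.fit(X)
        rows = []
        for img in X:
            fv = entropy_vector(np.asarray(img), self.spec_)
            rows.append({"T": fv.log_features, "H": fv.entropies,
                         "p": fv.relative_energies}[self.output])
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        return np.array([f"{self.output}{i}" for i in range(1, self.levels + 1)])
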