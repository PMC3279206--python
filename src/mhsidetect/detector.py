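"""Two-class sparse-representation tumor detector.

A pixel spectrum ``x`` (B bands) is coded against the concatenated
training dictionary ``A = [A_nc A_c]`` of noncancerous and cancerous
spectra.  The recovered coefficient vector splits into the noncancerous
block ``alpha`` and the cancerous block ``beta``, giving the class
reconstruction residuals

    r_nc(x) = ||x - A_nc alpha||_2,    r_c(x) = ||x - A_c beta||_2

and the decision score ``D(x) = log10(r_nc / r_c)``.  A tissue
reconstructed better by its own class's training pixels has the smaller
in-class residual, so ``D(x) > 0`` flags the pixel as cancerous and
``D(x) <= 0`` as noncancerous.  Residuals are floored before the ratio so
an exact in-class reconstruction (residual 0) yields a large finite score
rather than an infinity.

Glare blanks out pixels inside tumors; since those holes are enclosed by
detected tissue, a morphological hole fill on the binary mask recovers
them as a post-processing step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, ConsistencyError, ParameterError, SolverError
from .hsi_io import LabelMask, SpectralCube, SpectralDictionary
from .sparse_solver import Coefficients, SolverConfig, solve

__all__ = [
    "SparseCode",
    "DetectionMap",
    "build_dictionary",
    "classify_pixel",
    "classify_cube",
    "fill_holes",
]

#: residual floor preventing log10 of zero at exact reconstructions
DEFAULT_FLOOR = 1e-12


@dataclass
class SparseCode:
    """Classification record for a single pixel.

    ``score`` is ``log10(r_nc / r_c)`` after flooring; ``label`` is
    ``"cancerous"`` exactly when the score is positive (a tied score
    falls to noncancerous).
    """

    gamma: Coefficients
    r_nc: float
    r_c: float
    score: float
    label: str = field(init=False)

    def __post_init__(self) -> None:
        self.label = "cancerous" if self.score > 0 else "noncancerous"


@dataclass
class DetectionMap:
    """Per-pixel score map with raw and post-processed binary masks."""

    scores: np.ndarray
    raw_mask: np.ndarray
    final_mask: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.raw_mask = np.asarray(self.raw_mask, dtype=bool)
        self.final_mask = np.asarray(self.final_mask, dtype=bool)
        if not (self.scores.shape == self.raw_mask.shape == self.final_mask.shape):
            raise ConsistencyError("score map and masks must share one shape")


def build_dictionary(
    normal_spectra: np.ndarray,
    cancer_spectra: np.ndarray,
    normalize: bool = True,
    wavelengths_nm: Optional[np.ndarray] = None,
) -> SpectralDictionary:
    """Assemble A = [A_nc A_c] from per-class training spectra.

    Inputs are row-per-spectrum arrays (N_nc x B and N_c x B); atoms are
    the transposed spectra, noncancerous block first.  With *normalize*
    every column is scaled to unit l2 norm so atom selection is not
    biased toward bright spectra.
    """
    normal = np.atleast_2d(np.asarray(normal_spectra, dtype=float))
    cancer = np.atleast_2d(np.asarray(cancer_spectra, dtype=float))
    if normal.size == 0 or cancer.size == 0:
        raise ConfigurationError("both classes need at least one training spectrum")
    if normal.shape[1] != cancer.shape[1]:
        raise ConsistencyError(
            f"band count mismatch: {normal.shape[1]} vs {cancer.shape[1]}"
        )
    atoms = np.vstack([normal, cancer]).T
    if normalize:
        norms = np.linalg.norm(atoms, axis=0)
        if np.any(norms == 0):
            raise ConfigurationError(
                "all-zero training spectrum cannot be normalized"
            )
        atoms = atoms / norms
    labels = np.concatenate([
        np.zeros(normal.shape[0], dtype=int),
        np.ones(cancer.shape[0], dtype=int),
    ])
    return SpectralDictionary(atoms, labels, normalized=normalize,
                              wavelengths_nm=wavelengths_nm)


def classify_pixel(
    x: np.ndarray,
    dictionary: SpectralDictionary,
    cfg: Optional[SolverConfig] = None,
    floor: float = DEFAULT_FLOOR,
) -> SparseCode:
    """Classify one spectrum by comparing class reconstruction residuals."""
    cfg = cfg or SolverConfig()
    if floor <= 0:
        raise ParameterError("residual floor must be positive")
    x = np.asarray(x, dtype=float).ravel()
    if x.size != dictionary.n_bands:
        raise ConsistencyError(
            f"spectrum has {x.size} bands, dictionary expects {dictionary.n_bands}"
        )
    if not np.all(np.isfinite(x)):
        raise ConsistencyError("spectrum contains non-finite values")
    gamma = solve(x, dictionary.atoms, cfg)
    n_nc = dictionary.n_noncancerous
    alpha = gamma.values[:n_nc]
    beta = gamma.values[n_nc:]
    r_nc = float(np.linalg.norm(x - dictionary.noncancerous @ alpha))
    r_c = float(np.linalg.norm(x - dictionary.cancerous @ beta))
    score = float(np.log10(max(r_nc, floor) / max(r_c, floor)))
    return SparseCode(gamma, r_nc, r_c, score)


def classify_cube(
    cube: SpectralCube,
    dictionary: SpectralDictionary,
    cfg: Optional[SolverConfig] = None,
    mask_of_interest: Optional[LabelMask] = None,
    floor: float = DEFAULT_FLOOR,
) -> DetectionMap:
    """Classify every pixel of a reflectance cube.

    When *mask_of_interest* is given, only its labeled (non-255) pixels
    are coded; the rest receive score 0 (noncancerous).  The final mask
    equals the raw mask until :func:`fill_holes` is applied.
    """
    cfg = cfg or SolverConfig()
    if cube.kind != "reflectance":
        raise ConsistencyError("classify_cube expects a reflectance cube")
    if cube.n_bands != dictionary.n_bands:
        raise ConsistencyError(
            f"cube has {cube.n_bands} bands, dictionary {dictionary.n_bands}"
        )
    h, w, _ = cube.shape
    if mask_of_interest is not None and mask_of_interest.labels.shape != (h, w):
        raise ConsistencyError("mask of interest shape mismatch")
    scores = np.zeros((h, w), dtype=float)
    of_interest = (mask_of_interest.labeled if mask_of_interest is not None
                   else np.ones((h, w), dtype=bool))
    for i, j in np.argwhere(of_interest):
        try:
            scores[i, j] = classify_pixel(cube.data[i, j], dictionary, cfg,
                                          floor).score
        except SolverError as exc:
            raise SolverError(f"pixel (row={i}, col={j}): {exc}") from exc
    raw_mask = scores > 0
    return DetectionMap(scores, raw_mask, raw_mask.copy())


_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def fill_holes(detection: DetectionMap, connectivity: int = 4) -> DetectionMap:
    """Fill enclosed background holes in the raw detection mask.

    Every background connected component with no path to the image
    border becomes foreground; foreground pixels are never removed.
    *connectivity* (4 or 8) is the adjacency used for the background
    complement — 4 by default, pairing with 8-connected foreground to
    avoid topological paradoxes.
    """
    if connectivity not in _STRUCTURES:
        raise ParameterError("connectivity must be 4 or 8")
    filled = ndimage.binary_fill_holes(detection.raw_mask,
                                       structure=_STRUCTURES[connectivity])
    return DetectionMap(detection.scores, detection.raw_mask, filled)
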