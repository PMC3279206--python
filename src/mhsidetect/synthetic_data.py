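"""Synthetic tongue-scene simulator.

No public medical hyperspectral tumor database exists, so the pipeline
is exercised on simulated scenes that reproduce the statistical
structure the detector relies on: two tissue classes with smooth mean
reflectance spectra over 600-1000 nm whose gap peaks in the red/NIR,
wavelength-dependent per-class standard deviation rising toward the
NIR, elliptical tumor regions, sparse saliva-glare impulses saturating a
contiguous band range, and paired white/dark reference frames so that
calibration is part of the loop (raw counts are produced by inverting
the reflectance equation: raw = R * (white - dark) + dark).

All magnitudes are synthetic defaults chosen for realism; they are not
measurements.  Everything is driven by one integer seed and is
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.draw import ellipse as _draw_ellipse

from .errors import ParameterError, SplitError
from .hsi_io import (LabelMask, ReferencePair, SpectralCube, UNLABELED,
                     default_wavelengths)

__all__ = [
    "EllipseSpec",
    "SimulationConfig",
    "SimulatedScene",
    "TrainTestSplit",
    "default_signatures",
    "simulate_scene",
    "split_train_test",
]

logger = logging.getLogger(__name__)


def default_signatures(
    n_bands: int, separation: float,
    wavelengths_nm: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Smooth two-class mean/sd reflectance profiles.

    The normal-tissue mean is a gentle logistic rise across the red edge
    (~0.56 at 600 nm to ~0.75 at 1000 nm, typical of pale mucosa); the
    tumor mean sits below it by a smooth bump whose supremum equals
    *separation* exactly, peaking near 720 nm where hemoglobin-related
    absorption differences are strongest.  Standard deviations are
    positive and rise toward 1000 nm (0.02-0.05 nominal), the cancerous
    class slightly noisier.

    Returns ``(mean_normal, mean_cancer, sd_normal, sd_cancer)``, each of
    length *n_bands*; ``separation = 0`` yields identical means.
    """
    if n_bands < 2:
        raise ParameterError("need at least 2 bands")
    if not 0.0 <= separation <= 1.0:
        raise ParameterError("separation must lie in [0, 1]")
    lam = (np.asarray(wavelengths_nm, dtype=float)
           if wavelengths_nm is not None else default_wavelengths(n_bands))
    if lam.size != n_bands:
        raise ParameterError("wavelength grid length must equal n_bands")
    mean_normal = 0.55 + 0.2 / (1.0 + np.exp(-(lam - 750.0) / 50.0))
    bump = np.exp(-((lam - 720.0) / 90.0) ** 2)
    bump /= bump.max()  # sup-norm gap equals `separation` exactly on the grid
    mean_cancer = mean_normal - separation * bump
    t = (lam - lam[0]) / max(lam[-1] - lam[0], 1.0)
    sd_normal = 0.02 + 0.03 * t
    sd_cancer = 0.025 + 0.03 * t
    return mean_normal, mean_cancer, sd_normal, sd_cancer


@dataclass
class EllipseSpec:
    """A rasterized tumor region: center (row, col), semi-axes, rotation."""

    center: tuple[float, float]
    axes: tuple[float, float]
    angle: float = 0.0


@dataclass
class SimulationConfig:
    """Scene parameters; every field has a documented synthetic default.

    ``mean_*``/``sd_*`` default to :func:`default_signatures` at the
    given *separation*.  ``glare_fraction`` is the per-pixel Bernoulli
    probability of a saliva-glare impulse; glare saturates a random
    contiguous band range at ``impulse_value`` (1.5, above the white
    reference, as specular highlights are).  ``illumination_gain`` is
    the lamp spectrum in counts (halogen-like, brighter in the NIR);
    ``dark_level`` the mean dark current, with 0.5-count read noise.
    """

    height: int = 64
    width: int = 64
    wavelengths_nm: np.ndarray = field(default_factory=default_wavelengths)
    separation: float = 0.15
    mean_normal: Optional[np.ndarray] = None
    mean_cancer: Optional[np.ndarray] = None
    sd_normal: Optional[np.ndarray] = None
    sd_cancer: Optional[np.ndarray] = None
    tumor_shapes: Sequence[EllipseSpec] = field(default_factory=lambda: [
        EllipseSpec(center=(0.5, 0.5), axes=(0.22, 0.14), angle=0.4),
    ])
    glare_fraction: float = 0.01
    impulse_value: float = 1.5
    illumination_gain: Optional[np.ndarray] = None
    dark_level: float = 100.0
    dark_read_noise: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        b = self.wavelengths_nm.size
        if self.height < 1 or self.width < 1:
            raise ParameterError("scene dimensions must be positive")
        if not 0.0 <= self.glare_fraction < 1.0:
            raise ParameterError("glare_fraction must lie in [0, 1)")
        defaults = default_signatures(b, self.separation, self.wavelengths_nm)
        names = ("mean_normal", "mean_cancer", "sd_normal", "sd_cancer")
        for name, fallback in zip(names, defaults):
            value = getattr(self, name)
            if value is None:
                value = fallback
            value = np.broadcast_to(np.asarray(value, dtype=float), (b,)).copy()
            setattr(self, name, value)
        for name in ("mean_normal", "mean_cancer"):
            m = getattr(self, name)
            if np.any(m <= 0) or np.any(m >= 1):
                raise ParameterError(f"{name} must lie strictly in (0, 1)")
        for name in ("sd_normal", "sd_cancer"):
            if np.any(getattr(self, name) < 0):
                raise ParameterError(f"{name} must be non-negative")
        if self.illumination_gain is None:
            # halogen lamp: smooth, brighter toward the NIR
            t = (self.wavelengths_nm - self.wavelengths_nm[0]) / max(
                self.wavelengths_nm[-1] - self.wavelengths_nm[0], 1.0)
            self.illumination_gain = 2000.0 + 1500.0 * t
        self.illumination_gain = np.broadcast_to(
            np.asarray(self.illumination_gain, dtype=float), (b,)).copy()
        if np.any(self.illumination_gain <= 0):
            raise ParameterError("illumination_gain must be positive")

    @property
    def n_bands(self) -> int:
        return self.wavelengths_nm.size


@dataclass
class SimulatedScene:
    """A raw cube with its references, ground truth and noiseless target."""

    raw: SpectralCube
    refs: ReferencePair
    truth: LabelMask
    true_reflectance: SpectralCube


def _rasterize_tumors(cfg: SimulationConfig) -> np.ndarray:
    labels = np.zeros((cfg.height, cfg.width), dtype=np.uint8)
    scale = float(min(cfg.height, cfg.width))
    for shape in cfg.tumor_shapes:
        r0 = shape.center[0] * cfg.height
        c0 = shape.center[1] * cfg.width
        rr, cc = _draw_ellipse(r0, c0, shape.axes[0] * scale,
                               shape.axes[1] * scale,
                               shape=(cfg.height, cfg.width),
                               rotation=shape.angle)
        if rr.size == 0:
            logger.warning("tumor ellipse at %s falls entirely outside the frame",
                           shape.center)
            continue
        labels[rr, cc] = 1
    return labels


def simulate_scene(cfg: SimulationConfig) -> SimulatedScene:
    """Generate a raw scene, its reference frames and ground truth.

    The truth mask rasterizes the configured ellipses (1 inside).  True
    reflectance draws each pixel as its class mean plus per-band Gaussian
    noise with the class sd, then glare pixels (Bernoulli per pixel)
    overwrite a random contiguous band range with ``impulse_value``.
    Raw counts invert the calibration equation against the white frame
    (lamp spectrum broadcast over the scene) and the dark frame (mean
    dark level plus read noise).  A fixed seed reproduces the scene
    bit for bit.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w, b = cfg.height, cfg.width, cfg.n_bands
    truth = _rasterize_tumors(cfg)

    mean = np.where(truth[..., None] == 1, cfg.mean_cancer, cfg.mean_normal)
    sd = np.where(truth[..., None] == 1, cfg.sd_cancer, cfg.sd_normal)
    refl = mean + sd * rng.standard_normal((h, w, b))

    if cfg.glare_fraction > 0:
        glare = rng.random((h, w)) < cfg.glare_fraction
        for i, j in np.argwhere(glare):
            start = rng.integers(0, b)
            length = rng.integers(1, b - start + 1)
            refl[i, j, start:start + length] = cfg.impulse_value

    white = np.broadcast_to(cfg.illumination_gain, (h, w, b)).copy()
    dark = cfg.dark_level + cfg.dark_read_noise * rng.standard_normal((h, w, b))
    raw = refl * (white - dark) + dark

    return SimulatedScene(
        raw=SpectralCube(np.maximum(raw, 0.0), cfg.wavelengths_nm, kind="raw"),
        refs=ReferencePair(white=white, dark=dark),
        truth=LabelMask(truth),
        true_reflectance=SpectralCube(refl, cfg.wavelengths_nm,
                                      kind="reflectance"),
    )


@dataclass
class TrainTestSplit:
    """Per-class flat pixel indices (into ``labels.ravel()``)."""

    train: dict[int, np.ndarray]
    test: dict[int, np.ndarray]


def split_train_test(truth: LabelMask, train_frac: float,
                     seed: int) -> TrainTestSplit:
    """Random per-class split of labeled pixels, without replacement.

    Each class contributes ``round(train_frac * class size)`` training
    pixels (at least 1, at most size-1); train and test are disjoint and
    together exhaust the labeled pixels.  Unlabeled (255) pixels never
    appear in either side.
    """
    if not 0.0 < train_frac < 1.0:
        raise ParameterError("train_frac must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    flat = truth.labels.ravel()
    train: dict[int, np.ndarray] = {}
    test: dict[int, np.ndarray] = {}
    for cls in (0, 1):
        idx = np.flatnonzero(flat == cls)
        if idx.size < 2:
            raise SplitError(
                f"class {cls} has {idx.size} labeled pixels; need >= 2 to split"
            )
        n_train = int(np.clip(round(train_frac * idx.size), 1, idx.size - 1))
        perm = rng.permutation(idx.size)
        train[cls] = np.sort(idx[perm[:n_train]])
        test[cls] = np.sort(idx[perm[n_train:]])
    return TrainTestSplit(train=train, test=test)
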