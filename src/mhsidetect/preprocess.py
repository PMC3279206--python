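"""Denoising and reflectance calibration.

Raw tongue images carry impulse noise from saliva glints and tongue
motion; a per-band 2-D median filter suppresses it.  Radiance counts are
then converted to relative reflectance against a white board placed in
the scene and a dark-current frame captured with the shutter closed:

    R(lambda) = (I_raw - I_dark) / (I_white - I_dark)

computed elementwise per pixel and band.  The pipeline order is fixed:
denoise the raw counts first, then calibrate.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .errors import ConsistencyError, ParameterError
from .hsi_io import ReferencePair, SpectralCube

__all__ = ["median_denoise", "normalize_reflectance"]

logger = logging.getLogger(__name__)

#: denominator guard below which calibration is undefined (dead band)
DEFAULT_GUARD = 1e-9


def median_denoise(cube: SpectralCube, window: int = 3) -> SpectralCube:
    """Apply a ``window x window`` 2-D median filter to every band.

    Bands are filtered independently (spatial only, no smoothing along
    the spectral axis).  Edges use reflect padding so border pixels see a
    full window of in-image values.  ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"median window must be odd and >= 1, got {window}")
    if window == 1:
        return SpectralCube(cube.data.copy(), cube.wavelengths_nm, cube.kind)
    out = np.empty_like(cube.data, dtype=float)
    for b in range(cube.n_bands):
        out[:, :, b] = ndimage.median_filter(
            cube.data[:, :, b].astype(float), size=window, mode="reflect"
        )
    return SpectralCube(out, cube.wavelengths_nm, cube.kind)


def normalize_reflectance(
    raw: SpectralCube,
    refs: ReferencePair,
    guard: float = DEFAULT_GUARD,
) -> SpectralCube:
    """Convert raw radiance to relative reflectance using white/dark frames.

    Where the denominator ``|I_white - I_dark|`` falls below *guard* the
    band cannot be calibrated (dead band / sensor fault); those entries
    are set to 0 and reported through the calibration-warning log rather
    than propagating NaN or infinities.

    The transform is invariant under joint positive rescaling of the raw
    frame and both references.
    """
    if raw.kind != "raw":
        raise ConsistencyError("normalize_reflectance expects a raw cube")
    if refs.white.shape != raw.shape:
        raise ConsistencyError(
            f"reference shape {refs.white.shape} != cube shape {raw.shape}"
        )
    if guard <= 0:
        raise ParameterError("guard must be a small positive real")
    denom = refs.white - refs.dark
    dead = np.abs(denom) < guard
    numer = raw.data.astype(float) - refs.dark
    refl = np.zeros_like(numer)
    np.divide(numer, denom, out=refl, where=~dead)
    refl[dead] = 0.0
    n_dead = int(dead.sum())
    if n_dead:
        px = np.argwhere(dead)
        logger.warning(
            "calibration: %d pixel/band entries had |white-dark| < %g and "
            "were zero-filled (first at row=%d col=%d band=%d)",
            n_dead, guard, *px[0],
        )
    return SpectralCube(refl, raw.wavelengths_nm, kind="reflectance")
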