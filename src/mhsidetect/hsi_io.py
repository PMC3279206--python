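"""Hyperspectral cube, reference-frame, label-mask and dictionary I/O.

The on-disk cube format is the ENVI dialect: a small text header
(``samples``, ``lines``, ``bands``, ``data type``, ``interleave``,
``wavelength``) next to a raw binary file holding the samples in band-
sequential (bsq), band-interleaved-by-line (bil) or band-interleaved-by-
pixel (bip) order.  Label masks are single-channel 8-bit PNG/PGM images
with the convention 0 = noncancerous, 1 = cancerous, 255 = unlabeled.
Spectral dictionaries are delimited text tables, one atom per row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image

from .errors import ConfigurationError, ConsistencyError, FormatError

__all__ = [
    "SpectralCube",
    "ReferencePair",
    "LabelMask",
    "SpectralDictionary",
    "default_wavelengths",
    "read_envi_cube",
    "write_envi_cube",
    "read_mask",
    "write_mask",
    "save_dictionary",
    "load_dictionary",
]

#: value marking unlabeled pixels in a LabelMask
UNLABELED = 255

#: default spectral grid: 600-1000 nm at 5 nm, 81 bands
def default_wavelengths(n_bands: int = 81) -> np.ndarray:
    """Return the default wavelength grid (600 nm start, 5 nm step)."""
    return 600.0 + 5.0 * np.arange(n_bands, dtype=float)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SpectralCube:
    """An H x W x B image cube with its wavelength grid.

    ``kind`` distinguishes raw radiance counts (non-negative) from
    calibrated relative reflectance.  Reflectance has no upper bound:
    specular glare routinely exceeds the white reference, hence values
    above 1 are legal; all values must be finite.
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    kind: str = "reflectance"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.kind not in ("raw", "reflectance"):
            raise ConsistencyError(f"unknown cube kind {self.kind!r}")
        if self.data.ndim != 3:
            raise ConsistencyError(
                f"cube data must be H x W x B, got shape {self.data.shape}"
            )
        h, w, b = self.data.shape
        if min(h, w, b) < 1:
            raise ConsistencyError("cube dimensions must all be >= 1")
        if self.wavelengths_nm.shape != (b,):
            raise ConsistencyError(
                f"{b} bands but {self.wavelengths_nm.size} wavelengths"
            )
        if b > 1 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ConsistencyError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ConsistencyError("cube contains non-finite values")
        if self.kind == "raw" and np.any(self.data < 0):
            raise ConsistencyError("raw radiance counts must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class ReferencePair:
    """White-board and dark-current reference frames for calibration.

    ``white >= dark`` elementwise is deliberately NOT assumed: read noise
    on the dark frame can exceed the white signal in dead bands, which the
    calibration guard handles downstream.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ConsistencyError(
                f"white {self.white.shape} and dark {self.dark.shape} "
                "frames must have identical shapes"
            )


@dataclass
class LabelMask:
    """Per-pixel class labels: 0 noncancerous, 1 cancerous, 255 unlabeled."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ConsistencyError("label mask must be 2-D")
        bad = set(np.unique(self.labels)) - {0, 1, UNLABELED}
        if bad:
            raise ConsistencyError(f"mask contains illegal values {sorted(bad)}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def labeled(self) -> np.ndarray:
        """Boolean map of pixels carrying a class label."""
        return self.labels != UNLABELED


@dataclass
class SpectralDictionary:
    """Two-class training dictionary A = [A_nc A_c].

    ``atoms`` is B x (N_nc + N_c) with the noncancerous block first;
    ``labels`` tags each column (0 noncancerous, 1 cancerous).  When
    ``normalized`` is set every column has unit l2 norm.
    """

    atoms: np.ndarray
    labels: np.ndarray
    normalized: bool = True
    wavelengths_nm: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.atoms.ndim != 2:
            raise ConsistencyError("dictionary atoms must be a B x N matrix")
        n = self.atoms.shape[1]
        if self.labels.shape != (n,):
            raise ConsistencyError("one class label per atom required")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ConsistencyError("dictionary labels must be 0 or 1")
        n_nc = int(np.sum(self.labels == 0))
        n_c = n - n_nc
        if n_nc < 1 or n_c < 1:
            raise ConfigurationError(
                f"both classes need atoms (got N_nc={n_nc}, N_c={n_c})"
            )
        # noncancerous block first, then cancerous: two contiguous blocks
        if np.any(self.labels[:n_nc] != 0) or np.any(self.labels[n_nc:] != 1):
            raise ConsistencyError(
                "atoms must be ordered [A_nc A_c] (noncancerous block first)"
            )
        if self.normalized:
            norms = np.linalg.norm(self.atoms, axis=0)
            if np.any(np.abs(norms - 1.0) > 1e-10):
                raise ConsistencyError("normalized flag set but column norms != 1")

    @property
    def n_noncancerous(self) -> int:
        return int(np.sum(self.labels == 0))

    @property
    def n_cancerous(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_bands(self) -> int:
        return self.atoms.shape[0]

    @property
    def noncancerous(self) -> np.ndarray:
        """The noncancerous subdictionary A_nc (view)."""
        return self.atoms[:, : self.n_noncancerous]

    @property
    def cancerous(self) -> np.ndarray:
        """The cancerous subdictionary A_c (view)."""
        return self.atoms[:, self.n_noncancerous:]


# ---------------------------------------------------------------------------
# ENVI cube I/O
# ---------------------------------------------------------------------------

_DTYPE_TO_ENVI = {
    np.dtype(np.uint8): 1,
    np.dtype(np.int16): 2,
    np.dtype(np.int32): 3,
    np.dtype(np.float32): 4,
    np.dtype(np.float64): 5,
    np.dtype(np.uint16): 12,
}
_ENVI_TO_DTYPE = {v: k for k, v in _DTYPE_TO_ENVI.items()}

_INTERLEAVES = ("bsq", "bil", "bip")


def _data_path_for(header_path: Path) -> Path:
    return header_path.with_suffix(".raw")


def _find_data_file(header_path: Path) -> Path:
    stem = header_path.with_suffix("")
    for cand in (stem.with_suffix(".raw"), stem.with_suffix(".img"), stem):
        if cand.exists() and cand != header_path:
            return cand
    raise FormatError(f"no raw data file found next to {header_path}")


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("missing ENVI magic line in header")
    fields: dict[str, str] = {}
    # values are either single-line scalars or brace-delimited blocks
    pattern = re.compile(r"^\s*([a-z][a-z 0-9]*?)\s*=\s*(\{.*?\}|[^\n]*)",
                         re.MULTILINE | re.DOTALL | re.IGNORECASE)
    for m in pattern.finditer(text):
        key = " ".join(m.group(1).lower().split())
        val = m.group(2).strip()
        if val.startswith("{"):
            end = val.find("}")
            if end < 0:
                raise FormatError(f"unterminated '{{' block for key {key!r}")
            val = val[1:end]
        fields[key] = val.strip()
    return fields


def read_envi_cube(header_path) -> SpectralCube:
    """Read an ENVI header + raw binary pair into a :class:`SpectralCube`.

    The companion raw file is located by replacing the header suffix with
    ``.raw`` (``.img`` and suffix-less fallbacks are also probed).  Band
    order follows the header's wavelength list.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FormatError(f"header file {header_path} does not exist")
    fields = _parse_envi_header(header_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except (KeyError, ValueError) as exc:
        raise FormatError(f"garbled or incomplete ENVI header: {exc}") from exc
    if interleave not in _INTERLEAVES:
        raise FormatError(f"unsupported interleave {interleave!r}")
    if dtype_code not in _ENVI_TO_DTYPE:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    if "wavelength" not in fields:
        raise FormatError("header lacks a wavelength block")
    wavelengths = np.array(
        [float(tok) for tok in fields["wavelength"].replace("\n", " ").split(",")
         if tok.strip()],
        dtype=float,
    )
    if wavelengths.size != bands:
        raise ConsistencyError(
            f"header declares {bands} bands but {wavelengths.size} wavelengths"
        )
    dtype = _ENVI_TO_DTYPE[dtype_code]
    offset = int(fields.get("header offset", "0"))
    raw = np.fromfile(_find_data_file(header_path), dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ConsistencyError(
            f"raw file holds {raw.size} samples, header implies {expected}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = raw.reshape(lines, samples, bands)
    kind = fields.get("cube kind", "raw" if dtype.kind in "ui" else "reflectance")
    return SpectralCube(np.ascontiguousarray(data), wavelengths, kind=kind)


def write_envi_cube(cube: SpectralCube, header_path, interleave: str = "bsq") -> None:
    """Write *cube* as an ENVI header + raw binary pair.

    The stored sample type follows the array dtype (float32/float64 for
    calibrated reflectance, uint16 for camera counts); the header's
    ``data type`` field records it.  A nonstandard ``cube kind`` key
    preserves the raw/reflectance distinction across a round trip; ENVI
    readers ignore unknown keys.
    """
    if interleave not in _INTERLEAVES:
        raise FormatError(f"unsupported interleave {interleave!r}")
    header_path = Path(header_path)
    dtype = cube.data.dtype
    if dtype not in _DTYPE_TO_ENVI:
        raise FormatError(f"cannot store cube of dtype {dtype}")
    h, w, b = cube.shape
    if interleave == "bsq":
        ordered = cube.data.transpose(2, 0, 1)
    elif interleave == "bil":
        ordered = cube.data.transpose(0, 2, 1)
    else:  # bip
        ordered = cube.data
    wl = ", ".join(f"{x:.6g}" for x in cube.wavelengths_nm)
    header = (
        "ENVI\n"
        "description = { mhsidetect spectral cube }\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_TO_ENVI[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"cube kind = {cube.kind}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    try:
        header_path.write_text(header)
        np.ascontiguousarray(ordered).tofile(_data_path_for(header_path))
    except OSError as exc:
        raise FormatError(f"cannot write cube to {header_path}: {exc}") from exc


# ---------------------------------------------------------------------------
# label-mask I/O
# ---------------------------------------------------------------------------

def read_mask(path, treat_128_as_cancerous: bool = True) -> LabelMask:
    """Read a single-channel 8-bit PNG/PGM label mask.

    Pixel values map 0 -> noncancerous, 1 -> cancerous, 255 -> unlabeled;
    128 also maps to cancerous when *treat_128_as_cancerous* is set (some
    annotation tools store the positive class at mid-gray).
    """
    img = Image.open(path)
    if img.mode != "L":
        raise FormatError(
            f"mask {path} must be single-channel 8-bit, got mode {img.mode!r}"
        )
    arr = np.asarray(img)
    allowed = {0, 1, UNLABELED} | ({128} if treat_128_as_cancerous else set())
    bad = set(np.unique(arr)) - allowed
    if bad:
        raise FormatError(f"mask contains unexpected values {sorted(bad)}")
    labels = arr.copy()
    if treat_128_as_cancerous:
        labels[labels == 128] = 1
    return LabelMask(labels)


def write_mask(mask: LabelMask, path) -> None:
    """Write a label mask as an 8-bit grayscale image (format by suffix)."""
    Image.fromarray(mask.labels.astype(np.uint8), mode="L").save(path)


# ---------------------------------------------------------------------------
# dictionary table I/O
# ---------------------------------------------------------------------------

_CLASS_NAMES = {0: "noncancerous", 1: "cancerous"}
_CLASS_CODES = {v: k for k, v in _CLASS_NAMES.items()} | {"0": 0, "1": 1}


def save_dictionary(dictionary: SpectralDictionary, path) -> None:
    """Write a dictionary as CSV: header row ``class,l1,...,lB``, one atom
    per data row.  Values carry 17 significant digits so a round trip is
    exact to double precision."""
    path = Path(path)
    b = dictionary.n_bands
    if dictionary.wavelengths_nm is not None:
        cols = [f"{x:.6g}" for x in dictionary.wavelengths_nm]
    else:
        cols = [f"band{i}" for i in range(b)]
    lines = ["class," + ",".join(cols)]
    for j in range(dictionary.atoms.shape[1]):
        name = _CLASS_NAMES[int(dictionary.labels[j])]
        vals = ",".join(f"{v:.17g}" for v in dictionary.atoms[:, j])
        lines.append(f"{name},{vals}")
    path.write_text("\n".join(lines) + "\n")


def load_dictionary(path, normalized: Optional[bool] = None) -> SpectralDictionary:
    """Read a dictionary CSV written by :func:`save_dictionary`.

    *normalized* overrides the unit-norm flag; by default it is inferred
    from the column norms.
    """
    path = Path(path)
    rows = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if len(rows) < 2:
        raise FormatError(f"dictionary table {path} has no atom rows")
    header = rows[0].split(",")
    n_bands = len(header) - 1
    wavelengths = None
    try:
        wavelengths = np.array([float(tok) for tok in header[1:]], dtype=float)
    except ValueError:
        pass  # generic band names; no grid stored
    atoms, labels = [], []
    for i, row in enumerate(rows[1:], start=2):
        fields = row.split(",")
        if len(fields) != n_bands + 1:
            raise FormatError(
                f"row {i} has {len(fields) - 1} values, expected {n_bands}"
            )
        cls = fields[0].strip().lower()
        if cls not in _CLASS_CODES:
            raise FormatError(f"row {i}: unknown class tag {fields[0]!r}")
        labels.append(_CLASS_CODES[cls])
        try:
            atoms.append([float(tok) for tok in fields[1:]])
        except ValueError as exc:
            raise FormatError(f"row {i}: non-numeric value ({exc})") from exc
    atom_matrix = np.array(atoms, dtype=float).T
    if normalized is None:
        norms = np.linalg.norm(atom_matrix, axis=0)
        normalized = bool(np.all(np.abs(norms - 1.0) <= 1e-10))
    return SpectralDictionary(atom_matrix, np.array(labels), normalized=normalized,
                              wavelengths_nm=wavelengths)
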