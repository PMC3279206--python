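"""Pixel-level scoring and end-to-end pipeline orchestration.

Rates follow the standard screening definitions: the false negative
rate is the number of missed tumor pixels over all tumor pixels, the
false positive rate the number of normal pixels flagged as tumor over
all normal pixels, and accuracy the fraction of labeled pixels classified
correctly.  Unlabeled (255) pixels are excluded from every count.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from typing import Optional, Union

import numpy as np

from . import __version__
from .detector import (DetectionMap, build_dictionary, classify_cube,
                       fill_holes)
from .errors import ConsistencyError, EvaluationError, MhsiError, PipelineError
from .hsi_io import LabelMask, ReferencePair, SpectralCube
from .preprocess import median_denoise, normalize_reflectance
from .sparse_solver import SolverConfig
from .synthetic_data import SimulatedScene, SimulationConfig, simulate_scene, \
    split_train_test

__all__ = ["EvalReport", "PipelineConfig", "confusion", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """Confusion counts over labeled pixels with derived rates (percent).

    ``fnr``/``fpr`` are ``None`` (reported as not-applicable) when their
    denominator — tumor pixels, respectively normal pixels — is empty.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    fnr: Optional[float] = field(init=False)
    fpr: Optional[float] = field(init=False)
    accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")
        total = self.tp + self.fp + self.tn + self.fn
        if total == 0:
            raise EvaluationError("no labeled pixels to evaluate")
        pos = self.tp + self.fn
        neg = self.fp + self.tn
        self.fnr = 100.0 * self.fn / pos if pos > 0 else None
        self.fpr = 100.0 * self.fp / neg if neg > 0 else None
        self.accuracy = 100.0 * (self.tp + self.tn) / total

    @property
    def n_labeled(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fnr"] = "not-applicable" if self.fnr is None else self.fnr
        d["fpr"] = "not-applicable" if self.fpr is None else self.fpr
        return d


def confusion(pred: Union[LabelMask, DetectionMap, np.ndarray],
              truth: LabelMask) -> EvalReport:
    """Score a predicted tumor mask against ground truth.

    *pred* may be a LabelMask, a DetectionMap (its final mask is used),
    or a binary array.  Only labeled truth pixels enter the counts.
    """
    if isinstance(pred, DetectionMap):
        pred_arr = pred.final_mask
    elif isinstance(pred, LabelMask):
        pred_arr = pred.labels == 1
    else:
        pred_arr = np.asarray(pred).astype(bool)
    if pred_arr.shape != truth.labels.shape:
        raise ConsistencyError(
            f"prediction shape {pred_arr.shape} != truth {truth.labels.shape}"
        )
    labeled = truth.labeled
    if not labeled.any():
        raise EvaluationError("truth mask has no labeled pixels")
    t = truth.labels[labeled] == 1
    p = pred_arr[labeled]
    return EvalReport(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


@dataclass
class PipelineConfig:
    """End-to-end run settings (defaults mirror the reference protocol)."""

    median_window: int = 3
    calibration_guard: float = 1e-9
    train_frac: float = 0.1
    solver: SolverConfig = field(default_factory=SolverConfig)
    normalize_atoms: bool = True
    fill_holes: bool = True
    hole_connectivity: int = 4
    split_seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _config_digest(*configs) -> str:
    def _clean(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj

    payload = json.dumps([_clean(asdict(c)) for c in configs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(
    scene: Union[SimulationConfig, SimulatedScene],
    pipe: Optional[PipelineConfig] = None,
) -> tuple[DetectionMap, EvalReport, dict]:
    """Run the full detection pipeline on a (simulated) scene.

    Stages: simulate/load -> median denoise -> reflectance calibration ->
    per-class train/test split -> dictionary assembly from training
    pixels -> sparse-code classification of every pixel -> hole filling
    -> confusion against ground truth.  Returns the detection map, the
    pooled evaluation over all labeled pixels, and a run manifest
    (seeds, config hash, versions, counts) such that identical inputs
    yield byte-identical manifests; per-stage timings go to the log at
    INFO and are never part of the manifest.
    """
    pipe = pipe or PipelineConfig()
    if isinstance(scene, SimulationConfig):
        sim_cfg: Optional[SimulationConfig] = scene
        scene = simulate_scene(scene)
    else:
        sim_cfg = None

    timings: dict[str, float] = {}

    def _stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except MhsiError as exc:
            raise PipelineError(f"stage {name!r}: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        logger.info("stage %-12s %.3f s", name, timings[name])
        return out

    denoised = _stage("denoise", median_denoise, scene.raw, pipe.median_window)
    refl = _stage("normalize", normalize_reflectance, denoised, scene.refs,
                  pipe.calibration_guard)
    split = _stage("split", split_train_test, scene.truth, pipe.train_frac,
                   pipe.split_seed)
    spectra = refl.data.reshape(-1, refl.n_bands)
    dictionary = _stage(
        "dictionary", build_dictionary,
        spectra[split.train[0]], spectra[split.train[1]],
        pipe.normalize_atoms, refl.wavelengths_nm,
    )
    detection = _stage("classify", classify_cube, refl, dictionary, pipe.solver)
    if pipe.fill_holes:
        detection = _stage("fill_holes", fill_holes, detection,
                           pipe.hole_connectivity)
    report = _stage("evaluate", confusion, detection, scene.truth)

    manifest = {
        "package": "mhsidetect",
        "version": __version__,
        "numpy": np.__version__,
        "sim_seed": None if sim_cfg is None else sim_cfg.seed,
        "split_seed": pipe.split_seed,
        "config_sha256": _config_digest(*( [sim_cfg] if sim_cfg else [] ),
                                        pipe),
        "n_train": {c: int(v.size) for c, v in split.train.items()},
        "n_test": {c: int(v.size) for c, v in split.test.items()},
        "report": report.to_dict(),
    }
    return detection, report, manifest
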