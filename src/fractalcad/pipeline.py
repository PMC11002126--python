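"""End-to-end pipeline: segment -> contour -> FD (both estimators) ->
classify, plus batch evaluation against radiologist annotations.

``run_pipeline`` processes one grayscale slice and returns a result record;
``evaluate_batch`` joins per-nodule FD results with annotation consensus and
computes confusion counts, sensitivity/specificity/accuracy and the
FD-grade Pearson correlation per method.  Both are deterministic: identical
inputs and configuration produce identical result payloads.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .classify import (HIGH, LOW, Thresholds, confusion, consensus_grade,
                       metrics, pearson_correlation, true_class)
from .contour import centroid, extract_contour, radial_function
from .exceptions import (DegenerateSpectrumError, InvalidParameterError,
                         PipelineStageError)
from .fractal import fd_box_counting, fd_power_spectrum
from .segmentation import binarize, compute_histogram, largest_component, \
    yanni_horne_threshold

__all__ = ["PipelineConfig", "run_pipeline", "evaluate_batch", "report_from_counts"]

logger = logging.getLogger("fractalcad")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; validated on construction and
    round-trip serialisable to JSON."""

    roi: tuple[int, int, int, int] | None = None  # (r0, c0, r1, c1), end-exclusive
    include_zero_level: bool = False
    offset_by_gmin: bool = False
    keep_largest_component: bool = True
    centroid_mode: str = "geometric"
    fit_band: tuple[int, int] = (1, 30)
    grid_offsets: int = 0
    box_cutoff: float = 1.214
    spectrum_cutoff: float = 1.137
    tie_break: str = "high"
    seed: int = 0
    window_center: float = -600.0
    window_width: float = 1500.0

    def __post_init__(self):
        Thresholds(self.box_cutoff, self.spectrum_cutoff)  # range check
        if self.centroid_mode not in ("geometric", "mass"):
            raise InvalidParameterError(f"unknown centroid_mode {self.centroid_mode!r}")
        if self.tie_break not in ("high", "low", "mean-round"):
            raise InvalidParameterError(f"unknown tie_break {self.tie_break!r}")
        lo, hi = self.fit_band
        if not (1 <= lo < hi <= 180):
            raise InvalidParameterError("fit_band must satisfy 1 <= lo < hi <= 180")
        if self.grid_offsets < 0:
            raise InvalidParameterError("grid_offsets must be >= 0")
        if self.roi is not None:
            r0, c0, r1, c1 = self.roi
            if not (0 <= r0 < r1 and 0 <= c0 < c1):
                raise InvalidParameterError("roi must be (r0, c0, r1, c1) with r0<r1, c0<c1")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("roi") is not None:
            d["roi"] = tuple(d["roi"])
        if "fit_band" in d:
            d["fit_band"] = tuple(d["fit_band"])
        return cls(**d)


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(image, config: PipelineConfig | None = None,
                 out_dir=None, nodule_id: str = "nodule") -> dict:
    """Run the full analysis on one grayscale slice.

    ``image`` may be a path (PNG/TIFF/DICOM) or an 8-bit 2-D array already
    in memory.  Returns a JSON-serialisable record with the threshold
    diagnostics, both FD estimates with their fits, the two-class calls and
    all stage warnings; optionally writes mask/contour/radial/record
    artifacts under ``out_dir``.  Stage failures raise
    :class:`PipelineStageError` naming the stage, with partial artifacts
    attached.
    """
    config = config or PipelineConfig()
    record: dict = {"nodule_id": nodule_id, "config": json.loads(config.to_json()),
                    "warnings": []}
    stage = "load"
    try:
        if isinstance(image, (str, Path)):
            record["input_path"] = str(image)
            img = _io.load_gray_image(image, config.window_center, config.window_width)
        else:
            img = np.asarray(image)
        if config.roi is not None:
            r0, c0, r1, c1 = config.roi
            img = img[r0:r1, c0:c1]
        record["input_sha256"] = _sha256(img)
        record["shape"] = list(img.shape)
        logger.info("loaded %s: shape=%s hash=%s", nodule_id, img.shape,
                    record["input_sha256"])

        stage = "segmentation"
        t = yanni_horne_threshold(compute_histogram(img),
                                  include_zero_level=config.include_zero_level,
                                  offset_by_gmin=config.offset_by_gmin)
        mask = binarize(img, t)
        if config.keep_largest_component:
            mask = largest_component(mask)
        record["threshold"] = t.to_dict()
        logger.info("segmented %s: threshold=%.3f fg=%d", nodule_id,
                    t.threshold, int(mask.sum()))

        stage = "contour"
        cont = extract_contour(mask)
        center = centroid(cont, mode=config.centroid_mode)
        radial = radial_function(cont, center)
        record["centroid"] = list(center)
        record["coordinate_convention"] = "1-based at interface"
        record["n_contour_points"] = int(len(cont.points))
        record["warnings"] += list(radial.warnings)

        stage = "fractal"
        fd_box = fd_box_counting(cont.edge_mask, grid_offsets=config.grid_offsets)
        try:
            fd_spec = fd_power_spectrum(radial, fit_band=config.fit_band)
        except DegenerateSpectrumError:
            fd_spec = None
            record["warnings"].append("degenerate spectrum: smooth-shape fallback fd=1")
        record["fd_box"] = fd_box.to_dict()
        record["fd_spectrum"] = (fd_spec.to_dict() if fd_spec is not None else
                                 {"method": "power_spectrum", "fd": 1.0,
                                  "fd_clamped": 1.0, "fallback": True})
        record["warnings"] += list(fd_box.warnings)
        if fd_spec is not None:
            record["warnings"] += list(fd_spec.warnings)

        stage = "classify"
        thr = Thresholds(config.box_cutoff, config.spectrum_cutoff)
        fd_b = fd_box.fd_clamped
        fd_s = fd_spec.fd_clamped if fd_spec is not None else 1.0
        record["pred_box"] = HIGH if fd_b > thr.box_cutoff else LOW
        record["pred_spectrum"] = HIGH if fd_s > thr.spectrum_cutoff else LOW
        logger.info("classified %s: fd_box=%.4f (%s) fd_spectrum=%.4f (%s)",
                    nodule_id, fd_b, record["pred_box"], fd_s,
                    record["pred_spectrum"])
    except Exception as e:
        raise PipelineStageError(stage, e, partial=record) from e

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _io.save_gray_image(out / f"{nodule_id}_mask.png", mask)
        _io.save_gray_image(out / f"{nodule_id}_contour.png", cont.edge_mask)
        pd.DataFrame(cont.points, columns=["row", "col"]).to_csv(
            out / f"{nodule_id}_contour.csv", index=False)
        pd.DataFrame({"degree": np.arange(360),
                      "magnitude": radial.magnitudes}).to_csv(
            out / f"{nodule_id}_radial.csv", index=False)
        (out / f"{nodule_id}_result.json").write_text(
            json.dumps(record, indent=2, sort_keys=True))
    return record


def report_from_counts(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Metric table from raw confusion counts (counts-only evaluation)."""
    from .classify import ConfusionCounts
    rep = metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
    return rep.to_dict()


def evaluate_batch(results, annotations, config: PipelineConfig | None = None):
    """Join per-nodule FD results with annotations and evaluate per method.

    ``results`` / ``annotations`` are DataFrames or CSV paths; results need
    columns ``nodule_id, fd_box, fd_spectrum``, annotations ``nodule_id,
    rater1..rater4`` (blank = absent).  Returns ``(reports, rejects)`` where
    ``reports`` maps method name -> report dict and ``rejects`` lists
    nodule_ids present on only one side.
    """
    config = config or PipelineConfig()
    res = results if isinstance(results, pd.DataFrame) else pd.read_csv(results)
    ann = annotations if isinstance(annotations, pd.DataFrame) else pd.read_csv(annotations)
    res["nodule_id"] = res["nodule_id"].astype(str)
    ann["nodule_id"] = ann["nodule_id"].astype(str)
    merged = res.merge(ann, on="nodule_id", how="inner")
    rejects = sorted(set(res["nodule_id"]).symmetric_difference(ann["nodule_id"]))
    if len(merged) == 0:
        raise InvalidParameterError("no nodule_id matches between results and annotations")

    rater_cols = [c for c in ann.columns if c.startswith("rater")]
    grades, truths = [], []
    for _, row in merged.iterrows():
        votes = [int(row[c]) for c in rater_cols if pd.notna(row[c])]
        g = consensus_grade(votes, tie_break=config.tie_break)
        grades.append(g)
        truths.append(true_class(g))

    thr = Thresholds(config.box_cutoff, config.spectrum_cutoff)
    reports = {}
    for method, col in (("box_counting", "fd_box"), ("power_spectrum", "fd_spectrum")):
        fds = merged[col].astype(float).to_numpy()
        preds = [HIGH if fd > thr.for_method(method) else LOW for fd in fds]
        c = confusion(preds, truths)
        try:
            r = pearson_correlation(fds, grades)
        except Exception:
            r = None
        reports[method] = metrics(c, pearson_r=r).to_dict()
    return reports, rejects
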