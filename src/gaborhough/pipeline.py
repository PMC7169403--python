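"""End-to-end marking pipeline and the human-readable report string.

Stage order: Gabor-filter ROI localization -> edge extraction -> anisotropic
GHT over the pose grid -> ranking of the ten best recognition positions ->
deformation of the lateral band at the best pose -> optional SVM confidence.
If ROI extraction fails the pipeline degrades to a full-image search and
flags the result.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import gabor, ght
from .config import PipelineConfig
from .confidence import MarkingConfidenceSVC, featurize, score_confidence
from .template import GuidedTemplate, canonical_lv_template, deform_band

__all__ = [
    "MarkingResult",
    "PipelineError",
    "UnreadableImageError",
    "NoEdgesError",
    "NoDetectionsError",
    "run_pipeline",
    "format_report",
    "default_template_for_image",
]

logger = logging.getLogger("gaborhough")

REPORT_FORMAT = (
    "The best matching was found for scale %.6f and angle %.3f "
    "in position (%d, %d) with rate %d"
)


class PipelineError(RuntimeError):
    """Base class for pipeline failures; ``exit_code`` identifies the stage."""

    exit_code = 1


class UnreadableImageError(PipelineError):
    exit_code = 2


class NoEdgesError(PipelineError):
    exit_code = 3


class NoDetectionsError(PipelineError):
    exit_code = 4


def format_report(d: ght.Detection) -> str:
    """Render a detection as the standard one-line matching report.

    When the two scales coincide a single scale is printed; otherwise both
    are appended explicitly.
    """
    sx, sy = d.pose.scales
    x, y = d.pose.position
    text = REPORT_FORMAT % (sx, d.pose.rotation, int(x), int(y), d.rate)
    if not d.pose.isotropic:
        text += " (scales %.6f, %.6f)" % (sx, sy)
    return text


@dataclass
class MarkingResult:
    """Everything the pipeline produces for one image."""

    detections: list[ght.Detection]
    chosen: int
    lateral_polyline: np.ndarray
    confidence: float | None
    roi_bbox: tuple[int, int, int, int]
    roi_fallback: bool
    report: str

    @property
    def best(self) -> ght.Detection:
        return self.detections[self.chosen]

    def to_dict(self) -> dict:
        return {
            "detections": [d.to_dict() for d in self.detections],
            "chosen": self.chosen,
            "lateral_polyline": np.asarray(self.lateral_polyline).tolist(),
            "confidence": self.confidence,
            "roi_bbox": list(self.roi_bbox),
            "roi_fallback": self.roi_fallback,
            "report": self.report,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def default_template_for_image(shape: tuple[int, int]) -> GuidedTemplate:
    """Canonical LV template scaled to an image: cavity just below center."""
    h, w = shape
    return canonical_lv_template(
        cavity_center=(0.5 * w, 0.51 * h),
        cavity_axes=(0.16 * w, 0.21 * h),
    )


def load_image(path) -> np.ndarray:
    import imageio.v3 as iio

    try:
        img = iio.imread(path)
    except Exception as exc:
        raise UnreadableImageError(f"cannot read image: {path}") from exc
    img = np.asarray(img)
    if img.ndim == 3:  # collapse RGB(A) to grayscale
        img = img[..., :3].mean(axis=-1)
    return img.astype(float)


def run_pipeline(
    image,
    cfg: PipelineConfig | None = None,
    template: GuidedTemplate | None = None,
    return_accumulator: bool = False,
):
    """Run the full marking pipeline on an image or image path.

    Returns a :class:`MarkingResult` (and the :class:`~gaborhough.ght.Accumulator`
    if ``return_accumulator``).  Deterministic for fixed inputs and config.
    """
    cfg = cfg or PipelineConfig()
    if isinstance(image, (str, bytes)) or hasattr(image, "__fspath__"):
        img = load_image(image)
    else:
        img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise UnreadableImageError("expected a non-empty 2-D grayscale image")
    h, w = img.shape

    if template is None:
        if cfg.template_path:
            template = GuidedTemplate.load(cfg.template_path)
        else:
            template = default_template_for_image(img.shape)

    t0 = time.perf_counter()
    bank = gabor.quadrature_bank(
        orientations=tuple(cfg.gabor.orientations),
        wavelengths=tuple(cfg.gabor.wavelengths),
        gamma=cfg.gabor.gamma,
        bandwidth=cfg.gabor.bandwidth,
    )
    roi = None
    roi_fallback = False
    try:
        response = gabor.filter_bank_response(img, bank)
        roi = gabor.extract_roi(
            response, margin=cfg.roi.margin, closing_radius=cfg.roi.closing_radius
        )
        bbox = roi.bbox
    except gabor.NoRoiError:
        logger.warning("stage=roi no region of interest found; using full image")
        roi_fallback = True
        bbox = (0, 0, w, h)
    logger.info(
        "stage=roi bbox=%s fallback=%s elapsed=%.3fs",
        bbox, roi_fallback, time.perf_counter() - t0,
    )

    t0 = time.perf_counter()
    edges = ght.detect_edges(img, roi=roi, percentile=cfg.ght.edge_percentile)
    if len(edges) == 0:
        raise NoEdgesError("no edge points above threshold")
    logger.info(
        "stage=edges n=%d percentile=%.1f elapsed=%.3fs",
        len(edges), cfg.ght.edge_percentile, time.perf_counter() - t0,
    )

    t0 = time.perf_counter()
    rtable = ght.build_rtable(template.full_template(), n_bins=cfg.ght.n_bins)
    grid = ght.SearchGrid.from_ranges(
        bbox=bbox,
        sx=tuple(cfg.ght.sx),
        sy=tuple(cfg.ght.sy) if cfg.ght.sy else None,
        theta=tuple(cfg.ght.theta),
    )
    acc = ght.accumulate(edges, rtable, grid)
    detections = ght.top_candidates(
        acc, k=cfg.ght.k, suppression_radius=cfg.ght.suppression_radius
    )
    if not detections:
        raise NoDetectionsError("accumulator is empty; no candidate poses")
    logger.info(
        "stage=ght cells=%d best_rate=%d elapsed=%.3fs",
        grid.n_pose_cells, detections[0].rate, time.perf_counter() - t0,
    )

    t0 = time.perf_counter()
    best = detections[0]
    lateral = deform_band(img, template, best.pose, beta=cfg.band.beta)
    logger.info("stage=band n=%d elapsed=%.3fs", len(lateral), time.perf_counter() - t0)

    conf = None
    if cfg.confidence_model_path:
        model = MarkingConfidenceSVC.load(cfg.confidence_model_path)
        conf = score_confidence(model, featurize(acc, cfg.ght.suppression_radius))
        logger.info("stage=confidence value=%.3f", conf)

    result = MarkingResult(
        detections=detections,
        chosen=0,
        lateral_polyline=lateral,
        confidence=conf,
        roi_bbox=bbox,
        roi_fallback=roi_fallback,
        report=format_report(best),
    )
    if return_accumulator:
        return result, acc
    return result
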