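"""Seeded synthetic benches for evaluating the pipeline.

These benches stand in for a clinical image set: each draws a batch of
phantoms with randomized pose and image quality, runs the marking pipeline,
and collects accumulator-space features together with a geometric
correctness label (mean boundary error of the final marking <= 3 px).

Two accumulators are featurized per phantom: the *full* one, computed from
the whole image without any region-of-interest restriction, and the
*restricted* one, computed inside the Gabor ROI.  Comparing SVM accuracy on
the two feature sources probes whether the ROI restriction makes the
accumulator space more informative about marking quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import gabor, ght
from .config import PipelineConfig
from .confidence import MarkingConfidenceSVC, featurize
from .phantom import PhantomSpec, boundary_error, generate_phantom, identity_pose, phantom_template
from .template import apply_pose, deform_band

__all__ = ["BenchResult", "small_phantom_spec", "confidence_bench"]

CORRECT_MARKING_TOLERANCE_PX = 3.0


def small_phantom_spec(**overrides) -> PhantomSpec:
    """The 128x128 phantom geometry used by the benches."""
    base = dict(
        image_size=(128, 128),
        sector_apex=(64.0, 4.0),
        sector_angle=1.4,
        cavity_center=(64.0, 65.0),
        cavity_axes=(20.0, 28.0),
        wall_thickness=7.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@dataclass
class BenchResult:
    """Features and labels collected over one bench of phantoms."""

    features_full: np.ndarray  # (n, n_features)
    features_restricted: np.ndarray
    labels: np.ndarray  # (n,) 1 = marking within tolerance
    errors: np.ndarray  # (n,) mean boundary error of each marking, px

    def has_both_classes(self, min_per_class: int = 2) -> bool:
        return (
            (self.labels == 0).sum() >= min_per_class
            and (self.labels == 1).sum() >= min_per_class
        )

    def loocv_accuracies(self, seed: int = 0) -> tuple[float, float]:
        """(full-space, restricted-space) leave-one-out accuracies."""
        model = MarkingConfidenceSVC(seed=seed)
        return (
            model.loocv_accuracy(self.features_full, self.labels),
            model.loocv_accuracy(self.features_restricted, self.labels),
        )


def confidence_bench(
    seed: int,
    n: int = 48,
    cfg: PipelineConfig | None = None,
    speckle_range: tuple[float, float] = (0.1, 0.6),
    attenuation_range: tuple[float, float] = (0.0, 0.7),
    n_distractors: int = 2,
) -> BenchResult:
    """Run one seeded bench of ``n`` phantoms of mixed image quality.

    Poses are drawn continuously (not snapped to the search grid); speckle
    level and lateral-wall attenuation vary per phantom; bright distractor
    arcs emulate off-target anatomy.  The marking and its label come from
    the ROI-restricted pipeline; the full-image accumulator is computed for
    the same image so both feature sources describe identical data.
    """
    rng = np.random.default_rng(seed)
    cfg = cfg or PipelineConfig()
    base_spec = small_phantom_spec()
    base = identity_pose(base_spec)
    tpl = phantom_template(base_spec)
    rt = ght.build_rtable(tpl.full_template(), cfg.ght.n_bins)
    bank = gabor.quadrature_bank(
        orientations=tuple(cfg.gabor.orientations),
        wavelengths=tuple(cfg.gabor.wavelengths),
        gamma=cfg.gabor.gamma,
        bandwidth=cfg.gabor.bandwidth,
    )

    feats_f, feats_r, labels, errors = [], [], [], []
    for _ in range(n):
        pose = ght.PoseParameters(
            position=(
                float(base.position[0] + rng.uniform(-6, 6)),
                float(base.position[1] + rng.uniform(-6, 6)),
            ),
            scales=(float(rng.uniform(0.9, 1.1)), float(rng.uniform(0.9, 1.1))),
            rotation=float(rng.uniform(-0.2, 0.2)),
        )
        spec = small_phantom_spec(
            pose=pose,
            speckle_scale=float(rng.uniform(*speckle_range)),
            lateral_attenuation=float(rng.uniform(*attenuation_range)),
            n_distractors=n_distractors,
            seed=int(rng.integers(2 ** 31)),
        )
        img, gt = generate_phantom(spec)
        h, w = img.shape

        try:
            roi = gabor.extract_roi(
                gabor.filter_bank_response(img, bank),
                margin=cfg.roi.margin,
                closing_radius=cfg.roi.closing_radius,
            )
            bbox = roi.bbox
        except gabor.NoRoiError:
            roi, bbox = None, (0, 0, w, h)

        edges_r = ght.detect_edges(img, roi=roi, percentile=cfg.ght.edge_percentile)
        acc_r = ght.accumulate(
            edges_r, rt, ght.SearchGrid.from_ranges(bbox=bbox)
        )
        edges_f = ght.detect_edges(img, roi=None, percentile=cfg.ght.edge_percentile)
        acc_f = ght.accumulate(
            edges_f, rt, ght.SearchGrid.from_ranges(bbox=(0, 0, w, h))
        )

        best = ght.top_candidates(
            acc_r, k=1, suppression_radius=cfg.ght.suppression_radius
        )[0]
        lateral = deform_band(img, tpl, best.pose, beta=cfg.band.beta)
        septal = apply_pose(tpl.septal.points, tpl.reference, best.pose)
        err, _ = boundary_error(np.vstack([septal, lateral]), gt.boundary)

        labels.append(int(err <= CORRECT_MARKING_TOLERANCE_PX))
        errors.append(err)
        feats_f.append(featurize(acc_f, cfg.ght.suppression_radius))
        feats_r.append(featurize(acc_r, cfg.ght.suppression_radius))

    return BenchResult(
        features_full=np.array(feats_f),
        features_restricted=np.array(feats_r),
        labels=np.array(labels),
        errors=np.array(errors),
    )
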