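# gaborhough

Automatic marking of the left-ventricle (LV) endocardial border on 2-D
grayscale echocardiography-like images.

Tracing the inner boundary of the LV wall is the prerequisite for volume
and ejection-fraction estimation, and it is unreliable exactly where it
matters most: patients with a poor acoustic window, whose images are
low-contrast and artifact-laden. `gaborhough` implements a fast,
fully-automatic delineation pipeline intended as a decision-support step
between acquisition and the clinician:

1. **ROI localization** — a small Gabor filter bank (sinusoids under a
   Gaussian envelope; envelope width coupled to wavelength via the
   half-response bandwidth `b`, with `σ = 0.56 λ` at `b = 1`) highlights the
   textured myocardial wall; the largest connected component of the
   thresholded response bounds the search region.
2. **Anisotropic generalized Hough transform (GHT)** — every edge point
   votes, through an R-table of orientation-binned displacements, for
   candidate poses `a = (y, S, θ)` with independent scales `S = (Sx, Sy)`.
   The accumulator's maxima are the detections; the vote count at a
   maximum is the detection's *rate*. The ten best candidates are ranked.
3. **Guided deformable template** — a thin septal limb (the well-visualized
   wall) fixes the pose; the poorly-visualized lateral wall is refined
   inside a thick band by a dynamic program that trades gradient evidence
   against contour smoothness.
4. **Confidence score** — an SVM with a cubic kernel and an automatic
   kernel scale, trained on accumulator-space summary statistics, reports
   how much to trust the marking (0.5 = decision boundary).

Since clinical images are not distributable, the package ships a seeded
phantom generator (scan sector, elliptical cavity, bright wall with
attenuated lateral side, multiplicative speckle, optional chamber-like
distractors) with exact ground truth, used by the whole test suite.

## Worked example

```python
import numpy as np
import gaborhough as gh
from gaborhough.pipeline import run_pipeline

# a 256x256 phantom with speckle, at a known pose
spec = gh.PhantomSpec(
    speckle_scale=0.3, seed=7,
    pose=gh.PoseParameters(position=(132.0, 151.0),
                           scales=(0.95, 1.05), rotation=np.pi / 36),
)
img, truth = gh.generate_phantom(spec)

result = run_pipeline(img, template=gh.phantom_template(spec))
print(result.report)

mean_err, hausdorff = gh.boundary_error(result.lateral_polyline,
                                        truth.lateral_polyline)
print("lateral mean err %.2f px, hausdorff %.2f px" % (mean_err, hausdorff))
```

prints

```
The best matching was found for scale 0.950000 and angle 0.087 in position (132, 152) with rate 22 (scales 0.950000, 1.000000)
lateral mean err 0.52 px, hausdorff 5.16 px
```

The report line gives the best pose found on the search grid: here the
position is recovered to 1 px, the rotation to the grid step, and `Sx`
exactly; `Sy` lands one grid step low — the band deformation absorbs the
residual, leaving the final lateral border half a pixel from ground truth
on average. The rate (22) is the integer number of accumulator votes
behind the detection.

The same pipeline is scriptable from the shell:

```
gaborhough phantom --size 256 256 --seed 7 --speckle 0.3 --out img.png --truth truth.json
gaborhough mark img.png --out result.json --overlay overlay.png
gaborhough report --scale 0.885 0.885 --angle 1.047 --position 98 101 --rate 67
```

Subcommands: `phantom`, `roi`, `detect`, `mark`, `confidence train|score`,
`report`. All parameters live in a flat-dotted YAML config
(`--config`), e.g. `ght.edge_percentile: 60`.

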