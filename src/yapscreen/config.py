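"""Analysis constants and configuration containers.

All pixel-geometry constants refer to 20x spinning-disk images at
0.64 micrometres per pixel; areas throughout the package are in px^2
and intensities in camera counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

#: Physical pixel size of the screen images (micrometres per pixel at 20x).
PIXEL_SIZE_UM: float = 0.64

#: Perinuclear ring band: pixels whose Chebyshev distance from the (eroded)
#: nucleus border lies in [RING_INNER_PX, RING_OUTER_PX].
RING_INNER_PX: int = 2
RING_OUTER_PX: int = 7

#: Cytoplasm pixels dimmer than this fraction of the mean cytoplasm intensity
#: are classified as protrusive (outside the cell core).
PROTRUSION_INTENSITY_FRAC: float = 0.75

#: Cells whose nucleus centroid lies within this many pixels of the image
#: border are flagged and excluded from model fitting (required for LCD).
BORDER_EXCLUSION_PX: int = 30

#: Local cell density is LCD_SCALE / (clipped Voronoi area in px^2); the scale
#: puts confluent monolayer values in the tens, so thresholds such as
#: "LCD < 50" are usable.
LCD_SCALE: float = 1.0e5

#: Ring-region mean intensity used when back-deriving synthetic intensities
#: from a target log10 nuclear/ring ratio. Arbitrary: only ratios matter.
RING_BASE_INTENSITY: float = 1000.0

#: Canonical feature order of the six-feature shape model.
MLR6_FEATURES: tuple[str, ...] = ("cellA", "nucA", "NF", "LCD", "proA", "proX")

#: Four-feature variant without the protrusion features.
MLR4_FEATURES: tuple[str, ...] = ("cellA", "nucA", "NF", "LCD")


@dataclass
class SegmentationParams:
    """Tunable knobs of the segmentation operators.

    smooth_sigma_* are Gaussian sigmas (px) applied before thresholding or
    watershed; min_nucleus_area drops debris after the 1-px erosion.
    """

    smooth_sigma_nuclei: float = 2.0
    smooth_sigma_cells: float = 2.0
    min_nucleus_area: int = 40
    min_seed_distance: int = 8
    foreground_quantile: float = 0.5  # fallback when Otsu degenerates
    protrusion_frac: float = PROTRUSION_INTENSITY_FRAC
    ring_inner: int = RING_INNER_PX
    ring_outer: int = RING_OUTER_PX

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SegmentationParams":
        return cls(**json.loads(text))


#: Default QC thresholds. The screen tuned these per plate and never published
#: them; these are stated package defaults sized for the synthetic monolayers
#: (areas in px^2, intensities in counts). +/-inf disables a rule.
DEFAULT_QC_THRESHOLDS: dict[str, float] = {
    "nucA_min": 250.0,          # condensed (mitotic/pyknotic) nuclei
    "nucA_max": 2500.0,         # missegmented nucleus clumps
    "cellA_min": 400.0,
    "cellA_max": 30000.0,
    "ring_intensity_min": 50.0,  # dead/empty ring region
    "nuc_intensity_min": 50.0,
    "percent_protrusion_max": 0.9,
    "anuc_over_acell_max": 0.95,
}
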