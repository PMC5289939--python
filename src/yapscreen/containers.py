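"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PIXEL_SIZE_UM


@dataclass
class FieldImage:
    """One imaged field: three co-registered channels plus pixel size.

    Channels are 2D non-negative float arrays of identical shape:
    ``dna`` (Hoechst), ``actin`` (F-actin) and ``yap``.
    """

    dna: np.ndarray
    actin: np.ndarray
    yap: np.ndarray
    pixel_size_um: float = PIXEL_SIZE_UM
    well_id: str = ""
    field_id: str = ""

    def __post_init__(self):
        shapes = {self.dna.shape, self.actin.shape, self.yap.shape}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name in ("dna", "actin", "yap"):
            ch = getattr(self, name)
            if not np.all(np.isfinite(ch)) or np.any(ch < 0):
                raise ValueError(f"channel {name!r} has non-finite or negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dna.shape


@dataclass
class LabelMaps:
    """Integer label images from segmentation (or synthetic ground truth).

    Label ``k`` refers to the same cell in every map; maps other than
    ``nuclei``/``cells`` may be None until the corresponding operator runs.
    """

    nuclei: np.ndarray
    cells: np.ndarray
    rings: np.ndarray | None = None
    cores: np.ndarray | None = None
    protrusions: np.ndarray | None = None
    empty_ring_labels: frozenset[int] = field(default_factory=frozenset)
    flagged_outside_foreground: frozenset[int] = field(default_factory=frozenset)

    def labels(self) -> np.ndarray:
        out = np.unique(self.nuclei)
        return out[out > 0]
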