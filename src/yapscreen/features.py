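"""Per-cell intensity, shape and context features, QC flags, and the
live-imaging double normalization.

Core quantities:

* ``yap_ratio`` — log10(mean nuclear YAP / mean perinuclear-ring YAP), the
  nuclear-translocation readout. The log makes enrichment and depletion
  symmetric around zero.
* ``NF`` (neighbour fraction) — fraction of a cell's border pixels in
  contact with another cell.
* ``LCD`` (local cell density) — inverse free Voronoi area around each
  nucleus centroid, scaled by a configurable constant; cells whose
  centroid sits within 30 px of the image border are flagged and excluded
  from model fitting because their Voronoi cell is frame-truncated.
* protrusion area/extent, areas, total YAP, and the nuclear/cell area
  ratio.

QC flags mark mitotic, dead-or-missegmented, border and empty-ring cells;
records are never deleted, only flagged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import Voronoi, cKDTree

from .config import BORDER_EXCLUSION_PX, DEFAULT_QC_THRESHOLDS, LCD_SCALE
from .containers import FieldImage, LabelMaps

__all__ = [
    "yap_ratio",
    "neighbor_fraction",
    "local_cell_density",
    "extract_features",
    "qc_filter",
    "gfp_live_normalize",
    "UndefinedRatioError",
    "FEATURE_TABLE_COLUMNS",
]

#: Fixed column order of the exported per-cell feature table.
FEATURE_TABLE_COLUMNS = [
    "cell_id", "well_id", "field_id", "cellA", "nucA", "NF", "LCD",
    "proA", "proX", "anuc_over_acell", "yap_nuc_mean", "yap_ring_mean",
    "yap_ratio", "yap_total", "qc_flags",
]


class UndefinedRatioError(ValueError):
    """Nuclear or ring mean intensity was non-positive."""

    def __init__(self, cell_id=None):
        self.cell_id = cell_id
        suffix = f" (cell {cell_id})" if cell_id is not None else ""
        super().__init__(f"yap_ratio undefined for non-positive mean intensity{suffix}")


def yap_ratio(nuc_mean, ring_mean, cell_id=None):
    """log10 of nuclear over ring mean intensity; antisymmetric under swap."""
    nuc = np.asarray(nuc_mean, dtype=float)
    ring = np.asarray(ring_mean, dtype=float)
    if np.any(nuc <= 0) or np.any(ring <= 0):
        raise UndefinedRatioError(cell_id)
    out = np.log10(nuc / ring)
    return float(out) if out.ndim == 0 else out


def neighbor_fraction(cells: np.ndarray) -> pd.Series:
    """Fraction of each cell's border pixels touching another cell.

    A border pixel of cell k has a 4-neighbour with a different value
    (background, a different label, or out of frame); it counts as contact
    when at least one such neighbour is a different nonzero label.
    """
    cells = np.asarray(cells)
    padded = np.pad(cells, 1, constant_values=0)
    neighbors = [
        padded[:-2, 1:-1], padded[2:, 1:-1], padded[1:-1, :-2], padded[1:-1, 2:]
    ]
    fg = cells > 0
    is_border = np.zeros_like(fg)
    touches_other = np.zeros_like(fg)
    for nb in neighbors:
        diff = nb != cells
        is_border |= fg & diff
        touches_other |= fg & diff & (nb > 0)
    labels = np.unique(cells)
    labels = labels[labels > 0]
    if labels.size == 0:
        return pd.Series(dtype=float, name="NF")
    border_counts = ndi.sum(is_border, cells, index=labels)
    contact_counts = ndi.sum(touches_other, cells, index=labels)
    with np.errstate(invalid="ignore"):
        nf = np.where(border_counts > 0, contact_counts / border_counts, 0.0)
    return pd.Series(nf, index=labels, name="NF")


def _voronoi_areas_mirror(points: np.ndarray, frame: tuple[int, int]) -> np.ndarray:
    """Exact Voronoi areas clipped to the frame via boundary reflection.

    Reflecting every seed across the four frame edges bounds each original
    region by the frame rectangle exactly, so the polygon areas are the
    clipped Voronoi areas.
    """
    H, W = frame
    n = len(points)
    refl = [
        points,
        points * [-1, 1],                # across r = 0
        (2 * H - points[:, 0:1]) * [1, 0] + points * [0, 1],  # across r = H
        points * [1, -1],                # across c = 0
        points * [1, 0] + (2 * W - points[:, 1:2]) * [0, 1],  # across c = W
    ]
    allpts = np.vstack(refl)
    vor = Voronoi(allpts)
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        poly = vor.vertices[region]
        x, y = poly[:, 0], poly[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
    return areas


def _voronoi_areas_pixel(points: np.ndarray, frame: tuple[int, int]) -> np.ndarray:
    """Fallback: nearest-seed pixel counting (robust to degeneracies)."""
    H, W = frame
    rr, cc = np.mgrid[0:H, 0:W]
    grid = np.column_stack([rr.ravel() + 0.5, cc.ravel() + 0.5]).astype(float)
    _, idx = cKDTree(points).query(grid)
    return np.bincount(idx, minlength=len(points)).astype(float)


def local_cell_density(
    nucleus_centroids: np.ndarray,
    frame: tuple[int, int],
    scale: float = LCD_SCALE,
    border_px: int = BORDER_EXCLUSION_PX,
) -> pd.DataFrame:
    """LCD = scale / (Voronoi area clipped to the frame), plus border flags.

    LCD scales as 1/area: doubling uniform crowding doubles the mean LCD.
    A single centroid owns the whole frame. Centroids within ``border_px``
    of the frame edge get ``border=True`` (their free area is truncated by
    the frame and unreliable).
    """
    pts = np.atleast_2d(np.asarray(nucleus_centroids, dtype=float))
    if pts.shape[0] < 1:
        raise ValueError("need at least one centroid")
    H, W = frame
    if pts.shape[0] == 1:
        areas = np.array([float(H * W)])
    else:
        try:
            areas = _voronoi_areas_mirror(pts, frame)
        except Exception:  # qhull degeneracies (duplicates, precision)
            areas = _voronoi_areas_pixel(pts, frame)
    lcd = scale / np.maximum(areas, 1e-9)
    r, c = pts[:, 0], pts[:, 1]
    border = (r < border_px) | (r >= H - border_px) | (c < border_px) | (c >= W - border_px)
    return pd.DataFrame({"LCD": lcd, "voronoi_area": areas, "border": border})


def extract_features(
    label_maps: LabelMaps, image: FieldImage, lcd_scale: float = LCD_SCALE
) -> pd.DataFrame:
    """Join all segmentation outputs into one feature table.

    One row per cell label. Cells with an empty ring get the
    ``empty_ring`` flag and no ``yap_ratio``; centroids near the frame
    border get ``border``. Mismatched nucleus/cell label sets raise.
    """
    nuclei, cells = label_maps.nuclei, label_maps.cells
    nuc_ids = np.unique(nuclei)
    nuc_ids = nuc_ids[nuc_ids > 0]
    cell_ids = np.unique(cells)
    cell_ids = cell_ids[cell_ids > 0]
    if set(nuc_ids) != set(cell_ids):
        raise ValueError(
            "nucleus and cell label sets differ: "
            f"{sorted(set(nuc_ids) ^ set(cell_ids))}"
        )
    if len(nuc_ids) == 0:
        return pd.DataFrame(columns=FEATURE_TABLE_COLUMNS)
    if label_maps.rings is None or label_maps.protrusions is None:
        raise ValueError("label maps missing rings/protrusions; run segment_field")

    idx = nuc_ids
    yap = image.yap.astype(float)
    nucA = ndi.sum(np.ones_like(nuclei), nuclei, index=idx)
    cellA = ndi.sum(np.ones_like(cells), cells, index=idx)
    nuc_mean = np.asarray(ndi.mean(yap, nuclei, index=idx), dtype=float)
    yap_total = ndi.sum(yap, cells, index=idx)
    proA = ndi.sum(np.ones_like(cells), label_maps.protrusions, index=idx)

    ring_mean = np.full(len(idx), np.nan)
    have_ring = np.array([k not in label_maps.empty_ring_labels for k in idx])
    ring_ids = idx[have_ring]
    if ring_ids.size:
        ring_mean[have_ring] = ndi.mean(yap, label_maps.rings, index=ring_ids)

    nf = neighbor_fraction(cells).reindex(idx).to_numpy()
    centroids = np.array(ndi.center_of_mass(nuclei > 0, nuclei, index=idx))
    lcd_tbl = local_cell_density(centroids, image.shape, scale=lcd_scale)

    # protrusion extent from the core/protrusion decomposition
    from .segmentation import detect_protrusions

    _, _, pro_tbl = detect_protrusions(cells, nuclei, yap)
    pro_tbl = pro_tbl.set_index("label").reindex(idx)

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(
            (nuc_mean > 0) & (ring_mean > 0), np.log10(nuc_mean / ring_mean), np.nan
        )

    flags = []
    for i, k in enumerate(idx):
        f = []
        if not have_ring[i] or not np.isfinite(ratio[i]):
            f.append("empty_ring")
        if lcd_tbl["border"].iloc[i]:
            f.append("border")
        flags.append(";".join(f))

    table = pd.DataFrame(
        {
            "cell_id": [f"{image.well_id}:{image.field_id}:{int(k)}" for k in idx],
            "well_id": image.well_id,
            "field_id": image.field_id,
            "cellA": cellA,
            "nucA": nucA,
            "NF": nf,
            "LCD": lcd_tbl["LCD"].to_numpy(),
            "proA": pro_tbl["proA"].to_numpy(dtype=float),
            "proX": pro_tbl["proX"].to_numpy(dtype=float),
            "anuc_over_acell": nucA / cellA,
            "yap_nuc_mean": nuc_mean,
            "yap_ring_mean": ring_mean,
            "yap_ratio": ratio,
            "yap_total": yap_total,
            "qc_flags": flags,
        }
    )
    assert int(proA.sum()) == int(table["proA"].sum())
    return table.reset_index(drop=True)


class ConfigurationError(KeyError):
    pass


def qc_filter(records: pd.DataFrame, thresholds: dict[str, float] | None = None) -> pd.DataFrame:
    """Assign QC flags; never drops rows.

    ``mitotic`` marks condensed (small) nuclei; ``dead_or_missegmented``
    marks cells failing intensity, area, protrusion-share or area-ratio
    rules. Flags append to any existing ``border``/``empty_ring`` tokens.
    Every threshold key must be present; set a rule to +/-inf to disable.
    """
    thr = DEFAULT_QC_THRESHOLDS if thresholds is None else thresholds
    for key in DEFAULT_QC_THRESHOLDS:
        if key not in thr:
            raise ConfigurationError(f"missing QC threshold key: {key!r}")
    out = records.copy()
    mitotic = out["nucA"] < thr["nucA_min"]
    pct_pro = out["proA"] / out["cellA"]
    dead = (
        (out["nucA"] > thr["nucA_max"])
        | (out["cellA"] < thr["cellA_min"])
        | (out["cellA"] > thr["cellA_max"])
        | (out["yap_ring_mean"].fillna(np.inf) < thr["ring_intensity_min"])
        | (out["yap_nuc_mean"] < thr["nuc_intensity_min"])
        | (pct_pro > thr["percent_protrusion_max"])
        | (out["anuc_over_acell"] > thr["anuc_over_acell_max"])
    )
    existing = out.get("qc_flags", pd.Series("", index=out.index)).fillna("")
    new_flags = []
    for old, m, d in zip(existing, mitotic, dead):
        toks = [t for t in str(old).split(";") if t]
        if m and "mitotic" not in toks:
            toks.append("mitotic")
        if d and "dead_or_missegmented" not in toks:
            toks.append("dead_or_missegmented")
        new_flags.append(";".join(toks))
    out["qc_flags"] = new_flags
    return out


def gfp_live_normalize(
    traces: pd.DataFrame, control_traces: pd.DataFrame
) -> pd.DataFrame:
    """Double normalization of live GFP time courses.

    Both inputs are wide tables (rows = cells, columns = time points in
    order, first column = t0). Each trace is first normalized to its own
    t0, then divided by the time-matched mean of the control traces (also
    t0-normalized), cancelling intensity changes that both groups share —
    e.g. dimming as cells flatten. Output at t0 is 1 for every cell.
    """
    if control_traces.shape[0] == 0:
        raise ValueError("control group is empty")
    for name, tbl in (("traces", traces), ("control_traces", control_traces)):
        t0 = tbl.iloc[:, 0]
        bad = tbl.index[t0 <= 0].tolist()
        if bad:
            raise ValueError(f"{name}: non-positive t=0 intensity for {bad}")
    self_norm = traces.div(traces.iloc[:, 0], axis=0)
    ctrl_norm = control_traces.div(control_traces.iloc[:, 0], axis=0)
    return self_norm.div(ctrl_norm.mean(axis=0), axis=1)
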