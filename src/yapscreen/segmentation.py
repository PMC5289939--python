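"""Segmentation operators: nuclei, two-step watershed cell bodies,
perinuclear rings and protrusion/core decomposition.

The pipeline mirrors a classical high-content workflow:

1. nuclei from the DNA channel (smoothed threshold + distance-transform
   watershed to split touching nuclei), each label eroded by one pixel to
   compensate for boundary errors;
2. cell bodies in two watershed steps — bright "cell cores" on the YAP
   channel seeded by nuclei, then a second watershed on the actin channel
   seeded by the cores, restricted to a combined foreground mask;
3. the perinuclear ring: pixels whose Chebyshev distance from the eroded
   nucleus border lies in a fixed band (default 2-7 px), clipped to the
   cell and excluding all nuclei — the cytoplasmic reference region for the
   YAP ratio;
4. protrusions: cytoplasm dimmer than a fixed fraction (default 0.75) of
   the cell's mean cytoplasm intensity, with the remaining bright core used
   to measure protrusion extent (fraction of core border touching
   protrusive regions).

Connectivity conventions: 8-connected objects, 4-connected borders.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.feature import peak_local_max
from skimage.morphology import remove_small_holes, remove_small_objects
from skimage.segmentation import watershed

from .config import SegmentationParams
from .containers import FieldImage, LabelMaps

__all__ = [
    "segment_nuclei",
    "segment_cells",
    "build_ring",
    "detect_protrusions",
    "segment_field",
]

_S8 = np.ones((3, 3), bool)  # 8-connectivity structuring element


def _otsu_mask(img: np.ndarray) -> np.ndarray:
    if np.ptp(img) == 0:
        return np.zeros(img.shape, bool)
    return img > threshold_otsu(img)


def _foreground_mask(img: np.ndarray) -> np.ndarray:
    """Foreground by Otsu, guarded against near-confluent fields.

    When cells cover almost the whole frame the Otsu split lands *within*
    the cell intensities rather than between background and signal. The
    split is accepted only if the dark class is genuinely dark (mean under
    30% of the bright class); otherwise the whole frame is foreground.
    """
    if np.ptp(img) == 0:
        return np.zeros(img.shape, bool)
    t = threshold_otsu(img)
    fg = img > t
    dark = img[~fg]
    if dark.size == 0:
        return np.ones(img.shape, bool)
    if dark.mean() > 0.3 * img[fg].mean():
        return np.ones(img.shape, bool)
    return fg


def segment_nuclei(dna: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Label nuclei in the DNA channel.

    Touching nuclei are split by a watershed on the distance transform;
    every final label is eroded by one pixel (3x3 square) and labels
    falling below ``min_nucleus_area`` afterwards are dropped. An all-flat
    image yields an empty labeling.
    """
    params = params or SegmentationParams()
    dna = np.asarray(dna, dtype=float)
    if dna.size == 0:
        raise ValueError("empty image")
    sm = gaussian(dna, params.smooth_sigma_nuclei, preserve_range=True)
    fg = _otsu_mask(sm)
    if not fg.any():
        return np.zeros(dna.shape, dtype=np.int32)
    fg = remove_small_holes(fg, max_size=64)
    fg = remove_small_objects(fg, max_size=max(params.min_nucleus_area // 2, 8))
    if not fg.any():
        return np.zeros(dna.shape, dtype=np.int32)

    dist = ndi.distance_transform_edt(fg)
    coords = peak_local_max(
        dist, min_distance=params.min_seed_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros(dna.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    # components without a detected peak still need a seed
    comp, ncomp = ndi.label(fg, structure=_S8)
    seeded = set(np.unique(comp[markers > 0]))
    for c in range(1, ncomp + 1):
        if c not in seeded:
            mask = comp == c
            d = np.where(mask, dist, -1)
            markers[np.unravel_index(np.argmax(d), d.shape)] = markers.max() + 1
    labels = watershed(-dist, markers, mask=fg)

    # per-label 1-px erosion, dropping objects that become too small
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    for k in np.unique(labels):
        if k == 0:
            continue
        mask = labels == k
        eroded = ndi.binary_erosion(mask, structure=_S8, border_value=0)
        if eroded.sum() >= params.min_nucleus_area:
            out[eroded] = next_id
            next_id += 1
    return out


def segment_cells(
    nuclei: np.ndarray,
    yap: np.ndarray,
    actin: np.ndarray,
    params: SegmentationParams | None = None,
) -> tuple[np.ndarray, frozenset[int]]:
    """Two-step watershed cell-body segmentation.

    Returns the cell label grid (one region per nucleus label, tiling the
    combined YAP+actin foreground without overlap) and the set of nucleus
    labels that fell outside the foreground mask; those cells degrade to
    their eroded nucleus region.
    """
    params = params or SegmentationParams()
    nuclei = np.asarray(nuclei)
    if nuclei.max() == 0:
        return np.zeros(nuclei.shape, dtype=np.int32), frozenset()
    ysm = gaussian(np.asarray(yap, float), params.smooth_sigma_cells, preserve_range=True)
    asm = gaussian(np.asarray(actin, float), params.smooth_sigma_cells, preserve_range=True)

    fg_raw = _foreground_mask(ysm + asm)
    fg = remove_small_holes(fg_raw | (nuclei > 0), max_size=64)

    # step 1: bright cell cores on the YAP channel, seeded by nuclei
    core_mask = (_otsu_mask(ysm) | (nuclei > 0)) & fg
    cores = watershed(-ysm, markers=nuclei.astype(np.int32), mask=core_mask)
    # step 2: flood the full foreground on the actin channel (borders are
    # intensity ridges), seeded by the cores
    cells = watershed(asm, markers=cores, mask=fg)

    flagged = []
    for k in np.unique(nuclei):
        if k == 0:
            continue
        nucmask = nuclei == k
        if not fg_raw[nucmask].any():
            # nucleus outside the intensity foreground: degrade to the
            # eroded nucleus region and flag
            cells[nucmask] = k
            flagged.append(int(k))
        elif not (cells[nucmask] == k).any():
            cells[nucmask] = k
            flagged.append(int(k))
    # guarantee nucleus containment
    cells = np.where(nuclei > 0, nuclei, cells).astype(np.int32)
    return cells, frozenset(flagged)


def _bbox_slices(mask: np.ndarray, pad: int, shape: tuple[int, int]):
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    r0, r1 = max(rows[0] - pad, 0), min(rows[-1] + pad + 1, shape[0])
    c0, c1 = max(cols[0] - pad, 0), min(cols[-1] + pad + 1, shape[1])
    return slice(r0, r1), slice(c0, c1)


def build_ring(
    nuclei: np.ndarray,
    cells: np.ndarray,
    inner: int | None = None,
    outer: int | None = None,
    params: SegmentationParams | None = None,
) -> tuple[np.ndarray, frozenset[int]]:
    """Perinuclear ring label map.

    Ring ``k`` is the set of pixels whose Chebyshev distance from the
    stored (eroded) nucleus ``k`` lies in ``[inner, outer]`` (defaults
    2-7 px, i.e. the band swept by iterative 3x3 dilations), intersected
    with cell ``k`` and excluding every nucleus. Returns the ring labels
    and the labels whose ring came out empty (such cells are excluded
    downstream).
    """
    params = params or SegmentationParams()
    inner = params.ring_inner if inner is None else inner
    outer = params.ring_outer if outer is None else outer
    nuc_ids = np.unique(nuclei)
    nuc_ids = nuc_ids[nuc_ids > 0]
    cell_ids = np.unique(cells)
    cell_ids = cell_ids[cell_ids > 0]
    if set(nuc_ids) - set(cell_ids):
        raise ValueError(
            f"nucleus labels without matching cell: {sorted(set(nuc_ids) - set(cell_ids))}"
        )
    rings = np.zeros_like(nuclei, dtype=np.int32)
    any_nuc = nuclei > 0
    empty = []
    for k in nuc_ids:
        mask = nuclei == k
        sl = _bbox_slices(mask, outer + 1, nuclei.shape)
        local = mask[sl]
        dist = ndi.distance_transform_cdt(~local, metric="chessboard")
        band = (dist >= inner) & (dist <= outer)
        ring_local = band & (cells[sl] == k) & ~any_nuc[sl]
        if ring_local.any():
            rings[sl][ring_local] = k
        else:
            empty.append(int(k))
    return rings, frozenset(empty)


def detect_protrusions(
    cells: np.ndarray,
    nuclei: np.ndarray,
    yap: np.ndarray,
    threshold_frac: float | None = None,
    params: SegmentationParams | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Split each cell's cytoplasm into a bright core and dim protrusions.

    The core is the union of cytoplasm components at or above
    ``threshold_frac`` of the mean cytoplasm intensity that are adjacent to
    the nucleus; everything else in the cytoplasm is protrusive. Returns
    (cores, protrusions, table) where the table has one row per label with
    ``proA`` (protrusion pixel count), ``proX`` (fraction of the core's
    outer border in contact with protrusions) and a ``degenerate`` flag for
    cells with under 10 cytoplasm pixels.
    """
    params = params or SegmentationParams()
    frac = params.protrusion_frac if threshold_frac is None else threshold_frac
    yap = np.asarray(yap, float)
    cores = np.zeros_like(cells, dtype=np.int32)
    protr = np.zeros_like(cells, dtype=np.int32)
    rows = []
    for k in np.unique(cells):
        if k == 0:
            continue
        cellmask = cells == k
        sl = _bbox_slices(cellmask, 2, cells.shape)
        cell_l = cellmask[sl]
        nuc_l = nuclei[sl] == k
        cyto = cell_l & ~nuc_l
        if cyto.sum() < 10:
            rows.append(dict(label=int(k), proA=0, proX=0.0, degenerate=True))
            cores[sl][cyto] = k
            continue
        mean_cyto = yap[sl][cyto].mean()
        bright = cyto & (yap[sl] >= frac * mean_cyto)
        comp, ncomp = ndi.label(bright, structure=_S8)
        nuc_halo = ndi.binary_dilation(nuc_l, structure=_S8)
        adjacent = np.unique(comp[nuc_halo & bright])
        adjacent = adjacent[adjacent > 0]
        if adjacent.size == 0 and ncomp > 0:
            sizes = ndi.sum(bright, comp, index=np.arange(1, ncomp + 1))
            adjacent = np.array([int(np.argmax(sizes)) + 1])
        core = np.isin(comp, adjacent)
        pro = cyto & ~core
        cores[sl][core] = k
        protr[sl][pro] = k
        proA = int(pro.sum())
        # outer border of the core: 4-connected, excluding the nucleus side
        outside = ~(core | nuc_l)
        nb_out = np.zeros_like(core)
        nb_pro = np.zeros_like(core)
        for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            sh_out = _shift_bool(outside, axis, shift, fill=True)
            sh_pro = _shift_bool(pro, axis, shift, fill=False)
            nb_out |= sh_out
            nb_pro |= sh_pro
        border = core & nb_out
        touching = border & nb_pro
        proX = float(touching.sum() / border.sum()) if border.any() else 0.0
        rows.append(dict(label=int(k), proA=proA, proX=proX, degenerate=False))
    table = pd.DataFrame(rows, columns=["label", "proA", "proX", "degenerate"])
    return cores, protr, table


def _shift_bool(mask: np.ndarray, axis: int, shift: int, fill: bool) -> np.ndarray:
    out = np.full_like(mask, fill)
    src = [slice(None)] * mask.ndim
    dst = [slice(None)] * mask.ndim
    if shift > 0:
        src[axis], dst[axis] = slice(shift, None), slice(None, -shift)
    else:
        src[axis], dst[axis] = slice(None, shift), slice(-shift, None)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def segment_field(image: FieldImage, params: SegmentationParams | None = None) -> LabelMaps:
    """Run the full segmentation stack on one field."""
    params = params or SegmentationParams()
    nuclei = segment_nuclei(image.dna, params)
    cells, flagged = segment_cells(nuclei, image.yap, image.actin, params)
    rings, empty = build_ring(nuclei, cells, params=params)
    cores, protr, _ = detect_protrusions(cells, nuclei, image.yap, params=params)
    return LabelMaps(
        nuclei=nuclei,
        cells=cells,
        rings=rings,
        cores=cores,
        protrusions=protr,
        empty_ring_labels=empty,
        flagged_outside_foreground=flagged,
    )
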