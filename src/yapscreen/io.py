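"""File formats: multi-page TIFF fields, label maps, CSV tables, JSON specs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import FieldImage, LabelMaps

CHANNEL_ORDER = ("dna", "actin", "yap")


def write_field_tiff(path, image: FieldImage) -> None:
    """One page per channel, 16-bit, channel order recorded in metadata."""
    pages = np.stack(
        [np.clip(np.round(getattr(image, ch)), 0, 65535).astype(np.uint16) for ch in CHANNEL_ORDER]
    )
    meta = {
        "channels": list(CHANNEL_ORDER),
        "pixel_size_um": image.pixel_size_um,
        "well_id": image.well_id,
        "field_id": image.field_id,
    }
    tifffile.imwrite(
        path, pages, photometric="minisblack", description=json.dumps(meta)
    )


def read_field_tiff(path) -> FieldImage:
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray().astype(float)
        desc = tif.pages[0].description
    meta = json.loads(desc) if desc else {}
    order = meta.get("channels", list(CHANNEL_ORDER))
    channels = dict(zip(order, pages))
    return FieldImage(
        dna=channels["dna"],
        actin=channels["actin"],
        yap=channels["yap"],
        pixel_size_um=float(meta.get("pixel_size_um", 0.64)),
        well_id=meta.get("well_id", ""),
        field_id=meta.get("field_id", ""),
    )


def write_labels_tiff(path, labels: np.ndarray) -> None:
    if labels.max() > 65535:
        raise ValueError("more than 65535 labels do not fit a 16-bit TIFF")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_labels_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_label_maps(directory, maps: LabelMaps, prefix: str = "") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("nuclei", "cells", "rings", "cores", "protrusions"):
        arr = getattr(maps, name)
        if arr is not None:
            write_labels_tiff(directory / f"{prefix}{name}.tif", arr)


def write_feature_table(path, records: pd.DataFrame) -> None:
    """CSV by default; a columnar binary variant via a .parquet suffix."""
    if str(path).endswith(".parquet"):
        records.to_parquet(path, index=False)
    else:
        records.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    if str(path).endswith(".parquet"):
        table = pd.read_parquet(path)
    else:
        table = pd.read_csv(path)
    if "qc_flags" in table.columns:
        table["qc_flags"] = table["qc_flags"].fillna("")
    return table
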