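"""TIFF and plate-map IO.

Image files follow the strict naming convention
``P{plate}_W{well}_F{field}_C{channel}.tif`` with channel 1 = nuclei (DAPI)
and channel 2 = neutral lipid (Bodipy). Images are 16-bit grayscale TIFF;
bit depth is preserved on round trip.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import tifffile

from .screen import LAYOUT_COLUMNS
from .synth import FieldData

__all__ = [
    "image_filename",
    "write_field",
    "write_plate_images",
    "read_image_set",
    "read_plate_map",
    "write_plate_map",
]

FILENAME_RE = re.compile(
    r"^P(?P<plate>[A-Za-z0-9\-]+)_W(?P<well>[A-Za-z0-9]+)_F(?P<field>\d+)_C(?P<channel>\d+)\.tif$"
)

NUCLEI_CHANNEL = 1
DROPLET_CHANNEL = 2


def image_filename(plate: str, well: str, field: int, channel: int) -> str:
    return f"P{plate}_W{well}_F{field}_C{channel}.tif"


def write_field(
    directory: Path, plate: str, well: str, field: int, nuclei: np.ndarray, droplets: np.ndarray
) -> List[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for channel, img in ((NUCLEI_CHANNEL, nuclei), (DROPLET_CHANNEL, droplets)):
        path = directory / image_filename(plate, well, field, channel)
        tifffile.imwrite(path, np.asarray(img, dtype=np.uint16))
        paths.append(path)
    return paths


def write_plate_images(
    directory: Path, plate: str, fields: Dict[str, List[FieldData]]
) -> List[Path]:
    """Write every field of a rendered plate; returns the written paths."""
    paths = []
    for well, field_list in fields.items():
        for f_idx, fd in enumerate(field_list, start=1):
            paths.extend(write_field(directory, plate, well, f_idx, fd.nuclei, fd.droplets))
    return paths


def read_image_set(
    directory: Path,
) -> Dict[Tuple[str, str, int], Dict[int, np.ndarray]]:
    """Read all convention-named TIFFs under ``directory``.

    Returns a dict keyed by (plate, well, field) mapping channel number to
    image, in deterministic (sorted) order. A field missing either channel
    raises an error naming the well and field.
    """
    directory = Path(directory)
    groups: Dict[Tuple[str, str, int], Dict[int, np.ndarray]] = {}
    for path in sorted(directory.glob("*.tif")):
        m = FILENAME_RE.match(path.name)
        if m is None:
            continue
        key = (m.group("plate"), m.group("well"), int(m.group("field")))
        groups.setdefault(key, {})[int(m.group("channel"))] = tifffile.imread(path)
    for (plate, well, fidx), channels in groups.items():
        for ch in (NUCLEI_CHANNEL, DROPLET_CHANNEL):
            if ch not in channels:
                raise FileNotFoundError(
                    f"plate {plate} well {well} field {fidx}: channel {ch} image missing"
                )
    return dict(sorted(groups.items()))


def read_plate_map(path: Path) -> pd.DataFrame:
    """Read a plate-map CSV (well_id, extract_id, role, concentration, conc_units, replicate)."""
    df = pd.read_csv(path, dtype={"well_id": str, "extract_id": str, "role": str})
    missing = [c for c in ("well_id", "role") if c not in df.columns]
    if missing:
        raise ValueError(f"plate map missing required columns: {missing}")
    for col in LAYOUT_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col in ("extract_id", "conc_units") else np.nan
    df["extract_id"] = df["extract_id"].fillna("")
    if df["well_id"].duplicated().any():
        raise ValueError("plate map contains duplicate well ids")
    return df[LAYOUT_COLUMNS]


def write_plate_map(layout: pd.DataFrame, path: Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    layout.to_csv(path, index=False)
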