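"""Per-cell and per-well readouts derived from a segmentation.

Three readouts drive the downstream screen: mean LDs per cell (the primary
assay metric), nuclei per field (the cytotoxicity surrogate), and the
background-corrected integrated cytoplasmic intensity per cell (used for
fatty-acid uptake time courses). The LD-count frequency distribution is kept
as a unit-bin histogram so that treatment-induced left/right shifts of the
distribution can be quantified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .segment import SegmentationResult

__all__ = [
    "PerCellRecord",
    "WellSummary",
    "per_cell_measurements",
    "summarize_well",
    "ld_histogram",
    "distribution_shift",
]

PER_CELL_COLUMNS = [
    "cell_id",
    "ld_count",
    "integrated_cytoplasmic_intensity",
    "cytoplasm_area_px",
]

#: alias documenting the row schema of the per-cell table
PerCellRecord = pd.DataFrame


@dataclass
class WellSummary:
    """Pooled readouts for one well.

    ``mean_lds_per_cell`` is NaN (an explicit missing value, never a silent
    zero) when no cells were found. ``nuclei_per_field`` is the total cell
    count divided by the number of fields imaged. ``ld_histogram`` counts
    cells per integer LD-count bin; the last bin is open-ended at
    ``histogram_cap``.
    """

    well_id: str
    n_cells: int
    n_fields: int
    mean_lds_per_cell: float
    nuclei_per_field: float
    ld_histogram: np.ndarray
    mean_integrated_intensity: float
    histogram_cap: int

    def validate(self) -> None:
        if int(self.ld_histogram.sum()) != self.n_cells:
            raise ValueError("histogram mass must equal n_cells")
        if self.nuclei_per_field < 0:
            raise ValueError("nuclei_per_field must be >= 0")


def per_cell_measurements(
    seg: SegmentationResult,
    droplet_image: np.ndarray,
    background: str = "median",
) -> pd.DataFrame:
    """One row per cell territory: LD count, integrated intensity, area.

    Integrated cytoplasmic intensity is the sum of (pixel - background) over
    the territory, clipped at zero; the background estimate is the image
    median (``background="median"``) or zero (``background="none"``).
    """
    img = np.asarray(droplet_image, dtype=float)
    if background == "median":
        bg = float(np.median(img))
    elif background == "none":
        bg = 0.0
    else:
        raise ValueError(f"unknown background method {background!r}")
    n = seg.n_cells
    ids = np.arange(1, n + 1)
    counts = seg.per_cell_counts()
    if n:
        sums = ndi.sum_labels(img, labels=seg.cell_labels, index=ids)
        areas = ndi.sum_labels(
            np.ones_like(img), labels=seg.cell_labels, index=ids
        )
    else:
        sums = np.zeros(0)
        areas = np.zeros(0)
    integrated = np.clip(sums - bg * areas, 0.0, None)
    return pd.DataFrame(
        {
            "cell_id": ids,
            "ld_count": counts.reindex(ids).fillna(0).astype(int).values,
            "integrated_cytoplasmic_intensity": integrated,
            "cytoplasm_area_px": areas,
        },
        columns=PER_CELL_COLUMNS,
    )


def ld_histogram(ld_counts: Sequence[int], cap: int = 80) -> np.ndarray:
    """Unit-bin histogram of per-cell LD counts; counts >= cap pool in the top bin."""
    counts = np.asarray(ld_counts, dtype=int)
    clipped = np.minimum(counts, cap)
    return np.bincount(clipped, minlength=cap + 1)


def summarize_well(
    field_records: Sequence[pd.DataFrame],
    well_id: str = "",
    histogram_cap: int = 80,
) -> WellSummary:
    """Pool per-cell records across a well's fields into one summary.

    Cells are pooled at the cell level (not averaged per field), so wells
    with unequal cell numbers per field are weighted by cell, and
    nuclei_per_field is the total count divided by the number of fields.
    """
    if len(field_records) == 0:
        raise ValueError("at least one field is required")
    pooled = pd.concat(field_records, ignore_index=True) if field_records else pd.DataFrame()
    n_fields = len(field_records)
    n_cells = len(pooled)
    hist = ld_histogram(pooled["ld_count"] if n_cells else [], cap=histogram_cap)
    if n_cells:
        mean_ld = float(pooled["ld_count"].mean())
        mean_int = float(pooled["integrated_cytoplasmic_intensity"].mean())
    else:
        mean_ld = float("nan")
        mean_int = float("nan")
    summary = WellSummary(
        well_id=well_id,
        n_cells=n_cells,
        n_fields=n_fields,
        mean_lds_per_cell=mean_ld,
        nuclei_per_field=n_cells / n_fields,
        ld_histogram=hist,
        mean_integrated_intensity=mean_int,
        histogram_cap=histogram_cap,
    )
    summary.validate()
    return summary


def distribution_shift(hist_a: np.ndarray, hist_b: np.ndarray) -> float:
    """Signed shift of distribution B relative to A: mean(B) - mean(A).

    Positive = B sits to the right of A (more LDs per cell). Histograms must
    share the bin grid; an empty histogram yields NaN (explicit missing
    value).
    """
    a = np.asarray(hist_a, dtype=float)
    b = np.asarray(hist_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("histograms must share the same bin grid")
    if a.sum() == 0 or b.sum() == 0:
        return float("nan")
    bins = np.arange(len(a), dtype=float)
    return float((bins * b).sum() / b.sum() - (bins * a).sum() / a.sum())
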