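"""Slide processing: nucleus segmentation, rule-based cell classification
and per-patient CTC counting.

The identification rule mirrors the manual-selection criteria of the
immunofluorescence CTC platform this package models:

* an MSLN-positive CTC has a nucleus of at least 47 um^2, CKmix and MSLN
  total fluorescence at or above the respective slide-wide averages, and
  CD45 total fluorescence strictly below the slide-wide average
  (CKmix+/DAPI+/CD45-/MSLN+);
* a CTC satisfies the CKmix and CD45 gates (CKmix+/DAPI+/CD45-);
* a leukocyte shows the opposite pattern (CKmix-/DAPI+/CD45+);
* anything else is left unclassified.

Slide averages are taken over ALL segmented cells on the slide, so the gates
are relative: rescaling every intensity on a slide by a common factor leaves
every call unchanged.  DAPI positivity is equated with successful
segmentation on the DAPI channel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import expand_labels

from .simulate import CHANNELS

__all__ = [
    "RuleConfig", "SlideSummary", "CellClass", "segment_cells",
    "compute_slide_means", "classify_cell", "classify_cells", "count_ctcs",
    "ihc_score",
]

CellClass = str  # one of {"MSLN_POS_CTC", "CTC", "WBC", "UNCLASSIFIED"}
INTENSITY_COLUMNS = tuple(f"int_{ch}" for ch in CHANNELS)


@dataclass(frozen=True)
class RuleConfig:
    """Gates of the identification rule.

    ``area_min`` (um^2) applies to MSLN-positive calls only, unless
    ``apply_area_to_plain_ctc`` extends it to all CTCs.  With
    ``joint_vs_perchannel`` the MSLN/CKmix tumor gate compares the sum
    MSLN+CKmix against the sum of the slide averages instead of gating each
    channel against its own average.
    """

    area_min: float = 47.0
    joint_vs_perchannel: bool = False
    apply_area_to_plain_ctc: bool = False

    def __post_init__(self) -> None:
        if self.area_min <= 0:
            raise ValueError("area_min must be > 0")


@dataclass(frozen=True)
class SlideSummary:
    """Arithmetic means of the per-cell total intensities over all segmented
    cells on one slide."""

    n_cells: int
    mean_dapi: float
    mean_ckmix: float
    mean_cd45: float
    mean_msln: float


def compute_slide_means(cells: pd.DataFrame) -> SlideSummary:
    if len(cells) < 1:
        raise ValueError("no cells to summarize")
    return SlideSummary(
        n_cells=len(cells),
        mean_dapi=float(cells["int_dapi"].mean()),
        mean_ckmix=float(cells["int_ckmix"].mean()),
        mean_cd45=float(cells["int_cd45"].mean()),
        mean_msln=float(cells["int_msln"].mean()),
    )


def classify_cell(cell, slide: SlideSummary, rule: RuleConfig = RuleConfig()) -> CellClass:
    """Classify one cell against its slide's averages.

    Boundary handling is exact: tumor gates are inclusive (>=), the CD45
    gate is strict (<).  MSLN_POS_CTC calls imply the CTC conditions.
    """
    ck_pos = cell["int_ckmix"] >= slide.mean_ckmix
    cd45_low = cell["int_cd45"] < slide.mean_cd45
    area_ok = cell["area_um2"] >= rule.area_min
    if rule.joint_vs_perchannel:
        tumor_gate = (cell["int_ckmix"] + cell["int_msln"]
                      >= slide.mean_ckmix + slide.mean_msln)
    else:
        tumor_gate = ck_pos and cell["int_msln"] >= slide.mean_msln
    if tumor_gate and ck_pos and cd45_low and area_ok:
        return "MSLN_POS_CTC"
    if ck_pos and cd45_low and (area_ok or not rule.apply_area_to_plain_ctc):
        return "CTC"
    if not ck_pos and not cd45_low:
        return "WBC"
    return "UNCLASSIFIED"


def classify_cells(cells: pd.DataFrame, rule: RuleConfig = RuleConfig(),
                   by_slide: bool = True) -> pd.DataFrame:
    """Classify every cell; slide averages are computed per ``slide_id`` when
    present (each slide is its own reference population).  Adds a
    ``called_class`` column."""
    missing = [c for c in ("area_um2",) + INTENSITY_COLUMNS if c not in cells.columns]
    if missing:
        raise KeyError("cell table lacks required columns: " + ", ".join(missing))
    out = cells.copy()
    out["called_class"] = "UNCLASSIFIED"
    groups = out.groupby("slide_id", sort=False) if by_slide and "slide_id" in out.columns \
        else [(None, out)]
    for _, sub in groups:
        slide = compute_slide_means(sub)
        labels = [classify_cell(row, slide, rule) for _, row in sub.iterrows()]
        out.loc[sub.index, "called_class"] = labels
    return out


def count_ctcs(cells: pd.DataFrame) -> tuple[int, int]:
    """(msln_ctc_count, ctc_count) from a classified table; the CTC count
    includes the MSLN-positive subset."""
    if "called_class" not in cells.columns:
        raise KeyError("cells must be classified first (missing 'called_class')")
    n_msln = int((cells["called_class"] == "MSLN_POS_CTC").sum())
    n_plain = int((cells["called_class"] == "CTC").sum())
    return n_msln, n_msln + n_plain


def count_ctcs_by_slide(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-slide counts, one row per slide_id."""
    rows = []
    for sid, sub in cells.groupby("slide_id", sort=False):
        m, c = count_ctcs(sub)
        rows.append({"slide_id": sid, "msln_ctc_count": m, "ctc_count": c})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# segmentation

def segment_cells(images: np.ndarray, pixel_size: float,
                  min_area: float = 10.0, slide_id: str = "slide",
                  expand_px: float = 6.0) -> pd.DataFrame:
    """Segment nuclei on the DAPI channel and extract per-cell features.

    Nuclei are connected components above an Otsu threshold of the DAPI
    channel; the nuclear area is the component's pixel count times the pixel
    area.  Per-cell channel totals are sums of background-subtracted
    intensity over the component footprint dilated by ``expand_px`` pixels
    (so flux smeared beyond the thresholded core by the PSF is recovered;
    expansion respects neighbouring components).  Background is the
    per-channel median, a robust estimate because nuclei are rare relative
    to the field.  Components below ``min_area`` (um^2) are discarded.
    A blank DAPI channel yields an empty table with a warning, not an error.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    images = np.asarray(images, dtype=float)
    if images.ndim != 3 or images.shape[0] != len(CHANNELS):
        raise ValueError(f"expected a ({len(CHANNELS)}, H, W) stack, got {images.shape}")
    dapi = images[0]
    empty = pd.DataFrame(columns=["slide_id", "cell_id", "x_um", "y_um", "area_um2",
                                  *INTENSITY_COLUMNS])
    if np.ptp(dapi) == 0:
        warnings.warn("blank DAPI channel: no nuclei to segment", stacklevel=2)
        return empty
    thr = threshold_otsu(dapi)
    mask = dapi > thr
    labels = label(mask)
    expanded = expand_labels(labels, distance=expand_px) if expand_px > 0 else labels
    background = np.median(images.reshape(len(CHANNELS), -1), axis=1)
    rows = []
    for i, region in enumerate(regionprops(labels)):
        area = region.area * pixel_size**2
        if area < min_area:
            continue
        cy, cx = region.centroid
        foot = expanded == region.label
        n_foot = int(foot.sum())
        row = {"slide_id": slide_id, "cell_id": f"{slide_id}-c{i:05d}",
               "x_um": (cx + 0.5) * pixel_size, "y_um": (cy + 0.5) * pixel_size,
               "area_um2": area}
        for ci, ch in enumerate(CHANNELS):
            total = float(images[ci][foot].sum() - background[ci] * n_foot)
            row[f"int_{ch}"] = max(total, 0.0)
        rows.append(row)
    if not rows:
        warnings.warn("no nuclei above threshold/min_area", stacklevel=2)
        return empty
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# immunohistochemistry scoring

_PCT_BINS = ((5.0, 0), (25.0, 1), (50.0, 2), (75.0, 3), (100.0, 4))


def ihc_score(pct_positive: float, intensity: int) -> int:
    """Immunohistochemical total score: percent-positive bin score
    (0: <5%, 1: 5-25%, 2: 26-50%, 3: 51-75%, 4: >75%) times staining
    intensity (0 negative .. 3 strong)."""
    if not (0.0 <= pct_positive <= 100.0):
        raise ValueError(f"pct_positive must be in [0, 100], got {pct_positive}")
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity must be one of 0..3, got {intensity}")
    if pct_positive < 5.0:
        pct_score = 0
    elif pct_positive <= 25.0:
        pct_score = 1
    elif pct_positive <= 50.0:
        pct_score = 2
    elif pct_positive <= 75.0:
        pct_score = 3
    else:
        pct_score = 4
    return pct_score * intensity
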