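"""Fluorogold (FG) labelling calls and region x projection anatomy tables.

Retrogradely traced neurons are called FG-positive from confocal ROI
intensities relative to a TH-negative background: the intrinsic-signal
rule requires the ROI mean to exceed background mean + 2 SD; the
immuno-signal rule thresholds the image at background mean + 10 SD and
requires more than 5 punctate supra-threshold marks inside the soma.
Cell-count tables over midbrain regions and striatal projection targets
are summarised as two population matrices: the composition of each
region (rows sum to 100%) and the distribution of each projection
across regions (columns sum to 100%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage

__all__ = [
    "FGCriteria",
    "ROIMeasurement",
    "fg_intrinsic_positive",
    "fg_immuno_positive",
    "load_count_table",
    "population_matrices",
    "double_label_fraction",
    "REGIONS",
    "PROJECTIONS",
]

REGIONS = ("lSN", "mSN", "PBP", "PN", "IF")
PROJECTIONS = ("DLS", "DMS", "lNAcc", "mNAcc")


@dataclass(frozen=True)
class FGCriteria:
    intrinsic_sd_mult: float = 2.0
    immuno_sd_mult: float = 10.0
    min_marks: int = 5  # positive when strictly more marks than this
    min_mark_area: int = 2  # pixels; noise guard on connected components

    def __post_init__(self) -> None:
        if self.intrinsic_sd_mult <= 0 or self.immuno_sd_mult <= 0:
            raise ValueError("SD multipliers must be positive")
        if self.min_marks < 0:
            raise ValueError("min_marks must be non-negative")


@dataclass(frozen=True)
class ROIMeasurement:
    """Confocal measurement of one soma ROI against its background.

    Either ``roi_pixels`` (2-D intensity array, for the immuno rule) or a
    precomputed ``roi_mean`` (for the intrinsic rule) must be present.
    ``mask`` restricts mark counting to the soma; None means the whole
    array.  Background statistics come from TH-negative regions with
    nuclei excluded upstream.
    """

    background_mean: float
    background_sd: float
    roi_pixels: np.ndarray | None = None
    roi_mean: float | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.background_sd < 0:
            raise ValueError("background SD must be non-negative")
        if self.roi_pixels is None and self.roi_mean is None:
            raise ValueError("need roi_pixels or roi_mean")

    def mean_intensity(self) -> float:
        if self.roi_mean is not None:
            return float(self.roi_mean)
        px = self.roi_pixels
        if self.mask is not None:
            px = px[self.mask.astype(bool)]
        if px.size == 0:
            raise ValueError("empty ROI")
        return float(px.mean())


def fg_intrinsic_positive(m: ROIMeasurement,
                          c: FGCriteria = FGCriteria()) -> bool:
    """Intrinsic-signal call: ROI mean strictly above bg mean + 2 SD."""
    if m.background_sd == 0:
        warnings.warn("degenerate background SD = 0; comparing to the mean "
                      "only", stacklevel=2)
    return bool(m.mean_intensity()
                > m.background_mean + c.intrinsic_sd_mult * m.background_sd)


def fg_immuno_positive(m: ROIMeasurement,
                       c: FGCriteria = FGCriteria()) -> tuple[bool, int]:
    """Immuno-signal call: > min_marks puncta above bg mean + 10 SD.

    Marks are 8-connected components of supra-threshold pixels inside the
    soma mask with area >= ``min_mark_area`` pixels.  Returns
    ``(positive, n_marks)``.
    """
    if m.roi_pixels is None:
        raise ValueError("immuno rule needs the ROI pixel array")
    px = np.asarray(m.roi_pixels, dtype=float)
    mask = np.ones(px.shape, dtype=bool) if m.mask is None \
        else m.mask.astype(bool)
    if not mask.any():
        raise ValueError("empty soma mask")
    thr = m.background_mean + c.immuno_sd_mult * m.background_sd
    binary = (px > thr) & mask
    labels, n_comp = scipy.ndimage.label(binary, structure=np.ones((3, 3)))
    if n_comp:
        areas = np.bincount(labels.ravel())[1:]
        n_marks = int((areas >= c.min_mark_area).sum())
    else:
        n_marks = 0
    return n_marks > c.min_marks, n_marks


def load_count_table(path) -> pd.DataFrame:
    """Delimited text count table: rows = regions, columns = projections."""
    df = pd.read_csv(path, index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return df.astype(int)


def population_matrices(counts: pd.DataFrame) -> tuple[pd.DataFrame,
                                                       pd.DataFrame]:
    """(local_matrix, projection_matrix) in percent.

    local_matrix[r, p] = 100 * counts[r, p] / row total (what each region
    is composed of); projection_matrix[r, p] = 100 * counts[r, p] /
    column total (where each projection originates).  All-zero rows or
    columns yield NaN entries.
    """
    c = counts.astype(float)
    if c.empty:
        raise ValueError("empty count table")
    row_tot = c.sum(axis=1)
    col_tot = c.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        local = 100.0 * c.div(row_tot.replace(0, np.nan), axis=0)
        proj = 100.0 * c.div(col_tot.replace(0, np.nan), axis=1)
    return local, proj


def double_label_fraction(n_single: int, n_double: int) -> float:
    """Percentage of double-labelled neurons among all labelled neurons."""
    if n_single < 0 or n_double < 0:
        raise ValueError("counts must be non-negative")
    total = n_single + n_double
    if total == 0:
        raise ValueError("no labelled neurons counted")
    return 100.0 * n_double / total
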