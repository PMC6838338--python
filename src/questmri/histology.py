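"""Cytocochleogram and HO-1 intensity quantification from whole-mount images.

Hair cells sit in four rows along the cochlear spiral (one inner row IHC,
three outer rows OHC1-3).  Scoring marks each expected cell position present
or absent from the phalloidin channel; the cytocochleogram aggregates these
into percent-missing per position bin (percent distance from the apex).
The HO-1 channel is quantified as the mean epithelial intensity relative to
a background region containing no epithelium; the percent change from
background is computed downstream by :func:`questmri.stats.percent_change`.

Real manual score sheets can enter as CSV grids and flow through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .synthetic import CellLattice, HAIR_CELL_ROWS


@dataclass
class IntensityRecord:
    """Mean epithelial vs background HO-1 intensity for one image."""

    rat: str
    ear: str
    group: str
    subdivision: str
    image_id: str
    roi_mean: float
    background_mean: float


def score_image(image: np.ndarray, lattice: CellLattice) -> pd.DataFrame:
    """Score hair-cell presence from a phalloidin channel.

    Each lattice position is scored present iff the mean intensity inside
    its cell footprint exceeds an Otsu threshold derived from the image
    itself, which makes the call invariant to overall intensity rescaling.
    A channel with no signal at all (all zeros) scores everything absent.

    Returns a grid table with columns (row, position_pct, present).
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        if hi == 0.0:
            threshold = np.inf     # blank channel: nothing present
        else:
            raise ValueError("degenerate (saturated/constant) image")
    else:
        threshold = threshold_otsu(image)

    ny, nx = image.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = lattice.footprint_radius
    rows = []
    for (row, pos), (cy, cx) in lattice.centers.items():
        foot = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        if not foot.any():
            raise ValueError(f"cell footprint at ({cy}, {cx}) is outside the image")
        rows.append({"row": row, "position_pct": float(pos),
                     "present": bool(image[foot].mean() > threshold)})
    return pd.DataFrame(rows)


def build_cytocochleogram(grids, bin_width: float = 5.0) -> pd.DataFrame:
    """Percent missing hair cells per row and spiral-position bin.

    ``grids`` is an iterable of score tables (row, position_pct, present);
    ``bin_width`` is the bin size in percent distance from the apex and must
    divide 100.  Bins with no scored cells are reported as missing data
    (NaN), never as 0% loss.
    """
    if not np.isclose(100.0 % bin_width, 0.0) and not np.isclose(
            100.0 % bin_width, bin_width):
        raise ValueError("bin width must divide 100")
    grid = pd.concat(list(grids), ignore_index=True)
    if grid.empty:
        raise ValueError("no score grids supplied")
    if grid["position_pct"].min() < 0 or grid["position_pct"].max() > 100:
        raise ValueError("positions must lie in [0, 100]")
    edges = np.arange(0.0, 100.0 + bin_width / 2, bin_width)
    grid = grid.copy()
    grid["bin"] = pd.cut(grid["position_pct"], edges, right=False,
                         include_lowest=True)
    # cells exactly at 100% belong to the last bin
    grid.loc[grid["position_pct"] == 100.0, "bin"] = grid["bin"].cat.categories[-1]
    rows = []
    for row in HAIR_CELL_ROWS:
        sub = grid[grid["row"] == row]
        for interval in grid["bin"].cat.categories:
            cells = sub[sub["bin"] == interval]
            total = len(cells)
            absent = int((~cells["present"]).sum())
            rows.append({
                "row": row,
                "bin_start": float(interval.left),
                "bin_end": float(interval.right),
                "n_total": total,
                "n_absent": absent,
                "pct_missing": 100.0 * absent / total if total else np.nan,
            })
    return pd.DataFrame(rows)


def ho1_record(image: np.ndarray, epithelium_roi: np.ndarray,
               background_roi: np.ndarray, *, rat: str = "", ear: str = "",
               group: str = "", subdivision: str = "",
               image_id: str = "") -> IntensityRecord:
    """Mean HO-1 intensity in the epithelium and in a no-epithelium background.

    The two ROIs must be disjoint and nonempty; the percent change from
    background is left to the statistics layer.
    """
    image = np.asarray(image, dtype=float)
    epithelium_roi = np.asarray(epithelium_roi, dtype=bool)
    background_roi = np.asarray(background_roi, dtype=bool)
    if epithelium_roi.shape != image.shape or background_roi.shape != image.shape:
        raise ValueError("ROI shapes must match the image")
    if np.any(epithelium_roi & background_roi):
        raise ValueError("epithelium and background ROIs overlap")
    if not background_roi.any():
        raise ValueError("background ROI is empty")
    if not epithelium_roi.any():
        raise ValueError("epithelium ROI is empty")
    return IntensityRecord(
        rat=rat, ear=ear, group=group, subdivision=subdivision,
        image_id=image_id,
        roi_mean=float(image[epithelium_roi].mean()),
        background_mean=float(image[background_roi].mean()),
    )


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


# TIFF / CSV interchange ----------------------------------------------------

def save_channels_tiff(images, path) -> None:
    """Write a list of rendered fields as a multi-page TIFF.

    Pages alternate phalloidin / HO-1 per field.
    """
    import tifffile

    pages = []
    for img in images:
        pages.append(img.phalloidin.astype(np.float32))
        pages.append(img.ho1.astype(np.float32))
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")


def load_score_sheet(path) -> pd.DataFrame:
    """Load a manually scored grid (row, position_pct, present) from CSV."""
    grid = pd.read_csv(path)
    required = {"row", "position_pct", "present"}
    if not required <= set(grid.columns):
        raise ValueError(f"score sheet needs columns {sorted(required)}")
    grid["present"] = grid["present"].astype(bool)
    return grid
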