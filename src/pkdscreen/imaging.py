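"""Cyst quantification from bright-field-like z-stacks.

For each well the sharpest z-plane is selected with a Laplacian-energy
focus metric (a documented surrogate for proprietary ridge-texture
filters), candidate regions are segmented by contrast against the
background, and a region is accepted as a cyst iff its area is at least
3500 µm² and its region signal-to-background ratio (SBR) is at least 0.4.
Well summaries (cyst count, total cyst area) across an 8-point titration
are normalized to the DMSO median to form an imaging dose-response channel
that feeds the same Hill-fitting machinery as the viability readouts.

Because the assay is size-based, a solid cell aggregate and a swelled,
lumen-bearing cyst of equal size are indistinguishable to the area/SBR
rules; a ``lumen`` flag is reported only when annulus geometry (an
interior hole in the detected mask) is evident.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_closing, binary_fill_holes, laplace
from skimage.measure import label, regionprops

from .hillfit import Titration

__all__ = [
    "CystRegion",
    "MIN_AREA_UM2",
    "MIN_SBR",
    "select_focus_plane",
    "segment_cysts",
    "summarize_well",
    "cyst_dose_response",
    "read_stack",
    "write_stack",
]

logger = logging.getLogger(__name__)

#: accepted cyst regions must be at least this large
MIN_AREA_UM2 = 3500.0
#: and at least this distinct from background
MIN_SBR = 0.4
#: pixels deviating from background by more than this fraction of the
#: background enter the candidate mask (detection, not acceptance)
DETECT_FRACTION = 0.1
#: candidate specks smaller than this many pixels are dropped outright
MIN_SPECK_PX = 16
#: interior-hole fraction above which annulus (lumen) geometry is flagged
LUMEN_HOLE_FRACTION = 0.15


@dataclass
class CystRegion:
    """One segmented region with the quantities the acceptance rules use."""

    area_um2: float
    sbr: float
    centroid: tuple[float, float]
    z_plane: int
    accepted: bool
    lumen: bool = False


def select_focus_plane(stack: np.ndarray) -> int:
    """Index of the sharpest plane by Laplacian texture energy.

    The score of a plane is the variance of its Laplacian response (high
    for in-focus edges, low for defocus blur).  Ties break to the lowest
    index; a uniform stack scores zero everywhere and returns plane 0 with
    a warning.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be a (planes, H, W) array")
    scores = np.array([laplace(p).var() for p in stack])
    if np.all(scores == scores[0]):
        if stack.shape[0] > 1:
            warnings.warn("uniform focus scores; defaulting to plane 0",
                          stacklevel=2)
        return 0
    return int(np.argmax(scores))


def segment_cysts(plane: np.ndarray, pixel_size: float,
                  min_area_um2: float = MIN_AREA_UM2,
                  min_sbr: float = MIN_SBR,
                  z_plane: int = 0) -> list[CystRegion]:
    """Contrast-based cyst segmentation of one focal plane.

    Background is the median intensity of the plane (cysts occupy a small
    fraction of the field).  Pixels deviating from it by more than 10% of
    the background form the candidate mask, which is closed and
    hole-filled so an annulus and its lumen count as one region.  Each
    connected region's area comes from the filled footprint; its SBR is
    the mean absolute deviation from background over the detected (rim)
    pixels, normalized by the background — absolute so regions darker or
    brighter than background, or a mix (bright rim, dim lumen), measure
    alike.  Regions are accepted iff area >= ``min_area_um2`` and
    SBR >= ``min_sbr``.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    plane = np.asarray(plane, dtype=float)
    bg = float(np.median(plane))
    if bg <= 0:
        logger.warning("non-positive background estimate; empty result")
        return []
    dev = np.abs(plane - bg)
    detected = dev > DETECT_FRACTION * bg
    if not detected.any():
        return []
    closed = binary_closing(detected, structure=np.ones((3, 3)))
    filled = binary_fill_holes(closed)
    labels = label(filled)
    out: list[CystRegion] = []
    px_area = pixel_size * pixel_size
    for region in regionprops(labels):
        if region.area < MIN_SPECK_PX:
            continue
        mask = labels == region.label
        rim = mask & detected
        if not rim.any():
            continue
        sbr = float(dev[rim].mean() / bg)
        area = float(region.area * px_area)
        # annulus geometry: either an undetected interior hole, or a mix of
        # brighter-than-background rim and darker-than-background lumen
        hole_frac = 1.0 - rim.sum() / mask.sum()
        pos_frac = float(((plane > bg) & rim).sum() / mask.sum())
        neg_frac = float(((plane < bg) & rim).sum() / mask.sum())
        has_lumen = (hole_frac >= LUMEN_HOLE_FRACTION
                     or min(pos_frac, neg_frac) >= LUMEN_HOLE_FRACTION)
        out.append(CystRegion(
            area_um2=area, sbr=sbr,
            centroid=tuple(float(c) for c in region.centroid),
            z_plane=z_plane,
            accepted=(area >= min_area_um2 and sbr >= min_sbr),
            lumen=has_lumen))
    return out


def summarize_well(regions: list[CystRegion]) -> tuple[int, float]:
    """(cyst count, total cyst area µm²) over the accepted regions."""
    acc = [r for r in regions if r.accepted]
    return len(acc), float(sum(r.area_um2 for r in acc))


def analyze_stack(stack: np.ndarray, pixel_size: float,
                  min_area_um2: float = MIN_AREA_UM2,
                  min_sbr: float = MIN_SBR) -> tuple[int, list[CystRegion]]:
    """Focus selection + segmentation of one well's stack.

    Returns ``(focus_plane, regions)`` where regions come only from the
    selected focus plane.
    """
    z = select_focus_plane(stack)
    regions = segment_cysts(stack[z], pixel_size, min_area_um2, min_sbr, z_plane=z)
    return z, regions


def cyst_dose_response(summaries: pd.DataFrame) -> list[Titration]:
    """Imaging dose-response curves from per-well cyst summaries.

    ``summaries`` holds one row per well: compound_id, conc_um, role and
    total_area_um2 (from :func:`summarize_well` or the simulator's ground
    truth).  The neutral (DMSO) wells define the 0% reference; percent
    activity of a well is 100 x (area - DMSO median) / DMSO median, so
    complete loss of cysts is -100%.  Returns one ``cyst-area`` channel
    Titration per compound, ready for Hill fitting.
    """
    dmso = summaries.loc[summaries["role"] == "neutral", "total_area_um2"]
    if dmso.empty:
        raise ValueError("no neutral (DMSO) wells to define the 0% reference")
    ref = float(dmso.median())
    if ref <= 0:
        raise ValueError("DMSO reference area is not positive")
    cmp = summaries[summaries["role"] == "compound"]
    out = []
    for cid, grp in cmp.groupby("compound_id", sort=True):
        concs = np.sort(grp["conc_um"].unique())
        acts = np.array([
            100.0 * (grp.loc[grp["conc_um"] == c, "total_area_um2"].median() - ref)
            / ref for c in concs])
        cell_line = str(grp["cell_line"].iat[0]) if "cell_line" in grp else "3D"
        out.append(Titration(str(cid), cell_line, "cyst-area", concs, acts))
    return out


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF z-stack as a (planes, H, W) float array."""
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return np.asarray(arr, dtype=float)


def write_stack(stack: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")
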