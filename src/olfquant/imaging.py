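"""Glomerular image quantification.

Works on multi-channel fluorescence images of olfactory-bulb sections with
glomerulus ROIs given as binary masks (glomeruli are circumscribed by eye in
the source experiments; segmentation is out of scope).  Provides:

* ``binarize`` — hard or Otsu threshold to a binary signal mask.
* ``occupancy_curve`` — the multi-radius spatial-filter occupancy metric: for
  each filter radius r the ROI bounding box is tiled by non-overlapping square
  tiles of side 2r (grid anchored at the bounding-box origin); every tile
  overlapping the ROI by at least one pixel counts, and a tile is occupied when
  it contains at least one in-ROI signal pixel.  Occupancy(r) is the percentage
  of occupied tiles.  Compartmentalized innervation shows low occupancy at
  small radii; any non-empty signal reaches 100 % once one tile covers the
  whole glomerulus.
* ``compare_occupancy`` — two-way ANOVA (group × radius) on occupancy values,
  reporting the group main effect.
* ``colocalization_coefficient`` — percentage of marker-positive pixels within
  the glomerulus that are also reporter-positive.
* ``count_labeled_glomeruli`` and ``glomerulus_diameter`` — connected-component
  counting with a minimum area, and the equivalent-circle diameter.

Conventions: 0-based row-major pixel coordinates; masks are boolean arrays;
component connectivity is 8-connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .behavior import AnovaResult

__all__ = [
    "GlomerulusImage",
    "OccupancyCurve",
    "max_project",
    "binarize",
    "occupancy_curve",
    "compare_occupancy",
    "colocalization_coefficient",
    "count_labeled_glomeruli",
    "glomerulus_diameter",
]

DEFAULT_RADII = tuple(range(1, 21))  # filter radii 1–20 px
DEFAULT_MIN_AREA_PX = 50


@dataclass
class GlomerulusImage:
    """Multi-channel pixel grid with glomerulus ROI masks.

    ``channels`` maps names (e.g. ``axon``, ``dendrite``, ``marker``,
    ``nuclei``) to 2D intensity arrays of a shared shape; ``rois`` is a list of
    boolean masks of that shape.  ``truth`` carries generator ground truth for
    synthetic images.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0
    rois: list[np.ndarray] = field(default_factory=list)
    truth: dict | None = None

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")
        for roi in self.rois:
            if roi.shape not in shapes and shapes:
                raise ValueError("ROI shape must match channel shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass(frozen=True)
class OccupancyCurve:
    """Occupancy percentage per filter radius (radii increasing, values 0–100)."""

    radii_px: tuple[int, ...]
    occupancy_pct: tuple[float, ...]
    all_zero: bool = False

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"radius_px": self.radii_px, "occupancy_pct": self.occupancy_pct})


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a (z, y, x) stack, the standard
    flattening step before thresholding confocal stacks."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack
    if stack.ndim != 3:
        raise ValueError("expected a 2D image or a (z, y, x) stack")
    return stack.max(axis=0)


def binarize(channel: np.ndarray, method: str | float = "otsu",
             roi: np.ndarray | None = None) -> np.ndarray:
    """Threshold an intensity channel to a boolean mask.

    ``method`` is either a fixed numeric threshold (pixels strictly above it
    are positive) or ``"otsu"``, which derives the threshold from the in-ROI
    intensity histogram (whole image if no ROI is given).
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("empty channel")
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        return channel > float(method)
    if method != "otsu":
        raise ValueError(f"unknown binarization method {method!r}")
    values = channel[roi] if roi is not None else channel.ravel()
    if np.all(values == values.flat[0]):
        raise ValueError("channel is constant within the ROI; Otsu thresholding "
                         "is undefined — use a fixed threshold")
    return channel > threshold_otsu(values)


def _tile_ids(rows: np.ndarray, cols: np.ndarray, origin: tuple[int, int],
              side: int) -> set[tuple[int, int]]:
    return set(zip((rows - origin[0]) // side, (cols - origin[1]) // side))


def occupancy_curve(signal_mask: np.ndarray, roi: np.ndarray,
                    radii_px=DEFAULT_RADII) -> OccupancyCurve:
    """Multi-radius spatial-filter occupancy of a signal within a glomerulus.

    For each radius r, square tiles of side 2r anchored at the ROI bounding-box
    origin partition the plane; tiles overlapping the ROI by ≥ 1 pixel form the
    denominator and those containing ≥ 1 signal pixel inside the ROI the
    numerator.  Signal outside the ROI is ignored.  An empty signal yields an
    all-zero curve flagged via ``all_zero``; an empty ROI is an error.
    """
    signal_mask = np.asarray(signal_mask, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if signal_mask.shape != roi.shape:
        raise ValueError("signal mask and ROI must share one shape")
    radii = tuple(int(r) for r in radii_px)
    if any(r <= 0 for r in radii):
        raise ValueError("radii must be positive")
    roi_r, roi_c = np.nonzero(roi)
    if len(roi_r) == 0:
        raise ValueError("empty ROI")
    origin = (int(roi_r.min()), int(roi_c.min()))
    inside = signal_mask & roi
    sig_r, sig_c = np.nonzero(inside)
    occ = []
    for r in radii:
        side = 2 * r
        n_roi = len(_tile_ids(roi_r, roi_c, origin, side))
        n_occ = len(_tile_ids(sig_r, sig_c, origin, side)) if len(sig_r) else 0
        occ.append(100.0 * n_occ / n_roi)
    return OccupancyCurve(radii_px=radii, occupancy_pct=tuple(occ),
                          all_zero=not inside.any())


def compare_occupancy(curves_by_group: dict[str, list[OccupancyCurve]]) -> AnovaResult:
    """Two-way ANOVA on occupancy with factors group and filter radius.

    All curves must share one radii grid.  Returns the group main effect
    (type-II F and p); when the groups are identical the group sum of squares
    is zero and the result is F = 0, p = 1.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if len(curves_by_group) < 2:
        raise ValueError("need at least two groups")
    grids = {c.radii_px for curves in curves_by_group.values() for c in curves}
    if len(grids) != 1:
        raise ValueError("all occupancy curves must share one radii grid")
    rows = [
        {"group": g, "radius": r, "occupancy": o}
        for g, curves in curves_by_group.items()
        for c in curves
        for r, o in zip(c.radii_px, c.occupancy_pct)
    ]
    df = pd.DataFrame(rows)
    fit = smf.ols("occupancy ~ C(group) + C(radius)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    ss_group = float(table.loc["C(group)", "sum_sq"])
    dfb = int(table.loc["C(group)", "df"])
    dfw = int(table.loc["Residual", "df"])
    if ss_group <= 1e-12:
        return AnovaResult(f=0.0, p=1.0, df_between=dfb, df_within=dfw)
    f = float(table.loc["C(group)", "F"])
    p = float(table.loc["C(group)", "PR(>F)"])
    return AnovaResult(f=f, p=p, df_between=dfb, df_within=dfw)


def colocalization_coefficient(reporter_mask: np.ndarray, marker_mask: np.ndarray,
                               roi: np.ndarray) -> float:
    """Percentage of marker-positive pixels within the glomerulus that are also
    reporter-positive: 100 · |reporter ∩ marker ∩ roi| / |marker ∩ roi|."""
    reporter_mask = np.asarray(reporter_mask, dtype=bool)
    marker_mask = np.asarray(marker_mask, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    marker_in = marker_mask & roi
    denom = int(marker_in.sum())
    if denom == 0:
        raise ValueError("no marker-positive pixels inside the ROI; "
                         "colocalization coefficient is undefined")
    return 100.0 * int((reporter_mask & marker_in).sum()) / denom


def count_labeled_glomeruli(field_mask: np.ndarray,
                            min_area_px: int = DEFAULT_MIN_AREA_PX) -> tuple[int, pd.DataFrame]:
    """Count labeled glomeruli in a section field as 8-connected components of
    at least ``min_area_px`` pixels; returns the count and a table of component
    centroids and areas."""
    field_mask = np.asarray(field_mask, dtype=bool)
    lab = label(field_mask, connectivity=2)
    rows = [
        {"label": p.label, "area_px": int(p.area),
         "centroid_row": float(p.centroid[0]), "centroid_col": float(p.centroid[1])}
        for p in regionprops(lab) if p.area >= min_area_px
    ]
    return len(rows), pd.DataFrame(rows, columns=["label", "area_px", "centroid_row", "centroid_col"])


def glomerulus_diameter(roi: np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Equivalent-circle diameter of a glomerulus ROI: 2·√(area/π) scaled by
    the pixel size in microns."""
    roi = np.asarray(roi, dtype=bool)
    area = int(roi.sum())
    if area == 0:
        raise ValueError("empty ROI")
    return float(2.0 * np.sqrt(area / np.pi) * pixel_size_um)
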