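"""pS6 activation-density quantification per brain region.

Odor-evoked activation is mapped by counting phosphorylated-S6 (pS6)
immunopositive neurons in serial sections of valence-associated brain regions,
with the two hemispheres treated as independent samples.  Density for a
region/hemisphere is total count over total sectioned ROI area (cells/mm²), so
it does not depend on how cells happen to be split among sections.

``REGION_SECTIONS`` ships the per-region section counts and bregma ranges used
for the quantification (e.g. AHA: four sections at −0.85 to −1.05 mm from
bregma); deviations from the configured section count warn rather than fail,
since partial series are common in histology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops

from .behavior import AnovaResult, group_anova

__all__ = [
    "REGION_SECTIONS",
    "RegionCounts",
    "count_cells",
    "region_density",
    "compare_activation",
]

# region -> (number of sections, (bregma_min_mm, bregma_max_mm))
REGION_SECTIONS: dict[str, tuple[int, tuple[float, float]]] = {
    "AHA": (4, (-1.05, -0.85)),
    "MePD": (5, (-1.60, -1.35)),
    "MePV": (5, (-1.60, -1.35)),
    "VMHvl": (5, (-1.60, -1.35)),
    "VMH": (4, (-2.00, -1.80)),
    "BST": (3, (0.10, 0.25)),
    "ACo": (4, (-1.20, -1.00)),
    "PLCo": (5, (-1.60, -1.35)),
    "PVA": (4, (-0.45, -0.25)),
    "Pir": (5, (-1.60, -1.35)),
    "BLA": (5, (-1.35, -1.10)),
}


@dataclass
class RegionCounts:
    """Per-section pS6+ cell counts.

    ``sections`` is tidy with columns ``region``, ``hemisphere``, ``bregma_mm``,
    ``count`` and ``area_mm2`` (one row per section per hemisphere).  ``truth``
    carries generator densities for synthetic data.
    """

    sections: pd.DataFrame
    truth: dict | None = None

    def __post_init__(self) -> None:
        needed = {"region", "hemisphere", "bregma_mm", "count", "area_mm2"}
        missing = needed - set(self.sections.columns)
        if missing:
            raise ValueError(f"section table missing columns: {sorted(missing)}")
        if (self.sections["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.sections["area_mm2"] <= 0).any():
            raise ValueError("section areas must be positive")


def count_cells(points_or_mask: np.ndarray, roi: np.ndarray,
                min_area_px: int = 1) -> int:
    """Count cells inside a region ROI.

    Point mode: ``points_or_mask`` is an (n, 2) array of (row, col) pixel
    coordinates; cells whose rounded coordinates fall on ROI pixels are
    counted.  Mask mode: a boolean image; 8-connected components of at least
    ``min_area_px`` pixels whose centroid lies in the ROI are counted.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    arr = np.asarray(points_or_mask)
    if arr.dtype == bool or (arr.ndim == 2 and arr.shape == roi.shape and arr.dtype != float):
        if arr.shape == roi.shape:
            lab = label(np.asarray(arr, dtype=bool), connectivity=2)
            n = 0
            for p in regionprops(lab):
                if p.area < min_area_px:
                    continue
                r, c = (int(round(v)) for v in p.centroid)
                if 0 <= r < roi.shape[0] and 0 <= c < roi.shape[1] and roi[r, c]:
                    n += 1
            return n
    pts = arr.reshape(-1, 2)
    if len(pts) == 0:
        return 0
    rc = np.rint(pts).astype(int)
    ok = (rc[:, 0] >= 0) & (rc[:, 0] < roi.shape[0]) & (rc[:, 1] >= 0) & (rc[:, 1] < roi.shape[1])
    rc = rc[ok]
    return int(roi[rc[:, 0], rc[:, 1]].sum())


def region_density(counts: RegionCounts, check_sections: bool = True) -> pd.DataFrame:
    """Cells/mm² per region and hemisphere: Σcounts / Σareas over sections.

    Warns when a region's section count differs from the configured series
    length in ``REGION_SECTIONS``.
    """
    rows = []
    for (region, hemi), sub in counts.sections.groupby(["region", "hemisphere"]):
        total_area = float(sub["area_mm2"].sum())
        if total_area <= 0:
            raise ValueError(f"zero total area for {region}/{hemi}")
        if check_sections and region in REGION_SECTIONS:
            expected = REGION_SECTIONS[region][0]
            if len(sub) != expected:
                warnings.warn(
                    f"{region}/{hemi}: {len(sub)} sections, expected {expected}"
                )
        rows.append({
            "region": region, "hemisphere": hemi,
            "n_sections": len(sub),
            "total_count": int(sub["count"].sum()),
            "total_area_mm2": total_area,
            "density_cells_per_mm2": float(sub["count"].sum()) / total_area,
        })
    return pd.DataFrame(rows)


def compare_activation(densities_by_group: dict[str, dict[str, list[float]]],
                       posthoc: bool = False) -> dict[str, AnovaResult]:
    """Per-region one-way ANOVA of activation density across stimulus groups.

    ``densities_by_group`` maps group → region → list of per-hemisphere
    densities; every region present in all groups is compared via
    :func:`olfquant.behavior.group_anova`.
    """
    regions = set.intersection(*(set(d) for d in densities_by_group.values()))
    if not regions:
        raise ValueError("no region shared by all groups")
    out: dict[str, AnovaResult] = {}
    for region in sorted(regions):
        values, labels = [], []
        for grp, per_region in densities_by_group.items():
            values.extend(per_region[region])
            labels.extend([grp] * len(per_region[region]))
        out[region] = group_anova(values, labels, posthoc=posthoc)
    return out
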