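"""CTL-to-nearest-tumor-cell distances and the 100 CTL-nT summary statistic.

For each image, every CTL (CD45⁺CD8⁺DAPI⁺ cell, any compartment) is matched to
its nearest CK⁺DAPI⁺ tumor cell by Euclidean centroid-to-centroid distance in
µm, and the statistic is the arithmetic mean of the k = 100 shortest of those
per-CTL distances ("100 CTL-nT"). When an image holds fewer than k CTLs all
distances are used (sparse immunotypes would otherwise be unclassifiable).

Nearest-neighbour queries run on :class:`scipy.spatial.cKDTree`, an exact
structure: results equal the all-pairs brute-force minima bit-for-bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import ImageROI, Sample
from .phenotyping import CTL, TUMOR, PhenotypeStateError

logger = logging.getLogger(__name__)

DEFAULT_K = 100


class NoTumorCellsError(ValueError):
    """The ROI holds CTLs but no tumor cell, so distances are undefined."""


@dataclass
class DistanceResult:
    """Per-CTL nearest-tumor distances and the k-shortest-mean summary."""

    per_ctl: pd.DataFrame        # columns: ctl_id, tumor_id, distance_um
    statistic_um: float          # NaN when no CTL
    k_used: int
    n_ctl: int
    n_tumor: int


def nearest_tumor_distances(roi: ImageROI) -> pd.DataFrame:
    """Nearest tumor-cell distance for every CTL in the ROI.

    Returns a frame with ``ctl_id``, ``tumor_id``, ``distance_um`` (µm),
    empty when the ROI has no CTL. Raises :class:`NoTumorCellsError` when
    CTLs exist but no tumor cell does.
    """
    t = roi.table
    if len(t) and t["phenotype"].isna().any():
        raise PhenotypeStateError(f"ROI {roi.image_id} contains unphenotyped cells")
    ctl = t[t["phenotype"] == CTL]
    tumor = t[t["phenotype"] == TUMOR]
    if len(ctl) == 0:
        return pd.DataFrame(columns=["ctl_id", "tumor_id", "distance_um"])
    if len(tumor) == 0:
        raise NoTumorCellsError(
            f"ROI {roi.image_id}: {len(ctl)} CTL but no tumor cell")
    tree = cKDTree(tumor[["x_um", "y_um"]].to_numpy())
    dist, idx = tree.query(ctl[["x_um", "y_um"]].to_numpy(), k=1)
    return pd.DataFrame({
        "ctl_id": ctl["cell_id"].to_numpy(),
        "tumor_id": tumor["cell_id"].to_numpy()[idx],
        "distance_um": dist,
    })


def ctl_nt_statistic(distances, k: int = DEFAULT_K) -> tuple[float, int]:
    """Mean of the ``min(k, n)`` shortest distances; ``(nan, 0)`` when n = 0."""
    d = np.sort(np.asarray(distances, dtype=float))
    if d.size == 0:
        return math.nan, 0
    k_used = min(int(k), d.size)
    return float(d[:k_used].mean()), k_used


def roi_ctl_nt(roi: ImageROI, k: int = DEFAULT_K) -> DistanceResult:
    """Distances plus the k-shortest-mean statistic for one ROI."""
    t = roi.table
    n_tumor = int((t["phenotype"] == TUMOR).sum()) if len(t) else 0
    per_ctl = nearest_tumor_distances(roi)
    stat, k_used = ctl_nt_statistic(per_ctl["distance_um"].to_numpy(), k=k)
    return DistanceResult(per_ctl=per_ctl, statistic_um=stat, k_used=k_used,
                          n_ctl=len(per_ctl), n_tumor=n_tumor)


def sample_ctl_nt(sample: Sample, k: int = DEFAULT_K,
                  image_aggregation: str = "mean") -> float:
    """Per-sample CTL-nT statistic: mean (or median) across defined images.

    Images where the statistic is undefined (no CTL, or no tumor cell) are
    skipped with a warning; NaN when no image yields a defined statistic.
    """
    if image_aggregation not in ("mean", "median"):
        raise ValueError(f"unknown image_aggregation {image_aggregation!r}")
    stats = []
    for roi in sample.images:
        try:
            res = roi_ctl_nt(roi, k=k)
        except NoTumorCellsError:
            logger.warning("sample %s image %s: no tumor cells; statistic skipped",
                           sample.sample_id, roi.image_id)
            continue
        if math.isnan(res.statistic_um):
            logger.warning("sample %s image %s: no CTL; statistic skipped",
                           sample.sample_id, roi.image_id)
            continue
        stats.append(res.statistic_um)
    if not stats:
        return math.nan
    agg = np.mean if image_aggregation == "mean" else np.median
    return float(agg(stats))
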