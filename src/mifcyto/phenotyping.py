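"""Deterministic marker-gated phenotyping of segmented cells.

The gating lattice mirrors standard mIF immune phenotyping of tumor tissue:

* CD45⁻CK⁺          → Tumor (Tu)
* CD45⁺CD8⁺          → cytotoxic T lymphocyte (CTL)
* CD45⁺CD4⁺Foxp3⁻    → conventional CD4 T cell (Tcon)
* CD45⁺CD4⁺Foxp3⁺    → regulatory T cell (Treg)
* CD45⁺CD68⁺CD163⁻   → M1-like macrophage
* CD45⁺CD68⁺CD163⁺   → M2-like macrophage
* CD45⁺CD66b⁺        → neutrophil (Neu)
* remaining CD45⁺    → non-T, non-myeloid leukocyte (OtherLeu)
* CD45⁻CK⁻           → Unclassified (excluded from all denominators)

Multi-lineage marker conflicts are resolved with a fixed precedence — T-cell
markers outrank myeloid markers outrank CD66b, and CD45 dominates CK — so the
assignment is total and deterministic; CD45⁺CK⁺ anomalies are counted and
logged. Checkpoint positivity (PD-1 on T cells, PD-L1 on tumor cells and
macrophages) is carried per cell and interpreted only on the relevant lineages.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .model import MARKERS, ImageROI, Sample, SchemaError

logger = logging.getLogger(__name__)

# base labels (mutually exclusive)
TUMOR = "Tumor"
CTL = "CTL"
TCON = "Tcon"
TREG = "Treg"
M1 = "M1"
M2 = "M2"
NEU = "Neu"
OTHER_LEU = "OtherLeu"
UNCLASSIFIED = "Unclassified"

BASE_LABELS: tuple[str, ...] = (TUMOR, CTL, TCON, TREG, M1, M2, NEU,
                                OTHER_LEU, UNCLASSIFIED)

#: Derived groups as unions of base labels.
GROUPS: dict[str, tuple[str, ...]] = {
    "Leu": (CTL, TCON, TREG, M1, M2, NEU, OTHER_LEU),
    "panM": (M1, M2),
    "C_Tcon": (CTL, TCON),
    "allT": (CTL, TCON, TREG),
}

#: Labels on which PD-1 / PD-L1 positivity is interpretable.
PD1_LABELS = (CTL, TCON, TREG)
PDL1_LABELS = (TUMOR, M1, M2)


class PhenotypeStateError(RuntimeError):
    """An operation required phenotyped cells but found unassigned ones."""


def assign_phenotype(markers: Mapping[str, bool]) -> str:
    """Gate a single cell's marker calls into exactly one base label."""
    missing = [m for m in MARKERS if m not in markers]
    if missing:
        raise SchemaError(f"marker mapping missing key(s): {', '.join(missing)}")
    if not markers["DAPI"]:
        raise ValueError("cell is DAPI-negative; not an analyzable cell")
    if markers["CD45"]:
        if markers["CK"]:
            logger.debug("CD45+CK+ double positive resolved as leukocyte")
        if markers["CD8"]:
            return CTL
        if markers["CD4"]:
            return TREG if markers["Foxp3"] else TCON
        if markers["CD68"]:
            return M2 if markers["CD163"] else M1
        if markers["CD66b"]:
            return NEU
        return OTHER_LEU
    if markers["CK"]:
        return TUMOR
    return UNCLASSIFIED


def assign_phenotypes(table: pd.DataFrame) -> pd.Series:
    """Vectorised gating over a cell table; returns the label per row."""
    missing = [m for m in MARKERS if m not in table.columns]
    if missing:
        raise SchemaError(f"cell table missing marker(s): {', '.join(missing)}")
    if len(table) == 0:
        return pd.Series([], dtype=object)
    if not table["DAPI"].all():
        bad = table.loc[~table["DAPI"]].index[0]
        raise ValueError(f"DAPI-negative cell at row {bad}")
    cd45 = table["CD45"].to_numpy()
    ck = table["CK"].to_numpy()
    cd4 = table["CD4"].to_numpy()
    cd8 = table["CD8"].to_numpy()
    foxp3 = table["Foxp3"].to_numpy()
    cd68 = table["CD68"].to_numpy()
    cd163 = table["CD163"].to_numpy()
    cd66b = table["CD66b"].to_numpy()

    n_anom = int((cd45 & ck).sum())
    if n_anom:
        logger.warning("%d CD45+CK+ double-positive cell(s) resolved as leukocytes",
                       n_anom)

    label = np.select(
        [
            cd45 & cd8,
            cd45 & cd4 & ~foxp3,
            cd45 & cd4 & foxp3,
            cd45 & cd68 & ~cd163,
            cd45 & cd68 & cd163,
            cd45 & cd66b,
            cd45,
            ~cd45 & ck,
        ],
        [CTL, TCON, TREG, M1, M2, NEU, OTHER_LEU, TUMOR],
        default=UNCLASSIFIED,
    )
    return pd.Series(label, index=table.index, dtype=object)


def phenotype_roi(roi: ImageROI) -> ImageROI:
    """Return a copy of the ROI with the phenotype column assigned."""
    out = roi.copy()
    out.table["phenotype"] = assign_phenotypes(out.table)
    return out


def phenotype_sample(sample: Sample) -> Sample:
    return Sample(sample.sample_id, [phenotype_roi(r) for r in sample.images],
                  clinical=sample.clinical)


def annotate_checkpoint(cell) -> dict[str, bool]:
    """Checkpoint status of a phenotyped cell.

    PD-1 is interpretable on T-cell labels, PD-L1 on Tumor/M1/M2; the raw flags
    are carried regardless, and the ``*_interpretable`` fields say whether the
    flag enters any panel parameter.
    """
    if cell.phenotype is None:
        raise PhenotypeStateError(f"cell {cell.cell_id} has no phenotype")
    return {
        "pd1_positive": bool(cell.markers["PD1"]),
        "pdl1_positive": bool(cell.markers["PDL1"]),
        "pd1_interpretable": cell.phenotype in PD1_LABELS,
        "pdl1_interpretable": cell.phenotype in PDL1_LABELS,
    }


#: Checkpoint-positive count keys produced by :func:`phenotype_counts`.
CHECKPOINT_COUNT_KEYS = ("PD1_CTL", "PD1_Tcon", "PD1_Treg", "PD1_allT",
                         "PDL1_Tu", "PDL1_M1", "PDL1_M2", "PDL1_panM")


def phenotype_counts(roi: ImageROI, compartment_filter: str | None = None
                     ) -> dict[str, int]:
    """Count base labels, derived groups, and checkpoint-positive cells.

    Counts partition the (optionally compartment-filtered) DAPI⁺ cells; group
    counts are sums of their member labels.
    """
    t = roi.table
    if len(t) and t["phenotype"].isna().any():
        raise PhenotypeStateError(
            f"ROI {roi.image_id} contains unphenotyped cells")
    if compartment_filter is not None:
        t = t[t["compartment"] == compartment_filter]
    counts = {lab: 0 for lab in BASE_LABELS}
    if len(t):
        vc = t["phenotype"].value_counts()
        for lab, n in vc.items():
            counts[lab] = int(n)
    for g, members in GROUPS.items():
        counts[g] = sum(counts[m] for m in members)
    pd1 = t["PD1"] if len(t) else pd.Series(dtype=bool)
    pdl1 = t["PDL1"] if len(t) else pd.Series(dtype=bool)
    ph = t["phenotype"] if len(t) else pd.Series(dtype=object)
    def _n(mask) -> int:
        return int(mask.sum()) if len(t) else 0
    counts["PD1_CTL"] = _n(pd1 & (ph == CTL))
    counts["PD1_Tcon"] = _n(pd1 & (ph == TCON))
    counts["PD1_Treg"] = _n(pd1 & (ph == TREG))
    counts["PD1_allT"] = counts["PD1_CTL"] + counts["PD1_Tcon"] + counts["PD1_Treg"]
    counts["PDL1_Tu"] = _n(pdl1 & (ph == TUMOR))
    counts["PDL1_M1"] = _n(pdl1 & (ph == M1))
    counts["PDL1_M2"] = _n(pdl1 & (ph == M2))
    counts["PDL1_panM"] = counts["PDL1_M1"] + counts["PDL1_M2"]
    return counts


def gating_table() -> pd.DataFrame:
    """The gating rules in application order, exportable as an audit CSV."""
    rows = [
        (1, "CD45+ CD8+", CTL),
        (2, "CD45+ CD4+ Foxp3-", TCON),
        (3, "CD45+ CD4+ Foxp3+", TREG),
        (4, "CD45+ CD68+ CD163-", M1),
        (5, "CD45+ CD68+ CD163+", M2),
        (6, "CD45+ CD66b+", NEU),
        (7, "CD45+ (remaining)", OTHER_LEU),
        (8, "CD45- CK+", TUMOR),
        (9, "CD45- CK-", UNCLASSIFIED),
    ]
    return pd.DataFrame(rows, columns=["rule", "marker_pattern", "label"])
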