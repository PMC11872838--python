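"""Cell-level data model and file I/O for multiplex-immunofluorescence cell tables.

The pipeline starts downstream of image analysis: its inputs are per-image
cell-segmentation tables (one row per nucleated cell with a centroid position in
micrometres, boolean positivity calls for eleven markers, and a tumor-nest /
stroma compartment label) plus per-image region areas in mm² carried in a
metadata sidecar. Intensity thresholding and tissue segmentation are upstream
concerns and are consumed as given.

Tables are held as :class:`pandas.DataFrame` objects inside :class:`ImageROI`
so that million-cell cohorts stay vectorised; :class:`Cell` is the ergonomic
single-cell view used for construction and inspection.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Marker panel, in canonical column order. PD1/PDL1 are the checkpoint
#: receptor/ligand; DAPI marks a nucleated (analyzable) cell.
MARKERS: tuple[str, ...] = (
    "CD45", "CK", "CD4", "CD8", "Foxp3",
    "CD68", "CD163", "CD66b", "PD1", "PDL1", "DAPI",
)

TUMOR_NEST = "tumor_nest"
STROMA = "stroma"
COMPARTMENTS = (TUMOR_NEST, STROMA)

UM2_PER_MM2 = 1_000_000.0  # exact

#: Canonical cell-table column order (phenotype appended when assigned).
CELL_COLUMNS: tuple[str, ...] = ("cell_id", "x_um", "y_um", "compartment") + MARKERS


class CellTableError(Exception):
    """Base class for cell-table I/O failures."""


class SchemaError(CellTableError):
    """A required column (or column value vocabulary) is missing or unusable."""


class ParseError(CellTableError):
    """A cell value could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"{message} (row {row})")
        self.row = row


class ROIValidationError(CellTableError):
    """An ImageROI violates a structural invariant."""


@dataclass
class Cell:
    """One segmented cell: centroid position, marker calls, compartment."""

    cell_id: str
    x_um: float
    y_um: float
    markers: dict[str, bool]
    compartment: str
    phenotype: str | None = None


def _empty_table() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in CELL_COLUMNS})
    df["x_um"] = df["x_um"].astype(float)
    df["y_um"] = df["y_um"].astype(float)
    for m in MARKERS:
        df[m] = df[m].astype(bool)
    return df


def _normalize_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table missing column(s): {', '.join(missing)}")
    out = df.copy()
    out["cell_id"] = out["cell_id"].astype(str)
    out["x_um"] = out["x_um"].astype(float)
    out["y_um"] = out["y_um"].astype(float)
    out["compartment"] = out["compartment"].astype(str)
    for m in MARKERS:
        out[m] = out[m].astype(bool)
    if "phenotype" not in out.columns:
        out["phenotype"] = pd.Series([None] * len(out), dtype=object)
    cols = list(CELL_COLUMNS) + ["phenotype"]
    extra = [c for c in out.columns if c not in cols]
    return out[cols + extra].reset_index(drop=True)


@dataclass
class ImageROI:
    """One imaged field: a cell table plus compartment areas and extents.

    ``stroma_area_mm2`` is the density denominator for every stromal immune
    parameter and must be positive; ``tumor_area_mm2`` may be zero (no nest in
    the field). Extents bound the cell positions (image convention: origin at
    the top-left corner, y increasing downward).
    """

    image_id: str
    sample_id: str
    table: pd.DataFrame
    stroma_area_mm2: float
    tumor_area_mm2: float
    field_width_um: float
    field_height_um: float

    def __post_init__(self) -> None:
        if len(self.table.columns) == 0 and len(self.table) == 0:
            self.table = _empty_table()
        self.table = _normalize_table(self.table)

    # -- convenience views -------------------------------------------------
    @classmethod
    def from_cells(
        cls,
        cells: Iterable[Cell],
        *,
        image_id: str,
        sample_id: str,
        stroma_area_mm2: float,
        tumor_area_mm2: float = 0.0,
        field_width_um: float,
        field_height_um: float,
    ) -> "ImageROI":
        rows = []
        for c in cells:
            row = {"cell_id": c.cell_id, "x_um": c.x_um, "y_um": c.y_um,
                   "compartment": c.compartment, "phenotype": c.phenotype}
            missing = [m for m in MARKERS if m not in c.markers]
            if missing:
                raise SchemaError(
                    f"cell {c.cell_id} missing marker(s): {', '.join(missing)}")
            row.update({m: bool(c.markers[m]) for m in MARKERS})
            rows.append(row)
        df = pd.DataFrame(rows) if rows else _empty_table()
        return cls(image_id=image_id, sample_id=sample_id, table=df,
                   stroma_area_mm2=stroma_area_mm2, tumor_area_mm2=tumor_area_mm2,
                   field_width_um=field_width_um, field_height_um=field_height_um)

    @property
    def n_cells(self) -> int:
        return len(self.table)

    @property
    def cells(self) -> list[Cell]:
        """Materialise the table as Cell objects (small-ROI convenience)."""
        return list(self.iter_cells())

    def iter_cells(self) -> Iterator[Cell]:
        for row in self.table.itertuples(index=False):
            d = row._asdict()
            yield Cell(
                cell_id=d["cell_id"], x_um=d["x_um"], y_um=d["y_um"],
                markers={m: bool(d[m]) for m in MARKERS},
                compartment=d["compartment"], phenotype=d["phenotype"],
            )

    def copy(self) -> "ImageROI":
        return ImageROI(self.image_id, self.sample_id, self.table.copy(),
                        self.stroma_area_mm2, self.tumor_area_mm2,
                        self.field_width_um, self.field_height_um)


@dataclass
class Sample:
    """Per-patient aggregation unit: one or more imaged fields."""

    sample_id: str
    images: list[ImageROI]
    clinical: Mapping[str, object] | None = None

    def __post_init__(self) -> None:
        if not self.images:
            raise ROIValidationError(f"sample {self.sample_id} has no images")
        bad = [r.image_id for r in self.images if r.sample_id != self.sample_id]
        if bad:
            raise ROIValidationError(
                f"sample {self.sample_id}: images with foreign sample_id: {bad}")


# ---------------------------------------------------------------------------
# validation

def validate_roi(roi: ImageROI) -> list[str]:
    """Report every structural-invariant violation of an ROI (empty = valid)."""
    violations: list[str] = []
    t = roi.table
    if roi.stroma_area_mm2 <= 0:
        violations.append(
            f"stroma_area: stroma_area_mm2 must be > 0, got {roi.stroma_area_mm2}")
    if roi.tumor_area_mm2 < 0:
        violations.append(
            f"tumor_area: tumor_area_mm2 must be >= 0, got {roi.tumor_area_mm2}")
    field_mm2 = roi.field_width_um * roi.field_height_um / UM2_PER_MM2
    if roi.stroma_area_mm2 + max(roi.tumor_area_mm2, 0.0) > field_mm2 * (1 + 1e-9):
        violations.append(
            "areas: stroma_area_mm2 + tumor_area_mm2 exceeds the field area "
            f"({roi.stroma_area_mm2 + roi.tumor_area_mm2:.6g} > {field_mm2:.6g} mm²)")
    if len(t):
        finite = np.isfinite(t["x_um"].to_numpy()) & np.isfinite(t["y_um"].to_numpy())
        for cid in t.loc[~finite, "cell_id"]:
            violations.append(f"cell {cid}: non-finite position")
        in_x = (t["x_um"] >= 0) & (t["x_um"] <= roi.field_width_um)
        in_y = (t["y_um"] >= 0) & (t["y_um"] <= roi.field_height_um)
        for cid in t.loc[finite & ~(in_x & in_y), "cell_id"]:
            violations.append(f"cell {cid}: position outside field extents")
        for cid in t.loc[~t["DAPI"], "cell_id"]:
            violations.append(f"cell {cid}: DAPI negative (not an analyzable cell)")
        bad_comp = ~t["compartment"].isin(COMPARTMENTS)
        for cid in t.loc[bad_comp, "cell_id"]:
            violations.append(f"cell {cid}: unknown compartment")
    return violations


# ---------------------------------------------------------------------------
# parsing helpers

_TRUE = {"1", "true", "t", "yes", "y", "+", "pos", "positive"}
_FALSE = {"0", "false", "f", "no", "n", "-", "neg", "negative", ""}


def _parse_bool_column(series: pd.Series, colname: str) -> pd.Series:
    vals = series.astype(str).str.strip().str.lower()
    ok_true = vals.isin(_TRUE)
    ok_false = vals.isin(_FALSE)
    bad = ~(ok_true | ok_false)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ParseError(
            f"column {colname}: unrecognised positivity value "
            f"{series[bad].iloc[0]!r}", row=row)
    return ok_true


def _parse_float_column(series: pd.Series, colname: str) -> pd.Series:
    vals = series.astype(str).str.strip()
    # locale guard: decimal comma is rejected loudly rather than silently read
    out = pd.to_numeric(vals, errors="coerce")
    bad = out.isna() & vals.ne("")
    if bad.any() or out.isna().any():
        idx = int(np.flatnonzero((out.isna()).to_numpy())[0])
        raise ParseError(
            f"column {colname}: non-numeric coordinate {series.iloc[idx]!r} "
            "(decimal comma is not accepted)", row=idx + 2)
    return out.astype(float)


def _norm_header(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", name.lower())


_INFORM_MARKER_KEYS = {m: _norm_header(m) for m in MARKERS}


@dataclass
class ROIMetadata:
    """Sidecar record carrying per-image areas and extents."""

    image_id: str
    sample_id: str
    stroma_area_mm2: float
    tumor_area_mm2: float
    field_width_um: float
    field_height_um: float


METADATA_COLUMNS = ("image_id", "sample_id", "stroma_area_mm2",
                    "tumor_area_mm2", "field_width_um", "field_height_um")


def read_metadata_sidecar(path: str | Path) -> dict[str, ROIMetadata]:
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata sidecar missing column(s): {', '.join(missing)}")
    out: dict[str, ROIMetadata] = {}
    for row in df.itertuples(index=False):
        md = ROIMetadata(str(row.image_id), str(row.sample_id),
                         float(row.stroma_area_mm2), float(row.tumor_area_mm2),
                         float(row.field_width_um), float(row.field_height_um))
        out[md.image_id] = md
    return out


def write_metadata_sidecar(rois: Sequence[ImageROI], path: str | Path) -> None:
    rows = [{"image_id": r.image_id, "sample_id": r.sample_id,
             "stroma_area_mm2": r.stroma_area_mm2, "tumor_area_mm2": r.tumor_area_mm2,
             "field_width_um": r.field_width_um, "field_height_um": r.field_height_um}
            for r in rois]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, index=False)


def read_cell_table(
    path: str | Path,
    dialect: str = "canonical",
    *,
    metadata: ROIMetadata | str | Path | None = None,
    image_id: str | None = None,
    sample_id: str | None = None,
    stroma_area_mm2: float | None = None,
    tumor_area_mm2: float = 0.0,
    field_width_um: float | None = None,
    field_height_um: float | None = None,
) -> ImageROI:
    """Read one per-image cell table into a validated :class:`ImageROI`.

    ``dialect="canonical"`` expects the package's own column layout;
    ``dialect="inform_like"`` tolerates tables in the style of commercial
    imaging-software exports ("Cell X Position", "Tissue Category", per-marker
    positivity columns, tab or comma separated, quoted headers).

    Region areas are not inferable from cell positions without changing the
    densities, so they must arrive via ``metadata`` (a sidecar CSV path or
    :class:`ROIMetadata`) or the explicit keyword arguments.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if isinstance(metadata, (str, Path)):
        table = read_metadata_sidecar(metadata)
        key = image_id if image_id is not None else path.stem
        if key not in table:
            raise SchemaError(f"metadata sidecar has no row for image {key!r}")
        metadata = table[key]
    if isinstance(metadata, ROIMetadata):
        image_id = image_id or metadata.image_id
        sample_id = sample_id or metadata.sample_id
        stroma_area_mm2 = metadata.stroma_area_mm2
        tumor_area_mm2 = metadata.tumor_area_mm2
        field_width_um = metadata.field_width_um
        field_height_um = metadata.field_height_um
    if stroma_area_mm2 is None:
        raise SchemaError("stroma_area_mm2 must be supplied (sidecar or argument)")
    if stroma_area_mm2 <= 0:
        raise ROIValidationError(f"stroma_area_mm2 must be > 0, got {stroma_area_mm2}")

    if dialect == "canonical":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in CELL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"cell table missing column(s): {', '.join(missing)}")
        out = pd.DataFrame({
            "cell_id": df["cell_id"].astype(str),
            "x_um": _parse_float_column(df["x_um"], "x_um"),
            "y_um": _parse_float_column(df["y_um"], "y_um"),
            "compartment": df["compartment"].astype(str).str.strip(),
        })
        for m in MARKERS:
            out[m] = _parse_bool_column(df[m], m)
        if "phenotype" in df.columns:
            ph = df["phenotype"].astype(str).str.strip()
            out["phenotype"] = ph.where(ph.ne(""), None)
    elif dialect == "inform_like":
        df = pd.read_csv(path, dtype=str, keep_default_na=False,
                         sep=None, engine="python")
        norm = {_norm_header(c): c for c in df.columns}
        def find(*cands: str) -> str | None:
            for c in cands:
                if c in norm:
                    return norm[c]
            return None
        xcol = find("cellxposition", "xposition", "xum", "x")
        ycol = find("cellyposition", "yposition", "yum", "y")
        tcol = find("tissuecategory", "compartment")
        if xcol is None or ycol is None:
            raise SchemaError("inform_like table missing Cell X/Y Position columns")
        if tcol is None:
            raise SchemaError("inform_like table missing Tissue Category column")
        idcol = find("cellid", "objectid")
        marker_cols: dict[str, str] = {}
        for m, key in _INFORM_MARKER_KEYS.items():
            exact = norm.get(key)
            if exact is not None:
                marker_cols[m] = exact
                continue
            hits = [c for k, c in norm.items()
                    if key in k and ("positiv" in k or k == key)]
            if not hits:
                hits = [c for k, c in norm.items() if key in k]
            # avoid CD4 matching CD45/CD45-derived headers
            hits = [c for c in hits
                    if not any(_norm_header(c).find(other) >= 0
                               for o, other in _INFORM_MARKER_KEYS.items()
                               if o != m and len(other) > len(key))]
            if not hits:
                raise SchemaError(f"{m}")
            marker_cols[m] = hits[0]
        tissue = df[tcol].astype(str).str.strip().str.lower()
        comp = pd.Series(np.where(tissue.str.contains("tumor"), TUMOR_NEST,
                                  np.where(tissue.str.contains("stroma"), STROMA, "")),
                         index=df.index)
        if (comp == "").any():
            bad = tissue[comp == ""].iloc[0]
            raise SchemaError(f"unrecognised Tissue Category value {bad!r}")
        out = pd.DataFrame({
            "cell_id": (df[idcol].astype(str) if idcol is not None
                        else pd.Series(np.arange(len(df)).astype(str), index=df.index)),
            "x_um": _parse_float_column(df[xcol], xcol),
            "y_um": _parse_float_column(df[ycol], ycol),
            "compartment": comp,
        })
        for m in MARKERS:
            out[m] = _parse_bool_column(df[marker_cols[m]], marker_cols[m])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if field_width_um is None:
        field_width_um = float(out["x_um"].max()) if len(out) else 0.0
    if field_height_um is None:
        field_height_um = float(out["y_um"].max()) if len(out) else 0.0

    return ImageROI(
        image_id=image_id or path.stem,
        sample_id=sample_id or (image_id or path.stem),
        table=out,
        stroma_area_mm2=float(stroma_area_mm2),
        tumor_area_mm2=float(tumor_area_mm2),
        field_width_um=float(field_width_um),
        field_height_um=float(field_height_um),
    )


def write_cell_table(roi: ImageROI, path: str | Path) -> None:
    """Write the canonical-dialect CSV; read∘write is the identity on fields."""
    df = roi.table.copy()
    out = df[list(CELL_COLUMNS)].copy()
    for m in MARKERS:
        out[m] = df[m].astype(int)
    if df["phenotype"].notna().any():
        out["phenotype"] = df["phenotype"]
    out.to_csv(path, index=False)
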