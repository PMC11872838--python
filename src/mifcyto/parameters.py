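"""Per-sample immune-parameter panel: densities, percentages, fractions, ratios.

Every stromal immune parameter is a pooled count over a sample's images divided
by the pooled stromal area (ratio of sums — robust to unequal field areas); the
tumor-cell density uses tumor-nest counts over the pooled nest area. Leukocyte
percentages are fractions of the CD45⁺CK⁻ leukocyte count, checkpoint fractions
are PD-1⁺/PD-L1⁺ shares of their parent subset, and undefined quantities (zero
denominators) are encoded as NaN — missing, never zero.

The full 58-entry parameter registry is a reconstruction of the published axis
set (the original enumeration is defined in prior work and not restated): the
named densities/percentages/fractions plus checkpoint %-of-leukocyte and ratio
expansions, and the 100 CTL-nT distance. It is user-editable via YAML.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .model import STROMA, TUMOR_NEST, Sample
from .phenotyping import phenotype_counts
from .spatial import DEFAULT_K, sample_ctl_nt

#: Stromal density panel keys → the count key they are computed from.
DENSITY_KEYS: dict[str, str] = {
    "Leu_D": "Leu", "CTL_D": "CTL", "Tcon_D": "Tcon", "Treg_D": "Treg",
    "allT_D": "allT", "C_Tcon_D": "C_Tcon", "panM_D": "panM", "M1_D": "M1",
    "M2_D": "M2", "Neu_D": "Neu", "OtherLeu_D": "OtherLeu",
    "PD1_CTL_D": "PD1_CTL", "PD1_Tcon_D": "PD1_Tcon", "PD1_Treg_D": "PD1_Treg",
    "PD1_allT_D": "PD1_allT", "PDL1_panM_D": "PDL1_panM",
    "PDL1_M1_D": "PDL1_M1", "PDL1_M2_D": "PDL1_M2",
}

#: %-of-leukocyte panel keys.
LEU_PCT_KEYS: dict[str, str] = {
    "CTL_pct": "CTL", "Tcon_pct": "Tcon", "Treg_pct": "Treg",
    "allT_pct": "allT", "C_Tcon_pct": "C_Tcon", "panM_pct": "panM",
    "M1_pct": "M1", "M2_pct": "M2", "Neu_pct": "Neu", "OtherLeu_pct": "OtherLeu",
}

#: Subset-fraction keys → (numerator count, denominator count).
FRACTION_KEYS: dict[str, tuple[str, str]] = {
    "PD1_pct_CTL": ("PD1_CTL", "CTL"),
    "PD1_pct_Tcon": ("PD1_Tcon", "Tcon"),
    "PD1_pct_Treg": ("PD1_Treg", "Treg"),
    "PD1_pct_allT": ("PD1_allT", "allT"),
    "PDL1_pct_Tu": ("PDL1_Tu", "Tumor"),
    "PDL1_pct_panM": ("PDL1_panM", "panM"),
    "PDL1_pct_M1": ("PDL1_M1", "M1"),
    "PDL1_pct_M2": ("PDL1_M2", "M2"),
    "M1_pct_panM": ("M1", "panM"),
    "M2_pct_panM": ("M2", "panM"),
}


def density(count: int, area_mm2: float) -> float:
    """Cells per mm²: ``count / area_mm2`` exactly."""
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    if not area_mm2 > 0:
        raise ValueError(f"area_mm2 must be positive, got {area_mm2}")
    return count / area_mm2


def checkpoint_fractions(counts: dict[str, int]) -> dict[str, float]:
    """Subset fractions in percent; NaN (missing) when the parent count is 0."""
    out: dict[str, float] = {}
    for name, (num, den) in FRACTION_KEYS.items():
        d = counts.get(den, 0)
        out[name] = 100.0 * counts.get(num, 0) / d if d > 0 else math.nan
    return out


@dataclass
class SampleProfile:
    """Per-patient parameter vector over the stromal invasive-front fields."""

    sample_id: str
    densities: dict[str, float]
    leu_percent: dict[str, float]
    fractions: dict[str, float]
    ratios: dict[str, float]
    ctl_nt_um: float
    n_images: int

    def get(self, name: str) -> float:
        """Registry-style access to any panel entry by parameter name."""
        return parameter_value(self, name)


def compute_profile(sample: Sample, aggregation: str = "pooled",
                    k: int = DEFAULT_K,
                    image_aggregation: str = "mean") -> SampleProfile:
    """Compute the full parameter panel for one (phenotyped) sample.

    ``aggregation="pooled"`` (default) divides pooled counts by pooled areas;
    ``"mean_of_images"`` averages per-image densities instead (percentages and
    fractions always come from pooled counts).
    """
    if aggregation not in ("pooled", "mean_of_images"):
        raise ValueError(f"unknown aggregation {aggregation!r}")

    stroma_counts: list[dict[str, int]] = []
    nest_counts: list[dict[str, int]] = []
    stroma_areas: list[float] = []
    tumor_areas: list[float] = []
    for roi in sample.images:
        stroma_counts.append(phenotype_counts(roi, compartment_filter=STROMA))
        nest_counts.append(phenotype_counts(roi, compartment_filter=TUMOR_NEST))
        stroma_areas.append(roi.stroma_area_mm2)
        tumor_areas.append(roi.tumor_area_mm2)

    pooled_stroma_area = float(sum(stroma_areas))
    pooled_tumor_area = float(sum(tumor_areas))
    if not pooled_stroma_area > 0:
        raise ValueError(f"sample {sample.sample_id}: pooled stromal area is zero")

    keys = stroma_counts[0].keys()
    pooled = {key: sum(c[key] for c in stroma_counts) for key in keys}
    pooled_nest = {key: sum(c[key] for c in nest_counts) for key in keys}
    # checkpoint fractions use the compartment where the parent is quantified:
    # stromal leukocyte subsets, tumor-nest tumor cells
    frac_counts = dict(pooled)
    frac_counts["Tumor"] = pooled_nest["Tumor"]
    frac_counts["PDL1_Tu"] = pooled_nest["PDL1_Tu"]

    densities: dict[str, float] = {}
    if aggregation == "pooled":
        for name, key in DENSITY_KEYS.items():
            densities[name] = density(pooled[key], pooled_stroma_area)
        if pooled_tumor_area > 0:
            densities["Tu_D"] = density(pooled_nest["Tumor"], pooled_tumor_area)
            densities["PDL1_Tu_D"] = density(pooled_nest["PDL1_Tu"],
                                             pooled_tumor_area)
        else:
            densities["Tu_D"] = math.nan
            densities["PDL1_Tu_D"] = math.nan
    else:
        for name, key in DENSITY_KEYS.items():
            densities[name] = float(np.mean(
                [density(c[key], a) for c, a in zip(stroma_counts, stroma_areas)]))
        per_img_tu = [(c, a) for c, a in zip(nest_counts, tumor_areas) if a > 0]
        if per_img_tu:
            densities["Tu_D"] = float(np.mean(
                [density(c["Tumor"], a) for c, a in per_img_tu]))
            densities["PDL1_Tu_D"] = float(np.mean(
                [density(c["PDL1_Tu"], a) for c, a in per_img_tu]))
        else:
            densities["Tu_D"] = math.nan
            densities["PDL1_Tu_D"] = math.nan

    leu = pooled["Leu"]
    leu_percent = {
        name: (100.0 * pooled[key] / leu if leu > 0 else math.nan)
        for name, key in LEU_PCT_KEYS.items()
    }
    fractions = checkpoint_fractions(frac_counts)

    p1c, p1t = pooled["PD1_CTL"], pooled["PD1_Treg"]
    ratios = {"PD1CTL_over_PD1Treg": (p1c / p1t if p1t > 0 else math.nan)}

    ctl_nt = sample_ctl_nt(sample, k=k, image_aggregation=image_aggregation)

    return SampleProfile(
        sample_id=sample.sample_id, densities=densities,
        leu_percent=leu_percent, fractions=fractions, ratios=ratios,
        ctl_nt_um=ctl_nt, n_images=len(sample.images),
    )


# ---------------------------------------------------------------------------
# parameter registry (58-entry reconstruction of the published axis set)

def _ratio(num: float, den: float) -> float:
    if den is None or not np.isfinite(den) or den == 0:
        return math.nan
    return num / den


_DERIVED = {
    # checkpoint-positive subsets as % of leukocytes
    "PD1_CTL_pct": lambda p: _ratio(100 * p.densities["PD1_CTL_D"], p.densities["Leu_D"]),
    "PD1_Tcon_pct": lambda p: _ratio(100 * p.densities["PD1_Tcon_D"], p.densities["Leu_D"]),
    "PD1_Treg_pct": lambda p: _ratio(100 * p.densities["PD1_Treg_D"], p.densities["Leu_D"]),
    "PD1_allT_pct": lambda p: _ratio(100 * p.densities["PD1_allT_D"], p.densities["Leu_D"]),
    "PDL1_panM_pct": lambda p: _ratio(100 * p.densities["PDL1_panM_D"], p.densities["Leu_D"]),
    "PDL1_M1_pct": lambda p: _ratio(100 * p.densities["PDL1_M1_D"], p.densities["Leu_D"]),
    "PDL1_M2_pct": lambda p: _ratio(100 * p.densities["PDL1_M2_D"], p.densities["Leu_D"]),
    # subset balance ratios
    "CTL_over_Treg": lambda p: _ratio(p.densities["CTL_D"], p.densities["Treg_D"]),
    "C_Tcon_over_Treg": lambda p: _ratio(p.densities["C_Tcon_D"], p.densities["Treg_D"]),
    "M1_over_M2": lambda p: _ratio(p.densities["M1_D"], p.densities["M2_D"]),
    "CTL_over_panM": lambda p: _ratio(p.densities["CTL_D"], p.densities["panM_D"]),
    "Treg_over_panM": lambda p: _ratio(p.densities["Treg_D"], p.densities["panM_D"]),
    "panM_over_allT": lambda p: _ratio(p.densities["panM_D"], p.densities["allT_D"]),
    "Neu_over_allT": lambda p: _ratio(p.densities["Neu_D"], p.densities["allT_D"]),
    "M2_over_allT": lambda p: _ratio(p.densities["M2_D"], p.densities["allT_D"]),
    "PD1allT_over_PDL1panM": lambda p: _ratio(p.densities["PD1_allT_D"],
                                              p.densities["PDL1_panM_D"]),
}

DEFAULT_REGISTRY: tuple[str, ...] = (
    tuple(DENSITY_KEYS) + ("Tu_D", "PDL1_Tu_D")
    + tuple(LEU_PCT_KEYS)
    + tuple(FRACTION_KEYS)
    + ("PD1_CTL_pct", "PD1_Tcon_pct", "PD1_Treg_pct", "PD1_allT_pct",
       "PDL1_panM_pct", "PDL1_M1_pct", "PDL1_M2_pct")
    + ("PD1CTL_over_PD1Treg", "CTL_over_Treg", "C_Tcon_over_Treg", "M1_over_M2",
       "CTL_over_panM", "Treg_over_panM", "panM_over_allT", "Neu_over_allT",
       "M2_over_allT", "PD1allT_over_PDL1panM")
    + ("CTL_nT_um",)
)
assert len(DEFAULT_REGISTRY) == 58


def parameter_value(profile: SampleProfile, name: str) -> float:
    if name in profile.densities:
        return profile.densities[name]
    if name in profile.leu_percent:
        return profile.leu_percent[name]
    if name in profile.fractions:
        return profile.fractions[name]
    if name in profile.ratios:
        return profile.ratios[name]
    if name == "CTL_nT_um":
        return profile.ctl_nt_um
    if name in _DERIVED:
        return _DERIVED[name](profile)
    raise KeyError(f"unknown parameter {name!r}")


def profiles_to_frame(profiles: Sequence[SampleProfile],
                      registry: Sequence[str] | None = None) -> pd.DataFrame:
    """Samples × parameters matrix (index = sample_id, NaN = missing)."""
    registry = tuple(registry) if registry is not None else DEFAULT_REGISTRY
    rows = {p.sample_id: [parameter_value(p, name) for name in registry]
            for p in profiles}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(registry))


def save_registry(registry: Sequence[str], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump({"parameters": list(registry)}))


def load_registry(path: str | Path) -> tuple[str, ...]:
    data = yaml.safe_load(Path(path).read_text())
    return tuple(data["parameters"])
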