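"""Five-way immunotype stratification of sample profiles.

The decision tree stratifies each sample on the stromal leukocyte density
(Leu-D), effector T-cell proportions, and the 100 CTL-nT distance:

1. Leu-D < ``leu_low``                       → type V  (immunodesert)
2. Leu-D > ``leu_high``  and C/Tcon% > ref   → type I  (immunoactive)
3. Leu-D > ``leu_mid``   and CTL%    > ref   → type II (border)
4. otherwise: CTL-nT > ``ctl_nt_cut_um`` with a verified band-like
   stroma-rich zone                          → type IV (immunoisolating)
   else                                      → type III (immunosuppressed)

The default Leu-D cut points are the cohort mean ± 1 SD rounded to the printed
operational values (2500 / 5000 / 7500 cells/mm²) and the distance cut is
30 µm. All comparisons are strict, so equality at a cut point falls to the
less-extreme branch. Top-band samples that fail the C/Tcon% gate fall through
to the CTL% gate (and beyond), keeping the tree exhaustive.

A missing CTL-nT statistic (no CTL anywhere in the sample) with Leu-D at or
above ``leu_low`` is treated as above the distance cut — absence of CTLs near
tumor is the extreme of isolation — and flagged in the call's warnings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .parameters import SampleProfile
from .stats import summarize_counts

IMMUNOTYPES: tuple[str, ...] = ("I", "II", "III", "IV", "V")

IMMUNOTYPE_NAMES = {
    "I": "immunoactive", "II": "border", "III": "immunosuppressed",
    "IV": "immunoisolating", "V": "immunodesert",
}


@dataclass
class Thresholds:
    """Cut points of the decision tree (cells/mm², %, µm)."""

    leu_high: float = 7500.0
    leu_mid: float = 5000.0
    leu_low: float = 2500.0
    ctcon_pct_ref: float = 0.0
    ctl_pct_ref: float = 0.0
    ctl_nt_cut_um: float = 30.0

    def __post_init__(self) -> None:
        if not (self.leu_low < self.leu_mid < self.leu_high):
            raise ValueError(
                f"require leu_low < leu_mid < leu_high, got "
                f"({self.leu_low}, {self.leu_mid}, {self.leu_high})")
        if not self.ctl_nt_cut_um > 0:
            raise ValueError("ctl_nt_cut_um must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Thresholds":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class RuleCheck:
    criterion: str
    observed: float
    threshold: float
    outcome: bool


@dataclass
class ImmunotypeCall:
    sample_id: str
    immunotype: str
    rule_trace: list[RuleCheck]
    band_flag: bool | None = None
    warnings: list[str] = field(default_factory=list)


def derive_cohort_thresholds(
    profiles: Sequence[SampleProfile],
    mode: str = "published_defaults",
    *,
    ctcon_pct_ref: float | None = None,
    ctl_pct_ref: float | None = None,
    ctl_nt_cut_um: float = 30.0,
) -> Thresholds:
    """Fix the tree's cut points before classifying a cohort.

    ``published_defaults`` uses the printed Leu-D cuts (2500/5000/7500);
    ``cohort_derived`` sets mid = mean(Leu-D), high/low = mean ± 1 sample SD
    (low clamped just above 0 with a warning if the derivation goes negative).
    In both modes the percentage references default to the cohort means of
    C/Tcon% and CTL% unless fixed overrides are given.
    """
    if mode not in ("published_defaults", "cohort_derived"):
        raise ValueError(f"unknown mode {mode!r}")
    if ctcon_pct_ref is None or ctl_pct_ref is None:
        if not profiles:
            raise ValueError("percentage references require profiles or overrides")
        if ctcon_pct_ref is None:
            ctcon_pct_ref = float(np.nanmean(
                [p.leu_percent["C_Tcon_pct"] for p in profiles]))
        if ctl_pct_ref is None:
            ctl_pct_ref = float(np.nanmean(
                [p.leu_percent["CTL_pct"] for p in profiles]))
    if mode == "published_defaults":
        return Thresholds(ctcon_pct_ref=ctcon_pct_ref, ctl_pct_ref=ctl_pct_ref,
                          ctl_nt_cut_um=ctl_nt_cut_um)
    if len(profiles) < 2:
        raise ValueError("cohort_derived thresholds need at least 2 profiles")
    leu = np.asarray([p.densities["Leu_D"] for p in profiles], dtype=float)
    mean = float(np.mean(leu))
    sd = float(np.std(leu, ddof=1))
    low = mean - sd
    if low <= 0:
        import logging
        logging.getLogger(__name__).warning(
            "derived leu_low %.1f <= 0; clamped", low)
        low = np.nextafter(0.0, 1.0)
    return Thresholds(leu_high=mean + sd, leu_mid=mean, leu_low=low,
                      ctcon_pct_ref=ctcon_pct_ref, ctl_pct_ref=ctl_pct_ref,
                      ctl_nt_cut_um=ctl_nt_cut_um)


def classify_sample(profile: SampleProfile, thresholds: Thresholds,
                    band_flag: bool | None = None) -> ImmunotypeCall:
    """Assign exactly one immunotype with a machine-readable rule trace."""
    leu = profile.densities["Leu_D"]
    if leu is None or not np.isfinite(leu):
        raise ValueError(f"sample {profile.sample_id}: Leu-D is missing")
    trace: list[RuleCheck] = []
    warnings: list[str] = []

    c1 = leu < thresholds.leu_low
    trace.append(RuleCheck("Leu_D < leu_low", leu, thresholds.leu_low, c1))
    if c1:
        return ImmunotypeCall(profile.sample_id, "V", trace, band_flag, warnings)

    ctcon = profile.leu_percent["C_Tcon_pct"]
    high = leu > thresholds.leu_high
    trace.append(RuleCheck("Leu_D > leu_high", leu, thresholds.leu_high, high))
    if high:
        g = bool(np.isfinite(ctcon)) and ctcon > thresholds.ctcon_pct_ref
        trace.append(RuleCheck("C_Tcon_pct > ref", ctcon,
                               thresholds.ctcon_pct_ref, g))
        if g:
            return ImmunotypeCall(profile.sample_id, "I", trace, band_flag,
                                  warnings)

    ctl = profile.leu_percent["CTL_pct"]
    mid = leu > thresholds.leu_mid
    trace.append(RuleCheck("Leu_D > leu_mid", leu, thresholds.leu_mid, mid))
    if mid:
        g = bool(np.isfinite(ctl)) and ctl > thresholds.ctl_pct_ref
        trace.append(RuleCheck("CTL_pct > ref", ctl, thresholds.ctl_pct_ref, g))
        if g:
            return ImmunotypeCall(profile.sample_id, "II", trace, band_flag,
                                  warnings)

    nt = profile.ctl_nt_um
    if nt is None or not np.isfinite(nt):
        warnings.append("CTL-nT statistic missing (no CTL); treated as above "
                        "the distance cut (maximal isolation)")
        above = True
        trace.append(RuleCheck("ctl_nt_um > cut (missing→above)", math.nan,
                               thresholds.ctl_nt_cut_um, True))
    else:
        above = nt > thresholds.ctl_nt_cut_um
        trace.append(RuleCheck("ctl_nt_um > cut", nt, thresholds.ctl_nt_cut_um,
                               above))
    if above:
        if band_flag is None:
            warnings.append("band-like stroma-rich zone not visually verified; "
                            "distance criterion alone decided type IV")
            band_ok = True
        else:
            band_ok = bool(band_flag)
        trace.append(RuleCheck("band verified (or unverified-with-warning)",
                               float(band_ok), 1.0, band_ok))
        if band_ok:
            return ImmunotypeCall(profile.sample_id, "IV", trace, band_flag,
                                  warnings)
    return ImmunotypeCall(profile.sample_id, "III", trace, band_flag, warnings)


def classify_cohort(
    profiles: Sequence[SampleProfile],
    thresholds: Thresholds,
    band_flags: Mapping[str, bool] | None = None,
) -> tuple[list[ImmunotypeCall], dict]:
    """Classify every sample with fixed thresholds; summary counts/percentages.

    Per-sample errors are collected into the summary, not fatal to the cohort.
    """
    calls: list[ImmunotypeCall] = []
    errors: dict[str, str] = {}
    for p in profiles:
        flag = None if band_flags is None else band_flags.get(p.sample_id)
        try:
            calls.append(classify_sample(p, thresholds, band_flag=flag))
        except ValueError as exc:
            errors[p.sample_id] = str(exc)
    counts = {t: 0 for t in IMMUNOTYPES}
    for c in calls:
        counts[c.immunotype] += 1
    total = sum(counts.values())
    summary = {
        "counts": counts,
        "percentages": summarize_counts(counts) if total else
                       {t: math.nan for t in IMMUNOTYPES},
        "n": total,
        "errors": errors,
    }
    return calls, summary


def calls_to_frame(calls: Sequence[ImmunotypeCall]) -> pd.DataFrame:
    """Calls as a flat audit table (one row per sample, trace serialized)."""
    rows = []
    for c in calls:
        rows.append({
            "sample_id": c.sample_id,
            "immunotype": c.immunotype,
            "immunotype_name": IMMUNOTYPE_NAMES[c.immunotype],
            "band_flag": c.band_flag,
            "warnings": "; ".join(c.warnings),
            "rule_trace": " | ".join(
                f"{r.criterion}: {r.observed:.6g} vs {r.threshold:.6g} -> "
                f"{'pass' if r.outcome else 'fail'}" for r in c.rule_trace),
        })
    return pd.DataFrame(rows, columns=["sample_id", "immunotype",
                                       "immunotype_name", "band_flag",
                                       "warnings", "rule_trace"])
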