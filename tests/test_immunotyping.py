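"""Decision-tree thresholds, boundary semantics, and cohort classification."""

import math

import numpy as np
import pytest

from mifcyto.immunotyping import (ImmunotypeCall, Thresholds, calls_to_frame,
                                  classify_cohort, classify_sample,
                                  derive_cohort_thresholds)
from mifcyto.parameters import SampleProfile


def make_profile(sample_id="s0", leu_d=4000.0, ctcon_pct=30.0, ctl_pct=15.0,
                 ctl_nt=20.0) -> SampleProfile:
    densities = {"Leu_D": leu_d}
    leu_percent = {"C_Tcon_pct": ctcon_pct, "CTL_pct": ctl_pct}
    return SampleProfile(sample_id=sample_id, densities=densities,
                         leu_percent=leu_percent, fractions={}, ratios={},
                         ctl_nt_um=ctl_nt, n_images=1)


REF = Thresholds(ctcon_pct_ref=40.0, ctl_pct_ref=20.0)


class TestThresholds:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            Thresholds(leu_high=1000, leu_mid=5000, leu_low=2500)

    def test_published_defaults_use_printed_cuts(self):
        profiles = [make_profile(ctcon_pct=30, ctl_pct=10),
                    make_profile(ctcon_pct=50, ctl_pct=30)]
        t = derive_cohort_thresholds(profiles, mode="published_defaults")
        assert (t.leu_high, t.leu_mid, t.leu_low) == (7500, 5000, 2500)
        assert t.ctcon_pct_ref == 40.0 and t.ctl_pct_ref == 20.0

    def test_cohort_derived_is_mean_plus_minus_sd(self):
        # Leu-D mean 5000, sample SD 2500 -> cuts (7500, 5000, 2500)
        leu = [2500.0, 5000.0, 7500.0]
        sd = float(np.std(leu, ddof=1))
        profiles = [make_profile(leu_d=v) for v in leu]
        t = derive_cohort_thresholds(profiles, mode="cohort_derived")
        assert t.leu_mid == 5000.0
        assert t.leu_high == pytest.approx(5000 + sd)
        assert t.leu_low == pytest.approx(5000 - sd)

    def test_cohort_derived_recovers_distribution_moments(self, rng):
        mu, sigma, n = 5000.0, 1500.0, 400
        profiles = [make_profile(leu_d=v)
                    for v in rng.normal(mu, sigma, size=n)]
        t = derive_cohort_thresholds(profiles, mode="cohort_derived")
        se_mean = sigma / math.sqrt(n)
        assert abs(t.leu_mid - mu) < 2 * se_mean
        se_sd = sigma / math.sqrt(2 * (n - 1))
        assert abs((t.leu_high - t.leu_mid) - sigma) < 2 * se_sd

    def test_single_sample_cohort_derivation_errors(self):
        with pytest.raises(ValueError):
            derive_cohort_thresholds([make_profile()], mode="cohort_derived")

    def test_negative_low_clamped(self):
        profiles = [make_profile(leu_d=v) for v in (100.0, 5000.0)]
        t = derive_cohort_thresholds(profiles, mode="cohort_derived")
        assert t.leu_low > 0


class TestClassifySample:
    def test_desert_overrides_everything(self):
        call = classify_sample(make_profile(leu_d=2000, ctcon_pct=99,
                                            ctl_pct=99, ctl_nt=99), REF)
        assert call.immunotype == "V"

    def test_immunoactive(self):
        call = classify_sample(make_profile(leu_d=8000, ctcon_pct=50), REF)
        assert call.immunotype == "I"

    def test_border_in_mid_band(self):
        call = classify_sample(make_profile(leu_d=6000, ctcon_pct=10,
                                            ctl_pct=25), REF)
        assert call.immunotype == "II"

    def test_top_band_failing_ctcon_falls_through_to_ctl_gate(self):
        call = classify_sample(make_profile(leu_d=8000, ctcon_pct=30,
                                            ctl_pct=25), REF)
        assert call.immunotype == "II"

    def test_isolating_vs_suppressed_on_distance(self):
        iv = classify_sample(make_profile(leu_d=4000, ctl_nt=45.0), REF,
                             band_flag=True)
        iii = classify_sample(make_profile(leu_d=4000, ctl_nt=12.0), REF,
                              band_flag=True)
        assert (iv.immunotype, iii.immunotype) == ("IV", "III")

    def test_band_flag_false_vetoes_type_iv(self):
        call = classify_sample(make_profile(leu_d=4000, ctl_nt=45.0), REF,
                               band_flag=False)
        assert call.immunotype == "III"

    def test_absent_band_flag_warns_but_allows_iv(self):
        call = classify_sample(make_profile(leu_d=4000, ctl_nt=45.0), REF)
        assert call.immunotype == "IV"
        assert any("verified" in w for w in call.warnings)

    def test_missing_ctl_nt_treated_as_isolated_with_warning(self):
        call = classify_sample(make_profile(leu_d=4000, ctl_nt=math.nan), REF,
                               band_flag=True)
        assert call.immunotype == "IV"
        assert any("missing" in w for w in call.warnings)

    def test_missing_leu_d_is_an_error(self):
        with pytest.raises(ValueError):
            classify_sample(make_profile(leu_d=math.nan), REF)

    def test_trace_is_nonempty_and_consistent(self):
        call = classify_sample(make_profile(leu_d=8000, ctcon_pct=50), REF)
        assert call.rule_trace
        assert call.rule_trace[-1].outcome is True

    def test_determinism(self):
        p = make_profile(leu_d=6100, ctcon_pct=33, ctl_pct=21, ctl_nt=31)
        a = classify_sample(p, REF, band_flag=True)
        b = classify_sample(p, REF, band_flag=True)
        assert a == b


class TestBoundarySemantics:
    """Strict comparisons: equality at a cut point falls to the non-extreme
    branch."""

    def test_exactly_2500_is_not_desert(self):
        call = classify_sample(make_profile(leu_d=2500.0, ctl_nt=10.0), REF)
        assert call.immunotype != "V"

    def test_exactly_7500_is_not_top_band(self):
        # C/Tcon gate would pass, but strict > keeps the sample out of type I
        call = classify_sample(make_profile(leu_d=7500.0, ctcon_pct=99,
                                            ctl_pct=1, ctl_nt=1), REF)
        assert call.immunotype == "III"

    def test_exactly_5000_is_not_mid_band(self):
        call = classify_sample(make_profile(leu_d=5000.0, ctl_pct=99,
                                            ctl_nt=1), REF)
        assert call.immunotype == "III"

    def test_exactly_30_um_is_not_isolating(self):
        call = classify_sample(make_profile(leu_d=4000, ctl_nt=30.0), REF,
                               band_flag=True)
        assert call.immunotype == "III"

    def test_reference_percentage_equality_fails_gate(self):
        call = classify_sample(make_profile(leu_d=8000, ctcon_pct=40.0,
                                            ctl_pct=20.0, ctl_nt=1), REF)
        assert call.immunotype == "III"

    def test_monotone_below_leu_low(self, rng):
        for leu in rng.uniform(0, 2499.999, size=50):
            assert classify_sample(make_profile(leu_d=leu), REF).immunotype == "V"


class TestClassifyCohort:
    def test_exhaustive_exclusive_on_randomized_profiles(self, rng):
        profiles = [make_profile(f"s{i}", leu_d=rng.uniform(0, 12000),
                                 ctcon_pct=rng.uniform(0, 100),
                                 ctl_pct=rng.uniform(0, 100),
                                 ctl_nt=rng.uniform(0, 120))
                    for i in range(2000)]
        calls, summary = classify_cohort(profiles, REF)
        assert len(calls) == 2000
        assert sum(summary["counts"].values()) == 2000
        assert not summary["errors"]

    def test_printed_cohort_percentages(self):
        counts = {"I": 14, "II": 12, "III": 20, "IV": 21, "V": 20}
        profiles = []
        archetype = {"I": dict(leu_d=9000, ctcon_pct=60),
                     "II": dict(leu_d=6000, ctcon_pct=10, ctl_pct=30),
                     "III": dict(leu_d=4000, ctl_nt=10),
                     "IV": dict(leu_d=4000, ctl_nt=60),
                     "V": dict(leu_d=1000)}
        i = 0
        for itype, n in counts.items():
            for _ in range(n):
                profiles.append(make_profile(f"s{i}", **archetype[itype]))
                i += 1
        calls, summary = classify_cohort(profiles, REF,
                                         band_flags={p.sample_id: True
                                                     for p in profiles})
        assert summary["counts"] == counts
        assert summary["percentages"] == {"I": 16.1, "II": 13.8, "III": 23.0,
                                          "IV": 24.1, "V": 23.0}

    def test_empty_cohort(self):
        calls, summary = classify_cohort([], REF)
        assert calls == [] and summary["n"] == 0

    def test_per_sample_errors_collected_not_fatal(self):
        profiles = [make_profile("ok"), make_profile("bad", leu_d=math.nan)]
        calls, summary = classify_cohort(profiles, REF)
        assert len(calls) == 1
        assert "bad" in summary["errors"]

    def test_calls_frame_layout(self):
        calls, _ = classify_cohort([make_profile("a"), make_profile("b")], REF)
        frame = calls_to_frame(calls)
        assert list(frame["sample_id"]) == ["a", "b"]
        assert frame["rule_trace"].str.len().gt(0).all()
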