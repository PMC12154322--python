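"""Age bands, zone classification, threshold flags, bounds and windows."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adrisk import (
    BiomarkerRecord,
    CIParams,
    CohortTable,
    FlagLabel,
    TermParams,
    ZoneLabel,
    band_for_age,
    ci_from_age,
    classify_ci,
    classify_instance,
    flag_biomarker,
    four_zone_label,
    intervention_window,
    safe_biomarker_bounds,
    screen_cohort,
)
from adrisk.defaults import DEFAULT_CI_PARAMS, DEFAULT_REGISTRY, DEFAULT_THRESHOLDS

ZERO = TermParams(0.0, 0.0, 0.0)


class TestBandForAge:
    def test_upper_edge_belongs_to_band(self):
        band = band_for_age(40.0)
        assert (band.lower, band.upper) == (30, 40)

    def test_interior_point(self):
        band = band_for_age(41.0)
        assert (band.lower, band.upper) == (40, 50)

    @pytest.mark.parametrize("age", [30.0, 25.0, 70.5])
    def test_uncovered_ages_raise(self, age):
        with pytest.raises(ValueError):
            band_for_age(age)

    def test_default_registry_cut_points(self):
        cuts = [(b.lower, b.upper, b.gamma, b.delta) for b in DEFAULT_REGISTRY]
        assert cuts == [(30, 40, 3, 6), (40, 50, 4, 7), (50, 60, 5, 8), (60, 70, 6, 9)]


class TestClassifyCi:
    def test_worked_example_labels(self, worked_df):
        for row in worked_df.itertuples():
            assert classify_ci(row.Age, row.CI).value == row.Risk_Level

    @pytest.mark.parametrize(
        "age, ci, expected",
        [
            (35.0, 3.0, ZoneLabel.SAFE),       # ci == gamma is Safe
            (35.0, 6.0, ZoneLabel.MILD_RISK),  # ci == delta is Mild
            (35.0, 6.0001, ZoneLabel.UNSAFE),
            (47.0, 5.30, ZoneLabel.MILD_RISK),
            (58.0, 3.18, ZoneLabel.SAFE),
        ],
    )
    def test_boundary_conventions(self, age, ci, expected):
        assert classify_ci(age, ci) is expected

    def test_below_display_range_still_safe_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="adrisk.zones"):
            assert classify_ci(45.0, 0.5) is ZoneLabel.SAFE
        assert any("Safe range" in r.message for r in caplog.records)

    @settings(derandomize=True, max_examples=300)
    @given(
        age=st.floats(30.01, 70.0),
        ci=st.floats(-5.0, 20.0),
        bump=st.floats(0.0, 10.0),
    )
    def test_total_exclusive_and_monotone_in_ci(self, age, ci, bump):
        zone = classify_ci(age, ci)
        assert zone in (ZoneLabel.SAFE, ZoneLabel.MILD_RISK, ZoneLabel.UNSAFE)
        assert classify_ci(age, ci + bump).rank >= zone.rank


def _midpoint_probes():
    probes = []
    for table in DEFAULT_THRESHOLDS:
        for biomarker, rows in table.rows.items():
            for cat, label in (
                ("normal", FlagLabel.NORMAL),
                ("low_risk", FlagLabel.LOW_RISK),
                ("high_risk", FlagLabel.HIGH_RISK),
            ):
                lo, hi = rows[cat]
                probes.append((table.age_group, biomarker, (lo + hi) / 2, label))
    return probes


class TestFlagBiomarker:
    @pytest.mark.parametrize("age_group, biomarker, value, expected", _midpoint_probes())
    def test_every_range_midpoint_flags_its_own_category(
        self, age_group, biomarker, value, expected
    ):
        assert flag_biomarker(age_group, biomarker, value) is expected

    @pytest.mark.parametrize(
        "age_group, biomarker, value, expected",
        [
            ("30-40", "Amyloid_PET", 5.0, FlagLabel.NORMAL),
            ("30-40", "CSF_Tau", 11.0, FlagLabel.HIGH_RISK),
            ("40-50", "CSF_Ab42", 13.0, FlagLabel.NORMAL),
            ("30-40", "Amyloid_PET", 7.0, FlagLabel.LOW_RISK),  # boundary moves riskward
            ("30-40", "CSF_Ab42", 15.0, FlagLabel.LOW_RISK),    # riskward is downward
            ("30-40", "Amyloid_PET", 2.0, FlagLabel.OUT_OF_RANGE),
            ("30-40", "Amyloid_PET", 20.0, FlagLabel.HIGH_RISK),
            ("30-40", "CSF_Ab42", 30.0, FlagLabel.OUT_OF_RANGE),
            ("30-40", "CSF_Ab42", 4.0, FlagLabel.HIGH_RISK),
        ],
    )
    def test_specific_cells_and_extremes(self, age_group, biomarker, value, expected):
        assert flag_biomarker(age_group, biomarker, value) is expected

    def test_unknown_group_or_biomarker(self):
        with pytest.raises(KeyError):
            flag_biomarker("20-30", "CSF_Tau", 5.0)
        with pytest.raises(KeyError):
            flag_biomarker("30-40", "Plasma_NfL", 5.0)


class TestClassifyInstance:
    RECORD = BiomarkerRecord(age=45, csf_ab42=15.0, amyloid_pet=6.0,
                             csf_tau=5.0, mri_fdg_pet=4.0)

    def test_zero_weights_classify_on_age_term_alone(self):
        p = CIParams(alpha=0.5, beta=0.05, terms=(ZERO, ZERO, ZERO, ZERO))
        out = classify_instance(self.RECORD, p)
        assert out.ci == pytest.approx(0.5 * math.exp(0.05 * 45))
        assert out.zone is classify_ci(45, out.ci)

    def test_raising_protective_marker_never_raises_risk(self):
        for ab42 in np.linspace(5, 25, 9):
            lo = classify_instance(
                BiomarkerRecord(45, ab42, 6.0, 5.0, 4.0), DEFAULT_CI_PARAMS
            )
            hi = classify_instance(
                BiomarkerRecord(45, ab42 + 5.0, 6.0, 5.0, 4.0), DEFAULT_CI_PARAMS
            )
            assert hi.zone.rank <= lo.zone.rank

    def test_flags_attached_when_thresholds_supplied(self):
        out = classify_instance(
            self.RECORD, DEFAULT_CI_PARAMS, thresholds=DEFAULT_THRESHOLDS
        )
        assert out.flags is not None
        assert out.flags["CSF_Ab42"] is FlagLabel.NORMAL

    def test_no_flags_for_uncovered_threshold_age(self):
        rec = BiomarkerRecord(age=52, csf_ab42=12.0, amyloid_pet=8.0,
                              csf_tau=6.0, mri_fdg_pet=5.0)
        out = classify_instance(rec, DEFAULT_CI_PARAMS, thresholds=DEFAULT_THRESHOLDS)
        assert out.flags is None  # 52 falls between the 40-50 and 55-65 templates


class TestScreenCohort:
    def test_empty_cohort_counts_zero(self):
        result = screen_cohort(CohortTable(), DEFAULT_CI_PARAMS)
        assert result.counts == {"Safe": 0, "Mild Risk": 0, "Unsafe": 0}
        assert result.assessments == ()

    def test_precomputed_ci_column_reproduces_worked_example(self, worked_df):
        result = screen_cohort(CohortTable(df=worked_df), ci_params=None)
        assert result.counts == {"Safe": 2, "Mild Risk": 6, "Unsafe": 0}
        assert sum(result.counts.values()) == len(worked_df)

    def test_counts_are_permutation_invariant(self, worked_df):
        shuffled = worked_df.sample(frac=1, random_state=5).reset_index(drop=True)
        a = screen_cohort(CohortTable(df=worked_df), None)
        b = screen_cohort(CohortTable(df=shuffled), None)
        assert a.counts == b.counts

    def test_requires_ci_source(self, worked_df):
        df = worked_df.drop(columns=["CI"])
        with pytest.raises(ValueError):
            screen_cohort(CohortTable(df=df), ci_params=None)


class TestSafeBiomarkerBounds:
    FIXED = {"Amyloid_PET": 5.0, "CSF_Tau": 4.0, "MRI_FDG_PET": 3.0}

    def test_positive_weight_gives_upper_limit(self):
        p = CIParams(alpha=0.1, beta=0.01,
                     terms=(ZERO, TermParams(0.2, 1, 0), ZERO, ZERO))
        lo, hi = safe_biomarker_bounds(
            35.0, p, vary="Amyloid_PET",
            fixed={"CSF_Ab42": 18.0, "CSF_Tau": 4.0, "MRI_FDG_PET": 3.0},
        )
        assert lo == 0.0 and hi > 0.0

    def test_negative_weight_gives_lower_limit(self):
        lo, hi = safe_biomarker_bounds(
            35.0, DEFAULT_CI_PARAMS, vary="CSF_Ab42", fixed=self.FIXED
        )
        assert hi == math.inf and lo >= 0.0

    def test_exactly_exhausted_budget_gives_zero_bound(self):
        # alpha*e^0 = gamma exactly, all other contributions zero
        p = CIParams(alpha=3.0, beta=0.0,
                     terms=(ZERO, TermParams(0.5, 1, 0), ZERO, ZERO))
        lo, hi = safe_biomarker_bounds(
            35.0, p, vary="Amyloid_PET",
            fixed={"CSF_Ab42": 0.0, "CSF_Tau": 0.0, "MRI_FDG_PET": 0.0},
        )
        assert (lo, hi) == (0.0, 0.0)

    def test_zero_weight_rejected(self):
        p = CIParams(alpha=0.1, beta=0.01, terms=(ZERO, ZERO, ZERO, ZERO))
        fixed = {"CSF_Ab42": 10.0, "Amyloid_PET": 5.0, "MRI_FDG_PET": 3.0}
        with pytest.raises(ValueError):
            safe_biomarker_bounds(35.0, p, vary="CSF_Tau", fixed=fixed)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_bound_agrees_with_brute_force_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.uniform(-0.3, 0.3, 4)
        w[w == 0] = 0.1
        p = CIParams(
            alpha=float(rng.uniform(0, 1)), beta=float(rng.uniform(0, 0.05)),
            terms=tuple(TermParams(float(wi), 1.0, 0.0) for wi in w),
        )
        age = float(rng.uniform(30.1, 70.0))
        fixed = {"Amyloid_PET": float(rng.uniform(0, 10)),
                 "CSF_Tau": float(rng.uniform(0, 10)),
                 "MRI_FDG_PET": float(rng.uniform(0, 10))}
        res = safe_biomarker_bounds(age, p, vary="CSF_Ab42", fixed=fixed)
        eps = 1e-6

        def zone_at(v):
            rec = BiomarkerRecord(age, v, fixed["Amyloid_PET"],
                                  fixed["CSF_Tau"], fixed["MRI_FDG_PET"])
            return classify_instance(rec, p).zone

        if res is None:
            assert zone_at(0.0) is not ZoneLabel.SAFE
            return
        lo, hi = res
        b = hi if math.isfinite(hi) else lo
        # probe a hair inside the safe side (the boundary itself sits at
        # CI == gamma up to rounding) and a clear step on the risky side
        safe_side = b - eps if math.isfinite(hi) else b + eps
        if safe_side > 0:
            assert zone_at(safe_side) is ZoneLabel.SAFE
        risky = b + 1e-3 if math.isfinite(hi) else b - 1e-3
        if risky >= 0 and b > 0:
            assert zone_at(risky) is not ZoneLabel.SAFE


class TestInterventionWindow:
    def test_trajectory_never_leaving_safe_has_no_window(self):
        p = CIParams(alpha=0.1, beta=0.0, terms=(ZERO, ZERO, ZERO, ZERO))
        win = intervention_window(p, age_range=(31, 70))
        assert win.onset_age is None and win.unsafe_age is None and win.window is None

    def test_already_unsafe_at_range_start(self):
        p = CIParams(alpha=50.0, beta=0.0, terms=(ZERO, ZERO, ZERO, ZERO))
        win = intervention_window(p, age_range=(31, 70))
        assert win.onset_age == win.unsafe_age == 31.0
        assert win.window is None

    def test_crossings_match_dense_grid_search(self):
        win = intervention_window(DEFAULT_CI_PARAMS, age_range=(31, 70), step=0.5)
        dense = np.arange(31, 70, 1e-4)
        ranks = np.array(
            [classify_ci(a, float(ci_from_age(a, DEFAULT_CI_PARAMS))).rank for a in dense]
        )
        onset_oracle = dense[np.argmax(ranks >= 1)]
        unsafe_oracle = dense[np.argmax(ranks >= 2)]
        assert win.onset_age == pytest.approx(onset_oracle, abs=1e-3)
        assert win.unsafe_age == pytest.approx(unsafe_oracle, abs=1e-3)
        assert win.window == (win.onset_age, win.unsafe_age)

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            intervention_window(DEFAULT_CI_PARAMS, age_range=(31, 70), step=0.0)


def test_four_zone_relabeling_splits_unsafe_at_display_edge():
    assert four_zone_label(35.0, 2.0) == "Normal"
    assert four_zone_label(35.0, 4.5) == "Mild Risk"
    assert four_zone_label(35.0, 8.0) == "High Risk"   # within displayed unsafe range
    assert four_zone_label(35.0, 11.0) == "MCI"        # beyond its upper edge
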