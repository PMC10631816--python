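"""Cohort statistics: aggregation, paired comparisons, correlations, stars."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endooct import (
    CohortEffectModel,
    aggregate,
    classify_strength,
    compare_to_baseline,
    correlate,
    generate_cohort,
    p_to_stars,
)
from endooct.cohort import LOCATIONS, VISITS
from endooct.stats import holm_adjust, validate_study_table


def tiny_table(values_by_patient_visit, metric="bvd", location="da"):
    """Table with one location and the given {patient: {visit: value}}."""
    rows = []
    for pid, visits in values_by_patient_visit.items():
        for v, val in visits.items():
            rows.append({"patient_id": pid, "visit": v, "location": location,
                         "bvd": 0.2, "vet_um": 120.0, "vhi": 15, "vsq": 10})
            rows[-1][metric] = val
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(CohortEffectModel(n_patients=20, seed=0))


class TestAggregate:
    def test_constant_values(self):
        t = tiny_table({f"P{i}": {v: 0.4 for v in VISITS} for i in range(3)})
        agg = aggregate(t, "bvd")
        assert np.allclose(agg["mean"], 0.4)
        assert np.allclose(agg["se"], 0.0)

    def test_hand_computed_se(self):
        t = tiny_table({"P1": {1: 0.20}, "P2": {1: 0.30}})
        agg = aggregate(t, "bvd")
        row = agg[(agg.visit == 1) & (agg.location == "da")].iloc[0]
        assert row["mean"] == pytest.approx(0.25)
        assert row["se"] == pytest.approx(0.05)

    def test_grand_mean_pools_locations(self, cohort):
        agg = aggregate(cohort, "bvd")
        grand = agg[(agg.visit == 1) & (agg.location == "all")].iloc[0]
        assert grand["n"] == 20 * 4
        assert grand["mean"] == pytest.approx(cohort[cohort.visit == 1].bvd.mean())

    def test_missing_cell_absent_not_imputed(self, cohort):
        t = cohort[~((cohort.visit == 2) & (cohort.location == "pa"))]
        agg = aggregate(t, "bvd")
        assert agg[(agg.visit == 2) & (agg.location == "pa")].empty

    def test_unknown_location_rejected(self, cohort):
        bad = cohort.copy()
        bad.loc[bad.index[0], "location"] = "xx"
        with pytest.raises(ValueError, match="location"):
            validate_study_table(bad)


class TestCompare:
    def test_zero_deltas_give_p_one(self):
        t = tiny_table({f"P{i}": {v: 0.25 for v in VISITS} for i in range(5)})
        out = compare_to_baseline(t, "bvd")
        assert (out.p_value == 1.0).all()
        assert (out.stars == "ns").all()

    def test_insufficient_pairs_rejected(self):
        t = tiny_table({"P1": {1: 0.2, 2: 0.3}, "P2": {1: 0.2, 2: 0.3}})
        with pytest.raises(ValueError, match="insufficient pairs"):
            compare_to_baseline(t, "bvd")

    def test_pairwise_exclusion(self):
        vals = {f"P{i}": {1: 0.2, 2: 0.2 + 0.01 * i} for i in range(5)}
        vals["P9"] = {2: 0.9}  # missing baseline: must be excluded
        out = compare_to_baseline(tiny_table(vals), "bvd")
        assert out[out.visit == 2].iloc[0].n_pairs == 5

    def test_wilcoxon_option(self, cohort):
        out = compare_to_baseline(cohort, "bvd", test="wilcoxon")
        assert ((out.p_value >= 0) & (out.p_value <= 1)).all()

    def test_consecutive_mode_reference(self, cohort):
        out = compare_to_baseline(cohort, "bvd", mode="consecutive")
        assert (out.ref_visit == out.visit - 1).all()

    def test_unknown_test_rejected(self, cohort):
        with pytest.raises(ValueError, match="test"):
            compare_to_baseline(cohort, "bvd", test="anova")

    def test_holm_never_decreases_p(self, cohort):
        raw = compare_to_baseline(cohort, "bvd", holm=False)
        adj = compare_to_baseline(cohort, "bvd", holm=True)
        assert (adj.p_value.to_numpy() >= raw.p_value.to_numpy() - 1e-15).all()


class TestStars:
    @pytest.mark.parametrize("p,expected", [
        (0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.07, "ns"),
        (0.001, "**"), (0.01, "*"), (0.05, "ns"),
    ])
    def test_threshold_map(self, p, expected):
        assert p_to_stars(p) == expected

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.floats(0.0, 1.0))
    def test_pure_threshold_function(self, p):
        stars = p_to_stars(p)
        expected = ("***" if p < 0.001 else "**" if p < 0.01
                    else "*" if p < 0.05 else "ns")
        assert stars == expected

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            p_to_stars(1.2)


class TestCorrelate:
    def test_perfect_line(self):
        t = tiny_table({f"P{i}": {1: 0.1 + 0.01 * i} for i in range(6)})
        t["vet_um"] = 2 * t["bvd"] + 1
        res = correlate(t, "bvd", "vet_um")
        assert res.r == pytest.approx(1.0)
        assert res.strength == "strong"

    @pytest.mark.parametrize("r,expected", [
        (0.310, "moderate"), (0.384, "moderate"),
        (0.754, "strong"), (0.853, "strong"), (0.721, "strong"),
        (0.05, "negligible"), (0.1, "weak"), (0.299, "weak"),
        (0.3, "moderate"), (0.5, "strong"), (-0.6, "strong"),
    ])
    def test_strength_classification(self, r, expected):
        assert classify_strength(r) == expected

    def test_zero_variance_rejected(self):
        t = tiny_table({f"P{i}": {1: 0.2} for i in range(5)})
        with pytest.raises(ValueError, match="variance"):
            correlate(t, "bvd", "vet_um")

    def test_too_few_pairs_rejected(self):
        t = tiny_table({"P1": {1: 0.1}, "P2": {1: 0.2}})
        with pytest.raises(ValueError, match="3"):
            correlate(t, "bvd", "vet_um")

    def test_group_by_returns_frame(self, cohort):
        out = correlate(cohort, "vhi", "vet_um", group_by="visit")
        assert set(out.visit) == set(VISITS)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.floats(0.1, 50), st.floats(-10, 10))
    def test_affine_invariance(self, cohort, scale, shift):
        base = correlate(cohort, "bvd", "vet_um").r
        t = cohort.copy()
        t["vet_um"] = scale * t["vet_um"] + shift
        assert correlate(t, "bvd", "vet_um").r == pytest.approx(base)

    def test_sign_flips_with_negative_scale(self, cohort):
        base = correlate(cohort, "bvd", "vet_um").r
        t = cohort.copy()
        t["vet_um"] = -t["vet_um"]
        assert correlate(t, "bvd", "vet_um").r == pytest.approx(-base)


class TestHolm:
    def test_adjusted_values_monotone_and_bounded(self):
        p = np.array([0.01, 0.04, 0.03, 0.8])
        adj = holm_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        # order of evidence is preserved
        assert np.argsort(adj).tolist()[:1] == np.argsort(p).tolist()[:1]
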