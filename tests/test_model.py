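import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import costvar as cv
from conftest import make_standardized


class TestConfiguration:
    def test_paper_configuration_counts(self):
        config = cv.paper_configuration()
        assert len(config.objects) == 12
        assert len(config.areas) == 16
        assert len(config.factors) == 60
        kinds = {a.kind for a in config.areas}
        assert kinds == {"quantity", "unit_cost"}

    def test_duplicate_object_rejected(self):
        config = cv.paper_configuration()
        with pytest.raises(cv.ConfigurationError):
            cv.StudyConfiguration(
                config.factors, config.areas, config.objects + (config.objects[0],)
            )

    def test_every_cost_area_has_quantity_pair(self):
        config = cv.paper_configuration()
        for area in config.areas:
            if area.kind == "unit_cost":
                paired = config.quantity_area_for(area)
                assert paired.kind == "quantity"
                assert paired.members[0].category == area.members[0].category


class TestAggregation:
    def test_mean_of_per_patient_sums(self, toy_records):
        config = cv.paper_configuration()
        obj = config.objects[0]  # diagnosis France
        area = config.areas[0]  # Q biopsies
        assert cv.aggregate_quantity_area(toy_records, obj, area) == pytest.approx(2.0)

    def test_empty_phase_is_zero(self, toy_records):
        config = cv.paper_configuration()
        surgery_fr = next(o for o in config.objects if o.phase == "surgery" and o.country == "France")
        assert cv.aggregate_quantity_area(toy_records, surgery_fr, config.areas[0]) == 0.0

    def test_unknown_phase_label_rejected(self, toy_records):
        bad = toy_records.assign(phase="palliation")
        config = cv.paper_configuration()
        with pytest.raises(cv.ConfigurationError, match="phase"):
            cv.aggregate_quantity_area(bad, config.objects[0], config.areas[0])

    def test_cost_area_zero_when_resource_unused(self):
        config = cv.paper_configuration()
        costs = cv.UnitCostTable({("France", f.name): 100.0 for f in config.factors})
        cost_area = next(a for a in config.areas if a.kind == "unit_cost")
        value = cv.assign_cost_area(costs, config.objects[0], cost_area, paired_quantity=0.0)
        assert value == 0.0

    def test_simple_mean_of_member_costs(self):
        config = cv.paper_configuration()
        area = next(a for a in config.areas if a.label == "C transfusions")
        names = [f.name for f in area.members]
        costs = cv.UnitCostTable({("France", names[0]): 100.0, ("France", names[1]): 200.0})
        obj = next(o for o in config.objects if o.country == "France")
        assert cv.assign_cost_area(costs, obj, area, 1.5) == pytest.approx(150.0)

    def test_single_factor_area_returns_tariff(self):
        config = cv.paper_configuration()
        area = next(a for a in config.areas if a.label == "C external consultations")
        costs = cv.UnitCostTable({("Italy", area.members[0].name): 150.0})
        obj = next(o for o in config.objects if o.country == "Italy")
        assert cv.assign_cost_area(costs, obj, area, 2.0) == pytest.approx(150.0)

    def test_missing_unit_cost_is_configuration_error(self):
        config = cv.paper_configuration()
        area = next(a for a in config.areas if a.kind == "unit_cost")
        costs = cv.UnitCostTable({})
        with pytest.raises(cv.ConfigurationError, match="missing unit cost"):
            cv.assign_cost_area(costs, config.objects[0], area, 1.0)


class TestBuildMatrix:
    def test_shape_and_cost_quantity_pairing(self):
        cfg, _ = cv.planted_config(seed=3, n_per_country=25)
        records, costs = cv.generate_patients(cfg)
        vm = cv.build_matrix(records, costs)
        assert vm.shape == (12, 16)
        assert (vm.values >= 0).all()
        frame = vm.frame
        for q_label, c_label in [
            ("Q biopsies", "C biopsies"),
            ("Q radiotherapy sessions", "C radiotherapy sessions"),
            ("Q transfusions", "C transfusions"),
        ]:
            zero_q = frame[q_label] == 0
            assert ((frame[c_label] == 0) == zero_q).all()

    def test_all_zero_records_give_zero_matrix(self):
        records = pd.DataFrame(
            {
                "patient_id": ["p1"],
                "country": ["France"],
                "phase": ["diagnosis"],
                "factor": ["surgical biopsy"],
                "quantity": [0.0],
                "year_offset": [0],
            }
        )
        costs = cv.UnitCostTable(
            {("France", f.name): 1.0 for f in cv.paper_configuration().factors}
        )
        vm = cv.build_matrix(records, costs)
        assert (vm.values == 0).all()

    def test_cell_means_converge_to_configured_means(self):
        # law-of-large-numbers check against the generator configuration:
        # each Poisson-area cell must sit within max(2%, 4 sigma) of its mean
        cfg, _ = cv.planted_config(seed=11, n_per_country=5000)
        records, costs = cv.generate_patients(cfg)
        vm = cv.build_matrix(records, costs)
        config = cv.paper_configuration()
        counts = records.groupby(["country", "phase"])["patient_id"].nunique()
        checked = 0
        for obj in config.objects:
            n_obj = counts.get((obj.country, obj.phase), 0)
            if n_obj == 0:
                continue
            for area in config.areas:
                if area.kind != "quantity":
                    continue
                expected = sum(
                    cfg.quantity_means.get((obj.country, obj.phase, f.name), (0, ""))[0]
                    for f in area.members
                )
                got = vm.frame.loc[obj.label, area.label]
                if expected >= 0.5:
                    tol = max(0.02 * expected, 4 * np.sqrt(expected / n_obj))
                    assert abs(got - expected) <= tol
                    checked += 1
        assert checked >= 20


class TestStandardize:
    def test_two_point_column(self):
        X = make_standardized([[0.0, 5.0], [2.0, 7.0]])
        assert np.allclose(X.values, [[-1, -1], [1, 1]])

    def test_columns_have_zero_mean_unit_population_sd(self, sarcoma_X):
        arr = sarcoma_X.values
        assert np.abs(arr.mean(axis=0)).max() < 1e-9
        assert np.abs(arr.std(axis=0, ddof=0) - 1).max() < 1e-9

    def test_constant_column_raises_naming_the_area(self):
        frame = pd.DataFrame({"varies": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
        with pytest.raises(cv.ConfigurationError, match="flat"):
            cv.standardize(cv.VariabilityMatrix(frame))

    def test_fixture_moments_match_independent_pass(self, sarcoma, sarcoma_X):
        # independent per-column arithmetic, no pandas aggregation
        arr = sarcoma.values
        m = arr.shape[0]
        for j, label in enumerate(sarcoma.frame.columns):
            mean = sum(arr[i, j] for i in range(m)) / m
            sd = (sum((arr[i, j] - mean) ** 2 for i in range(m)) / m) ** 0.5
            assert sarcoma_X.col_means[label] == pytest.approx(mean, abs=1e-12)
            assert sarcoma_X.col_sds[label] == pytest.approx(sd, abs=1e-12)


class TestDiscount:
    @pytest.mark.parametrize(
        "amount,years,rate,expected",
        [
            (100.0, 0, 0.04, 100.0),
            (100.0, 1, 0.04, 96.15384615384616),
            (100.0, 2, 0.04, 92.45562130177515),
        ],
    )
    def test_present_value(self, amount, years, rate, expected):
        assert cv.discount(amount, years, rate) == pytest.approx(expected, rel=1e-12)

    def test_negative_years_rejected(self):
        with pytest.raises(ValueError):
            cv.discount(100.0, -1, 0.04)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        amount=st.floats(0.01, 1e6),
        years=st.integers(0, 30),
        rate=st.floats(0.001, 0.5),
    )
    def test_monotone_in_years_and_rate(self, amount, years, rate):
        assert cv.discount(amount, years, rate) <= amount + 1e-9
        assert cv.discount(amount, years + 1, rate) < cv.discount(amount, years, rate) or amount == 0
        assert cv.discount(amount, years, rate + 0.01) <= cv.discount(amount, years, rate) + 1e-12
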