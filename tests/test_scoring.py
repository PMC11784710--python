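"""Severity level, weights, score matrix, maximum risk, bands, persistence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbrisk.clustering import PATTERN_NAMES
from cbrisk.cohort import Cohort, Group
from cbrisk.reference import (
    REFERENCE_CHI,
    REFERENCE_DELTA,
    REFERENCE_PSI,
    REFERENCE_THRESHOLDS,
    REFERENCE_TOTAL_WEIGHT,
)
from cbrisk.scoring import (
    AssociationRow,
    GlucoseWindows,
    RiskModel,
    ScoreMatrix,
    build_association,
    load_model,
    max_risk,
    risk_table,
    save_model,
    score_matrix,
    severity_level,
    train,
    weight,
)

from conftest import make_subject


class TestSeverityLevel:
    def test_worked_example(self, reference):
        # the first reference subject's series was built so the two terms
        # evaluate to 93 and 125.15
        cohort, _ = reference
        g = cohort.subject("20180101001").glucose
        assert g[:34].mean() == pytest.approx(93.0)
        assert g[54:].sum() / 21 == pytest.approx(125.15)
        assert severity_level(g) == pytest.approx(218.15)

    def test_constant_series_as_printed(self):
        # 26 samples in minutes 55..80 divided by 21
        g = np.full(80, 100.0)
        assert severity_level(g) == pytest.approx(100 + 100 * 26 / 21)

    def test_constant_series_window_mean(self):
        g = np.full(80, 100.0)
        assert severity_level(g, mode="window_mean") == pytest.approx(200.0)

    def test_all_zero_series(self):
        assert severity_level(np.zeros(80)) == 0.0

    def test_missing_glucose_errors(self):
        with pytest.raises(ValueError, match="glucose"):
            severity_level(None)

    def test_windows_outside_grid_error(self):
        with pytest.raises(ValueError, match="window"):
            severity_level(np.full(50, 90.0), GlucoseWindows(t_g=34, T_g=55))

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            GlucoseWindows(t_g=55, T_g=34)


class TestWeight:
    @pytest.mark.parametrize("sl,w", [(218.15, 2.1815), (0.0, 0.0), (1000.0, 10.0)])
    def test_scaling(self, sl, w):
        assert weight(sl) == pytest.approx(w)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            weight(-1.0)


class TestScoreMatrix:
    def test_reference_delta_reproduces_printed_cells(self):
        psi = score_matrix(list(REFERENCE_DELTA))
        # printed values are truncated to 2 decimals -> compare within 0.01
        assert np.allclose(psi.values, REFERENCE_PSI.values, atol=0.01)
        assert psi.cell("DU", "HR") == pytest.approx(9.6474)

    def test_columns_conserve_total_weight(self):
        psi = score_matrix(list(REFERENCE_DELTA))
        np.testing.assert_allclose(
            psi.column_sums(), REFERENCE_TOTAL_WEIGHT, atol=0.02
        )

    def test_single_row_places_three_cells(self):
        row = AssociationRow("x", 1.0, {"HR": "DU", "RR": "DD", "RRxHR": "T"})
        psi = score_matrix([row])
        assert psi.cell("DU", "HR") == 1.0
        assert psi.cell("DD", "RR") == 1.0
        assert psi.cell("T", "RRxHR") == 1.0
        assert psi.values.sum() == pytest.approx(3.0)

    def test_empty_delta_errors(self):
        with pytest.raises(ValueError):
            score_matrix([])

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.1, max_value=10.0),
                st.sampled_from(PATTERN_NAMES),
                st.sampled_from(PATTERN_NAMES),
                st.sampled_from(PATTERN_NAMES),
            ),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_conservation_on_random_delta(self, rows):
        delta = [
            AssociationRow(f"s{i}", w, {"HR": a, "RR": b, "RRxHR": c})
            for i, (w, a, b, c) in enumerate(rows)
        ]
        psi = score_matrix(delta)
        total = sum(r.weight for r in delta)
        np.testing.assert_allclose(psi.column_sums(), total, rtol=1e-9)
        chi = max_risk(psi)
        assert chi <= 3 * total + 1e-9
        assert chi >= psi.values.max() - 1e-9


class TestMaxRiskAndBands:
    def test_printed_matrix_chi(self):
        assert max_risk(REFERENCE_PSI) == pytest.approx(REFERENCE_CHI, abs=1e-9)

    def test_zero_matrix(self):
        assert max_risk(ScoreMatrix(values=np.zeros((5, 3)))) == 0.0

    def test_one_cell_per_column_sums(self):
        vals = np.zeros((5, 3))
        vals[0, 0], vals[2, 1], vals[4, 2] = 2.0, 3.0, 4.0
        assert max_risk(ScoreMatrix(values=vals)) == pytest.approx(9.0)

    def test_band_boundaries(self):
        bands = risk_table(REFERENCE_CHI)
        assert bands[0][1] == pytest.approx(REFERENCE_THRESHOLDS[0], abs=0.005)
        assert bands[1][1] == pytest.approx(REFERENCE_THRESHOLDS[1], abs=0.005)
        assert [b[2] for b in bands] == ["Low", "Medium", "High"]

    def test_chi_three_splits_at_integers(self):
        bands = risk_table(3.0)
        assert bands[0][1] == pytest.approx(1.0)
        assert bands[1][1] == pytest.approx(2.0)

    def test_nonpositive_chi_errors(self):
        with pytest.raises(ValueError):
            risk_table(0.0)


class TestBuildAssociationAndTrain:
    def test_reference_cohort_reproduces_delta(self, reference):
        cohort, expected = reference
        delta = build_association(cohort)
        assert [r.subject_id for r in delta] == [r.subject_id for r in expected]
        for got, exp in zip(delta, expected):
            assert got.weight == pytest.approx(exp.weight, abs=1e-9)
            assert got.patterns == exp.patterns

    def test_train_end_to_end_matches_reference(self, reference):
        cohort, _ = reference
        model = train(cohort)
        assert model.chi == pytest.approx(REFERENCE_CHI, abs=0.02)
        assert np.allclose(model.psi.values, REFERENCE_PSI.values, atol=0.01)
        assert model.thresholds[0] == pytest.approx(REFERENCE_THRESHOLDS[0], abs=0.01)

    def test_train_deterministic(self, reference):
        cohort, _ = reference
        np.testing.assert_array_equal(
            train(cohort).psi.values, train(cohort).psi.values
        )

    def test_control_subject_rejected(self):
        cohort = Cohort(
            subjects=(make_subject("c", Group.CONTROL, glucose_level=90),)
        )
        with pytest.raises(ValueError, match="prediabetes"):
            build_association(cohort)

    def test_missing_glucose_names_subject(self):
        cohort = Cohort(subjects=(make_subject("p7", Group.PREDIABETES),))
        with pytest.raises(ValueError, match="p7"):
            build_association(cohort)

    def test_train_needs_two_subjects(self):
        cohort = Cohort(
            subjects=(make_subject("p", Group.PREDIABETES, glucose_level=100),)
        )
        with pytest.raises(ValueError, match="2"):
            train(cohort)

    def test_single_shared_pattern_chi_is_triple_total(self):
        # if every subject lands in one pattern per variable, each column has
        # one occupied row equal to the total weight, so chi = 3 * total
        rows = [
            AssociationRow(f"s{i}", 2.0, {"HR": "S", "RR": "S", "RRxHR": "S"})
            for i in range(4)
        ]
        psi = score_matrix(rows)
        assert max_risk(psi) == pytest.approx(3 * 8.0)


class TestModelPersistence:
    def test_round_trip(self, reference, tmp_path):
        cohort, _ = reference
        model = train(cohort)
        path = save_model(model, tmp_path / "m.json")
        back = load_model(path)
        np.testing.assert_allclose(back.psi.values, model.psi.values)
        assert back.chi == pytest.approx(model.chi)
        assert back.config == model.config

    def test_truncated_file_errors(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"version": 1, "psi"')
        with pytest.raises(Exception):
            load_model(p)

    def test_version_mismatch_errors(self, reference, tmp_path):
        cohort, _ = reference
        path = save_model(train(cohort), tmp_path / "m.json")
        import json

        payload = json.loads(path.read_text())
        payload["version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="version"):
            load_model(path)

    def test_unknown_pattern_row_errors(self, reference, tmp_path):
        cohort, _ = reference
        path = save_model(train(cohort), tmp_path / "m.json")
        path.write_text(path.read_text().replace('"DUD"', '"XX"'))
        with pytest.raises(ValueError, match="pattern"):
            load_model(path)
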