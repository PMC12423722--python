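"""Feature formulas against direct-arithmetic oracles; combination and
aggregation policies."""

import numpy as np
import pandas as pd
import pytest

from wristpwv import features, fiducials, wpd
from wristpwv.preprocessing import PulseCycle

FS = 256.0


def make_fiducials(**sdppg_amps) -> fiducials.FiducialSet:
    fset = fiducials.FiducialSet(n_sys=60, A_sys=0.9, n_ms=25, A_ms1=12.0)
    for i, (name, amp) in enumerate(sdppg_amps.items()):
        fset.sdppg[name] = (10 + 12 * i, amp)
    return fset


def make_cycle(M=200, n_r=-180) -> PulseCycle:
    s = np.sin(np.linspace(0, np.pi, M)) ** 2
    return PulseCycle(s, M, 1 / FS, onset_index=1000, r_index=1000 + n_r)


class TestPpgFeatures:
    def test_age_index_formulas(self):
        fset = make_fiducials(a=1.2, b=-0.8, c=0.15, d=-0.25, e=0.1)
        v = features.extract_ppg_features(make_cycle(), fset)
        assert v.get("age_index") == pytest.approx((-0.8 - 0.15 + 0.25 - 0.1) / 1.2)
        assert v.get("age_index") == pytest.approx(-0.6667, abs=1e-4)
        assert v.get("age_index_v") == pytest.approx(-0.5833, abs=1e-4)

    def test_p2o_is_cycle_minus_systolic_position(self):
        fset = make_fiducials(a=1.0, b=-0.5, c=0.1, d=-0.2, e=0.05)
        v = features.extract_ppg_features(make_cycle(M=200), fset)
        assert v.get("p2o") == 140.0  # M=200, n_sys=60

    def test_missing_diastole_propagates_only_dia_features(self):
        fset = make_fiducials(a=1.0, b=-0.5, c=0.1, d=-0.2, e=0.05)
        fset.missing.add("diastolic")
        v = features.extract_ppg_features(make_cycle(), fset)
        assert "n_dia" not in v and "A_dia" not in v
        assert "p2o" in v and "age_index" in v

    def test_tiny_denominator_drops_index(self):
        fset = make_fiducials(a=1e-12, b=-0.5, c=0.1, d=-0.2, e=0.05)
        v = features.extract_ppg_features(make_cycle(), fset)
        assert "age_index" not in v and "age_index_v" not in v


class TestWpdFeatures:
    def _decomposition(self, n_ps=35, n_pd=95):
        comps = wpd.ComponentSet.from_arrays(
            [1.0, 0.5, 0.3, 0.2, 0.1], [30, 38, 55, 92, 110], [8, 10, 12, 10, 12]
        )
        dec = wpd.Decomposition(
            theta_hat=comps, synthesized=np.zeros(160), wpd_sqi=0.0,
            weighted_objective=0.0, offset=0.0, n_pf=30, n_ps=n_ps, n_pd=n_pd,
        )
        return dec

    def test_si_is_peak_interval(self):
        v = features.extract_wpd_features(self._decomposition())
        assert v.get("si") == 60.0

    def test_component_to_forward_intervals(self):
        v = features.extract_wpd_features(self._decomposition())
        assert v.get("beta3_minus_npf") == 25.0  # beta3 55 - n_pf 30
        assert v.get("beta4_minus_npf") == 62.0

    def test_missing_diastolic_peak_drops_si(self):
        v = features.extract_wpd_features(self._decomposition(n_pd=None))
        assert "si" not in v
        assert "n_ps" in v


class TestEcgFeatures:
    def test_pat_sign_convention(self):
        v = features.extract_ecg_features(make_cycle(n_r=-180), fiducials.FiducialSet())
        assert v.get("pat") == 180.0
        assert v.get("pat2") == 32400.0

    def test_height_over_pat_squared(self):
        v = features.extract_ecg_features(
            make_cycle(n_r=-180), fiducials.FiducialSet(), height_cm=170.0
        )
        assert v.get("h2_over_pat2") == pytest.approx(28900.0 / 32400.0)
        assert v.get("h2_over_pat2") == pytest.approx(0.8920, abs=1e-4)

    def test_r_to_max_slope_span(self):
        fset = fiducials.FiducialSet(n_ms=25)
        v = features.extract_ecg_features(make_cycle(n_r=-180), fset)
        assert v.get("r_to_ms") == 205.0

    def test_positive_n_r_rejected(self):
        cyc = make_cycle(n_r=-1)
        cyc.r_index = cyc.onset_index - 1
        fset = fiducials.FiducialSet(n_R=5)
        with pytest.raises(ValueError):
            features.extract_ecg_features(cyc, fset)


class TestBodyLengths:
    @pytest.mark.parametrize(
        "height,la,lb",
        [(170.0, 152.051, 35.242), (160.0, 143.832, 33.047)],
    )
    def test_path_length_approximations(self, height, la, lb):
        v = features.compute_body_lengths(height)
        assert v.get("la") == pytest.approx(la, abs=1e-3)
        assert v.get("lb") == pytest.approx(lb, abs=1e-3)
        assert v.get("la_minus_lb") == pytest.approx(la - lb, abs=1e-3)

    def test_age_and_bmi_passthrough(self):
        v = features.compute_body_lengths(170.0, age=60.0, weight_kg=70.0)
        assert v.get("age") == 60.0 and v.get("age2") == 3600.0
        assert v.get("bmi") == pytest.approx(70.0 / 1.7**2)

    def test_out_of_range_height_rejected(self):
        with pytest.raises(ValueError):
            features.compute_body_lengths(0.0)
        with pytest.raises(ValueError):
            features.compute_body_lengths(250.0)


class TestRatioCombination:
    def test_simple_ratio(self):
        v = features.FeatureVector({"u": 4.0, "v": 2.0}, {})
        out = features.combine_ratio_features(v, [("u", "v")])
        assert out.get("u_over_v") == 2.0

    def test_age_over_nms_example(self):
        v = features.FeatureVector({"age": 60.0, "n_ms": 25.0}, {})
        out = features.combine_ratio_features(v, [("age", "n_ms")])
        assert out.get("age_over_n_ms") == 2.4

    def test_missing_or_tiny_denominator_skipped(self):
        v = features.FeatureVector({"u": 4.0, "eps": 1e-12}, {})
        out = features.combine_ratio_features(v, [("u", "v"), ("u", "eps")])
        assert "u_over_v" not in out and "u_over_eps" not in out

    def test_default_all_ordered_pairs_excluding_diagonal(self):
        v = features.FeatureVector({"x": 1.0, "y": 2.0, "z": 4.0}, {})
        out = features.combine_ratio_features(v)
        combined = [k for k in out.values if "_over_" in k]
        assert len(combined) == 6
        assert "x_over_x" not in out.values


class TestAggregation:
    def test_median_then_mean(self):
        rows = [
            {"measurement_id": "m1", "sequence_id": "s1", "f": 10.0},
            {"measurement_id": "m1", "sequence_id": "s1", "f": 12.0},
            {"measurement_id": "m1", "sequence_id": "s1", "f": 100.0},
            {"measurement_id": "m1", "sequence_id": "s2", "f": 14.0},
        ]
        out = features.aggregate_measurement(pd.DataFrame(rows))
        # sequence medians 12 and 14, measurement mean 13
        assert out.loc["m1", "f"] == 13.0

    def test_feature_present_in_one_sequence_only(self):
        rows = [
            {"measurement_id": "m1", "sequence_id": "s1", "f": 7.0},
            {"measurement_id": "m1", "sequence_id": "s2", "f": np.nan},
            {"measurement_id": "m1", "sequence_id": "s3", "f": np.nan},
        ]
        out = features.aggregate_measurement(pd.DataFrame(rows))
        assert out.loc["m1", "f"] == 7.0

    def test_median_robust_to_minority_outliers(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            clean = rng.normal(50.0, 1.0, 100)
            corrupted = clean.copy()
            corrupted[:40] = 1e4  # 40% outliers
            iqr = float(np.subtract(*np.percentile(clean, [75, 25])))
            assert abs(np.median(corrupted) - np.median(clean)) <= abs(iqr)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            features.aggregate_measurement(
                pd.DataFrame(columns=["measurement_id", "sequence_id", "f"])
            )


def test_catalog_registers_all_text_named_features():
    named = [
        "p2o", "si", "pat", "pat2", "h2_over_pat2", "age_index", "age_index_v",
        "A_c2", "A_d2", "A_e2", "age", "age2", "la", "lb", "la_minus_lb",
        "r_to_ms", "r_to_ps", "r_to_beta2",
    ]
    for fid in named:
        assert fid in features.CATALOG.registry, fid
    assert set(features.CANONICAL_IDS.values()) == {1, 18, 19, 20, 23, 51, 63}


def test_positions_convert_to_seconds_by_ts(template_cycle):
    fset = fiducials.extract_fiducials(template_cycle)
    v = features.extract_ppg_features(template_cycle, fset)
    # sample-domain features are fs-free; seconds view is position * Ts
    assert v.get("n_sys") / FS == pytest.approx(v.get("n_sys") * template_cycle.Ts)
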