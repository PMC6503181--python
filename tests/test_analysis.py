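"""Tandem-lesion strategy enumeration and paired-FFR statistics."""

import numpy as np
import pytest

import stentflow as sf
from stentflow.analysis import (
    LesionSpec,
    PairedFFR,
    bland_altman,
    correlation,
    diagnostic_accuracy,
    tandem_analysis,
)
from stentflow.hemodynamics import compute_vffr, solve_reduced
from stentflow.stenting import deploy_stents


@pytest.fixture()
def tandem_vessel():
    """Two significant lesions in series, 80 mm vessel."""
    return sf.make_synthetic_vessel(
        80.0, 1.5,
        [sf.StenosisSpec(25.0, 14.0, 0.55), sf.StenosisSpec(55.0, 14.0, 0.5)],
    )


@pytest.fixture()
def tandem_lesions():
    return [LesionSpec(17.0, 33.0, 3.0), LesionSpec(47.0, 63.0, 3.0)]


class TestTandemAnalysis:
    def test_two_lesion_strategy_ordering(self, tandem_vessel, tandem_lesions, bc_default):
        rep = tandem_analysis(tandem_vessel, tandem_lesions, bc_default)
        both = rep.vffr_of((0, 1))
        prox = rep.vffr_of((0,))
        dist = rep.vffr_of((1,))
        # treating everything beats either single-lesion strategy, which
        # beats leaving both untreated
        assert both > max(prox, dist) > rep.baseline_vffr
        assert rep.best.lesions == (0, 1)

    def test_single_lesion_report_matches_manual_composition(self, bc_default):
        v = sf.make_synthetic_vessel(50.0, 1.5, [sf.StenosisSpec(25.0, 14.0, 0.5)])
        lesion = LesionSpec(17.0, 33.0, 3.0)
        rep = tandem_analysis(v, [lesion], bc_default)
        stented = deploy_stents(v, [lesion.to_stent()])
        manual = compute_vffr(
            solve_reduced(stented, bc_default), 0.0, stented.length
        ).vffr
        assert rep.vffr_of((0,)) == pytest.approx(manual, abs=1e-12)

    def test_monotonicity_over_all_subsets_three_lesions(self, bc_default):
        v = sf.make_synthetic_vessel(
            100.0, 1.5,
            [
                sf.StenosisSpec(20.0, 10.0, 0.5),
                sf.StenosisSpec(50.0, 10.0, 0.45),
                sf.StenosisSpec(80.0, 10.0, 0.4),
            ],
        )
        lesions = [
            LesionSpec(14.0, 26.0, 3.0),
            LesionSpec(44.0, 56.0, 3.0),
            LesionSpec(74.0, 86.0, 3.0),
        ]
        rep = tandem_analysis(v, lesions, bc_default)
        results = {st.lesions: st.vffr for st in rep.strategies}
        results[()] = rep.baseline_vffr
        for subset, vffr in results.items():
            for bigger, vffr_b in results.items():
                if set(subset) < set(bigger):
                    assert vffr_b >= vffr - 1e-9

    def test_overlapping_lesions_rejected(self, tandem_vessel, bc_default):
        with pytest.raises(ValueError, match="overlap"):
            tandem_analysis(
                tandem_vessel,
                [LesionSpec(17.0, 40.0, 3.0), LesionSpec(35.0, 63.0, 3.0)],
                bc_default,
            )

    def test_lesion_cap_guards_strategy_explosion(self, bc_default):
        v = sf.make_synthetic_vessel(200.0, 1.5, [])
        lesions = [LesionSpec(10.0 * i + 5, 10.0 * i + 12, 3.0) for i in range(7)]
        with pytest.raises(ValueError, match="max_lesions"):
            tandem_analysis(v, lesions, bc_default)

    def test_deterministic_report_ordering(self, tandem_vessel, tandem_lesions, bc_default):
        rep = tandem_analysis(tandem_vessel, tandem_lesions, bc_default)
        assert [st.lesions for st in rep.strategies] == [(0,), (1,), (0, 1)]


class TestBlandAltman:
    def test_perfect_agreement(self):
        x = np.array([0.7, 0.8, 0.9])
        ba = bland_altman(PairedFFR(x, x))
        assert ba["bias"] == 0.0
        assert ba["sd"] == 0.0

    def test_hand_computed_values(self):
        mffr = np.array([0.80, 0.70, 0.90])
        vffr = mffr - np.array([0.02, -0.04, 0.05])
        ba = bland_altman(PairedFFR(mffr, vffr))
        assert ba["bias"] == pytest.approx(0.01, abs=1e-12)
        assert ba["sd"] == pytest.approx(0.045826, abs=1e-5)
        assert ba["limits"][0] == pytest.approx(0.01 - 2 * 0.045826, abs=1e-5)
        assert ba["limits"][1] == pytest.approx(0.01 + 2 * 0.045826, abs=1e-5)

    def test_swapping_measurements_negates_bias(self):
        rng = np.random.default_rng(11)
        m = np.clip(0.8 + 0.1 * rng.standard_normal(20), 0.05, 1.0)
        v = np.clip(m + 0.03 * rng.standard_normal(20), 0.05, 1.0)
        fwd = bland_altman(PairedFFR(m, v))
        rev = bland_altman(PairedFFR(v, m))
        assert rev["bias"] == pytest.approx(-fwd["bias"], abs=1e-15)
        assert rev["sd"] == pytest.approx(fwd["sd"], abs=1e-15)

    def test_limits_contain_95_percent_of_gaussian_differences(self):
        rng = np.random.default_rng(42)
        n = 10_000
        m = np.clip(0.8 + 0.05 * rng.standard_normal(n), 0.05, 1.0)
        v = np.clip(m + 0.02 * rng.standard_normal(n), 0.05, 1.0)
        ba = bland_altman(PairedFFR(m, v))
        d = ba["differences"]
        frac = np.mean((d >= ba["limits"][0]) & (d <= ba["limits"][1]))
        assert frac >= 0.95

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            bland_altman(PairedFFR([0.8], [0.8]))


class TestDiagnosticAccuracy:
    def test_all_concordant_gives_perfect_metrics(self):
        m = np.array([0.7, 0.75, 0.85, 0.9])
        da = diagnostic_accuracy(PairedFFR(m, m))
        assert da["sensitivity"] == 1.0
        assert da["specificity"] == 1.0
        assert da["accuracy"] == 1.0

    def test_reconstructed_cohort_confusion_matrix(self):
        """TP=46, FN=4, TN=7, FP=0 reproduces sensitivity 92%, specificity
        100%, PPV 100%, NPV 64%, accuracy 93%."""
        mffr = np.concatenate(
            [np.full(46, 0.70), np.full(4, 0.75), np.full(7, 0.90)]
        )
        vffr = np.concatenate(
            [np.full(46, 0.72), np.full(4, 0.85), np.full(7, 0.88)]
        )
        da = diagnostic_accuracy(PairedFFR(mffr, vffr))
        assert da["confusion"] == {"tp": 46, "fn": 4, "fp": 0, "tn": 7}
        assert da["sensitivity"] == pytest.approx(0.92)
        assert da["specificity"] == pytest.approx(1.00)
        assert da["ppv"] == pytest.approx(1.00)
        assert da["npv"] == pytest.approx(7 / 11, abs=5e-3)  # 63.6% ~ 64%
        assert da["accuracy"] == pytest.approx(53 / 57, abs=1e-12)  # 93.0%

    def test_boundary_value_is_positive(self):
        da = diagnostic_accuracy(PairedFFR([0.80], [0.80]))
        assert da["confusion"]["tp"] == 1

    def test_undefined_ratios_flagged_not_zeroed(self):
        m = np.array([0.9, 0.95])  # no ischemic vessels at all
        da = diagnostic_accuracy(PairedFFR(m, m))
        assert np.isnan(da["sensitivity"])
        assert "sensitivity" in da["undefined"]
        assert "ppv" in da["undefined"]

    def test_pair_order_invariance_and_count_consistency(self):
        rng = np.random.default_rng(5)
        m = np.clip(0.8 + 0.1 * rng.standard_normal(30), 0.05, 1.0)
        v = np.clip(m + 0.05 * rng.standard_normal(30), 0.05, 1.0)
        da1 = diagnostic_accuracy(PairedFFR(m, v))
        perm = rng.permutation(30)
        da2 = diagnostic_accuracy(PairedFFR(m[perm], v[perm]))
        assert da1["confusion"] == da2["confusion"]
        assert sum(da1["confusion"].values()) == 30

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            PairedFFR([0.8, 1.2], [0.8, 0.9])


class TestCorrelation:
    def test_perfectly_linear_pairs(self):
        m = np.array([0.5, 0.6, 0.7, 0.8])
        co = correlation(PairedFFR(m, m * 0.9 + 0.05))
        assert co["r"] == pytest.approx(1.0)

    def test_anti_linear_pairs(self):
        m = np.array([0.5, 0.6, 0.7, 0.8])
        co = correlation(PairedFFR(m, 1.0 - 0.5 * m))
        assert co["r"] == pytest.approx(-1.0)

    def test_hand_picked_pairs_match_direct_formula(self):
        m = np.array([0.55, 0.68, 0.79, 0.92])
        v = np.array([0.60, 0.66, 0.83, 0.88])
        co = correlation(PairedFFR(m, v))
        mc, vc = m - m.mean(), v - v.mean()
        r_direct = (mc * vc).sum() / np.sqrt((mc**2).sum() * (vc**2).sum())
        assert co["r"] == pytest.approx(r_direct, abs=1e-12)
        slope_direct = (m * v).sum() / (m * m).sum()
        assert co["slope_through_origin"] == pytest.approx(slope_direct, abs=1e-12)

    def test_zero_variance_flagged(self):
        co = correlation(PairedFFR([0.8, 0.8, 0.8], [0.7, 0.8, 0.9]))
        assert np.isnan(co["r"])
        assert "r" in co["undefined"]
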