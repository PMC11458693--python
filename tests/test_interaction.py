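import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scftir.interaction import (
    CombinationMeasurement,
    DoseResponseTable,
    bliss_independence,
    cdi_additivity,
    fit_ic50_4pl,
    four_param_logistic,
    hsa_independence,
    interaction_report,
    mass_to_molar,
    to_inhibition,
)

fractions = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestMassToMolar:
    # printed dose pairs for resveratrol (228.25 g/mol) and cisplatin (300.05 g/mol)
    @pytest.mark.parametrize(
        "ug_ml,molar_mass,expected_um",
        [
            (24.0, 228.25, 105.15),
            (21.06, 228.25, 92.27),
            (80.0, 228.25, 350.50),
            (9.0, 300.05, 30.00),
            (4.98, 300.05, 16.60),
            (4.5, 300.05, 15.00),
        ],
    )
    def test_printed_dose_pairs_within_2_hundredths_um(self, ug_ml, molar_mass, expected_um):
        assert mass_to_molar(ug_ml, molar_mass) == pytest.approx(expected_um, abs=0.02)

    def test_zero_concentration(self):
        assert mass_to_molar(0.0, 228.25) == 0.0

    def test_nonpositive_molar_mass_rejected(self):
        with pytest.raises(ValueError):
            mass_to_molar(1.0, 0.0)


class TestCdiAdditivity:
    def test_cdi_above_one_is_antagonism(self):
        # viability triple with P(a+b)/(Pa*Pb) = 0.48/0.20 = 2.4
        m = CombinationMeasurement(0.5, 0.4, 0.48, "viability")
        r = cdi_additivity(m)
        assert r.statistic == pytest.approx(2.4)
        assert r.call == "antagonism"

    def test_product_response_is_additive(self):
        m = CombinationMeasurement(0.5, 0.8, 0.4, "viability")
        r = cdi_additivity(m)
        assert r.statistic == pytest.approx(1.0)
        assert r.call == "additivity"

    def test_cdi_below_one_is_synergy(self):
        m = CombinationMeasurement(0.5, 0.8, 0.3, "viability")
        r = cdi_additivity(m)
        assert r.statistic == pytest.approx(0.75)
        assert r.call == "synergy"

    def test_zero_single_agent_product_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cdi_additivity(CombinationMeasurement(0.0, 0.5, 0.3))

    def test_rescaling_changes_the_statistic(self):
        # CDI is a ratio of a response to a product of responses: a common
        # rescaling of all three responses changes it and must not be hidden
        a = cdi_additivity(CombinationMeasurement(0.5, 0.4, 0.48)).statistic
        b = cdi_additivity(CombinationMeasurement(0.25, 0.2, 0.24)).statistic
        assert a != pytest.approx(b)


class TestBlissIndependence:
    def test_observed_088_vs_expected_084_is_synergy(self):
        m = CombinationMeasurement(0.6, 0.6, 0.88, "inhibition")
        r = bliss_independence(m)
        assert r.expected == pytest.approx(0.84)
        assert r.call == "synergy"

    def test_zero_single_agents_follow_combination_sign(self):
        base = CombinationMeasurement(0.0, 0.0, 0.0, "inhibition")
        assert bliss_independence(base).call == "additivity"
        hot = CombinationMeasurement(0.0, 0.0, 0.5, "inhibition")
        assert bliss_independence(hot).call == "synergy"

    def test_expected_hand_arithmetic(self):
        m = CombinationMeasurement(0.5, 0.6, 0.7, "inhibition")
        assert bliss_independence(m).expected == pytest.approx(0.8)

    def test_viability_kind_rejected_with_conversion_hint(self):
        with pytest.raises(ValueError, match="to_inhibition"):
            bliss_independence(CombinationMeasurement(0.5, 0.5, 0.5, "viability"))


class TestHsaIndependence:
    def test_combination_above_both_singles_is_synergy(self):
        m = CombinationMeasurement(0.7, 0.6, 0.88, "inhibition")
        r = hsa_independence(m)
        assert r.expected == pytest.approx(0.7)
        assert r.call == "synergy"

    def test_combination_at_best_single_is_additive(self):
        m = CombinationMeasurement(0.6, 0.4, 0.6, "inhibition")
        assert hsa_independence(m).call == "additivity"

    def test_combination_below_best_single_is_antagonism(self):
        m = CombinationMeasurement(0.6, 0.3, 0.4, "inhibition")
        assert hsa_independence(m).call == "antagonism"


class TestToInhibition:
    def test_complement(self):
        m = to_inhibition(CombinationMeasurement(0.5, 0.6, 0.12, "viability"))
        assert m.response_ab == pytest.approx(0.88)
        assert m.response_kind == "inhibition"

    def test_involution(self):
        m = CombinationMeasurement(0.25, 0.75, 0.5, "viability")
        assert to_inhibition(to_inhibition(m)) == m

    def test_full_viability_maps_to_zero_inhibition(self):
        m = to_inhibition(CombinationMeasurement(1.0, 1.0, 1.0, "viability"))
        assert (m.response_a, m.response_b, m.response_ab) == (0.0, 0.0, 0.0)


class TestCrossModelProperties:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(pa=fractions, pb=fractions)
    def test_bliss_expected_symmetric_bounded_and_exact(self, pa, pb):
        e1 = 1.0 - (1.0 - pa) * (1.0 - pb)
        m = CombinationMeasurement(pa, pb, 0.5, "inhibition")
        r = bliss_independence(m)
        assert r.expected == pytest.approx(pa + pb - pa * pb, abs=1e-12)
        m_swap = CombinationMeasurement(pb, pa, 0.5, "inhibition")
        assert bliss_independence(m_swap).expected == pytest.approx(e1, abs=1e-12)
        assert max(pa, pb) - 1e-12 <= r.expected <= 1.0 + 1e-12

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(pa=fractions, pb=fractions)
    def test_hsa_expected_never_exceeds_bliss_expected(self, pa, pb):
        m = CombinationMeasurement(pa, pb, 0.5, "inhibition")
        assert hsa_independence(m).expected <= bliss_independence(m).expected + 1e-12


class TestInteractionReport:
    def test_discordant_models_resolve_to_synergy_by_majority(self):
        # the published workflow: CDI computed on one assay's viability
        # fractions (> 1, antagonism) while Bliss and HSA on separately
        # measured inhibition rates both call synergy -> consensus synergy
        from scftir.interaction import consensus_call

        cdi = cdi_additivity(CombinationMeasurement(0.5, 0.4, 0.48, "viability"))
        inh = CombinationMeasurement(0.6, 0.6, 0.88, "inhibition")
        results = [cdi, bliss_independence(inh), hsa_independence(inh)]
        assert [r.call for r in results] == ["antagonism", "synergy", "synergy"]
        assert consensus_call(results) == "synergy"

    def test_all_boundary_cases_yield_additivity(self):
        m = CombinationMeasurement(1.0, 1.0, 1.0, "viability")
        report = interaction_report(m)
        assert report["consensus"] == "additivity"

    def test_consistent_antagonistic_measurement(self):
        # combined viability above the single-agent product: CDI antagonism,
        # and the inhibition complements fall below both null expectations
        m = CombinationMeasurement(0.5, 0.4, 0.48, "viability")
        report = interaction_report(m)
        assert [r.call for r in report["results"]] == [
            "antagonism", "antagonism", "antagonism",
        ]
        assert report["consensus"] == "antagonism"


class TestIC50:
    def test_noise_free_recovery_within_0p1_pct(self):
        c = np.array([1.25, 2.5, 5.0, 10.0, 20.0, 40.0, 80.0])
        y = four_param_logistic(c, 0.05, 1.0, 21.06, 1.5)
        fit = fit_ic50_4pl(DoseResponseTable.from_arrays(c, y))
        assert fit.ic50 == pytest.approx(21.06, rel=1e-3)
        assert fit.hill == pytest.approx(1.5, rel=1e-2)

    def test_constant_responses_rejected(self):
        c = np.array([1.0, 2.0, 4.0, 8.0])
        with pytest.raises(ValueError, match="degenerate"):
            fit_ic50_4pl(DoseResponseTable.from_arrays(c, np.full(4, 0.5)))

    def test_fewer_than_four_distinct_concentrations_rejected(self):
        c = np.array([1.0, 2.0, 4.0, 4.0])
        y = np.array([0.9, 0.7, 0.4, 0.41])
        with pytest.raises(ValueError, match="4 distinct"):
            fit_ic50_4pl(DoseResponseTable.from_arrays(c, y))

    def test_non_monotone_responses_warn(self):
        c = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        y = np.array([0.5, 0.9, 0.3, 0.8, 0.5, 0.6])
        with pytest.warns(UserWarning, match="monotone"):
            try:
                fit_ic50_4pl(DoseResponseTable.from_arrays(c, y))
            except RuntimeError:
                pass

    def test_log_ic50_bias_shrinks_with_noise(self):
        # parameter recovery: median |log error| decreases as noise -> 0
        doses = np.tile(np.array([2.5, 5.0, 10.0, 20.0, 40.0, 80.0]), 3)
        truth = four_param_logistic(doses, 0.05, 1.0, 21.06, 1.5)
        biases = []
        for i, sd in enumerate((0.08, 0.02, 0.005)):
            rng = np.random.default_rng(100 + i)
            errs = [
                abs(
                    np.log(
                        fit_ic50_4pl(
                            DoseResponseTable.from_arrays(
                                doses,
                                np.clip(truth + rng.normal(0, sd, doses.size), 0, 1),
                            )
                        ).ic50
                    )
                    - np.log(21.06)
                )
                for _ in range(30)
            ]
            biases.append(np.median(errs))
        assert biases[0] > biases[2]
        assert biases[2] < 0.02

    def test_invalid_response_fractions_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            DoseResponseTable.from_arrays([1, 2, 4, 8], [1.5, 0.5, 0.4, 0.2])
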