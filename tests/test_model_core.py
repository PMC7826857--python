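"""Reaction propensities and state observables of the whole-cell layer."""

import numpy as np
import pytest

from stocellator import (
    CellState,
    ConstructDesign,
    TranscriptLattice,
    dilution_propensities,
    growth_rate,
    mass_fractions,
    metabolism_propensities,
    mrna_protein_mass_ratio,
    transcription_propensity,
)
from stocellator.model_core import heterologous_mass_fraction
from stocellator.params import ModelParameters


class TestTranscription:
    def test_no_energy_no_transcription(self, mini_params, mini_design, mini_state):
        mini_state.a = 0
        for c in ("R", "ET", "EM", "Q", "H"):
            assert transcription_propensity(c, mini_state, mini_params,
                                            mini_design) == 0.0

    def test_promoter_scaling_saturates(self, mini_params, mini_state):
        design = ConstructDesign(promH=3.0, RBSH=1.0,
                                 codon_profile=np.ones(6))
        mini_state.a = 10 ** 9  # deep saturation of the energy Hill term
        rate = transcription_propensity("H", mini_state, mini_params, design)
        assert rate == pytest.approx(3.0 * mini_params.w["H"], rel=1e-6)

    def test_housekeeping_autoinhibition_half_point(self, mini_design):
        # at a = theta_Q and p_Q = K_q with h_q = 2 both factors are 1/2
        params = ModelParameters(h_q=2.0)
        state = CellState(a=int(params.theta["Q"]),
                          p={"R": 1, "ET": 0, "EM": 0,
                             "Q": int(params.K_q), "H": 0})
        # theta_Q is not an integer; use an exact integer threshold instead
        params = params.replace(theta={**params.theta, "Q": float(state.a)})
        rate = transcription_propensity("Q", state, params, mini_design)
        assert rate == pytest.approx(params.w["Q"] * 0.25, rel=1e-9)

    def test_autoinhibition_monotone_in_pq(self, mini_params, mini_design, mini_state):
        rates = []
        for pq in (0, 50, 200, 1000, 5000):
            mini_state.p["Q"] = pq
            rates.append(transcription_propensity("Q", mini_state,
                                                  mini_params, mini_design))
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_unknown_class_rejected(self, mini_params, mini_design, mini_state):
        with pytest.raises(ValueError):
            transcription_propensity("Z", mini_state, mini_params, mini_design)


class TestMetabolism:
    def test_no_transporter_no_import(self, mini_params, mini_state):
        mini_state.p["ET"] = 0
        imp, _ = metabolism_propensities(mini_state, mini_params)
        assert imp == 0.0

    def test_no_nutrient_no_catabolism(self, mini_params, mini_state):
        mini_state.s_i = 0
        _, cat = metabolism_propensities(mini_state, mini_params)
        assert cat == 0.0

    def test_catabolism_half_saturation(self, mini_params, mini_state):
        mini_state.s_i = int(mini_params.K_m)
        mini_state.p["EM"] = 10
        _, cat = metabolism_propensities(mini_state, mini_params)
        assert cat == pytest.approx(10 * mini_params.v_m / 2, rel=1e-9)


class TestGrowthAndDilution:
    def test_no_translation_no_growth(self, mini_params, mini_state):
        assert mini_state.bound_ribosomes == 0
        assert growth_rate(mini_state, mini_params) == 0.0

    def test_hand_evaluated_growth_rate(self):
        params = ModelParameters(gamma_max=10.0, K_gamma=100.0, M=1e5)
        state = CellState(
            a=100, r_free=0,
            p={"R": 100, "ET": 0, "EM": 0, "Q": 0, "H": 0},
            lattices=[TranscriptLattice("R", L=750,
                                        positions=list(range(1, 101)))],
        )
        assert growth_rate(state, params) == pytest.approx(
            10 * 0.5 * 100 / 1e5, rel=1e-12)

    def test_saturation_identity(self, mini_params):
        # a -> infinity and B = M/gamma_max give Grate -> 1
        B = 50
        params = mini_params.replace(M=float(B) * mini_params.gamma_max)
        state = CellState(
            a=10 ** 12, r_free=0,
            p={"R": B, "ET": 0, "EM": 0, "Q": 0, "H": 0},
            lattices=[TranscriptLattice("R", L=2 * B,
                                        positions=list(range(1, B + 1)))])
        assert growth_rate(state, params) == pytest.approx(1.0, rel=1e-6)

    def test_dilution_proportional_and_zero_at_rest(self, mini_params, mini_state):
        props = dilution_propensities(mini_state, mini_params)
        assert all(v == 0.0 for v in props.values())  # no bound ribosomes
        mini_state.lattices.append(
            TranscriptLattice("H", L=6, positions=[2, 4]))
        mini_state.m_free["H"] = 5
        g = growth_rate(mini_state, mini_params)
        assert g > 0
        props = dilution_propensities(mini_state, mini_params)
        assert props["m_free_H"] == pytest.approx(5 * g)
        assert props["lattice"] == pytest.approx(g)

    def test_lattice_removal_bookkeeping(self, mini_state):
        lat = TranscriptLattice("H", L=6, positions=[1, 3, 5])
        mini_state.lattices.append(lat)
        before = mini_state.bound_ribosomes
        mini_state.lattices.remove(lat)
        assert before - mini_state.bound_ribosomes == 3


class TestMassObservables:
    def test_fractions_sum_to_one(self, mini_params, mini_state):
        fr = mass_fractions(mini_state, mini_params)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)
        assert fr["H"] == heterologous_mass_fraction(mini_state, mini_params)

    def test_hfrac_zero_without_construct(self, mini_params, mini_state):
        mini_state.p["H"] = 0
        assert heterologous_mass_fraction(mini_state, mini_params) == 0.0

    def test_single_class_fraction_is_one(self, mini_params):
        state = CellState(p={"R": 0, "ET": 0, "EM": 0, "Q": 7, "H": 0})
        assert mass_fractions(state, mini_params)["Q"] == 1.0

    def test_equal_mass_split(self):
        # 1 ribosome (750 Rf) against 25 construct proteins (30 Rf each)
        params = ModelParameters()
        state = CellState(p={"R": 1, "ET": 0, "EM": 0, "Q": 0, "H": 25})
        assert mass_fractions(state, params)["H"] == pytest.approx(0.5)

    def test_empty_proteome_rejected(self, mini_params):
        state = CellState()
        with pytest.raises(ValueError):
            mass_fractions(state, mini_params)

    def test_mrna_protein_ratio_hand_value(self):
        params = ModelParameters(mass_per_nt=1.0, mass_per_aa=1.0)
        state = CellState(m_free={"R": 0, "ET": 0, "EM": 0, "Q": 0, "H": 1},
                          p={"R": 0, "ET": 0, "EM": 0, "Q": 0, "H": 10})
        # (1 transcript * 30 Rf * 30 nt) / (10 proteins * 30 Rf * 10 aa)
        assert mrna_protein_mass_ratio(state, params) == pytest.approx(0.3)

    def test_ratio_linear_in_mrna(self, mini_params, mini_state):
        r1 = mrna_protein_mass_ratio(mini_state, mini_params)
        mini_state.m_free = {c: 2 * v for c, v in mini_state.m_free.items()}
        assert mrna_protein_mass_ratio(mini_state, mini_params) == pytest.approx(
            2 * r1, rel=1e-12)

    def test_occupied_transcripts_counted(self, mini_params, mini_state):
        r1 = mrna_protein_mass_ratio(mini_state, mini_params)
        mini_state.lattices.append(TranscriptLattice("Q", L=6, positions=[1]))
        assert mrna_protein_mass_ratio(mini_state, mini_params) > r1
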