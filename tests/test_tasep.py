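"""Exclusion-process translation: transition vector, moves, oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stocellator import (
    CellState,
    ConstructDesign,
    TranscriptLattice,
    apply_move,
    degradation_propensity,
    initiation_propensity,
    simulate_single_lattice,
    stationary_oracle,
    transition_vector,
)
from stocellator.tasep import hop_out_rates


class TestTransitionVector:
    def test_blocked_ribosome_gets_zero(self, unit_gamma):
        lat = TranscriptLattice("H", L=10, positions=[4, 5])
        tv = transition_vector(lat, 1.0, unit_gamma)
        assert tv[0] == 0.0          # directly behind the one at 5
        assert tv[1] == pytest.approx(1.0)

    def test_empty_lattice_empty_vector(self, unit_gamma):
        lat = TranscriptLattice("H", L=10)
        assert transition_vector(lat, 1.0, unit_gamma).size == 0

    def test_spaced_ribosomes_all_free(self, unit_gamma):
        lat = TranscriptLattice("H", L=10, positions=[1, 3])
        tv = transition_vector(lat, 1.0, unit_gamma)
        assert tv == pytest.approx([1.0, 1.0])

    def test_slow_codon_gates_entry_into_its_site(self, unit_gamma):
        # the ribosome approaching the slow site carries its efficiency;
        # the one sitting past it moves at full speed
        eff = np.ones(10)
        eff[5] = 0.01                # site 6 is slow
        lat = TranscriptLattice("H", L=10, positions=[5, 7], eff=eff)
        tv = transition_vector(lat, 1.0, unit_gamma)
        assert tv[0] == pytest.approx(0.01)
        assert tv[1] == pytest.approx(1.0)

    def test_termination_always_allowed(self, unit_gamma):
        lat = TranscriptLattice("H", L=10, positions=[9, 10])
        tv = transition_vector(lat, 1.0, unit_gamma)
        assert tv[0] == 0.0
        assert tv[1] == pytest.approx(1.0)

    def test_energy_scales_all_entries(self, unit_gamma):
        lat = TranscriptLattice("H", L=10, positions=[2, 6])
        tv1 = transition_vector(lat, 1.0, unit_gamma)
        # gamma(a) = 2a/(1+a): a=3 gives 1.5
        tv3 = transition_vector(lat, 3.0, unit_gamma)
        assert tv3 == pytest.approx(1.5 * tv1)


class TestApplyMove:
    def test_termination_releases_protein(self):
        lat = TranscriptLattice("H", L=30, positions=[30])
        lat, released = apply_move(lat, 0)
        assert released == "H"
        assert lat.positions == []

    def test_interior_hop(self):
        lat = TranscriptLattice("H", L=30, positions=[7])
        lat, released = apply_move(lat, 0)
        assert released is None
        assert lat.positions == [8]

    def test_queue_resolves_from_the_front(self):
        eff = np.ones(30)
        eff[25] = 0.005              # slow site 26
        lat = TranscriptLattice("H", L=30, positions=[25, 26], eff=eff)

        class G:
            gamma_max, K_gamma = 2.0, 1.0

        tv = transition_vector(lat, 1.0, G)
        assert tv[0] == 0.0 and tv[1] > 0     # only the front one can move
        apply_move(lat, 1)
        assert lat.positions == [25, 27]
        tv = transition_vector(lat, 1.0, G)
        assert tv[0] > 0                       # the rear one is free now

    def test_blocked_selection_is_an_error(self):
        lat = TranscriptLattice("H", L=30, positions=[4, 5])
        with pytest.raises(ValueError):
            apply_move(lat, 0)


class TestInitiationAndDegradation:
    def test_no_free_ribosomes_no_initiation(self, mini_params, mini_design,
                                             mini_state):
        mini_state.r_free = 0
        assert initiation_propensity("H", mini_state, mini_params,
                                     mini_design) == 0.0

    def test_entry_exclusion(self, mini_params, mini_design, mini_state):
        mini_state.m_free["H"] = 0
        mini_state.lattices = [TranscriptLattice("H", L=6, positions=[1, 4])]
        assert initiation_propensity("H", mini_state, mini_params,
                                     mini_design) == 0.0

    def test_counts_eligible_targets(self, mini_params, mini_state):
        design = ConstructDesign(promH=1.0, RBSH=2.0, codon_profile=np.ones(6))
        mini_state.m_free["H"] = 2
        mini_state.r_free = 5
        mini_state.lattices = [TranscriptLattice("H", L=6, positions=[3])]
        rate = initiation_propensity("H", mini_state, mini_params, design)
        assert rate == pytest.approx(mini_params.b["H"] * 2.0 * 5 * 3)

    def test_ribosome_protection(self, mini_params, mini_state):
        mini_state.m_free["Q"] = 0
        mini_state.lattices = [TranscriptLattice("Q", L=6, positions=[2])
                               for _ in range(10)]
        assert degradation_propensity("Q", mini_state, mini_params) == 0.0

    def test_free_mrna_decay_proportional(self, mini_params, mini_state):
        mini_state.m_free["Q"] = 4
        assert degradation_propensity("Q", mini_state, mini_params) == (
            pytest.approx(4 * mini_params.d_m))


class TestExclusionInvariant:
    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_random_event_streams_preserve_exclusion(self, seed):
        """Random initiation/hop sequences never put two ribosomes on a site."""
        rng = np.random.default_rng(seed)
        eff = np.ones(12)
        eff[rng.integers(1, 12)] = 0.05
        lat = TranscriptLattice("H", L=12, positions=[], eff=eff)

        class G:
            gamma_max, K_gamma = 2.0, 1.0

        for _ in range(300):
            tv = transition_vector(lat, 1.0, G)
            movable = np.flatnonzero(tv)
            can_enter = 1 not in lat.positions
            n_opts = movable.size + (1 if can_enter else 0)
            if n_opts == 0:
                break
            k = rng.integers(n_opts)
            if k < movable.size:
                apply_move(lat, int(movable[k]))
            else:
                lat.positions.insert(0, 1)
            lat.validate()           # raises on any exclusion violation
            assert len(set(lat.positions)) == len(lat.positions)


class TestStationaryOracle:
    def test_single_site_closed_form(self):
        entry, exit_ = 0.7, 1.3
        dens, cur = stationary_oracle(1, entry, np.array([exit_]), exit_)
        assert dens[0] == pytest.approx(entry / (entry + exit_), rel=1e-9)
        assert cur == pytest.approx(entry * exit_ / (entry + exit_), rel=1e-9)

    def test_absorbing_interior_block_kills_current(self):
        hop = np.array([1.0, 0.0, 1.0, 1.0])
        dens, cur = stationary_oracle(4, 0.8, hop, 1.0)
        assert cur == pytest.approx(0.0, abs=1e-9)
        assert dens[:2] == pytest.approx([1.0, 1.0], abs=1e-6)

    def test_oracle_size_guard(self):
        with pytest.raises(ValueError):
            stationary_oracle(13, 1.0, np.ones(13), 1.0)

    def test_simulation_matches_oracle_uniform(self):
        """Long-run event-level density agrees with the exact solution."""
        L, entry = 5, 0.6
        profile = np.ones(L)
        dens_exact, cur_exact = stationary_oracle(
            L, entry, hop_out_rates(profile), profile[-1])
        reps = []
        for seed in range(6):
            rng = np.random.default_rng(1000 + seed)
            d, c, _ = simulate_single_lattice(L, entry, profile, t_max=800.0,
                                              rng=rng, t_burn=80.0)
            reps.append(np.append(d, c))
        reps = np.array(reps)
        mean = reps.mean(axis=0)
        se = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
        target = np.append(dens_exact, cur_exact)
        assert np.all(np.abs(mean - target) <= 3 * se + 1e-3)


class TestClassicEquivalence:
    def test_rejection_scheme_matches_modified_scheme(self):
        """Selecting blocked ribosomes and rejecting their moves (classic
        scheme) gives the same stationary law as never selecting them."""
        L, entry = 4, 0.8
        profile = np.ones(L)
        profile[2] = 0.25

        def classic(seed, t_max=600.0, t_burn=60.0):
            rng = np.random.default_rng(seed)
            out = hop_out_rates(profile)
            occ = np.zeros(L, dtype=int)
            t, occ_time = 0.0, np.zeros(L)
            while t < t_max:
                # every ribosome is selectable; blocked moves are rejected
                rates = [out[j] for j in range(L) if occ[j]]
                sites = [j for j in range(L) if occ[j]]
                if occ[0] == 0:
                    rates.append(entry)
                    sites.append(-1)
                total = sum(rates)
                dt = rng.exponential(1 / total)
                t_new = min(t + dt, t_max)
                if t >= t_burn:
                    occ_time += occ * (t_new - t)
                elif t_new > t_burn:
                    occ_time += occ * (t_new - t_burn)
                t = t_new
                if t >= t_max:
                    break
                j = sites[rng.choice(len(rates), p=np.array(rates) / total)]
                if j == -1:
                    occ[0] = 1
                elif j == L - 1:
                    occ[j] = 0
                elif occ[j + 1] == 0:
                    occ[j], occ[j + 1] = 0, 1
                # else: rejected (time already advanced)
            return occ_time / (t_max - t_burn)

        classic_d = np.array([classic(s) for s in range(6)])
        modified_d = np.array([
            simulate_single_lattice(L, entry, profile, 600.0,
                                    np.random.default_rng(100 + s), 60.0)[0]
            for s in range(6)])
        se = np.sqrt(classic_d.var(axis=0, ddof=1) / 6
                     + modified_d.var(axis=0, ddof=1) / 6)
        diff = np.abs(classic_d.mean(axis=0) - modified_d.mean(axis=0))
        assert np.all(diff <= 3 * se + 2e-2)

    def test_queue_builds_upstream_of_slow_site(self):
        """Time-averaged occupancy just upstream of a slow site exceeds the
        uniform-profile occupancy at the same sites."""
        L = 10
        slow = np.ones(L)
        slow[6] = 0.02               # site 7 slow
        d_slow, _ = stationary_oracle(L, 0.5, hop_out_rates(slow), 1.0)
        d_unif, _ = stationary_oracle(L, 0.5, hop_out_rates(np.ones(L)), 1.0)
        assert np.all(d_slow[4:6] > d_unif[4:6])
        assert d_slow.argmax() == 5  # immediately upstream of site 7
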