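"""Stochastic engine: propensities, exactness oracles, dwell-time statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hipba as h
from hipba.fixtures import birth_death_network, two_state_promoter_network


def get_reaction(net, name):
    return next(r for r in net.reactions if r.name == name)


class TestPropensity:
    def test_dimerization_uses_combinatorial_counting(self, wt_network,
                                                      nominal):
        rxn = get_reaction(wt_network, "HipB dimerization")
        state = np.zeros(8, dtype=int)
        state[wt_network.species_index("B")] = 2
        # beta_B2 * C(2, 2) = 60 * 1; the naive square reading would give 120
        assert h.propensity(rxn, state, nominal, wt_network) == 60.0

    def test_association_needs_two_toxin_copies(self, wt_network, nominal):
        rxn = get_reaction(wt_network, "complex association")
        state = np.zeros(8, dtype=int)
        state[wt_network.species_index("A")] = 1
        state[wt_network.species_index("B2")] = 50
        assert h.propensity(rxn, state, nominal, wt_network) == 0.0

    def test_repressed_promoter_transcribes_at_reduced_rate(self, wt_network,
                                                            nominal):
        rxn = get_reaction(wt_network, "transcription P_b2")
        state = np.zeros(8, dtype=int)
        state[wt_network.species_index("P_b2")] = 1
        assert h.propensity(rxn, state, nominal, wt_network) == 6.0

    def test_negative_counts_rejected(self, wt_network, nominal):
        rxn = wt_network.reactions[0]
        with pytest.raises(ValueError):
            h.propensity(rxn, -np.ones(8, dtype=int), nominal, wt_network)


class TestGillespie:
    def test_same_seed_gives_identical_event_sequence(self, wt_network,
                                                      nominal):
        kwargs = dict(t_end=20.0, seed=99, burn_in=0.0)
        a = h.gillespie_run(wt_network, nominal, **kwargs)
        b = h.gillespie_run(wt_network, nominal, **kwargs)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.states, b.states)

    def test_promoter_conservation_exact_at_every_event(self, wt_ensemble):
        run = wt_ensemble[0]
        totals = run.states[:, :3].sum(axis=1)
        assert np.all(totals == 1)

    def test_counts_are_nonnegative_integers(self, wt_ensemble):
        run = wt_ensemble[0]
        assert run.states.dtype.kind == "i"
        assert run.states.min() >= 0
        assert np.all(np.diff(run.times) > 0)

    def test_absorbing_state_flagged(self, nominal):
        """Pure-decay system empties and is reported as absorbed."""
        net = birth_death_network()
        params = {"alpha": 1e-12, "delta_M": 6.0}
        # promoter removed from the initial state: only decay can fire
        run = h.gillespie_run(
            net, params, init=[0, 5], t_end=1000.0, seed=0, burn_in=0.0
        )
        assert run.absorbed
        assert run.states[-1].tolist() == [0, 0]

    def test_burn_in_must_precede_t_end(self, wt_network, nominal):
        with pytest.raises(ValueError):
            h.gillespie_run(wt_network, nominal, t_end=10.0, burn_in=10.0)


class TestCalibrationOracles:
    def test_birth_death_matches_poisson_law(self, nominal):
        """Constitutive transcription/decay: stationary mean alpha/delta_M
        = 10 and Fano factor 1, within 3 standard errors across seeds."""
        net = birth_death_network()
        means, fanos = [], []
        for seed in range(6):
            run = h.gillespie_run(
                net, nominal, init=[1, 0], t_end=600.0, seed=seed,
                burn_in=100.0,
            )
            stats = h.time_weighted_stats(run, "M")
            means.append(stats.mean)
            fanos.append(stats.fano)
        for observed, expected in ((means, 10.0), (fanos, 1.0)):
            sem = np.std(observed, ddof=1) / np.sqrt(len(observed))
            assert abs(np.mean(observed) - expected) < 3 * sem + 1e-9

    def test_two_state_promoter_occupancy_matches_closed_form(self, nominal):
        """P <-> P' toggling with one repressor copy: bound occupancy is
        theta/(theta + gamma)."""
        net = two_state_promoter_network()
        occs = []
        for seed in range(5):
            run = h.gillespie_run(
                net, nominal, init=[1, 0, 1], t_end=100.0, seed=seed,
                burn_in=5.0,
            )
            occs.append(h.time_weighted_stats(run, "P_b2").mean)
        expected = nominal.theta_B2 / (nominal.theta_B2 + nominal.gamma_B2)
        sem = np.std(occs, ddof=1) / np.sqrt(len(occs))
        assert abs(np.mean(occs) - expected) < 3 * sem + 1e-4

    def test_volume_scaled_means_approach_ode_equilibrium(self, nominal):
        """With counts scaled up 10x (bimolecular rates scaled down), the
        stochastic time averages approach the deterministic equilibrium."""
        scale = 10.0
        params = nominal.replace(
            alpha=nominal.alpha * scale,
            alpha_B2=nominal.alpha_B2 * scale,
            alpha_AB2A=nominal.alpha_AB2A * scale,
            theta_B2=nominal.theta_B2 / scale,
            theta_AB2A=nominal.theta_AB2A / scale,
            beta_B2=nominal.beta_B2 / scale,
            mu=nominal.mu / scale**2,
        )
        net = h.build_wild_type()
        x_eq = h.find_equilibrium(net, params)
        iA = net.species_index("AB2A")
        means = []
        for seed in range(6):
            run = h.gillespie_run(
                net, params, t_end=120.0, seed=seed, burn_in=20.0
            )
            means.append(h.time_weighted_stats(run, "AB2A").mean)
        sem = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - x_eq[iA]) < 3 * sem + 0.02 * x_eq[iA]


class TestTimeWeightedStats:
    def test_constant_observable_has_zero_variance(self):
        mean, var = h.weighted_mean_var(
            np.array([0.0, 1.0, 2.0]), np.array([4.0, 4.0, 4.0]), 0.0, 3.0
        )
        assert (mean, var) == (4.0, 0.0)

    def test_dwell_weighting_not_event_weighting(self):
        # value 1 holds for 9 h, value 0 for 1 h: mean must be 0.9
        mean, _ = h.weighted_mean_var(
            np.array([0.0, 9.0]), np.array([1.0, 0.0]), 0.0, 10.0
        )
        assert mean == pytest.approx(0.9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_stats_invariant_under_redundant_sampling_points(self, seed):
        rng = np.random.default_rng(seed)
        times = np.sort(rng.uniform(0, 10, size=8))
        times[0] = 0.0
        values = rng.integers(0, 5, size=8).astype(float)
        base = h.weighted_mean_var(times, values, 0.0, 12.0)
        # duplicate each segment midpoint with the same value
        mids = (times[:-1] + times[1:]) / 2
        t2 = np.sort(np.concatenate([times, mids]))
        v2 = values[np.searchsorted(times, t2, side="right") - 1]
        dense = h.weighted_mean_var(t2, v2, 0.0, 12.0)
        np.testing.assert_allclose(dense, base, rtol=1e-12)

    def test_fano_undefined_at_zero_mean_with_variance(self):
        stats = h.SummaryStats(mean=0.0, variance=1.0)
        with pytest.raises(ValueError):
            stats.fano

    def test_disjoint_seed_batches_agree_on_fano(self, nominal):
        """Ensemble statistics do not depend on the choice of seed batch."""
        net = birth_death_network()

        def batch(seeds):
            fanos = [
                h.time_weighted_stats(
                    h.gillespie_run(
                        net, nominal, init=[1, 0], t_end=400.0, seed=s,
                        burn_in=50.0,
                    ),
                    "M",
                ).fano
                for s in seeds
            ]
            return np.mean(fanos), np.std(fanos, ddof=1) / np.sqrt(len(fanos))

        m1, se1 = batch(range(100, 105))
        m2, se2 = batch(range(200, 205))
        assert abs(m1 - m2) < 3 * np.hypot(se1, se2)
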