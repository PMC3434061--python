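"""R statistic, threshold events, histograms and architecture comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hipba as h
from hipba.persistence import RSeries, total_antitoxin, total_toxin
from conftest import weighted_corr


def series(values, times=None, t_end=None, burn_in=0.0, threshold=0.5):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(len(values), dtype=float)
    if t_end is None:
        t_end = float(len(values))
    return RSeries(
        times=np.asarray(times, dtype=float), values=values,
        t_end=t_end, burn_in=burn_in, threshold=threshold,
    )


class TestComputeR:
    @pytest.mark.parametrize(
        "A,B,B2,expected",
        [
            (10, 10, 0, 0.5),  # boundary: equal free counts, not a persister
            (0, 7, 3, 0.0),
            (3, 1, 0, 0.75),
        ],
    )
    def test_ratio_definition(self, wt_network, nominal, A, B, B2, expected):
        x = np.zeros(8, dtype=int)
        x[wt_network.species_index("P")] = 1
        x[wt_network.species_index("A")] = A
        x[wt_network.species_index("B")] = B
        x[wt_network.species_index("B2")] = B2
        run = h.gillespie_run(
            wt_network, nominal, init=x, t_end=1e-7, seed=0, burn_in=0.0
        )
        s = h.compute_R(run)
        assert s.values[0] == pytest.approx(
            A / (A + B + 2 * B2) if (A + B + 2 * B2) else np.nan
        )
        s_mono = h.compute_R(run, count_dimers=False)
        assert s_mono.values[0] == pytest.approx(expected)

    def test_no_free_protein_is_undefined_not_an_error(self, wt_network,
                                                       nominal):
        x = np.zeros(8, dtype=int)
        x[wt_network.species_index("P")] = 1
        run = h.gillespie_run(
            wt_network, nominal, init=x, t_end=1e-7, seed=0, burn_in=0.0
        )
        assert np.isnan(h.compute_R(run).values[0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=200),
    )
    def test_bounds_and_monotonicity_in_toxin(self, A, B, B2):
        denom = A + B + 2 * B2
        if denom == 0:
            return
        r = A / denom
        assert 0.0 <= r <= 1.0
        r_more = (A + 1) / (A + 1 + B + 2 * B2)
        assert r_more > r or (B + 2 * B2 == 0 and r == r_more == 1.0)


class TestDetectPersistence:
    def test_below_threshold_has_no_events(self):
        events, frac = h.detect_persistence(series([0.4] * 5))
        assert events == [] and frac == 0.0

    def test_single_excursion_counted_once(self):
        # 0.3 for 2 h, 0.7 for 2 h, 0.3 for 2 h
        s = series([0.3, 0.7, 0.3], times=[0.0, 2.0, 4.0], t_end=6.0)
        events, frac = h.detect_persistence(s)
        assert events == [(2.0, 4.0)]
        assert frac == pytest.approx(2.0 / 6.0)

    def test_all_undefined_flagged(self):
        with pytest.raises(ValueError):
            h.detect_persistence(series([np.nan, np.nan]))

    def test_threshold_agrees_with_raw_count_comparison(self, wt_ensemble):
        """R > 0.5 is exactly 'free toxin exceeds free antitoxin'."""
        run = wt_ensemble[1]
        s = h.compute_R(run)
        A = run.species_series("A")
        free_B = run.species_series("B") + 2 * run.species_series("B2")
        defined = ~np.isnan(s.values)
        np.testing.assert_array_equal(
            s.values[defined] > 0.5, (A > free_B)[defined]
        )


class TestHistogram:
    def test_constant_series_mass_in_one_bin(self):
        edges, mass = h.r_histogram([series([0.2] * 4)], bins=10)
        assert mass.sum() == pytest.approx(1.0, abs=1e-12)
        assert mass[2] == pytest.approx(1.0)

    def test_ensemble_mass_normalized(self, wt_ensemble):
        _, mass = h.r_histogram([h.compute_R(r) for r in wt_ensemble])
        assert mass.sum() == pytest.approx(1.0, abs=1e-12)


class TestWildTypePhenomenology:
    def test_toxin_and_antitoxin_totals_positively_correlated(
        self, wt_ensemble
    ):
        """Cotranscription correlates the two protein totals."""
        cors = [
            weighted_corr(
                run,
                total_toxin(run.states, run.network),
                total_antitoxin(run.states, run.network),
            )
            for run in wt_ensemble
        ]
        assert min(cors) > 0.3

    def test_r_mass_predominantly_below_threshold(self, wt_ensemble):
        edges, mass = h.r_histogram([h.compute_R(r) for r in wt_ensemble])
        below = mass[edges[1:] <= 0.5].sum()
        assert below > 0.5

    def test_persistence_events_present_but_rare(self, wt_ensemble):
        fracs, counts = [], []
        for run in wt_ensemble:
            events, frac = h.detect_persistence(h.compute_R(run))
            fracs.append(frac)
            counts.append(len(events))
        assert sum(counts) > 0
        assert np.mean(fracs) < 0.5


class TestCompareArchitectures:
    def test_replicate_table_schema_and_determinism(self, nominal):
        a = h.compare_architectures(nominal, seeds=range(3), horizon=60.0,
                                    burn_in=10.0)
        b = h.compare_architectures(nominal, seeds=range(3), horizon=60.0,
                                    burn_in=10.0)
        assert list(a.summary.architecture) == [
            "wild_type", "uncoupled", "no_feedback"
        ]
        assert a.replicates.equals(b.replicates)
        assert a.order_tests == {}  # too few seeds for rank tests

    def test_too_few_seeds_rejected(self, nominal):
        with pytest.raises(ValueError):
            h.compare_architectures(nominal, seeds=[1, 2], horizon=50.0)


def test_uncoupled_transcripts_are_uncorrelated(nominal):
    """Separate promoters destroy the transcript-level coupling: the
    stationary correlation of the two mRNAs is indistinguishable from 0."""
    net = h.build_uncoupled()
    init = h.default_ssa_init(net, nominal)
    cors = []
    for seed in range(10):
        run = h.gillespie_run(
            net, nominal, init=init, t_end=150.0, seed=seed, burn_in=30.0
        )
        cors.append(
            weighted_corr(
                run,
                run.species_series("M_A").astype(float),
                run.species_series("M_B").astype(float),
            )
        )
    sem = np.std(cors, ddof=1) / np.sqrt(len(cors))
    assert abs(np.mean(cors)) < 3 * sem + 0.02
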