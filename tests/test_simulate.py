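"""Mosaic simulation: renewal structure, truth composition, pattern emission."""

import numpy as np
import pytest
from scipy import stats as sps

from cgenes import (
    STATES,
    InputError,
    SiteDensities,
    SubcladeSpec,
    TrichotomyModel,
    compose_tracks,
    default_model,
    delimit_subclade,
    emit_alignment,
    ladder_spec,
    simulate_mosaic,
)
from cgenes.fourgamete import extract_informative_sites
from cgenes.io_align import subset
from cgenes.simulate import (
    default_outgroups,
    expected_occupancy,
    topology_of_state,
    topology_track,
)


def uniform_model(mean=200.0):
    return TrichotomyModel(
        mean_length={s: mean for s in STATES},
        stationary_freq={s: 0.25 for s in STATES},
    )


class TestSimulateMosaic:
    def test_same_seed_identical_tracks(self):
        m1 = simulate_mosaic(default_model(), 50_000, seed=11)
        m2 = simulate_mosaic(default_model(), 50_000, seed=11)
        assert m1 == m2

    def test_track_tiles_and_alternates(self):
        m = simulate_mosaic(uniform_model(), 10_000, seed=3)
        assert m.track[0][1] == 0 and m.track[-1][2] == 10_000
        for (s1, _, e1), (s2, b2, _) in zip(m.track, m.track[1:]):
            assert e1 == b2
            assert s1 != s2

    def test_segment_count_matches_renewal_expectation(self):
        L, mean = 1_000_000, 100.0
        m = simulate_mosaic(uniform_model(mean), L, seed=5)
        expected = L / mean
        assert abs(m.n_segments - expected) < 3 * np.sqrt(expected)

    def test_single_state_spans_whole_segment(self):
        model = TrichotomyModel(
            mean_length={s: 100.0 for s in STATES},
            stationary_freq={
                "concordant_deep0": 1.0,
                "concordant_deep1": 0.0,
                "discordant_a": 0.0,
                "discordant_b": 0.0,
            },
        )
        m = simulate_mosaic(model, 5000, seed=1)
        assert m.track == (("concordant_deep0", 0, 5000),)

    def test_occupancy_matches_chain_stationary(self):
        model = default_model()
        L = 10_000_000
        m = simulate_mosaic(model, L, seed=9)
        occ = {s: 0 for s in STATES}
        for state, s, e in m.track:
            occ[state] += e - s
        occ = {s: v / L for s, v in occ.items()}
        exact = expected_occupancy(model)
        for s in STATES:  # ~3 Monte-Carlo standard errors at this L
            assert occ[s] == pytest.approx(exact[s], abs=0.02)
        # and close to the configured frequencies (the design target)
        for s in STATES:
            assert occ[s] == pytest.approx(model.stationary_freq[s], abs=0.05)

    def test_lengths_fit_configured_geometric(self):
        """Per-state lengths pass a chi-square GOF in >= 19 of 20 seeds."""
        model = uniform_model(mean=150.0)
        passes = 0
        for seed in range(20):
            m = simulate_mosaic(model, 600_000, seed=seed)
            lengths = np.array(
                [e - s for st, s, e in m.track[:-1]]  # last segment truncated
            )
            # pool states (identical means) and bin at geometric quantiles
            geom = sps.geom(1 / 150.0)
            qs = np.arange(1, 10) / 10
            cuts = np.concatenate(([0.5], np.unique(geom.ppf(qs)) + 0.5, [np.inf]))
            obs, _ = np.histogram(lengths, bins=cuts)
            exp = np.diff(geom.cdf(cuts)) * len(lengths)
            exp *= obs.sum() / exp.sum()
            _, p = sps.chisquare(obs, exp)
            passes += p > 0.01
        assert passes >= 19


class TestComposeTracks:
    def test_two_tracks_nine_changes_each(self):
        from cgenes.simulate import TrichotomyMosaic

        spec = ladder_spec(2)

        def track_with_changes(positions, L=10_000):
            states = ["concordant_deep0", "discordant_a"]
            edges = [0, *positions, L]
            return TrichotomyMosaic(
                segment_length=L,
                track=tuple(
                    (states[i % 2], edges[i], edges[i + 1])
                    for i in range(len(edges) - 1)
                ),
            )

        m1 = track_with_changes(list(range(1000, 10_000, 1000)))
        m2 = track_with_changes(list(range(500, 9500, 1000)))
        truth = compose_tracks([m1, m2], spec)
        assert len(truth.breakpoints) == 18
        assert truth.n_cgenes == 19
        assert all(len(lab) == 2 for lab in truth.labels)

    def test_deep_coalescence_only_changes_are_silent(self):
        from cgenes.simulate import TrichotomyMosaic

        spec = ladder_spec(1)
        m = TrichotomyMosaic(
            segment_length=3000,
            track=(
                ("concordant_deep0", 0, 1000),
                ("concordant_deep1", 1000, 2000),
                ("concordant_deep0", 2000, 3000),
            ),
        )
        truth = compose_tracks([m], spec)
        assert truth.breakpoints == ()  # one topological c-gene
        assert truth.n_cgenes == 1
        assert truth.annotations == (1000, 2000)

    def test_composite_mean_approaches_m_over_k(self):
        spec = ladder_spec(3)
        model = uniform_model(mean=300.0)
        rng = np.random.default_rng(77)
        L = 1_500_000
        mosaics = [simulate_mosaic(model, L, rng) for _ in range(3)]
        truth = compose_tracks(mosaics, spec)
        composite_mean = L / truth.n_cgenes
        # every state change is a topology change for 1/... not all: deep0<->deep1
        # silent changes reduce breakpoints; account via per-track topology changes
        n_topo = sum(
            len(topology_track(m, t)[0]) - 1
            for m, t in zip(mosaics, spec.trichotomies)
        )
        assert truth.n_cgenes == n_topo + 1 - _n_coincident(truth)
        # uniform model: transitions out of a concordant state are silent
        # (deep0<->deep1) with probability 1/3, and half of all segments are
        # concordant, so 5/6 of state changes alter topology; the composite
        # mean tracks m / (k * 5/6) within Monte-Carlo error
        expected = 300.0 / (3 * (5 / 6))
        assert composite_mean == pytest.approx(expected, rel=0.05)


def _n_coincident(cmap):
    return sum(len(w) - 1 for w in (cmap.provenance or {}).values())


class TestTopologyOfState:
    def test_concordant_states_share_species_resolution(self):
        tri = ladder_spec(1).trichotomies[0]
        assert topology_of_state("concordant_deep0", tri) == tri.species_pair
        assert topology_of_state("concordant_deep1", tri) == tri.species_pair

    def test_discordant_states_take_remaining_resolutions(self):
        tri = ladder_spec(1, species_pair="T1T3").trichotomies[0]
        assert topology_of_state("discordant_a", tri) == "T1T2"
        assert topology_of_state("discordant_b", tri) == "T2T3"


class TestEmitAlignment:
    @pytest.fixture
    def clean_setup(self):
        spec = ladder_spec(2)
        model = uniform_model(mean=800.0)
        rng = np.random.default_rng(123)
        mosaics = [simulate_mosaic(model, 12_000, rng) for _ in range(2)]
        truth = compose_tracks(mosaics, spec)
        return spec, mosaics, truth, rng

    def test_clean_data_recovers_truth_exactly(self, clean_setup):
        spec, mosaics, truth, rng = clean_setup
        aln = emit_alignment(truth, spec, SiteDensities(0.4, 0.1, 0.5), rng)
        outgroups = default_outgroups(spec)
        for tri, mosaic in zip(spec.trichotomies, mosaics):
            sc = SubcladeSpec(name=tri.name, ingroup=tri.taxa, outgroup=outgroups[tri.name])
            detected = delimit_subclade(aln, sc)
            n_topo_changes = len(topology_track(mosaic, tri)[0]) - 1
            assert detected.n_breakpoints == n_topo_changes

    def test_branch_length_only_changes_never_detected(self):
        from cgenes.simulate import TrichotomyMosaic

        spec = ladder_spec(2)
        m_silent = TrichotomyMosaic(
            segment_length=4000,
            track=(
                ("concordant_deep0", 0, 1500),
                ("concordant_deep1", 1500, 3000),
                ("concordant_deep0", 3000, 4000),
            ),
        )
        m_flat = TrichotomyMosaic(
            segment_length=4000, track=(("discordant_a", 0, 4000),)
        )
        truth = compose_tracks([m_silent, m_flat], spec)
        aln = emit_alignment(truth, spec, SiteDensities(0.5, 0.1, 0.4), seed=6)
        outgroups = default_outgroups(spec)
        for tri in spec.trichotomies:
            sc = SubcladeSpec(name=tri.name, ingroup=tri.taxa, outgroup=outgroups[tri.name])
            assert delimit_subclade(aln, sc).n_breakpoints == 0

    def test_zero_informative_density_no_breakpoints(self, clean_setup):
        spec, _, truth, rng = clean_setup
        aln = emit_alignment(truth, spec, SiteDensities(0.0, 0.3, 0.7), rng)
        outgroups = default_outgroups(spec)
        tri = spec.trichotomies[0]
        sc = SubcladeSpec(name=tri.name, ingroup=tri.taxa, outgroup=outgroups[tri.name])
        sub = subset(aln, sc)
        assert extract_informative_sites(sub) == []
        assert delimit_subclade(aln, sc).n_breakpoints == 0

    def test_homoplasy_inflates_detected_breakpoints(self, clean_setup):
        spec, mosaics, truth, _ = clean_setup
        outgroups = default_outgroups(spec)
        truth_counts = sum(
            len(topology_track(m, t)[0]) - 1
            for m, t in zip(mosaics, spec.trichotomies)
        )

        def total_detected(homoplasy_rate, seed):
            aln = emit_alignment(
                truth, spec, SiteDensities(0.4, 0.1, 0.5), seed,
                homoplasy_rate=homoplasy_rate,
            )
            return sum(
                delimit_subclade(
                    aln,
                    SubcladeSpec(name=t.name, ingroup=t.taxa, outgroup=outgroups[t.name]),
                ).n_breakpoints
                for t in spec.trichotomies
            )

        clean = np.mean([total_detected(0.0, s) for s in range(3)])
        noisy = np.mean([total_detected(0.15, s) for s in range(3)])
        assert clean == truth_counts
        assert noisy > clean

    def test_deterministic_per_seed(self, clean_setup):
        spec, _, truth, _ = clean_setup
        a1 = emit_alignment(truth, spec, SiteDensities(0.2, 0.2, 0.6), seed=99)
        a2 = emit_alignment(truth, spec, SiteDensities(0.2, 0.2, 0.6), seed=99)
        assert a1 == a2

    def test_bad_densities_rejected(self):
        with pytest.raises(InputError):
            SiteDensities(0.5, 0.2, 0.2)

    def test_single_trichotomy_needs_extra_outgroup(self):
        spec = ladder_spec(1)
        with pytest.raises(InputError):
            default_outgroups(spec)
        assert default_outgroups(spec, ("out",)) == {"T1": "out"}
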