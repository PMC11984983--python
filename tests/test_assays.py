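"""Bench-assay calculators, classifiers and network filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import beta

from chromodyn.assays import (
    InteractionEdge,
    MillerInput,
    StabilityCounts,
    chromosome_loss_frequency,
    classify_kar9_distribution,
    classify_spb_inheritance,
    filter_interaction_network,
    fold_change,
    loss_fold_change,
    miller_units,
    mitotic_stability,
    read_biogrid,
    spindle_geometry,
)


class TestMillerUnits:
    @pytest.mark.parametrize(
        "od420,od550,od610,t,v,expected",
        [
            (0.0, 0.0, 1.0, 30.0, 0.1, 0.0),
            (0.5, 0.0, 1.0, 30.0, 0.1, 1000 * 0.5 / (30 * 0.1 * 1.0)),  # 166.667
            (0.5, 0.2, 0.8, 15.0, 0.1, 1000 * (0.5 - 1.75 * 0.2) / (15 * 0.1 * 0.8)),  # 125.0
        ],
    )
    def test_direct_evaluation(self, od420, od550, od610, t, v, expected):
        got = miller_units(MillerInput(od420, od550, od610, t, v))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_negative_result_warns(self):
        with pytest.warns(UserWarning, match="negative"):
            miller_units(MillerInput(0.1, 0.2, 1.0, 30.0, 0.1))

    @given(
        od420=st.floats(0.01, 2.0),
        od550=st.floats(0.0, 0.005),
        od610=st.floats(0.1, 2.0),
        t=st.floats(1.0, 120.0),
        v=st.floats(0.01, 1.0),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_doubling_reaction_time_halves_units(self, od420, od550, od610, t, v):
        u1 = miller_units(MillerInput(od420, od550, od610, t, v))
        u2 = miller_units(MillerInput(od420, od550, od610, 2 * t, v))
        assert u2 == pytest.approx(u1 / 2.0, rel=1e-12)


class TestStabilityAndLoss:
    def test_half_stable(self):
        assert mitotic_stability(StabilityCounts(50, 100)).per_100 == pytest.approx(50.0)

    def test_zero_successes_has_positive_upper_bound(self):
        res = mitotic_stability(StabilityCounts(0, 100))
        assert res.per_100 == 0.0
        assert res.ci_low == 0.0 and res.ci_high > 0.0

    def test_clopper_pearson_against_beta_quantile_oracle(self):
        res = mitotic_stability(StabilityCounts(87, 100))
        lo = beta.ppf(0.025, 87, 14) * 100
        hi = beta.ppf(0.975, 88, 13) * 100
        assert res.ci_low == pytest.approx(lo, abs=1e-9)
        assert res.ci_high == pytest.approx(hi, abs=1e-9)
        assert (round(res.ci_low, 1), round(res.ci_high, 1)) == (78.8, 92.9)

    def test_loss_frequency_and_fold(self):
        assert chromosome_loss_frequency(0, 500) == 0.0
        assert fold_change(5 / 1000, 1 / 1000) == pytest.approx(5.0)

    def test_zero_reference_fold_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(fold_change(0.01, 0.0))

    def test_score_interval_coverage(self):
        """The ratio CI covers the true 5x fold change in >= 93% of
        simulated replicates (nominal 95%, binomial slack)."""
        rng = np.random.default_rng(8)
        true_ratio = 5.0
        covered = total = 0
        for _ in range(1000):
            x1 = rng.binomial(1000, 0.005)
            x2 = rng.binomial(1000, 0.001)
            if x1 == 0 and x2 == 0:
                continue
            res = loss_fold_change(x1, 1000, x2, 1000)
            total += 1
            covered += res.ci_low <= true_ratio <= res.ci_high
        assert covered / total >= 0.93


class TestClassifiers:
    @pytest.mark.parametrize(
        "daughter,mother,expected",
        [
            (1000.0, 300.0, "proper"),
            (300.0, 1000.0, "reversed"),
            (520.0, 500.0, "symmetric"),
        ],
    )
    def test_spb_inheritance(self, daughter, mother, expected):
        assert classify_spb_inheritance(daughter, mother, asymmetry_threshold=1.5) == expected

    def test_spb_both_zero_warns_symmetric(self):
        with pytest.warns(UserWarning):
            assert classify_spb_inheritance(0.0, 0.0) == "symmetric"

    @pytest.mark.parametrize(
        "i1,i2,expected",
        [
            (1000.0, 0.0, "strong_asymmetry"),
            (500.0, 500.0, "symmetry"),
            (800.0, 300.0, "weak_asymmetry"),
        ],
    )
    def test_kar9_distribution(self, i1, i2, expected):
        assert classify_kar9_distribution(i1, i2, strong_threshold=5.0, weak_threshold=1.5) == expected

    @given(
        d=st.floats(0.0, 1e6),
        m=st.floats(0.0, 1e6),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_classification_is_exhaustive(self, d, m):
        assert classify_spb_inheritance(d, m) in {"proper", "reversed", "symmetric"}
        assert classify_kar9_distribution(d, m) in {"strong_asymmetry", "weak_asymmetry", "symmetry"}


class TestSpindleGeometry:
    def test_parallel_spindle_is_zero_degrees(self):
        g = spindle_geometry((0, 0), (2, 0), (0, 0), (5, 0), 4.0, 3.0)
        assert g.alignment_angle_deg == pytest.approx(0.0, abs=1e-9)
        assert g.spindle_length_um == pytest.approx(2.0)
        assert g.is_metaphase_length

    def test_perpendicular_spindle_is_ninety_degrees(self):
        g = spindle_geometry((0, 0), (0, 2), (0, 0), (5, 0), 4.0, 3.0)
        assert g.alignment_angle_deg == pytest.approx(90.0)

    def test_obtuse_angle_reported_as_supplement(self):
        v = (np.cos(np.radians(120)), np.sin(np.radians(120)))
        g = spindle_geometry((0, 0), v, (0, 0), (1, 0), 4.0, 3.0)
        assert g.alignment_angle_deg == pytest.approx(60.0)

    def test_budding_index_threshold(self):
        assert spindle_geometry((0, 0), (1.7, 0), (0, 0), (5, 0), 4.0, 2.8).is_large_budded
        assert not spindle_geometry((0, 0), (1.7, 0), (0, 0), (5, 0), 4.0, 2.0).is_large_budded

    def test_coincident_spbs_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            spindle_geometry((1, 1), (1, 1), (0, 0), (5, 0), 4.0, 3.0)

    @given(
        ax=st.floats(-10, 10), ay=st.floats(-10, 10),
        bx=st.floats(-10, 10), by=st.floats(-10, 10),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_angle_always_in_0_90(self, ax, ay, bx, by):
        if np.hypot(ax, ay) < 1e-6 or np.hypot(bx, by) < 1e-6:
            return
        g = spindle_geometry((0, 0), (ax, ay), (0, 0), (bx, by), 4.0, 3.0)
        assert 0.0 <= g.alignment_angle_deg <= 90.0


FIXTURE_EDGES = [
    InteractionEdge("ATG11", "SPC72", 4),
    InteractionEdge("ATG11", "ATG19", 5),
    InteractionEdge("ATG11", "KAR9", 2),  # below the 3-study bar
    InteractionEdge("SPC72", "STU2", 3),
    InteractionEdge("STU2", "BIM1", 6),
    InteractionEdge("ATG19", "AMS1", 3),
]


class TestNetworkFilter:
    def test_weakly_supported_edge_excluded(self):
        g = filter_interaction_network(FIXTURE_EDGES, ["ATG11"], min_studies=3, hops=1)
        assert not g.has_edge("ATG11", "KAR9")

    def test_zero_hops_returns_seeds_only(self):
        g = filter_interaction_network(FIXTURE_EDGES, ["ATG11"], hops=0)
        assert set(g.nodes) == {"ATG11"}
        assert g.number_of_edges() == 0

    def test_two_hop_subnetwork_matches_hand_enumeration(self):
        """Hand-enumerated answer on the 6-edge fixture: hop 1 from ATG11
        reaches SPC72 and ATG19 (KAR9 excluded at 2 studies); hop 2 adds
        STU2 and AMS1; BIM1 is three hops out and absent."""
        g = filter_interaction_network(FIXTURE_EDGES, ["ATG11"], min_studies=3, hops=2)
        assert set(g.nodes) == {"ATG11", "SPC72", "ATG19", "STU2", "AMS1"}
        assert set(map(frozenset, g.edges)) == {
            frozenset({"ATG11", "SPC72"}),
            frozenset({"ATG11", "ATG19"}),
            frozenset({"SPC72", "STU2"}),
            frozenset({"ATG19", "AMS1"}),
        }

    def test_monotone_in_min_studies(self):
        sizes = [
            filter_interaction_network(FIXTURE_EDGES, ["ATG11"], min_studies=k, hops=2).number_of_edges()
            for k in (1, 3, 5, 7)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_absent_seed_kept_as_isolate_with_warning(self):
        with pytest.warns(UserWarning, match="absent"):
            g = filter_interaction_network(FIXTURE_EDGES, ["NUP2"], min_studies=3, hops=2)
        assert set(g.nodes) == {"NUP2"}

    def test_read_biogrid_pools_distinct_publications(self, tmp_path):
        rows = [
            "Official Symbol Interactor A\tOfficial Symbol Interactor B\tPublication Source\tExperimental System Type",
            "ATG11\tSPC72\tPUBMED:1\tphysical",
            "SPC72\tATG11\tPUBMED:2\tphysical",
            "ATG11\tSPC72\tPUBMED:1\tgenetic",  # same study, different system
            "ATG11\tKAR9\tPUBMED:3\tgenetic",
        ]
        path = tmp_path / "biogrid.tab3.txt"
        path.write_text("\n".join(rows) + "\n")
        edges = {e.pair: e for e in read_biogrid(path)}
        assert edges[frozenset({"ATG11", "SPC72"})].n_studies == 2
        assert edges[frozenset({"ATG11", "KAR9"})].n_studies == 1
        physical = read_biogrid(path, physical_only=True)
        assert {e.pair for e in physical} == {frozenset({"ATG11", "SPC72"})}
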