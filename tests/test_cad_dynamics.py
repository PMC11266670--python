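import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cadpipe import cad_dynamics as cad
from cadpipe.genome_io import RegionSet
from conftest import make_rs
from oracles import template_label_oracle


def all_state_vectors(t=8):
    for bits in itertools.product([False, True], repeat=t + 2):
        yield bits[0], bits[1:-1], bits[-1]


class TestClassifyStateVector:
    def test_matches_rule_table_enumeration(self):
        """Every possible 10-bit presence vector labels identically to an
        independently written template-table oracle, at several tolerances."""
        for tol in (0, 1, 2):
            for mef, d, esc in all_state_vectors():
                assert cad.classify_state_vector(mef, d, esc, tol) == \
                    template_label_oracle(mef, d, esc, tol), (mef, d, esc, tol)

    @pytest.mark.parametrize(
        "mef,d,esc,expected",
        [
            # closed through the course, open only in the destination state
            (False, (0, 0, 0, 0, 0, 0, 0, 0), True, "CO9"),
            # open in the start state, closed from the first timepoint
            (True, (0, 0, 0, 0, 0, 0, 0, 0), False, "OC1"),
            # closed through D3 (3rd timepoint), open from D5 on
            (False, (0, 0, 0, 1, 1, 1, 1, 1), True, "CO4"),
            # open through the course, closing only in the destination state
            (True, (1, 1, 1, 1, 1, 1, 1, 1), False, "OC9"),
            (True, (1, 1, 1, 1, 1, 1, 1, 1), True, "static_open"),
            (False, (0, 0, 0, 0, 0, 0, 0, 0), False, "static_closed"),
            # references agree but course is transient
            (True, (0, 0, 1, 1, 0, 0, 1, 1), True, "complex"),
        ],
    )
    def test_canonical_patterns(self, mef, d, esc, expected):
        assert cad.classify_state_vector(mef, [bool(x) for x in d], esc, 1) == expected

    def test_single_flicker_tolerated(self):
        # one dropout inside an otherwise clean CO3 tail keeps the label
        assert cad.classify_state_vector(False, (0, 0, 1, 1, 0, 1, 1, 1), True, 1) == "CO3"
        assert cad.classify_state_vector(False, (0, 0, 1, 1, 0, 1, 1, 1), True, 0) == "complex"

    @settings(derandomize=True, max_examples=200)
    @given(bits=st.tuples(*[st.booleans()] * 10), tol=st.integers(0, 3))
    def test_raising_tolerance_never_adds_complex(self, bits, tol):
        mef, d, esc = bits[0], bits[1:-1], bits[-1]
        if cad.classify_state_vector(mef, d, esc, tol) != "complex":
            assert cad.classify_state_vector(mef, d, esc, tol + 1) != "complex"


class TestBuildPresence:
    def test_hand_worked_fixture(self, assembly):
        tp = {
            "D0": make_rs([("chr1", 100, 200)], assembly),
            "D1": make_rs([("chr1", 150, 250), ("chr1", 5000, 5400)], assembly),
        }
        mef = make_rs([("chr1", 100, 180)], assembly)
        esc = make_rs([("chr1", 9000, 9100)], assembly)
        pm = cad.build_presence(tp, mef, esc)
        # universe: merged [100,250), [5000,5400), [9000,9100)
        assert len(pm.loci) == 3
        expected = pd.DataFrame(
            {"D0": [True, False, False], "D1": [True, True, False]}
        )
        pd.testing.assert_frame_equal(pm.states, expected)
        assert pm.mef.tolist() == [True, False, False]
        # locus present only in the destination set: closed at every timepoint
        assert pm.esc.tolist() == [False, False, True]
        assert not pm.states.iloc[2].any()

    def test_abutting_peaks_stay_two_loci(self, assembly):
        tp = {
            "D0": make_rs([("chr1", 100, 200)], assembly),
            "D1": make_rs([("chr1", 200, 300)], assembly),
        }
        pm = cad.build_presence(tp, make_rs([], assembly), make_rs([], assembly))
        assert len(pm.loci) == 2

    def test_all_empty_rejected(self, assembly):
        empty = make_rs([], assembly)
        with pytest.raises(ValueError):
            cad.build_presence({"D0": empty, "D1": empty}, empty, empty)


def _assignment(labels, assembly=None):
    loci = make_rs([("chr1", 1000 * i, 1000 * i + 500) for i in range(len(labels))], assembly)
    return cad.DynamicGroupAssignment(
        loci=loci,
        labels=pd.Series(labels),
        timepoints=list(cad.DEFAULT_TIMEPOINTS),
        flicker_tolerance=1,
    )


class TestCompareTrajectories:
    def test_identical_assignments_have_no_failures(self):
        ga = _assignment(["CO3", "CO5", "OC2", "static_open"])
        comp = cad.compare_trajectories(ga, ga)
        assert len(comp.failed_to_open) == 0
        assert len(comp.failed_to_close) == 0

    def test_hand_worked_ten_locus_fixture(self):
        """3 of B's 6 early-CO loci are CO3 in B but never open in A:
        failed-to-open count 3 and early fraction 3/6."""
        b = _assignment(
            ["CO3", "CO3", "CO3", "CO2", "CO2", "CO2", "OC3", "OC3", "static_open", "static_closed"]
        )
        a = _assignment(
            ["CO9", "CO9", "static_closed", "CO2", "CO2", "CO2", "OC3", "OC3", "static_open", "static_closed"]
        )
        comp = cad.compare_trajectories(b, a)
        assert len(comp.failed_to_open) == 3
        assert comp.early_open_fraction == pytest.approx(0.5)
        assert comp.contingency["co_affected_both"] == 3
        assert comp.contingency["co_b_only"] == 3

    def test_failed_to_close_requires_a_still_open(self):
        b = _assignment(["OC3", "OC5", "OC9", "OC9"])
        a = _assignment(["OC9", "static_open", "OC9", "OC3"])
        comp = cad.compare_trajectories(b, a)
        # OC9/OC9 is the same trajectory, not a failure
        assert len(comp.failed_to_close) == 2

    def test_disjoint_universes_rejected(self):
        b = _assignment(["CO3"])
        a = cad.DynamicGroupAssignment(
            loci=make_rs([("chr2", 0, 100)]),
            labels=pd.Series(["CO3"]),
            timepoints=list(cad.DEFAULT_TIMEPOINTS),
            flicker_tolerance=1,
        )
        with pytest.raises(ValueError, match="disjoint"):
            cad.compare_trajectories(b, a)


class TestSyntheticRoundTrip:
    def test_noise_free_labels_and_failures_recovered_exactly(self, noise_free_sim):
        sim = noise_free_sim
        ga = {}
        for cond in ("BiD", "WT"):
            pm = cad.build_presence(
                sim.peaksets[cond], sim.mef_peaks, sim.esc_peaks, universe=sim.loci
            )
            ga[cond] = cad.assign_groups(pm, flicker_tolerance=0)
            assert (
                ga[cond].labels.to_numpy() == sim.truth[f"group_{cond}"].to_numpy()
            ).all()
        comp = cad.compare_trajectories(ga["BiD"], ga["WT"])
        np.testing.assert_array_equal(
            comp.failed_open_mask, sim.truth["failed_to_open"].to_numpy()
        )
        np.testing.assert_array_equal(
            comp.failed_close_mask, sim.truth["failed_to_close"].to_numpy()
        )

    def test_group_counts_partition_universe(self, noise_free_sim):
        sim = noise_free_sim
        pm = cad.build_presence(
            sim.peaksets["BiD"], sim.mef_peaks, sim.esc_peaks, universe=sim.loci
        )
        ga = cad.assign_groups(pm)
        summary = cad.summarize_groups(ga)
        assert summary.counts.sum() == len(sim.loci)
        # planted 12 loci in each of CO1..CO8
        assert summary.co_reprogramming_total == 8 * 12

    def test_counts_invariant_to_locus_order(self, noise_free_sim):
        sim = noise_free_sim
        pm = cad.build_presence(
            sim.peaksets["BiD"], sim.mef_peaks, sim.esc_peaks, universe=sim.loci
        )
        ga = cad.assign_groups(pm)
        perm = np.random.default_rng(1).permutation(len(ga.labels))
        shuffled = cad.DynamicGroupAssignment(
            loci=RegionSet(ga.loci.df.iloc[perm], ga.loci.assembly),
            labels=pd.Series(ga.labels.to_numpy()[perm]),
            timepoints=ga.timepoints,
            flicker_tolerance=ga.flicker_tolerance,
        )
        pd.testing.assert_series_equal(
            cad.summarize_groups(ga).counts, cad.summarize_groups(shuffled).counts
        )
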