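"""Temporal classification of chromatin accessibility dynamics (CAD).

Loci are binarized per timepoint (open = overlaps a called peak) over an
ordered reprogramming time course flanked by a start (MEF) and destination
(ESC) reference state. Each locus is labelled by the timepoint at which it
transitions closed-to-open (CO1..CO_T, with CO_{T+1} for loci opening only
in the destination state) or open-to-closed (OC1..OC_T, OC_{T+1} closing
only in the destination state), or as static/complex. Comparing two
condition trajectories yields the loci that failed to open or failed to
close in the reference condition.

With the default eight reprogramming timepoints (D0..D12) the labels are
CO1..CO9 / OC1..OC9: CO9 = closed through D12 but open in ESC, OC1 = open
in MEF and closed from D0 onward.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import RegionSet, merge_regions, overlap, overlaps_any

__all__ = [
    "DEFAULT_TIMEPOINTS",
    "PresenceMatrix",
    "DynamicGroupAssignment",
    "TrajectoryComparison",
    "classify_state_vector",
    "build_presence",
    "assign_groups",
    "compare_trajectories",
    "summarize_groups",
]

DEFAULT_TIMEPOINTS = ("D0", "D1", "D3", "D5", "D7", "D8", "D10", "D12")


@dataclass
class PresenceMatrix:
    """Binary open/closed states per locus over the time course plus references."""

    loci: RegionSet
    states: pd.DataFrame  # bool, loci x timepoints
    mef: np.ndarray  # bool per locus, start reference
    esc: np.ndarray  # bool per locus, destination reference

    def __post_init__(self) -> None:
        n = len(self.loci)
        if len(self.states) != n or len(self.mef) != n or len(self.esc) != n:
            raise ValueError("presence matrix dimensions inconsistent")

    @property
    def timepoints(self) -> list[str]:
        return list(self.states.columns)


@dataclass
class DynamicGroupAssignment:
    """Per-locus CO/OC/static/complex label; labels partition the universe."""

    loci: RegionSet
    labels: pd.Series  # str per locus, positional index
    timepoints: list[str]
    flicker_tolerance: int

    def group_counts(self) -> pd.Series:
        order = group_order(len(self.timepoints))
        counts = self.labels.value_counts()
        return counts.reindex(order, fill_value=0).astype(int)

    def loci_in(self, groups: Sequence[str]) -> np.ndarray:
        return self.labels.isin(list(groups)).to_numpy()


@dataclass
class TrajectoryComparison:
    """Loci dynamic in condition B but static in condition A, per direction."""

    failed_to_open: RegionSet
    failed_to_close: RegionSet
    failed_open_mask: np.ndarray  # over B's locus universe
    failed_close_mask: np.ndarray
    group_fractions: pd.DataFrame  # per B-group: n, n_failed, fraction
    early_open_fraction: float
    early_close_fraction: float
    contingency: dict = field(default_factory=dict)


def group_order(n_timepoints: int) -> list[str]:
    t = n_timepoints
    return (
        [f"CO{k}" for k in range(1, t + 2)]
        + [f"OC{k}" for k in range(1, t + 2)]
        + ["static_open", "static_closed", "complex"]
    )


def co_groups(n_timepoints: int = 8, include_terminal: bool = False) -> list[str]:
    """CO labels over the reprogramming window (CO1..CO_T), optionally + terminal."""
    upper = n_timepoints + 1 if include_terminal else n_timepoints
    return [f"CO{k}" for k in range(1, upper + 1)]


def oc_groups(n_timepoints: int = 8, start: int = 1, include_terminal: bool = True) -> list[str]:
    upper = n_timepoints + 1 if include_terminal else n_timepoints
    return [f"OC{k}" for k in range(start, upper + 1)]


# ---------------------------------------------------------------------------
# state-vector classification


@functools.lru_cache(maxsize=None)
def _classify_cached(mef: bool, d: tuple, esc: bool, tol: int) -> str:
    t = len(d)
    if mef and esc:
        return "static_open" if sum(1 for x in d if not x) <= tol else "complex"
    if not mef and not esc:
        return "static_closed" if sum(d) <= tol else "complex"
    if not mef and esc:
        # closed-to-open orientation: step templates open from timepoint k,
        # k = t+1 meaning open only in the destination reference
        best_k, best_m = None, tol + 1
        for k in range(1, t + 2):
            mismatch = sum(1 for i in range(t) if d[i] != (i >= k - 1))
            if mismatch < best_m:
                best_k, best_m = k, mismatch
        return f"CO{best_k}" if best_k is not None else "complex"
    # open-to-closed orientation: closed from timepoint k
    best_k, best_m = None, tol + 1
    for k in range(1, t + 2):
        mismatch = sum(1 for i in range(t) if d[i] != (i < k - 1))
        if mismatch < best_m:
            best_k, best_m = k, mismatch
    return f"OC{best_k}" if best_k is not None else "complex"


def classify_state_vector(
    mef: bool, states: Sequence[bool], esc: bool, flicker_tolerance: int = 1
) -> str:
    """Label one locus trajectory by its nearest step template.

    The reference states pick the orientation (MEF closed / ESC open ->
    CO, the reverse -> OC, equal references -> static or complex). Within
    the orientation the course is matched against the ideal step patterns
    "open (closed) from timepoint k", k = 1..T+1, and the label is the
    template with the fewest mismatching timepoints, earliest transition
    winning ties. A locus whose nearest template differs at more than
    ``flicker_tolerance`` timepoints is ``complex``; at tolerance 0 the
    labels are exact pattern matches.
    """
    if len(states) < 2:
        raise ValueError("need at least two timepoints")
    if flicker_tolerance < 0:
        raise ValueError("flicker_tolerance must be >= 0")
    return _classify_cached(bool(mef), tuple(bool(x) for x in states), bool(esc), int(flicker_tolerance))


# ---------------------------------------------------------------------------
# matrix construction and assignment


def build_presence(
    timepoint_peaksets: Mapping[str, RegionSet],
    mef_peaks: RegionSet,
    esc_peaks: RegionSet,
    universe: RegionSet | None = None,
) -> PresenceMatrix:
    """Binarize peak calls onto a merged locus universe.

    The universe is the overlap-merge of every input peak set (abutting
    half-open intervals stay distinct); a locus is open at a timepoint iff
    it overlaps (>=1 bp) a peak called there.
    """
    if len(timepoint_peaksets) < 2:
        raise ValueError("need at least two timepoints")
    all_sets = list(timepoint_peaksets.values()) + [mef_peaks, esc_peaks]
    if universe is None:
        nonempty = [s for s in all_sets if len(s)]
        if not nonempty:
            raise ValueError("cannot build presence matrix: all peak sets empty")
        universe = merge_regions(nonempty, name="locus_universe")
    if not len(universe):
        raise ValueError("empty locus universe")
    states = pd.DataFrame(
        {
            label: overlaps_any(universe, peaks) if len(peaks) else np.zeros(len(universe), bool)
            for label, peaks in timepoint_peaksets.items()
        }
    )
    mef = overlaps_any(universe, mef_peaks) if len(mef_peaks) else np.zeros(len(universe), bool)
    esc = overlaps_any(universe, esc_peaks) if len(esc_peaks) else np.zeros(len(universe), bool)
    return PresenceMatrix(loci=universe, states=states, mef=mef, esc=esc)


def assign_groups(pm: PresenceMatrix, flicker_tolerance: int = 1) -> DynamicGroupAssignment:
    """Label every locus of a presence matrix; the labels partition the universe."""
    vals = pm.states.to_numpy(dtype=bool)
    labels = [
        classify_state_vector(pm.mef[i], vals[i], pm.esc[i], flicker_tolerance)
        for i in range(len(pm.loci))
    ]
    return DynamicGroupAssignment(
        loci=pm.loci,
        labels=pd.Series(labels),
        timepoints=pm.timepoints,
        flicker_tolerance=flicker_tolerance,
    )


# ---------------------------------------------------------------------------
# trajectory comparison


def _match_labels(ga_B: DynamicGroupAssignment, ga_A: DynamicGroupAssignment) -> pd.Series:
    """A-condition label for each B locus, matched by >=1 bp overlap.

    Identical universes match positionally. A B locus absent from A's
    universe was never called open in any A sample and is treated as
    static_closed. When several A loci overlap, the first by coordinate
    wins.
    """
    if len(ga_B.loci) == len(ga_A.loci) and ga_B.loci.df[["chrom", "start", "end"]].equals(
        ga_A.loci.df[["chrom", "start", "end"]]
    ):
        return ga_A.labels.copy()
    pairs = overlap(ga_B.loci, ga_A.loci)
    if pairs.empty:
        raise ValueError("trajectory universes are disjoint; nothing to compare")
    first = pairs.groupby("a_index")["b_index"].first()
    out = pd.Series("static_closed", index=range(len(ga_B.loci)))
    out.loc[first.index] = ga_A.labels.iloc[first.to_numpy()].to_numpy()
    return out


def compare_trajectories(
    ga_B: DynamicGroupAssignment,
    ga_A: DynamicGroupAssignment,
    co_scope: Sequence[str] | None = None,
    oc_scope: Sequence[str] | None = None,
    early_max_group: int = 5,
) -> TrajectoryComparison:
    """Find loci dynamic in condition B whose condition-A trajectory never moved.

    failed-to-open: B label in ``co_scope`` (default CO1..CO_T, the loci
    opening during reprogramming) while A never opens by the final
    timepoint (A label CO_{T+1} or static_closed). failed-to-close is the
    mirror over ``oc_scope`` (default OC2..OC_{T+1}). ``early_max_group``
    bounds the "early" groups used for the headline early-failure fraction.
    """
    t = len(ga_B.timepoints)
    if co_scope is None:
        co_scope = co_groups(t, include_terminal=False)
    if oc_scope is None:
        oc_scope = oc_groups(t, start=2, include_terminal=True)
    a_labels = _match_labels(ga_B, ga_A)
    b_labels = ga_B.labels

    never_open_A = a_labels.isin([f"CO{t + 1}", "static_closed"])
    never_close_A = a_labels.isin([f"OC{t + 1}", "static_open"])

    in_co = b_labels.isin(list(co_scope))
    in_oc = b_labels.isin(list(oc_scope))
    failed_open = (in_co & never_open_A).to_numpy()
    failed_close = (in_oc & never_close_A & (a_labels != b_labels)).to_numpy()

    rows = []
    for g in list(co_scope) + list(oc_scope):
        sel = (b_labels == g).to_numpy()
        n = int(sel.sum())
        nf = int((sel & (failed_open | failed_close)).sum())
        rows.append((g, n, nf, nf / n if n else np.nan))
    fractions = pd.DataFrame(rows, columns=["group", "n", "n_failed", "fraction"]).set_index(
        "group"
    )

    early_co = [g for g in co_scope if int(g[2:]) <= early_max_group]
    early_oc = [g for g in oc_scope if int(g[2:]) <= early_max_group]
    eo_sel = b_labels.isin(early_co).to_numpy()
    ec_sel = b_labels.isin(early_oc).to_numpy()
    early_open_fraction = float((eo_sel & failed_open).sum() / eo_sel.sum()) if eo_sel.any() else np.nan
    early_close_fraction = float((ec_sel & failed_close).sum() / ec_sel.sum()) if ec_sel.any() else np.nan

    contingency = {
        "co_affected_both": int((in_co & a_labels.isin(list(co_scope))).sum()),
        "co_b_only": int(failed_open.sum()),
        "oc_affected_both": int((in_oc & a_labels.isin(list(oc_scope))).sum()),
        "oc_b_only": int(failed_close.sum()),
    }

    uni = ga_B.loci
    return TrajectoryComparison(
        failed_to_open=RegionSet(uni.df[failed_open], uni.assembly, "failed_to_open"),
        failed_to_close=RegionSet(uni.df[failed_close], uni.assembly, "failed_to_close"),
        failed_open_mask=failed_open,
        failed_close_mask=failed_close,
        group_fractions=fractions,
        early_open_fraction=early_open_fraction,
        early_close_fraction=early_close_fraction,
        contingency=contingency,
    )


@dataclass
class GroupSummary:
    counts: pd.Series
    co_reprogramming_total: int  # CO1..CO_T (transitions during the course)
    oc_reprogramming_total: int  # OC1..OC_T


def summarize_groups(ga: DynamicGroupAssignment) -> GroupSummary:
    """Per-group member counts; counts sum to the locus-universe size."""
    counts = ga.group_counts()
    t = len(ga.timepoints)
    co_total = int(counts.loc[co_groups(t)].sum())
    oc_total = int(counts.loc[[f"OC{k}" for k in range(1, t + 1)]].sum())
    assert int(counts.sum()) == len(ga.loci)
    return GroupSummary(counts=counts, co_reprogramming_total=co_total, oc_reprogramming_total=oc_total)
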