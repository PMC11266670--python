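"""Factor/condition co-occupancy codes over binding-peak universes.

Each region of the merged universe of four peak sets — NANOG in the
wild-type condition, NANOG in the engineered (BiD) condition, BRG1 in each
— gets a 4-bit code in that fixed bit order: bit b is 1 iff the region
overlaps the b-th peak set. The codes the analysis focusses on are 0101
(bound by NANOG and BRG1 only in the engineered condition), 0100
(engineered-condition NANOG without a BRG1 peak), and 1101/1100 (the
NANOG-common group with/without engineered-condition BRG1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomeAssembly, RegionSet, merge_regions, overlaps_any

__all__ = [
    "BIT_ORDER",
    "CooccupancyTable",
    "venn_classify",
    "assign_codes",
    "aggregate_signals",
    "stratify_by_annotation",
]

BIT_ORDER = ("NANOG_WT", "NANOG_BiD", "BRG1_WT", "BRG1_BiD")


@dataclass
class VennResult:
    universe: RegionSet
    classes: pd.Series  # per merged region: left_specific / common / right_specific
    counts: pd.Series


@dataclass
class CooccupancyTable:
    """Merged binding universe with a 4-bit presence code per region."""

    regions: RegionSet
    codes: pd.Series  # 4-char strings over {0,1}, bit order BIT_ORDER
    membership: pd.DataFrame  # bool per region per track

    def class_counts(self) -> pd.Series:
        counts = self.codes.value_counts().sort_index()
        counts.name = "n"
        return counts

    def regions_with_code(self, code: str) -> RegionSet:
        mask = (self.codes == code).to_numpy()
        return RegionSet(self.regions.df[mask], self.regions.assembly, f"code_{code}")

    def venn_class(self, factor: str = "NANOG") -> pd.Series:
        """WT-specific / common / BiD-specific from the factor's two bits."""
        wt = self.membership[f"{factor}_WT"]
        bid = self.membership[f"{factor}_BiD"]
        out = pd.Series("absent", index=self.codes.index, dtype=object)
        out[wt & ~bid] = "WT_specific"
        out[~wt & bid] = "BiD_specific"
        out[wt & bid] = "common"
        return out


def venn_classify(peaks_left: RegionSet, peaks_right: RegionSet,
                  labels: tuple[str, str] = ("WT", "BiD")) -> VennResult:
    """Two-set venn over the merged universe; common regions counted once."""
    universe = merge_regions([peaks_left, peaks_right], name="venn_universe")
    in_l = overlaps_any(universe, peaks_left)
    in_r = overlaps_any(universe, peaks_right)
    cls = pd.Series(np.where(in_l & in_r, "common",
                    np.where(in_l, f"{labels[0]}_specific", f"{labels[1]}_specific")))
    counts = cls.value_counts().reindex(
        [f"{labels[0]}_specific", "common", f"{labels[1]}_specific"], fill_value=0
    )
    return VennResult(universe=universe, classes=cls, counts=counts)


def assign_codes(
    nanog_wt: RegionSet,
    nanog_bid: RegionSet,
    brg1_wt: RegionSet,
    brg1_bid: RegionSet,
) -> CooccupancyTable:
    """Code every region of the merged 4-set universe by per-set overlap."""
    if not len(nanog_wt) and not len(nanog_bid):
        raise ValueError("empty NANOG peak union")
    track_sets = dict(zip(BIT_ORDER, (nanog_wt, nanog_bid, brg1_wt, brg1_bid)))
    universe = merge_regions([s for s in track_sets.values() if len(s)], name="cooccupancy_universe")
    membership = pd.DataFrame(
        {
            track: overlaps_any(universe, peaks) if len(peaks) else np.zeros(len(universe), bool)
            for track, peaks in track_sets.items()
        }
    )
    bits = membership.to_numpy().astype(int).astype(str)
    codes = pd.Series(["".join(row) for row in bits])
    return CooccupancyTable(regions=universe, codes=codes, membership=membership)


def _box_summary(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo = x[x >= q1 - 1.5 * iqr].min() if len(x) else np.nan
    hi = x[x <= q3 + 1.5 * iqr].max() if len(x) else np.nan
    return {
        "n": len(x),
        "median": med,
        "q1": q1,
        "q3": q3,
        "whisker_low": lo,
        "whisker_high": hi,
        "mean": float(np.mean(x)),
    }


def aggregate_signals(
    table: CooccupancyTable,
    tracks: pd.DataFrame,
    condition_pairs: Mapping[str, tuple[str, str]] | None = None,
    codes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Boxplot-style summaries of signal per co-occupancy class per track.

    ``tracks``: per-region signal, rows aligned to the coded universe,
    one column per track (e.g. ATAC_WT, ATAC_BiD, H3K27ac_BiD ...).
    ``condition_pairs`` maps a contrast name to a (column_A, column_B)
    pair; for every class the two samples are compared by a two-sided
    Welch t-test. Summaries are median, quartiles and 1.5*IQR whiskers.
    """
    if len(tracks) != len(table.regions):
        raise ValueError(
            f"track rows ({len(tracks)}) do not cover the region universe "
            f"({len(table.regions)})"
        )
    if tracks.isna().any().any():
        bad = tracks.index[tracks.isna().any(axis=1)][:5].tolist()
        raise ValueError(f"missing signal for regions: {bad}")
    tracks = tracks.reset_index(drop=True)
    use_codes = list(codes) if codes is not None else sorted(table.codes.unique())
    rows = []
    for code in use_codes:
        mask = (table.codes == code).to_numpy()
        for col in tracks.columns:
            x = tracks.loc[mask, col].to_numpy(dtype=float)
            if not len(x):
                continue
            rows.append({"code": code, "track": col, **_box_summary(x)})
    out = pd.DataFrame(rows)
    if condition_pairs:
        tests = []
        for code in use_codes:
            mask = (table.codes == code).to_numpy()
            for contrast, (col_a, col_b) in condition_pairs.items():
                a = tracks.loc[mask, col_a].to_numpy(dtype=float)
                b = tracks.loc[mask, col_b].to_numpy(dtype=float)
                if len(a) < 2:
                    p = np.nan
                elif np.array_equal(a, b):
                    p = 1.0  # identical samples carry no evidence
                else:
                    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
                tests.append({"code": code, "contrast": contrast, "p_value": p})
        out = out.merge(
            pd.DataFrame(tests).pivot(index="code", columns="contrast", values="p_value"),
            left_on="code",
            right_index=True,
            how="left",
        )
    return out


def stratify_by_annotation(
    table: CooccupancyTable,
    annotations: Mapping[str, RegionSet],
    assembly: GenomeAssembly,
    codes: Sequence[str] = ("0100", "0101", "1100", "1101"),
    n_permutations: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Overlap fraction and permutation z of each class in each annotation space.

    ``annotations`` typically maps {"enhancer": ..., "promoter": ...};
    the z-score comes from length- and chromosome-preserving uniform
    relocation of the class regions (see
    :func:`cadpipe.association_enrichment.permutation_z`).
    """
    from .association_enrichment import permutation_z

    rows = []
    for i, code in enumerate(codes):
        sub = table.regions_with_code(code)
        for j, (ann_name, ann) in enumerate(annotations.items()):
            if not len(sub):
                rows.append((code, ann_name, 0, np.nan, np.nan))
                continue
            frac = float(overlaps_any(sub, ann).mean())
            enr = permutation_z(
                sub, ann, assembly, n_permutations=n_permutations,
                seed=seed + 7919 * i + 104729 * j,
            )
            rows.append((code, ann_name, len(sub), frac, enr.z))
    return pd.DataFrame(
        rows, columns=["code", "annotation", "n", "overlap_fraction", "z"]
    )
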