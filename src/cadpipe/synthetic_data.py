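"""Miniature two-condition reprogramming dataset with planted ground truth.

Every downstream stage of the pipeline is exercised by data generated
here: accessibility time courses with known CO/OC transition days and
planted failed-to-open/close loci, binding peak sets with known 4-bit
co-occupancy codes, a TF peak compendium with one designed-in enriched
factor, expression time courses with known cluster memberships, and a
pull-down intensity table with known interactors. In the noise-free
setting each analysis stage recovers its planted labels exactly, which is
the central verification mechanism of the package.

Signal model: open loci draw Normal(5, noise_sd), closed Normal(0.5,
noise_sd), truncated at zero — separable but overlappable. Loci are
non-overlapping fixed-width windows (default 500 bp). Both conditions
share one timepoint grid and one pair of MEF/ESC reference states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cad_dynamics import DEFAULT_TIMEPOINTS
from .cooccupancy import BIT_ORDER
from .genome_io import GeneModel, GenomeAssembly, RegionSet, SignalTable

__all__ = [
    "OPEN_MEAN",
    "CLOSED_MEAN",
    "make_genome",
    "make_accessibility_timecourse",
    "make_binding_data",
    "make_compendium",
    "make_expression",
    "make_ipms",
    "make_gene_models",
    "AccessibilitySim",
    "BindingSim",
    "CompendiumSim",
    "ExpressionSim",
    "IpmsSim",
]

OPEN_MEAN = 5.0
CLOSED_MEAN = 0.5

# Fractions of condition-B dynamic loci planted as condition-A failures.
# They mirror the study conditions this generator emulates: the engineered
# condition carries about twice the reprogramming CO loci of the wild type
# (so half of them never open there), while under 10% of closing loci
# differ between conditions.
DEFAULT_FAILED_OPEN_FRAC = 0.5
DEFAULT_FAILED_CLOSE_FRAC = 0.08


def make_genome(n_chroms: int = 2, chrom_length: int = 1_000_000, seed: int = 0) -> GenomeAssembly:
    """Toy assembly of equal-length chromosomes named chr1..chrN."""
    if n_chroms < 1:
        raise ValueError("need at least one chromosome")
    if chrom_length < 100_000:
        raise ValueError("chromosomes shorter than 1e5 leave no room for loci")
    lengths = {f"chr{i + 1}": int(chrom_length) for i in range(n_chroms)}
    return GenomeAssembly(lengths, name=f"synthetic_seed{seed}")


def _place_loci(
    assembly: GenomeAssembly, n: int, width: int, rng: np.random.Generator, gap: int | None = None
) -> pd.DataFrame:
    """Sample n non-overlapping width-bp windows from a genome-wide slot grid."""
    gap = width if gap is None else gap
    step = width + gap
    slots = []
    for chrom in assembly.chroms:
        starts = np.arange(0, assembly.length(chrom) - width + 1, step)
        slots.extend((chrom, int(s)) for s in starts)
    if n > len(slots):
        raise ValueError(
            f"requested {n} loci but the genome only fits {len(slots)} "
            f"non-overlapping {width} bp windows"
        )
    idx = rng.choice(len(slots), size=n, replace=False)
    chosen = [slots[i] for i in sorted(idx)]
    return pd.DataFrame(
        {
            "chrom": [c for c, _ in chosen],
            "start": [s for _, s in chosen],
            "end": [s + width for _, s in chosen],
        }
    )


# ---------------------------------------------------------------------------
# accessibility time course


@dataclass
class AccessibilitySim:
    loci: RegionSet
    timepoints: list[str]
    peaksets: dict  # condition -> {timepoint -> RegionSet}
    mef_peaks: RegionSet  # shared start reference
    esc_peaks: RegionSet  # shared destination reference
    signals: dict  # condition -> SignalTable (loci x [MEF, D.., ESC])
    truth: pd.DataFrame  # per locus: group per condition + failure flags
    seed: int


def _ideal_states(label: str, t: int) -> tuple[bool, np.ndarray, bool]:
    """(mef, course, esc) presence for a group label's noise-free pattern."""
    d = np.zeros(t, dtype=bool)
    if label == "static_open":
        return True, ~d, True
    if label == "static_closed":
        return False, d, False
    kind, k = label[:2], int(label[2:])
    if kind == "CO":
        if k <= t:
            d[k - 1 :] = True
        return False, d, True
    if kind == "OC":
        d[:] = True
        if k <= t:
            d[k - 1 :] = False
        return True, d, False
    raise ValueError(f"unknown group label {label!r}")


def make_accessibility_timecourse(
    assembly: GenomeAssembly,
    n_loci_per_group: int | Mapping[str, int] = 40,
    timepoints: Sequence[str] = DEFAULT_TIMEPOINTS,
    flicker_rate: float = 0.0,
    noise_sd: float = 0.5,
    locus_width: int = 500,
    failed_open_frac: float = DEFAULT_FAILED_OPEN_FRAC,
    failed_close_frac: float = DEFAULT_FAILED_CLOSE_FRAC,
    seed: int = 0,
) -> AccessibilitySim:
    """Two-condition accessibility time course with planted dynamics.

    Condition B (the engineered, BiD-like path) carries the planted group
    labels; condition A (wild-type-like) shares them except for the
    failure loci: ``failed_open_frac`` of each CO1..CO_T group never opens
    in A (its A-label is the terminal CO group), and ``failed_close_frac``
    of each OC2..OC_T group never closes in A by the final timepoint.
    MEF/ESC reference states are shared between conditions, so failures
    are only planted where that sharing permits them. ``flicker_rate``
    flips single-timepoint presence calls independently per condition.
    """
    if not (0 <= flicker_rate < 1):
        raise ValueError("flicker_rate must be in [0,1)")
    t = len(timepoints)
    rng = np.random.default_rng(seed)
    groups = (
        [f"CO{k}" for k in range(1, t + 2)]
        + [f"OC{k}" for k in range(1, t + 2)]
        + ["static_open", "static_closed"]
    )
    if isinstance(n_loci_per_group, Mapping):
        counts = {g: int(n_loci_per_group.get(g, 0)) for g in groups}
    else:
        counts = {g: int(n_loci_per_group) for g in groups}
    labels_b: list[str] = []
    for g in groups:
        labels_b.extend([g] * counts[g])
    n = len(labels_b)
    if n == 0:
        raise ValueError("no loci requested")
    loci_df = _place_loci(assembly, n, locus_width, rng)
    labels_b = list(rng.permutation(labels_b))

    labels_a = list(labels_b)
    failed_open = np.zeros(n, dtype=bool)
    failed_close = np.zeros(n, dtype=bool)
    lab_arr = np.array(labels_b)
    for k in range(1, t + 1):
        members = np.nonzero(lab_arr == f"CO{k}")[0]
        n_fail = int(round(failed_open_frac * len(members)))
        for i in rng.choice(members, size=n_fail, replace=False) if n_fail else []:
            labels_a[i] = f"CO{t + 1}"
            failed_open[i] = True
    for k in range(2, t + 1):
        members = np.nonzero(lab_arr == f"OC{k}")[0]
        n_fail = int(round(failed_close_frac * len(members)))
        for i in rng.choice(members, size=n_fail, replace=False) if n_fail else []:
            labels_a[i] = f"OC{t + 1}"
            failed_close[i] = True

    loci = RegionSet(loci_df, assembly=assembly, name="synthetic_loci")
    all_cols = ["MEF"] + list(timepoints) + ["ESC"]
    peaksets: dict = {}
    signals: dict = {}
    mef_open = np.zeros(n, dtype=bool)
    esc_open = np.zeros(n, dtype=bool)
    for cond, labels in (("BiD", labels_b), ("WT", labels_a)):
        states = np.zeros((n, t), dtype=bool)
        for i, lab in enumerate(labels):
            mef, d, esc = _ideal_states(lab, t)
            states[i] = d
            mef_open[i], esc_open[i] = mef, esc  # identical across conditions
        if flicker_rate > 0:
            flips = rng.random((n, t)) < flicker_rate
            states = states ^ flips
        peaksets[cond] = {
            tp: RegionSet(loci_df[states[:, j]], assembly, f"{cond}_{tp}")
            for j, tp in enumerate(timepoints)
        }
        full = np.column_stack([mef_open, states, esc_open])
        means = np.where(full, OPEN_MEAN, CLOSED_MEAN)
        vals = np.clip(means + rng.normal(0, noise_sd, means.shape) if noise_sd > 0 else means, 0, None)
        signals[cond] = SignalTable(
            pd.DataFrame(vals, index=loci.region_ids(), columns=all_cols)
        )
    truth = pd.DataFrame(
        {
            "group_BiD": labels_b,
            "group_WT": labels_a,
            "failed_to_open": failed_open,
            "failed_to_close": failed_close,
        },
        index=loci.region_ids(),
    )
    return AccessibilitySim(
        loci=loci,
        timepoints=list(timepoints),
        peaksets=peaksets,
        mef_peaks=RegionSet(loci_df[mef_open], assembly, "MEF"),
        esc_peaks=RegionSet(loci_df[esc_open], assembly, "ESC"),
        signals=signals,
        truth=truth,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# binding data (co-occupancy codes)


@dataclass
class BindingSim:
    regions: RegionSet
    peaksets: dict  # track (BIT_ORDER) -> RegionSet
    signals: pd.DataFrame  # region x track mean signal
    truth: pd.Series  # planted 4-bit code per region
    seed: int


#: Desk-scale default counts echoing the proportions of the four printed
#: co-occupancy classes (about 104:173:142:67 per thousand).
DEFAULT_CLASS_COUNTS = {"0101": 104, "0100": 173, "1101": 142, "1100": 67, "1111": 30, "1010": 20}


def make_binding_data(
    assembly: GenomeAssembly,
    class_counts: Mapping[str, int] | None = None,
    strong_mean: float = OPEN_MEAN,
    weak_mean: float = CLOSED_MEAN,
    noise_sd: float = 0.0,
    region_width: int = 500,
    seed: int = 0,
) -> BindingSim:
    """Binding regions with planted 4-bit co-occupancy codes.

    Each planted region appears in exactly the peak sets named by its
    code's set bits (bit order NANOG_WT, NANOG_BiD, BRG1_WT, BRG1_BiD);
    per-track signal is strong where the bit is set, weak otherwise.
    """
    counts = dict(DEFAULT_CLASS_COUNTS if class_counts is None else class_counts)
    for code in counts:
        if len(code) != 4 or set(code) - {"0", "1"} or code == "0000":
            raise ValueError(f"invalid co-occupancy code {code!r}")
    rng = np.random.default_rng(seed)
    codes: list[str] = []
    for code, c in counts.items():
        codes.extend([code] * int(c))
    codes = list(rng.permutation(codes))
    df = _place_loci(assembly, len(codes), region_width, rng)
    regions = RegionSet(df, assembly=assembly, name="binding_regions")
    bits = np.array([[int(b) for b in code] for code in codes], dtype=bool)
    peaksets = {
        track: RegionSet(df[bits[:, j]], assembly, track) for j, track in enumerate(BIT_ORDER)
    }
    means = np.where(bits, strong_mean, weak_mean)
    if noise_sd > 0:
        means = np.clip(means + rng.normal(0, noise_sd, means.shape), 0, None)
    signals = pd.DataFrame(means, index=regions.region_ids(), columns=list(BIT_ORDER))
    return BindingSim(
        regions=regions,
        peaksets=peaksets,
        signals=signals,
        truth=pd.Series(codes, index=regions.region_ids()),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# TF peak compendium


@dataclass
class CompendiumSim:
    factors: dict  # factor id -> RegionSet
    enriched_factor_id: str
    seed: int


def make_compendium(
    assembly: GenomeAssembly,
    query: RegionSet,
    n_factors: int = 10,
    enriched_factor_overlap_frac: float = 0.8,
    peaks_per_factor: int | None = None,
    peak_width: int = 500,
    seed: int = 0,
) -> CompendiumSim:
    """Reference TF peak compendium with one designed-in enriched factor.

    The enriched factor duplicates ``overlap_frac`` of the query loci (the
    remainder of its peaks uniform); every other factor is placed
    uniformly at random, so only the designed factor shares more than
    background overlap with the query.
    """
    if not (0 < enriched_factor_overlap_frac <= 1):
        raise ValueError("overlap fraction must be in (0, 1]")
    if not len(query):
        raise ValueError("empty query set")
    rng = np.random.default_rng(seed)
    n_peaks = len(query) if peaks_per_factor is None else int(peaks_per_factor)
    names = [f"TF{i + 1:02d}" for i in range(n_factors)]
    enriched = names[int(rng.integers(n_factors))]
    factors = {}
    for name in names:
        if name == enriched:
            n_copy = int(round(enriched_factor_overlap_frac * n_peaks))
            take = rng.choice(len(query), size=min(n_copy, len(query)), replace=False)
            parts = [query.df.iloc[sorted(take)][["chrom", "start", "end"]]]
            if n_peaks - len(take) > 0:
                parts.append(_uniform_regions(assembly, n_peaks - len(take), peak_width, rng))
            df = pd.concat(parts, ignore_index=True)
        else:
            df = _uniform_regions(assembly, n_peaks, peak_width, rng)
        factors[name] = RegionSet(df, assembly=assembly, name=name)
    return CompendiumSim(factors=factors, enriched_factor_id=enriched, seed=seed)


def _uniform_regions(
    assembly: GenomeAssembly, n: int, width: int, rng: np.random.Generator
) -> pd.DataFrame:
    """n width-bp regions with uniform random starts (overlaps allowed)."""
    chrom_names = assembly.chroms
    lengths = np.array([assembly.length(c) for c in chrom_names], dtype=float)
    probs = lengths / lengths.sum()
    which = rng.choice(len(chrom_names), size=n, p=probs)
    starts = np.array(
        [rng.integers(0, assembly.length(chrom_names[w]) - width + 1) for w in which]
    )
    return pd.DataFrame(
        {
            "chrom": [chrom_names[w] for w in which],
            "start": starts,
            "end": starts + width,
        }
    )


# ---------------------------------------------------------------------------
# expression time courses


@dataclass
class ExpressionSim:
    fpkm: SignalTable
    truth: pd.Series  # cluster id per gene
    profiles: pd.DataFrame  # cluster x timepoint mean curves
    seed: int


#: FPKM swing of the default trend shapes; several-fold expression changes
#: are typical of differential genes in a reprogramming course.
DEFAULT_PROFILE_AMPLITUDE = 8.0


def default_cluster_profiles(timepoints: Sequence[str], k: int = 3,
                             baseline: float = 4.0,
                             amplitude: float = DEFAULT_PROFILE_AMPLITUDE) -> pd.DataFrame:
    """Smooth canonical trend shapes (up, down, transient, ...) over a grid."""
    t = np.linspace(0, 1, len(timepoints))
    shapes = [
        t,                       # monotone up
        1 - t,                   # monotone down
        np.sin(np.pi * t),       # transient peak
        1 - np.sin(np.pi * t),   # transient dip
        np.where(t < 0.5, 0, 1),  # late step
    ]
    if k > len(shapes):
        raise ValueError(f"at most {len(shapes)} default profiles available")
    rows = [baseline + amplitude * s for s in shapes[:k]]
    return pd.DataFrame(rows, index=range(1, k + 1), columns=list(timepoints))


def make_expression(
    genes: int | Sequence[str],
    cluster_profiles: pd.DataFrame | None = None,
    noise_sd: float = 0.25 * DEFAULT_PROFILE_AMPLITUDE,
    timepoints: Sequence[str] | None = None,
    seed: int = 0,
) -> ExpressionSim:
    """FPKM time courses: each gene = its cluster's mean curve + Gaussian noise."""
    if cluster_profiles is None:
        tps = list(timepoints) if timepoints is not None else ["MEF"] + list(DEFAULT_TIMEPOINTS) + ["ESC"]
        cluster_profiles = default_cluster_profiles(tps, k=3)
    k = len(cluster_profiles)
    if k < 2:
        raise ValueError("need at least two cluster profiles")
    rng = np.random.default_rng(seed)
    if isinstance(genes, int):
        gene_ids = [f"gene_{i + 1:04d}" for i in range(genes)]
    else:
        gene_ids = list(genes)
    n = len(gene_ids)
    cluster_ids = rng.integers(1, k + 1, size=n)
    prof = cluster_profiles.to_numpy()
    vals = prof[cluster_ids - 1] + rng.normal(0, noise_sd, (n, prof.shape[1]))
    fpkm = SignalTable(
        pd.DataFrame(np.clip(vals, 0, None), index=gene_ids, columns=cluster_profiles.columns)
    )
    return ExpressionSim(
        fpkm=fpkm,
        truth=pd.Series(cluster_ids, index=gene_ids, name="cluster_id"),
        profiles=cluster_profiles,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# IP-MS intensities


@dataclass
class IpmsSim:
    intensities: pd.DataFrame  # long form: protein, condition, replicate, intensity
    truth: pd.Series  # status per protein
    seed: int


def make_ipms(
    n_proteins: int = 1000,
    n_true_bid: int = 19,
    n_true_wt: int = 2,
    n_shared: int = 531,
    effect_log2: float = 3.0,
    replicate_cv: float = 0.05,
    control_condition: str = "control",
    conditions: tuple[str, str] = ("WT", "BiD"),
    n_replicates: int = 2,
    seed: int = 0,
) -> IpmsSim:
    """Pull-down intensity table with planted interactors.

    True interactors of a condition have mean log2 enrichment
    ``effect_log2`` over the control; nulls center at zero. Replicate
    noise is multiplicative lognormal with the given CV. Default planted
    counts mirror the pull-down this emulates (19 engineered-specific, 2
    wild-type-specific, 531 shared partners).
    """
    if effect_log2 <= 0:
        raise ValueError("effect_log2 must be positive")
    if n_true_bid + n_true_wt + n_shared > n_proteins:
        raise ValueError("planted interactors exceed protein count")
    rng = np.random.default_rng(seed)
    cond_a, cond_b = conditions
    status = np.array(["negative"] * n_proteins, dtype=object)
    order = rng.permutation(n_proteins)
    status[order[:n_true_bid]] = f"{cond_b}_specific"
    status[order[n_true_bid : n_true_bid + n_true_wt]] = f"{cond_a}_specific"
    status[order[n_true_bid + n_true_wt : n_true_bid + n_true_wt + n_shared]] = "shared"
    proteins = [f"P{i + 1:05d}" for i in range(n_proteins)]
    base = 2.0 ** rng.uniform(15, 22, n_proteins)
    rows = []
    for cond in (control_condition, cond_a, cond_b):
        enriched = np.isin(status, ["shared", f"{cond}_specific"]) if cond != control_condition else np.zeros(n_proteins, bool)
        mean = base * np.where(enriched, 2.0**effect_log2, 1.0)
        for rep in range(1, n_replicates + 1):
            vals = mean * np.exp(rng.normal(0, replicate_cv, n_proteins))
            rows.append(
                pd.DataFrame(
                    {
                        "protein": proteins,
                        "condition": cond,
                        "replicate": rep,
                        "intensity": vals,
                    }
                )
            )
    return IpmsSim(
        intensities=pd.concat(rows, ignore_index=True),
        truth=pd.Series(status, index=proteins, name="status"),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# gene models


def make_gene_models(
    assembly: GenomeAssembly,
    n_genes: int = 200,
    tf_frac: float = 0.2,
    near_regions: RegionSet | None = None,
    n_near: int = 0,
    seed: int = 0,
) -> list[GeneModel]:
    """Random TSS table; optionally place the first ``n_near`` genes next to
    given regions (within 10 kb) so that region-gene association finds them."""
    rng = np.random.default_rng(seed)
    genes = []
    chrom_names = assembly.chroms
    for i in range(n_genes):
        gid = f"gene_{i + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if near_regions is not None and i < n_near and i < len(near_regions):
            row = near_regions.df.iloc[i]
            chrom = row["chrom"]
            tss = int(
                np.clip(row["start"] + int(rng.integers(-10_000, 10_000)), 0,
                        assembly.length(chrom) - 1)
            )
        else:
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            tss = int(rng.integers(0, assembly.length(chrom)))
        genes.append(
            GeneModel(
                gene_id=gid,
                gene_name=gid.upper(),
                chrom=chrom,
                tss=tss,
                strand=strand,
                is_tf=bool(rng.random() < tf_frac),
            )
        )
    return genes
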