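"""Region-gene association, region-set enrichment and regulator ranking.

Four statistics around region sets:

* a GREAT-like distance rule assigning regions to genes (upstream 5 kb,
  downstream 2 kb, distal 100 kb of the TSS, plus promoter overlap);
* a permutation z-score for overlap of one region set with another, with
  a chromosome- and length-preserving uniform null;
* known-motif enrichment in summit windows with a hypergeometric tail and
  the reporting thresholds fold >= 3, p < 1e-5;
* a composite regulator score, (-log10 p) * log2(odds ratio) from a
  genome-bin Fisher test of query regions against each compendium factor,
  used to rank candidate cell-fate regulators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GeneModel, GenomeAssembly, RegionSet, merge_regions, overlaps_any

__all__ = [
    "RegionGeneMap",
    "PermutationEnrichment",
    "associate_genes",
    "permutation_z",
    "motif_enrichment",
    "scan_pwm",
    "rank_regulators",
]

FOLD_CAP = float(2**20)
_P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# region -> gene association


@dataclass
class RegionGeneMap:
    """Region-gene pairs with the relation that produced each pair."""

    pairs: pd.DataFrame  # region_index, gene_id, relation, distance
    parameters: dict

    def gene_ids(self) -> list[str]:
        return sorted(self.pairs["gene_id"].unique())

    def genes_for_region(self, region_index: int) -> list[str]:
        sel = self.pairs["region_index"] == region_index
        return sorted(self.pairs.loc[sel, "gene_id"].unique())


def associate_genes(
    regions: RegionSet,
    genes: Sequence[GeneModel],
    upstream_bp: int = 5000,
    downstream_bp: int = 2000,
    distal_bp: int = 100_000,
    promoter_halfwidth: int = 2000,
) -> RegionGeneMap:
    """Assign regions to genes by strand-oriented distance from the TSS.

    Distances are signed along the gene (negative upstream). A region is
    associated when any of its bases lies within ``distal_bp`` of the TSS;
    the relation is ``promoter_overlap`` when it intersects the +/-
    ``promoter_halfwidth`` promoter, else ``upstream``/``downstream`` when
    it intersects those proximal windows, else ``distal``. With the default
    parameters the downstream window lies inside the promoter, so the
    ``downstream`` relation only surfaces for narrower promoters.
    """
    params = dict(
        upstream_bp=upstream_bp,
        downstream_bp=downstream_bp,
        distal_bp=distal_bp,
        promoter_halfwidth=promoter_halfwidth,
    )
    starts = regions.df["start"].to_numpy(np.int64)
    ends = regions.df["end"].to_numpy(np.int64)
    chroms = regions.df["chrom"].to_numpy()
    rows = []
    for gene in genes:
        if gene.tss is None:
            raise ValueError(f"gene {gene.gene_id} has no TSS")
        on_chrom = np.nonzero(chroms == gene.chrom)[0]
        if not len(on_chrom):
            continue
        s, e = starts[on_chrom], ends[on_chrom]
        if gene.strand == "+":
            lo, hi = s - gene.tss, e - 1 - gene.tss
        else:
            lo, hi = gene.tss - (e - 1), gene.tss - s
        # signed-distance interval [lo, hi] of the region's bases
        assoc = (lo <= distal_bp) & (hi >= -distal_bp)
        if not assoc.any():
            continue
        promoter = (lo <= promoter_halfwidth) & (hi >= -promoter_halfwidth)
        upstream = (lo <= -1) & (hi >= -upstream_bp)
        downstream = (lo <= downstream_bp) & (hi >= 0)
        dist = np.where(lo > 0, lo, np.where(hi < 0, -hi, 0))
        for idx_local in np.nonzero(assoc)[0]:
            if promoter[idx_local]:
                relation = "promoter_overlap"
            elif upstream[idx_local]:
                relation = "upstream"
            elif downstream[idx_local]:
                relation = "downstream"
            else:
                relation = "distal"
            rows.append(
                (int(on_chrom[idx_local]), gene.gene_id, relation, int(dist[idx_local]))
            )
    pairs = pd.DataFrame(rows, columns=["region_index", "gene_id", "relation", "distance"])
    return RegionGeneMap(pairs=pairs, parameters=params)


# ---------------------------------------------------------------------------
# permutation overlap enrichment


@dataclass
class PermutationEnrichment:
    observed_overlap: int
    null_mean: float
    null_sd: float
    z: float
    n_permutations: int
    seed: int


def _merged_lookup(setB: RegionSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = merge_regions(setB).df
    return {
        chrom: (
            grp["start"].to_numpy(np.int64),
            grp["end"].to_numpy(np.int64),
        )
        for chrom, grp in merged.groupby("chrom", sort=False)
    }


def _count_overlapping(starts: np.ndarray, ends: np.ndarray,
                       b_starts: np.ndarray, b_ends: np.ndarray) -> int:
    """Count query intervals overlapping any of the disjoint sorted b intervals."""
    if not len(b_starts):
        return 0
    idx = np.searchsorted(b_starts, ends, side="left")
    hit = idx > 0
    hit[hit] = b_ends[idx[hit] - 1] > starts[hit]
    return int(hit.sum())


def permutation_z(
    setA: RegionSet,
    setB: RegionSet,
    assembly: GenomeAssembly,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermutationEnrichment:
    """Overlap enrichment of setA in setB against a uniform relocation null.

    The observed statistic is the number of A regions overlapping (>= 1 bp)
    any B region. Each permutation relocates every A region uniformly
    within its own chromosome, preserving length and chromosome but not
    spacing, and recounts; z = (observed - null mean) / null sd.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if not len(setA) or not len(setB):
        raise ValueError("empty region set")
    lookup = _merged_lookup(setB)
    by_chrom: list[tuple[str, np.ndarray, np.ndarray, int]] = []
    observed = 0
    for chrom, grp in setA.df.groupby("chrom", sort=False):
        lengths = (grp["end"] - grp["start"]).to_numpy(np.int64)
        chrom_len = assembly.length(chrom)
        if (lengths > chrom_len).any():
            raise ValueError(f"region longer than chromosome {chrom}")
        b_starts, b_ends = lookup.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        observed += _count_overlapping(
            grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64), b_starts, b_ends
        )
        by_chrom.append((chrom, lengths, np.stack([b_starts, b_ends]), chrom_len))

    rng = np.random.default_rng(seed)
    null = np.zeros(n_permutations, dtype=np.int64)
    for i in range(n_permutations):
        total = 0
        for chrom, lengths, b, chrom_len in by_chrom:
            starts = rng.integers(0, chrom_len - lengths + 1)
            total += _count_overlapping(starts, starts + lengths, b[0], b[1])
        null[i] = total
    mean, sd = float(null.mean()), float(null.std(ddof=0))
    z = (observed - mean) / sd if sd > 0 else np.nan
    return PermutationEnrichment(
        observed_overlap=observed,
        null_mean=mean,
        null_sd=sd,
        z=float(z),
        n_permutations=n_permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# known-motif enrichment


def summit_windows(rs: RegionSet, halfwidth: int = 25) -> RegionSet:
    """Summit +/- halfwidth windows (midpoint when no summit is recorded)."""
    centers = np.where(
        rs.df["summit"].notna(),
        rs.df["start"] + rs.df["summit"].fillna(0).astype(np.int64),
        (rs.df["start"] + rs.df["end"]) // 2,
    ).astype(np.int64)
    starts = np.maximum(centers - halfwidth, 0)
    return RegionSet.from_arrays(
        rs.df["chrom"], starts, centers + halfwidth + 1, assembly=rs.assembly,
        name=f"{rs.name}_windows",
    )


def motif_enrichment(
    target: RegionSet,
    background: RegionSet,
    motif_occurrences: Mapping[str, RegionSet],
    fold_min: float = 3.0,
    p_max: float = 1e-5,
    window_halfwidth: int | None = 25,
    exclude_target_from_background: bool = True,
) -> pd.DataFrame:
    """Known-motif enrichment of target windows over background windows.

    Windows are summit +/- ``window_halfwidth`` (the regions themselves
    when ``None``); a window is a hit for a motif when it overlaps >= 1
    occurrence. Fold = target hit rate / background hit rate and p is the
    hypergeometric right tail of the target hit count. A motif is
    ``reported`` iff fold >= fold_min (inclusive) and p < p_max.
    """
    if window_halfwidth is not None:
        target_w = summit_windows(target, window_halfwidth)
        background_w = summit_windows(background, window_halfwidth)
    else:
        target_w, background_w = target, background
    if exclude_target_from_background and len(background_w) and len(target_w):
        keep = ~overlaps_any(background_w, target_w)
        background_w = RegionSet(background_w.df[keep], background_w.assembly, background_w.name)
    if not len(background_w):
        raise ValueError("empty background after excluding target windows")
    n_t, n_b = len(target_w), len(background_w)
    rows = []
    for motif_id, occ in motif_occurrences.items():
        k_t = int(overlaps_any(target_w, occ).sum()) if len(occ) else 0
        k_b = int(overlaps_any(background_w, occ).sum()) if len(occ) else 0
        if k_t == 0:
            fold = 0.0
        elif k_b == 0:
            fold = FOLD_CAP
        else:
            fold = (k_t / n_t) / (k_b / n_b)
        p = float(stats.hypergeom.sf(k_t - 1, n_t + n_b, k_t + k_b, n_t))
        rows.append(
            {
                "motif_id": motif_id,
                "hits_in_target": k_t,
                "target_size": n_t,
                "hits_in_background": k_b,
                "background_size": n_b,
                "fold": fold,
                "p": p,
                "reported": bool(fold >= fold_min and p < p_max),
            }
        )
    return pd.DataFrame(rows).sort_values("p", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# PWM scanning

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _parse_window_key(key: str) -> tuple[str, int]:
    if ":" in key and "-" in key.rsplit(":", 1)[1]:
        chrom, span = key.rsplit(":", 1)
        start = int(span.split("-")[0])
        return chrom, start
    return key, 0


def scan_pwm(
    sequences: Mapping[str, str],
    pwm: np.ndarray,
    log_odds_threshold: float,
    max_non_acgt_frac: float = 0.1,
) -> RegionSet:
    """Scan windows for PWM occurrences on both strands.

    ``pwm`` is a 4 x L probability matrix (rows A, C, G, T; columns sum to
    1). Scores are log2 odds against a uniform background; a hit is any
    offset scoring >= threshold on either strand. Sequence keys of the form
    ``chrom:start-end`` anchor hits to absolute coordinates. Windows whose
    non-ACGT fraction exceeds the tolerance are skipped with a warning;
    k-mers containing other characters are not scored.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[0] != 4:
        raise ValueError("pwm must be a 4 x L matrix")
    if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("pwm columns must sum to 1")
    L = pwm.shape[1]
    logodds = np.log2(np.clip(pwm, 1e-9, None) / 0.25)
    hits = []
    for key, seq in sequences.items():
        seq = seq.upper()
        bad = sum(1 for c in seq if c not in _BASE_INDEX)
        if len(seq) and bad / len(seq) > max_non_acgt_frac:
            warnings.warn(f"window {key}: skipped ({bad}/{len(seq)} non-ACGT bases)")
            continue
        chrom, offset = _parse_window_key(key)
        for strand, s in (("+", seq), ("-", seq.translate(_COMPLEMENT)[::-1])):
            for i in range(len(s) - L + 1):
                kmer = s[i : i + L]
                if any(c not in _BASE_INDEX for c in kmer):
                    continue
                score = float(sum(logodds[_BASE_INDEX[c], j] for j, c in enumerate(kmer)))
                if score >= log_odds_threshold:
                    # map minus-strand offset back to forward coordinates
                    fwd = i if strand == "+" else len(s) - L - i
                    hits.append((chrom, offset + fwd, offset + fwd + L, strand, score))
    if not hits:
        return RegionSet([], name="pwm_hits")
    df = pd.DataFrame(hits, columns=["chrom", "start", "end", "strand", "score"])
    return RegionSet(df, name="pwm_hits")


# ---------------------------------------------------------------------------
# composite regulator ranking


def _bin_hits(rs: RegionSet, assembly: GenomeAssembly, bin_size: int,
              offsets: dict[str, int], total_bins: int) -> np.ndarray:
    mask = np.zeros(total_bins, dtype=bool)
    for row in rs.df.itertuples(index=False):
        off = offsets[row.chrom]
        lo = off + row.start // bin_size
        hi = off + (row.end - 1) // bin_size
        mask[lo : hi + 1] = True
    return mask


def rank_regulators(
    query: RegionSet,
    compendium: Mapping[str, RegionSet],
    assembly: GenomeAssembly,
    bin_size: int = 1000,
) -> pd.DataFrame:
    """Composite-score ranking of compendium factors against a query set.

    The genome is tiled into fixed bins; per factor a 2x2 table of bins by
    (overlaps query, overlaps factor peaks) feeds a right-tailed Fisher
    test. Zero cells get the Haldane-Anscombe 0.5 correction for the odds
    ratio. score = (-log10 p) * log2(odds ratio), descending rank.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not compendium:
        raise ValueError("empty compendium")
    offsets: dict[str, int] = {}
    total = 0
    for chrom in assembly.chroms:
        offsets[chrom] = total
        total += -(-assembly.length(chrom) // bin_size)
    q = _bin_hits(query, assembly, bin_size, offsets, total)
    rows = []
    for factor_id in sorted(compendium):
        f = _bin_hits(compendium[factor_id], assembly, bin_size, offsets, total)
        a = int((q & f).sum())
        b = int((q & ~f).sum())
        c = int((~q & f).sum())
        d = int((~q & ~f).sum())
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        if min(a, b, c, d) == 0:
            odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        else:
            odds = a * d / (b * c)
        log2_or = float(np.clip(np.log2(odds), -20.0, 20.0))
        score = -np.log10(max(p, _P_FLOOR)) * log2_or
        rows.append(
            {
                "factor_id": factor_id,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": float(odds),
                "p": float(p),
                "score": float(score),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["score", "factor_id"], ascending=[False, True], kind="mergesort"
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
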