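"""Expression-dynamics clustering, the IP-MS interactor filter and integration.

Three threshold-driven analyses: a pseudocounted log2 fold-change score
with a strict > 0.5 cutoff standing in for posterior fold-change callers;
k-means clustering of z-scored FPKM time courses (default 12 clusters);
and the pull-down interactor chain — detected in both replicates of a
condition, log2 enrichment over control strictly > 1.2, Welch-t p < 0.05
— whose candidates partition into condition-specific and shared statuses.
Finally, genes of one expression cluster are intersected with the genes
associated to condition-sensitive closed-to-open regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .association_enrichment import RegionGeneMap, associate_genes
from .genome_io import GeneModel, RegionSet, SignalTable

__all__ = [
    "ExpressionClustering",
    "IntegrationResult",
    "de_standin",
    "cluster_timecourses",
    "call_interactors",
    "integrate_cluster_with_regions",
]


# ---------------------------------------------------------------------------
# differential expression stand-in


def de_standin(
    fpkm: SignalTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 1.0,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Pseudocounted log2 fold change of b over a; DE iff |score| > threshold.

    score = log2((mean_b + pc) / (mean_a + pc)); the cutoff is strict, so a
    score of exactly +/- threshold is not called differential. Swapping the
    contrast negates the score.
    """
    missing = [s for s in list(group_a) + list(group_b) if s not in fpkm.values.columns]
    if missing:
        raise ValueError(f"contrast samples not in table: {missing}")
    vals = fpkm.values
    if (vals.to_numpy() < 0).any():
        raise ValueError("negative FPKM values")
    mean_a = vals[list(group_a)].mean(axis=1)
    mean_b = vals[list(group_b)].mean(axis=1)
    score = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    return pd.DataFrame(
        {"score": score, "de": np.abs(score) > threshold}, index=vals.index
    )


# ---------------------------------------------------------------------------
# expression time-course clustering


@dataclass
class ExpressionClustering:
    k: int
    cluster_ids: pd.Series  # per gene, 1..k
    cluster_trends: pd.DataFrame  # k x timepoints, member means of z-profiles
    zscores: pd.DataFrame

    def genes_in(self, cluster_id: int) -> list[str]:
        return list(self.cluster_ids.index[self.cluster_ids == cluster_id])


def _zscore_profiles(values: pd.DataFrame, sd_floor: float = 1e-8) -> pd.DataFrame:
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    flat = sd < sd_floor
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant expression profiles; z-scored with sd floor")
    return values.sub(mu, axis=0).div(sd.clip(lower=sd_floor), axis=0)


def cluster_timecourses(fpkm: SignalTable, k: int = 12, seed: int = 0,
                        n_init: int = 25) -> ExpressionClustering:
    """K-means on per-gene z-scored profiles; deterministic for a fixed seed.

    Cluster ids are relabelled 1..k in decreasing cluster size so the
    labelling does not depend on k-means initialisation order.
    """
    if k > len(fpkm.values):
        raise ValueError("k exceeds number of genes")
    z = _zscore_profiles(fpkm.values)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(z.to_numpy())
    order = pd.Series(raw).value_counts().index  # big clusters first
    remap = {old: new + 1 for new, old in enumerate(order)}
    ids = pd.Series([remap[r] for r in raw], index=z.index, name="cluster_id")
    trends = z.groupby(ids).mean()
    trends.index.name = "cluster_id"
    return ExpressionClustering(k=k, cluster_ids=ids, cluster_trends=trends, zscores=z)


# ---------------------------------------------------------------------------
# IP-MS interactor filter chain


def call_interactors(
    intensities: pd.DataFrame,
    control_condition: str,
    conditions: tuple[str, str] = ("WT", "BiD"),
    log2_min: float = 1.2,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Filter pull-down candidates per condition and assign statuses.

    ``intensities`` is long-form: columns protein, condition, replicate,
    intensity (0 or NaN = not detected). A protein is a candidate in a
    condition iff it is detected in every replicate of that condition, its
    mean log2 enrichment over the control strictly exceeds ``log2_min``,
    and the two-sided Welch t-test on log2 intensities versus control has
    p < ``p_max``. Statuses: ``{cond}_specific`` for candidates in exactly
    one condition, ``shared`` for both, ``negative`` otherwise — the three
    positive statuses partition the candidates.
    """
    required = {"protein", "condition", "replicate", "intensity"}
    if not required <= set(intensities.columns):
        raise ValueError(f"intensity table needs columns {sorted(required)}")
    if control_condition not in set(intensities["condition"]):
        raise ValueError(f"control condition {control_condition!r} missing")
    cond_a, cond_b = conditions
    wide = intensities.pivot_table(
        index="protein", columns=["condition", "replicate"], values="intensity",
        aggfunc="first",
    )
    for cond in (control_condition, cond_a, cond_b):
        if cond not in wide.columns.get_level_values(0):
            raise ValueError(f"condition {cond!r} missing from intensity table")
        if wide[cond].shape[1] < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 replicates")

    def detected(block: pd.DataFrame) -> pd.Series:
        return (block.notna() & (block > 0)).all(axis=1)

    ctrl = wide[control_condition]
    log2_ctrl = np.log2(ctrl.where(ctrl > 0))
    ctrl_mean = log2_ctrl.mean(axis=1)

    out = pd.DataFrame(index=wide.index)
    for cond in (cond_a, cond_b):
        block = wide[cond]
        present = detected(block)
        log2_block = np.log2(block.where(block > 0))
        enrich = log2_block.mean(axis=1) - ctrl_mean
        pvals = pd.Series(np.nan, index=wide.index)
        both = present & log2_ctrl.notna().all(axis=1)
        if both.any():
            res = stats.ttest_ind(
                log2_block[both].to_numpy(),
                log2_ctrl[both].to_numpy(),
                axis=1,
                equal_var=False,
            )
            pvals[both] = res.pvalue
        out[f"{cond}_present_in_both_replicates"] = present
        out[f"{cond}_log2_enrichment"] = enrich
        out[f"{cond}_p_value"] = pvals
        out[f"{cond}_candidate"] = (
            present & (enrich > log2_min) & (pvals < p_max)
        ).fillna(False)

    a, b = out[f"{cond_a}_candidate"], out[f"{cond_b}_candidate"]
    out["status"] = np.select(
        [a & b, a & ~b, ~a & b],
        ["shared", f"{cond_a}_specific", f"{cond_b}_specific"],
        default="negative",
    )
    return out


# ---------------------------------------------------------------------------
# integration of expression clusters with sensitive CO regions


@dataclass
class IntegrationResult:
    cluster_genes: list[str]
    co_region_genes: list[str]
    overlap_genes: list[str]
    tf_subset: list[str]
    region_gene_map: RegionGeneMap


def integrate_cluster_with_regions(
    cluster_genes: Sequence[str],
    failed_co_regions: RegionSet,
    genes: Sequence[GeneModel],
    **associate_kwargs,
) -> IntegrationResult:
    """Intersect an expression cluster with genes of sensitive CO regions.

    The failed-to-open regions are mapped to genes by the distance rule
    (:func:`cadpipe.association_enrichment.associate_genes`); the overlap
    with the cluster gene list is reported along with its transcription-
    factor subset.
    """
    if not len(cluster_genes) or not len(failed_co_regions):
        raise ValueError("cluster gene list and region set must be nonempty")
    rgmap = associate_genes(failed_co_regions, genes, **associate_kwargs)
    co_genes = rgmap.gene_ids()
    overlap = sorted(set(cluster_genes) & set(co_genes))
    tf_ids = {g.gene_id for g in genes if g.is_tf}
    return IntegrationResult(
        cluster_genes=sorted(set(cluster_genes)),
        co_region_genes=co_genes,
        overlap_genes=overlap,
        tf_subset=sorted(set(overlap) & tf_ids),
        region_gene_map=rgmap,
    )
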