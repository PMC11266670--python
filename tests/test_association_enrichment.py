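import numpy as np
import pandas as pd
import pytest

from cadpipe import association_enrichment as enr
from cadpipe import synthetic_data as synth
from cadpipe.genome_io import GeneModel, GenomeAssembly, RegionSet
from conftest import make_rs, random_regions
from oracles import (
    brute_force_associate,
    expected_overlap_uniform,
    hypergeom_right_tail,
    pwm_rescan,
)


def _genes(rng, assembly, n):
    out = []
    for i in range(n):
        chrom = assembly.chroms[int(rng.integers(len(assembly.chroms)))]
        out.append(
            GeneModel(
                gene_id=f"g{i}",
                gene_name=f"G{i}",
                chrom=chrom,
                tss=int(rng.integers(0, assembly.length(chrom))),
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    return out


class TestAssociateGenes:
    def test_matches_brute_force_all_pairs(self, rng, assembly):
        regions = random_regions(rng, assembly, 150)
        genes = _genes(rng, assembly, 50)
        got = {
            (r.region_index, r.gene_id, r.relation)
            for r in enr.associate_genes(regions, genes).pairs.itertuples(index=False)
        }
        assert got == brute_force_associate(regions.df, genes)

    def test_promoter_overlap_relation(self):
        gene = GeneModel("g1", "G1", "chr1", 10_000, "+")
        regions = make_rs([("chr1", 9_500, 9_600)])
        pairs = enr.associate_genes(regions, [gene]).pairs
        assert pairs.iloc[0]["relation"] == "promoter_overlap"

    def test_upstream_window_is_strand_oriented(self):
        plus = GeneModel("g1", "G1", "chr1", 10_000, "+")
        minus = GeneModel("g2", "G2", "chr1", 10_000, "-")
        region = make_rs([("chr1", 6_000, 6_500)])  # 3.5-4 kb left of the TSS
        rel_plus = enr.associate_genes(region, [plus]).pairs.iloc[0]["relation"]
        rel_minus = enr.associate_genes(region, [minus]).pairs.iloc[0]["relation"]
        assert rel_plus == "upstream"
        # left of a minus-strand TSS is its downstream side, and 3.5 kb is
        # beyond the 2 kb downstream window
        assert rel_minus == "distal"

    def test_beyond_distal_cap_not_associated(self):
        gene = GeneModel("g1", "G1", "chr1", 200_000, "+")
        region = make_rs([("chr1", 25_000, 25_500)])  # 150 kb away
        assert enr.associate_genes(region, [gene]).pairs.empty


class TestPermutationZ:
    def test_self_overlap_positive_control(self, assembly, rng):
        dense = random_regions(rng, assembly, 100, min_len=400, max_len=600)
        res = enr.permutation_z(dense, dense, assembly, n_permutations=200, seed=0)
        assert res.observed_overlap == 100
        assert res.z > 4

    def test_seed_determinism(self, assembly, rng):
        a = random_regions(rng, assembly, 40)
        b = random_regions(rng, assembly, 40)
        r1 = enr.permutation_z(a, b, assembly, n_permutations=150, seed=9)
        r2 = enr.permutation_z(a, b, assembly, n_permutations=150, seed=9)
        assert (r1.null_mean, r1.null_sd, r1.z) == (r2.null_mean, r2.null_sd, r2.z)

    def test_null_mean_matches_closed_form(self, assembly, rng):
        a = random_regions(rng, assembly, 80, min_len=200, max_len=1500)
        b = random_regions(rng, assembly, 120, min_len=200, max_len=1500)
        res = enr.permutation_z(a, b, assembly, n_permutations=1000, seed=3)
        expected = expected_overlap_uniform(a.df, b.df, assembly.chrom_lengths)
        assert abs(res.null_mean - expected) < 3 * res.null_sd

    def test_too_few_permutations_rejected(self, assembly, rng):
        a = random_regions(rng, assembly, 5)
        with pytest.raises(ValueError, match="permutations"):
            enr.permutation_z(a, a, assembly, n_permutations=0)

    def test_region_longer_than_chromosome_rejected(self):
        asm = GenomeAssembly({"chrS": 1000})
        a = RegionSet(pd.DataFrame({"chrom": ["chrS"], "start": [0], "end": [900]}))
        big = RegionSet(pd.DataFrame({"chrom": ["chrS"], "start": [0], "end": [999]}))
        # relocate a 1500 bp region on a 1000 bp chromosome is impossible
        asm2 = GenomeAssembly({"chrS": 1200})
        long_rs = RegionSet(pd.DataFrame({"chrom": ["chrS"], "start": [0], "end": [1201]}))
        with pytest.raises(Exception):
            enr.permutation_z(long_rs, big, asm, n_permutations=100)


def _windows(chrom, n, start=0, width=51, gap=100):
    return make_rs([(chrom, start + i * (width + gap), start + i * (width + gap) + width)
                    for i in range(n)])


class TestMotifEnrichment:
    def test_p_matches_exact_tail_summation(self):
        """Hypergeometric right tail agrees with rational-arithmetic direct
        summation to 1e-12 relative error (counts 40/100 vs 20/1000)."""
        target = _windows("chr1", 100)
        background = _windows("chr2", 1000)
        occ = RegionSet(
            pd.concat([target.df.iloc[:40], background.df.iloc[:20]], ignore_index=True)
        )
        out = enr.motif_enrichment(
            target, background, {"m": occ}, window_halfwidth=None,
            exclude_target_from_background=False,
        ).iloc[0]
        assert (out["hits_in_target"], out["hits_in_background"]) == (40, 20)
        exact = float(hypergeom_right_tail(40, 100, 20, 1000))
        assert out["p"] == pytest.approx(exact, rel=1e-12)

    def test_fold_below_three_not_reported_despite_tiny_p(self):
        target = _windows("chr1", 100)
        background = _windows("chr2", 1000)
        occ = RegionSet(
            pd.concat([target.df.iloc[:29], background.df.iloc[:100]], ignore_index=True)
        )
        out = enr.motif_enrichment(
            target, background, {"m": occ}, window_halfwidth=None,
            exclude_target_from_background=False,
        ).iloc[0]
        assert out["fold"] == pytest.approx(2.9)
        assert out["p"] < 1e-5
        assert not out["reported"]

    def test_all_target_no_background_fold_capped_and_reported(self):
        target = _windows("chr1", 50)
        background = _windows("chr2", 500)
        out = enr.motif_enrichment(
            target, background, {"m": target}, window_halfwidth=None,
            exclude_target_from_background=False,
        ).iloc[0]
        assert out["fold"] == enr.FOLD_CAP
        assert out["reported"]

    def test_summit_windows_centered_on_summit(self):
        rs = make_rs([("chr1", 100, 200)])
        rs.df.loc[0, "summit"] = 50
        w = enr.summit_windows(rs, halfwidth=25)
        assert (w.df.loc[0, "start"], w.df.loc[0, "end"]) == (125, 176)

    def test_empty_background_rejected(self):
        target = _windows("chr1", 10)
        with pytest.raises(ValueError, match="background"):
            enr.motif_enrichment(target, target, {"m": target}, window_halfwidth=None)


class TestScanPwm:
    def test_poly_a_motif_single_hit(self):
        pwm = np.array([[1.0] * 4, [0.0] * 4, [0.0] * 4, [0.0] * 4])
        hits = enr.scan_pwm({"w1": "AAAA"}, pwm, log_odds_threshold=0.0)
        assert len(hits) == 1

    def test_strand_symmetry_on_reverse_complement(self):
        rng = np.random.default_rng(5)
        pwm = rng.dirichlet([1, 1, 1, 1], size=6).T
        seq = "".join(rng.choice(list("ACGT"), 300))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        h1 = enr.scan_pwm({"w": seq}, pwm, 4.0)
        h2 = enr.scan_pwm({"w": rc}, pwm, 4.0)
        assert len(h1) == len(h2)

    def test_matches_naive_rescan(self):
        rng = np.random.default_rng(11)
        pwm = rng.dirichlet([2, 1, 1, 2], size=8).T
        seq = "".join(rng.choice(list("ACGT"), 1000))
        hits = enr.scan_pwm({"chr1:0-1000": seq}, pwm, 6.0)
        expected = pwm_rescan(seq, pwm, 6.0)
        got = sorted(zip(hits.df["start"], hits.df["strand"]))
        assert got == expected

    def test_bad_column_sums_rejected(self):
        pwm = np.full((4, 3), 0.3)
        with pytest.raises(ValueError, match="sum"):
            enr.scan_pwm({"w": "ACGT"}, pwm, 0.0)

    def test_non_acgt_window_skipped_with_warning(self):
        pwm = np.full((4, 2), 0.25)
        with pytest.warns(UserWarning, match="non-ACGT"):
            hits = enr.scan_pwm({"w": "NNNNNNAC"}, pwm, -1.0)
        assert len(hits) == 0


class TestRankRegulators:
    def test_query_itself_ranks_first(self, assembly, rng):
        query = random_regions(rng, assembly, 60, min_len=400, max_len=600)
        comp = {"self": query}
        for i in range(5):
            comp[f"rand{i}"] = random_regions(rng, assembly, 60, min_len=400, max_len=600)
        out = enr.rank_regulators(query, comp, assembly)
        assert out.iloc[0]["factor_id"] == "self"

    def test_score_zero_at_odds_ratio_one(self):
        asm = GenomeAssembly({"chr1": 100_000, "chr2": 100_000})
        query = make_rs([("chr1", 0, 50_000)])
        factor = make_rs(
            [("chr1", 0, 25_000), ("chr1", 50_000, 100_000), ("chr2", 0, 25_000)]
        )
        out = enr.rank_regulators(query, {"f": factor}, asm, bin_size=1000).iloc[0]
        assert out["odds_ratio"] == pytest.approx(1.0)
        assert out["score"] == 0.0

    def test_independent_factor_scores_near_zero(self, assembly):
        scores = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            query = random_regions(r, assembly, 200, min_len=400, max_len=600)
            factor = random_regions(r, assembly, 200, min_len=400, max_len=600)
            out = enr.rank_regulators(query, {"f": factor}, assembly)
            scores.append(out.iloc[0]["score"])
        assert np.max(np.abs(scores)) < 2

    def test_monotone_in_planted_overlap_fraction(self, assembly, rng):
        query = random_regions(rng, assembly, 80, min_len=400, max_len=600)
        scores = []
        for frac in (0.2, 0.5, 0.9):
            sim = synth.make_compendium(
                assembly, query, n_factors=1, enriched_factor_overlap_frac=frac, seed=13
            )
            out = enr.rank_regulators(query, sim.factors, assembly)
            scores.append(out.iloc[0]["score"])
        assert scores[0] < scores[1] < scores[2]

    def test_invariant_to_factor_ordering(self, assembly, rng):
        comp = {f"f{i}": random_regions(rng, assembly, 30) for i in range(4)}
        query = random_regions(rng, assembly, 30)
        out1 = enr.rank_regulators(query, comp, assembly)
        out2 = enr.rank_regulators(query, dict(reversed(list(comp.items()))), assembly)
        pd.testing.assert_frame_equal(out1, out2)

    def test_bad_bin_size_rejected(self, assembly, rng):
        q = random_regions(rng, assembly, 5)
        with pytest.raises(ValueError):
            enr.rank_regulators(q, {"f": q}, assembly, bin_size=0)
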