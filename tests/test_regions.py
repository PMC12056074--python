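"""Region derivation, CpG island calling and region-level aggregation."""

import numpy as np
import pandas as pd
import pytest

from spermeth.core import MethMatrix
from spermeth.regions import (
    aggregate_region_methylation,
    derive_gene_features,
    derive_promoters,
    derive_shores,
    detect_cpg_islands,
    detect_cpg_islands_fasta,
    filter_regions,
)

CHROM_SIZES = {"LG1": 20_000}


def _genes(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])


class TestPromoters:
    def test_plus_strand_upstream(self):
        prom = derive_promoters(_genes([("LG1", 5000, 8000, "+", "g1")]), CHROM_SIZES)
        assert (prom.loc[0, "start"], prom.loc[0, "end"]) == (4000, 5000)

    def test_minus_strand_mirror(self):
        prom = derive_promoters(_genes([("LG1", 5000, 8000, "-", "g1")]), CHROM_SIZES)
        assert (prom.loc[0, "start"], prom.loc[0, "end"]) == (8000, 9000)

    def test_truncated_at_chromosome_start(self):
        prom = derive_promoters(_genes([("LG1", 300, 900, "+", "g1")]), CHROM_SIZES)
        assert (prom.loc[0, "start"], prom.loc[0, "end"]) == (0, 300)

    def test_truncated_at_chromosome_end(self):
        prom = derive_promoters(_genes([("LG1", 18_000, 19_500, "-", "g1")]), CHROM_SIZES)
        assert (prom.loc[0, "start"], prom.loc[0, "end"]) == (19_500, 20_000)


class TestGeneFeatures:
    def _exons(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])

    def test_plus_strand_first_intron_is_first_gap(self):
        genes = _genes([("LG1", 0, 300, "+", "g")])
        exons = self._exons([("LG1", 0, 100, "+", "g"), ("LG1", 200, 300, "+", "g")])
        feats = derive_gene_features(genes, exons, CHROM_SIZES)
        fi = feats["first_intron"]
        assert (fi.loc[0, "start"], fi.loc[0, "end"]) == (100, 200)

    def test_minus_strand_first_intron_is_last_genomic_gap(self):
        genes = _genes([("LG1", 0, 500, "-", "g")])
        exons = self._exons(
            [("LG1", 0, 100, "-", "g"), ("LG1", 200, 300, "-", "g"),
             ("LG1", 400, 500, "-", "g")]
        )
        feats = derive_gene_features(genes, exons, CHROM_SIZES)
        fi = feats["first_intron"]
        # transcription runs right-to-left: the gap nearest the TSS (at 500)
        # is the last one in genomic order
        assert (fi.loc[0, "start"], fi.loc[0, "end"]) == (300, 400)

    def test_single_exon_gene_has_no_intron(self):
        genes = _genes([("LG1", 0, 100, "+", "g")])
        exons = self._exons([("LG1", 0, 100, "+", "g")])
        feats = derive_gene_features(genes, exons, CHROM_SIZES)
        assert len(feats["intron"]) == 0 and len(feats["first_intron"]) == 0

    def test_intergenic_complement_exhaustive_small_genome(self):
        sizes = {"LG1": 10_000}
        genes = _genes(
            [("LG1", 1000, 3000, "+", "a"), ("LG1", 6000, 7000, "-", "b")]
        )
        exons = self._exons(
            [("LG1", 1000, 1500, "+", "a"), ("LG1", 2500, 3000, "+", "a"),
             ("LG1", 6000, 6400, "-", "b"), ("LG1", 6600, 7000, "-", "b")]
        )
        feats = derive_gene_features(genes, exons, sizes)
        inter = feats["intergenic"]
        spans = list(zip(inter["start"], inter["end"]))
        assert spans == [(0, 1000), (3000, 6000), (7000, 10_000)]
        # position-by-position: every base is gene xor intergenic
        covered = np.zeros(10_000, dtype=int)
        for _, r in pd.concat([feats["gene"], inter]).iterrows():
            covered[r["start"]:r["end"]] += 1
        assert (covered == 1).all()


class TestIslands:
    def test_cg_repeat_block_called_as_single_island(self):
        seq = "A" * 500 + "CG" * 150 + "A" * 500
        isl = detect_cpg_islands({"c": seq})
        assert len(isl) == 1
        s, e = isl.loc[0, "start"], isl.loc[0, "end"]
        # called island is trimmed to CG boundaries of the planted block
        assert s == 500 and e == 800

    def test_obs_exp_of_cg_repeat(self):
        # 200 bp of CG repeats: N_C = N_G = 100, N_CG = 100 fully inside
        # obs/exp = 100 * 200 / (100 * 100) = 2 >= 0.6, GC = 100%
        isl = detect_cpg_islands({"c": "CG" * 100})
        assert len(isl) == 1

    def test_pure_a_has_no_island(self):
        assert len(detect_cpg_islands({"c": "A" * 1000})) == 0

    def test_gc_rich_without_cpg_fails(self):
        # GC-rich but all Cs before all Gs: only one CG dinucleotide at the
        # junction -> obs/exp far below 0.6
        seq = "C" * 400 + "G" * 400
        assert len(detect_cpg_islands({"c": seq})) == 0

    def test_planted_islands_recovered(self, small_study):
        manifest, outdir = small_study
        called = detect_cpg_islands_fasta(outdir / manifest["files"]["fasta"])
        recovered = 0
        for p in manifest["islands"]:
            sub = called[called["chrom"] == p["chrom"]]
            for r in sub.itertuples(index=False):
                ov = min(r.end, p["end"]) - max(r.start, p["start"])
                if ov > 0 and ov >= 0.8 * (r.end - r.start) and ov >= 0.8 * (
                    p["end"] - p["start"]
                ):
                    recovered += 1
                    break
        assert recovered >= 0.95 * len(manifest["islands"])


class TestShores:
    def test_flanks_of_isolated_island(self):
        islands = pd.DataFrame(
            [("LG1", 10_000, 10_500, ".", "i1", "cpg_island")],
            columns=["chrom", "start", "end", "strand", "label", "feature_kind"],
        )
        shores = derive_shores(islands, {"LG1": 50_000}, width=2000)
        spans = sorted(zip(shores["start"], shores["end"]))
        assert spans == [(8_000, 10_000), (10_500, 12_500)]

    def test_clipped_at_chromosome_start(self):
        islands = pd.DataFrame(
            [("LG1", 500, 900, ".", "i1", "cpg_island")],
            columns=["chrom", "start", "end", "strand", "label", "feature_kind"],
        )
        shores = derive_shores(islands, {"LG1": 50_000}, width=2000)
        spans = sorted(zip(shores["start"], shores["end"]))
        assert spans == [(0, 500), (900, 2_900)]

    def test_shores_never_overlap_islands(self):
        islands = pd.DataFrame(
            [
                ("LG1", 10_000, 10_500, ".", "i1", "cpg_island"),
                ("LG1", 11_500, 12_000, ".", "i2", "cpg_island"),
            ],
            columns=["chrom", "start", "end", "strand", "label", "feature_kind"],
        )
        shores = derive_shores(islands, {"LG1": 50_000}, width=2000)
        for s in shores.itertuples(index=False):
            for i in islands.itertuples(index=False):
                assert min(s.end, i.end) <= max(s.start, i.start)


class TestAggregation:
    def _mm(self, C, M_counts, positions):
        C = np.asarray(C)
        M = np.asarray(M_counts)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(C > 0, M / np.maximum(C, 1), np.nan)
        loci = pd.DataFrame({"chrom": "LG1", "pos": positions})
        return MethMatrix(
            ids=[f"i{k}" for k in range(C.shape[0])], loci=loci, P=P,
            C=C.astype(np.int64),
        )

    def _region(self, start, end):
        return pd.DataFrame(
            [("LG1", start, end, ".", "promoter", "r1")],
            columns=["chrom", "start", "end", "strand", "feature_kind", "label"],
        )

    def test_equal_coverage_mean(self):
        mm = self._mm([[10, 10]], [[4, 6]], [10, 20])
        out = aggregate_region_methylation(mm, self._region(0, 100))
        assert out.V[0, 0] == pytest.approx(0.5)

    def test_coverage_weighting_matters(self):
        mm = self._mm([[1, 99]], [[1, 0]], [10, 20])
        out = aggregate_region_methylation(mm, self._region(0, 100))
        assert out.V[0, 0] == pytest.approx(0.01)
        un = aggregate_region_methylation(mm, self._region(0, 100), weighted=False)
        assert un.V[0, 0] == pytest.approx(0.5)

    def test_unweighted_equals_weighted_at_equal_coverage(self, rng):
        C = np.full((5, 10), 20)
        M = rng.integers(0, 21, size=(5, 10))
        mm = self._mm(C, M, np.arange(10) * 10)
        w = aggregate_region_methylation(mm, self._region(0, 1000))
        u = aggregate_region_methylation(mm, self._region(0, 1000), weighted=False)
        np.testing.assert_allclose(w.V, u.V, atol=1e-12)

    def test_empty_region_flagged_nan(self):
        mm = self._mm([[10]], [[5]], [10])
        out = aggregate_region_methylation(mm, self._region(5000, 6000))
        assert np.isnan(out.V[0, 0]) and out.COV[0, 0] == 0

    def test_bounded_by_member_proportions(self, rng):
        C = rng.integers(1, 50, size=(8, 20))
        M = rng.binomial(C, 0.7)
        mm = self._mm(C, M, np.arange(20) * 10)
        out = aggregate_region_methylation(mm, self._region(0, 1000))
        assert (out.V[:, 0] >= mm.P.min(axis=1) - 1e-12).all()
        assert (out.V[:, 0] <= mm.P.max(axis=1) + 1e-12).all()

    def test_invariant_to_cpg_ordering(self, rng):
        C = rng.integers(5, 50, size=(4, 6))
        M = rng.binomial(C, 0.5)
        mm = self._mm(C, M, np.arange(6) * 10)
        perm = rng.permutation(6)
        mm_p = MethMatrix(
            ids=mm.ids, loci=mm.loci.iloc[perm].reset_index(drop=True),
            P=mm.P[:, perm], C=mm.C[:, perm],
        )
        a = aggregate_region_methylation(mm, self._region(0, 100)).V
        b = aggregate_region_methylation(mm_p, self._region(0, 100)).V
        np.testing.assert_allclose(a, b)


class TestFilterRegions:
    def test_constant_region_dropped_and_brute_force_match(self, rng):
        from spermeth.core import RegionMethMatrix

        n_ind, n_reg = 12, 60
        V = rng.uniform(0.2, 0.8, size=(n_ind, n_reg))
        V[:, 0] = 0.5  # constant -> dropped
        COV = rng.integers(5, 60, size=(n_ind, n_reg))
        regions = pd.DataFrame(
            {
                "chrom": "LG1",
                "start": np.arange(n_reg) * 100,
                "end": np.arange(n_reg) * 100 + 50,
                "strand": ".",
                "feature_kind": "promoter",
                "label": [f"r{k}" for k in range(n_reg)],
            }
        )
        rmm = RegionMethMatrix(
            ids=[f"i{k}" for k in range(n_ind)], regions=regions, V=V,
            COV=COV.astype(np.int64),
        )
        out = filter_regions(rmm, methsd_min=0.05, coverage_min=10)
        # brute force, region by region
        expected = [
            k
            for k in range(n_reg)
            if np.std(V[:, k], ddof=1) > 0.05 and (COV[:, k] >= 10).all()
        ]
        assert list(out.regions.index) == list(range(len(expected)))
        assert [f"r{k}" for k in expected] == list(out.regions["label"])
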