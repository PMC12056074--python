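"""CpG-cluster scan: cluster formation, extremes, Welch test, adjustments."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from spermeth.core import MethMatrix, ValidationError
from spermeth.scan import (
    adjust_pvalues,
    annotate_hits,
    form_clusters,
    run_scan,
    split_extremes,
    welch_test,
)


def _qualifying_matrix(positions, n_ind=12, chrom="LG1"):
    """All loci pass methSD/coverage filters by construction."""
    rng = np.random.default_rng(0)
    n = len(positions)
    P = np.clip(0.5 + rng.normal(0, 0.25, size=(n_ind, n)), 0.02, 0.98)
    loci = pd.DataFrame({"chrom": chrom, "pos": positions})
    return MethMatrix(
        ids=[f"i{k}" for k in range(n_ind)], loci=loci, P=P,
        C=np.full((n_ind, n), 30, dtype=np.int64),
    )


def _brute_force_runs(positions, max_gap=150, min_size=5):
    runs, current = [], [positions[0]]
    for p in positions[1:]:
        if p - current[-1] <= max_gap:
            current.append(p)
        else:
            runs.append(current)
            current = [p]
    runs.append(current)
    return [r for r in runs if len(r) >= min_size]


class TestFormClusters:
    def test_five_members_with_small_gaps(self):
        mm = _qualifying_matrix([100, 180, 250, 330, 400])
        clusters = form_clusters(mm)
        assert len(clusters) == 1
        assert clusters.loc[0, "n_cpgs"] == 5
        assert clusters.loc[0, "start"] == 100 and clusters.loc[0, "end"] == 402

    def test_large_gap_breaks_run(self):
        mm = _qualifying_matrix([100, 180, 250, 330, 552])  # gap 222 > 150
        assert len(form_clusters(mm)) == 0

    def test_four_members_not_enough(self):
        mm = _qualifying_matrix([100, 150, 200, 250])
        assert len(form_clusters(mm)) == 0

    def test_non_qualifying_member_breaks_run(self):
        mm = _qualifying_matrix([100, 190, 280, 370, 460, 550])
        mm.C[0, 2] = 5  # coverage < 10 in one individual kills locus 280
        clusters = form_clusters(mm)
        # dropping 280 leaves a 190 -> 370 gap (180 > 150): runs of 2 and 3
        assert len(clusters) == 0

    def test_matches_brute_force_on_random_positions(self, rng):
        for trial in range(20):
            r = np.random.default_rng(trial)
            pos = np.sort(r.choice(5000, size=60, replace=False))
            mm = _qualifying_matrix(pos.tolist())
            got = form_clusters(mm)
            expected = _brute_force_runs(pos.tolist())
            assert len(got) == len(expected)
            for row, run in zip(got.itertuples(index=False), expected):
                assert row.n_cpgs == len(run) and row.start == run[0]

    def test_clusters_respect_chromosome_boundaries(self):
        loci = [100, 180, 250, 330, 400]
        mm1 = _qualifying_matrix(loci, chrom="LG1")
        mm2 = _qualifying_matrix(loci, chrom="LG2")
        both = MethMatrix(
            ids=mm1.ids,
            loci=pd.concat([mm1.loci, mm2.loci], ignore_index=True),
            P=np.hstack([mm1.P, mm2.P]),
            C=np.hstack([mm1.C, mm2.C]),
        )
        clusters = form_clusters(both)
        assert len(clusters) == 2 and set(clusters["chrom"]) == {"LG1", "LG2"}


class TestSplitExtremes:
    def _traits(self, values):
        return pd.DataFrame({"id": [f"i{k:03d}" for k in range(len(values))],
                             "vcl": values})

    def test_forty_six_individuals_twenty_each(self):
        traits = self._traits(np.arange(46, dtype=float))
        cases, controls = split_extremes(traits, "vcl", k=20)
        assert len(cases) == 20 and len(controls) == 20
        assert set(cases).isdisjoint(controls)
        assert cases == [f"i{k:03d}" for k in range(20)]
        assert controls == [f"i{k:03d}" for k in range(26, 46)]

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValidationError):
            split_extremes(self._traits([1.0, 2.0, 3.0]), "vcl", k=2)

    def test_all_tied_is_deterministic_with_warning(self):
        traits = self._traits(np.ones(10))
        with pytest.warns(UserWarning, match="tied"):
            c1 = split_extremes(traits, "vcl", k=4)
        with pytest.warns(UserWarning):
            c2 = split_extremes(traits, "vcl", k=4)
        assert c1 == c2

    def test_missing_values_ignored(self):
        vals = np.arange(12, dtype=float)
        traits = self._traits(vals)
        traits.loc[0, "vcl"] = np.nan
        cases, controls = split_extremes(traits, "vcl", k=5)
        assert "i000" not in cases + controls


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert t == 0 and p == pytest.approx(1.0)

    def test_hand_computed_case(self):
        # cases (0.2, 0.3, 0.25) vs controls (0.7, 0.8, 0.75):
        # means 0.25/0.75, each var 0.0025, se = sqrt(2*0.0025/3) = 0.040825,
        # t = -0.5/0.040825 = -12.2474, df = 4 (equal variances/sizes)
        t, df, p = welch_test([0.2, 0.3, 0.25], [0.7, 0.8, 0.75])
        assert t == pytest.approx(-12.247449, abs=1e-6)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert p < 0.001

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            x = rng.normal(0, 1, size=rng.integers(3, 30))
            y = rng.normal(0.3, 2, size=rng.integers(3, 30))
            t, df, p = welch_test(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_zero_variance(self):
        t, df, p = welch_test([0.5, 0.5], [0.5, 0.5])
        assert p == 1.0
        t, df, p = welch_test([0.2, 0.2], [0.8, 0.8])
        assert p == 0.0 and t < 0

    def test_group_of_one_rejected(self):
        with pytest.raises(ValidationError):
            welch_test([0.5], [0.2, 0.3])


class TestAdjustPvalues:
    def test_single_p(self):
        out = adjust_pvalues([0.03])
        assert out.loc[0, "p_bh"] == pytest.approx(0.03)
        assert out.loc[0, "bonferroni_significant"]

    def test_hand_step_up_example(self):
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out["p_bh"], [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_empty_input(self):
        assert len(adjust_pvalues([])) == 0

    def test_bonferroni_flag_threshold(self):
        out = adjust_pvalues([0.04, 0.004], alpha=0.05)
        assert list(out["bonferroni_significant"]) == [False, True]

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=40))
    def test_bh_monotone_and_order_invariant(self, pvals):
        out = adjust_pvalues(pvals)
        order = np.argsort(pvals, kind="stable")
        sorted_bh = out["p_bh"].to_numpy()[order]
        assert (np.diff(sorted_bh) >= -1e-12).all()
        assert (out["p_bh"] <= 1.0 + 1e-12).all()
        # permuting the input permutes the output identically
        perm = list(reversed(range(len(pvals))))
        out2 = adjust_pvalues([pvals[i] for i in perm])
        np.testing.assert_allclose(
            out2["p_bh"].to_numpy()[np.argsort(perm, kind="stable")],
            out["p_bh"].to_numpy(),
            atol=1e-12,
        )


class TestRunScan:
    def test_planted_hypermethylation_in_low_group_direction(self):
        from spermeth.simulate import simulate_cluster_matrix

        mm, traits, spans = simulate_cluster_matrix(
            n_clusters=30, n_planted=2, seed=5
        )
        res = run_scan(mm, traits, "trait", k=20)
        for chrom, s, e in spans:
            row = res[(res["chrom"] == chrom) & (res["start"] == s)].iloc[0]
            assert row["direction"] == "hyper_in_cases"
            assert row["mean_cases"] > row["mean_controls"]

    def test_empty_result_when_no_clusters(self):
        mm = _qualifying_matrix([100, 5000, 9000], n_ind=46)
        traits = pd.DataFrame(
            {"id": mm.ids, "trait": np.arange(46, dtype=float)}
        )
        with pytest.warns(UserWarning, match="no clusters"):
            res = run_scan(mm, traits, "trait", k=20)
        assert len(res) == 0


class TestAnnotateHits:
    GENES = pd.DataFrame(
        {
            "chrom": ["LG1", "LG1", "LG1"],
            "start": [50_000, 150_000, 400_000],
            "end": [60_000, 160_000, 410_000],
            "strand": ["+", "-", "+"],
            "gene_id": ["near", "mid", "far"],
        }
    )

    def _hits(self):
        return pd.DataFrame({"chrom": ["LG1"], "start": [100_000], "end": [100_500]})

    def test_gene_within_flank_included(self):
        ann = annotate_hits(self._hits(), self.GENES, flank=50_000)
        assert set(ann["gene_id"]) == {"near", "mid"}

    def test_gene_beyond_flank_excluded(self):
        ann = annotate_hits(self._hits(), self.GENES, flank=30_000)
        assert set(ann["gene_id"]) == set()

    def test_distances_and_brute_force(self, rng):
        genes = pd.DataFrame(
            {
                "chrom": "LG1",
                "start": np.sort(rng.choice(1_000_000, 50, replace=False)),
                "strand": "+",
            }
        )
        genes["end"] = genes["start"] + rng.integers(500, 5000, 50)
        genes["gene_id"] = [f"g{k}" for k in range(50)]
        hits = pd.DataFrame(
            {"chrom": ["LG1"] * 5,
             "start": np.sort(rng.choice(900_000, 5, replace=False))}
        )
        hits["end"] = hits["start"] + 400
        ann = annotate_hits(hits, genes, flank=50_000)
        for h in hits.itertuples(index=False):
            expected = {
                g.gene_id
                for g in genes.itertuples(index=False)
                if g.end > h.start - 50_000 and g.start < h.end + 50_000
            }
            got = set(ann[(ann["start"] == h.start)]["gene_id"])
            assert got == expected
        assert (ann["distance"] >= 0).all() and (ann["distance"] <= 50_000).all()
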