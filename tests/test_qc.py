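"""Sample QC, filtering rules and phenotype cleaning."""

import numpy as np
import pandas as pd
import pytest

from spermeth import io as io_mod, qc
from spermeth.core import MethMatrix, SpermethError, ValidationError


def _ctrl(meth, unmeth):
    return pd.DataFrame({"count_meth": [meth], "count_unmeth": [unmeth]})


class TestConversionQC:
    def test_error_rate_arithmetic(self):
        rep = qc.conversion_qc("s", _ctrl(990, 10), _ctrl(5, 995))
        assert rep["conversion_error"] == pytest.approx(0.005)
        assert rep["protection"] == pytest.approx(0.99)
        assert rep["qc_pass"]

    def test_failed_conversion_flagged(self):
        rep = qc.conversion_qc("s", _ctrl(990, 10), _ctrl(500, 500))
        assert not rep["qc_pass"] and "conversion error" in rep["reason"]

    def test_poor_protection_flagged(self):
        rep = qc.conversion_qc("s", _ctrl(900, 100), _ctrl(5, 995))
        assert not rep["qc_pass"] and "protection" in rep["reason"]

    def test_zero_control_coverage(self):
        rep = qc.conversion_qc("s", _ctrl(0, 0), _ctrl(5, 995))
        assert not rep["qc_pass"] and rep["reason"] == "no control signal"


class TestGlobalLevels:
    def test_fully_methylated(self):
        tab = pd.DataFrame(
            {"context": ["CpG", "CHG", "CHH"], "count_meth": [10, 10, 10],
             "count_unmeth": [0, 0, 0]}
        )
        levels = qc.global_context_levels(tab)
        assert levels == {"CpG": 1.0, "CHG": 1.0, "CHH": 1.0}

    def test_pooled_not_averaged(self):
        tab = pd.DataFrame(
            {"context": ["CpG", "CpG"], "count_meth": [860, 0],
             "count_unmeth": [140, 0]}
        )
        assert qc.global_context_levels(tab)["CpG"] == pytest.approx(0.86)

    def test_absent_context_is_undefined_not_zero(self):
        tab = pd.DataFrame({"context": ["CpG"], "count_meth": [1], "count_unmeth": [1]})
        assert qc.global_context_levels(tab)["CHH"] is None

    def test_fixture_global_level_near_configured_mean(self, small_study, small_matrix):
        manifest, _ = small_study
        pooled = np.nansum(small_matrix.P * small_matrix.C) / small_matrix.C.sum()
        assert pooled * 100 == pytest.approx(86.0, abs=1.0)


class TestOutlierDetection:
    def _reports(self, cpg, ok=None):
        n = len(cpg)
        return pd.DataFrame(
            {"id": [f"s{i}" for i in range(n)], "cpg_pct": cpg,
             "qc_pass": ok if ok is not None else [True] * n,
             "reason": [""] * n}
        )

    def test_homogeneous_cohort_keeps_everyone(self):
        excl = qc.detect_outlier_samples(self._reports([85.1, 85.5, 86.0, 85.8]))
        assert len(excl) == 0

    def test_hypermethylated_outlier_excluded(self):
        excl = qc.detect_outlier_samples(
            self._reports([85.1, 85.5, 86.0, 85.8, 86.2, 99.5])
        )
        assert list(excl["id"]) == ["s5"]

    def test_all_excluded_is_hard_error(self):
        with pytest.raises(SpermethError, match="all samples"):
            qc.detect_outlier_samples(
                self._reports([85.0, 85.5, 86.0], ok=[False, False, False])
            )

    def test_study_excludes_exactly_the_corrupted_sample(self, small_study):
        manifest, outdir = small_study
        sample_tables, control_tables = {}, {}
        for sid in manifest["samples"]:
            sample_tables[sid] = io_mod.read_bismark_cov(
                outdir / manifest["files"][f"cov:{sid}"]
            )
            ctrl = io_mod.read_bismark_cov(outdir / manifest["files"][f"controls:{sid}"])
            control_tables[sid] = (
                ctrl[ctrl["chrom"] == "pUC19_control"],
                ctrl[ctrl["chrom"] == "lambda_control"],
            )
        report = qc.build_sample_qc(sample_tables, control_tables)
        excl = qc.detect_outlier_samples(report)
        assert list(excl["id"]) == manifest["corrupted_samples"]


class TestSnpExclusion:
    def test_no_overlap_is_identity(self, small_matrix):
        out, n = qc.exclude_snp_cpgs(small_matrix, {("LGX", 1)})
        assert n == 0 and out.n_loci == small_matrix.n_loci

    def test_transversion_positions_do_not_drop(self, small_matrix):
        # positions not in the set are untouched even if they are real loci
        out, n = qc.exclude_snp_cpgs(small_matrix, set())
        assert n == 0

    def test_study_drops_exactly_the_planted_transitions(self, small_study, small_matrix):
        manifest, outdir = small_study
        transitions = io_mod.read_vcf_transition_sites(outdir / manifest["files"]["vcf"])
        out, n = qc.exclude_snp_cpgs(small_matrix, transitions)
        assert n == len(manifest["transition_snps_on_cpg"])
        kept = set(zip(out.loci["chrom"], out.loci["pos"]))
        for chrom, pos in manifest["transition_snps_on_cpg"]:
            assert (chrom, pos) not in kept


class TestVariableSelection:
    def _matrix(self, P, C):
        P = np.asarray(P, float)
        C = np.asarray(C)
        loci = pd.DataFrame(
            {"chrom": "LG1", "pos": np.arange(P.shape[1]) * 100}
        )
        return MethMatrix(
            ids=[f"i{k}" for k in range(P.shape[0])], loci=loci, P=P, C=C
        )

    def test_constant_locus_dropped(self):
        P = np.full((4, 1), 0.86)
        mm = self._matrix(P, np.full((4, 1), 20))
        assert qc.select_variable_cpgs(mm).n_loci == 0

    def test_hand_computed_methsd_kept(self):
        P = np.array([[0.1], [0.9], [0.1], [0.9]])
        mm = self._matrix(P, np.full((4, 1), 10))
        # sample SD of (0.1, 0.9, 0.1, 0.9) = 0.46188 > 0.1
        assert np.std(P, ddof=1) == pytest.approx(0.46188, abs=1e-4)
        assert qc.select_variable_cpgs(mm).n_loci == 1

    def test_low_coverage_in_one_individual_drops_locus(self):
        P = np.array([[0.1, 0.1], [0.9, 0.9], [0.1, 0.1], [0.9, 0.9]])
        C = np.array([[10, 10], [10, 9], [10, 10], [10, 10]])
        mm = self._matrix(P, C)
        kept = qc.select_variable_cpgs(mm)
        assert kept.n_loci == 1 and kept.loci.loc[0, "pos"] == 0

    def test_mean_coverage_interpretation_flag(self):
        P = np.array([[0.1, 0.1], [0.9, 0.9], [0.1, 0.1], [0.9, 0.9]])
        C = np.array([[10, 40], [10, 9], [10, 1], [10, 10]])
        mm = self._matrix(P, C)
        assert qc.select_variable_cpgs(mm, per_individual_coverage=False).n_loci == 2

    def test_idempotence(self, small_matrix):
        once = qc.select_variable_cpgs(small_matrix)
        twice = qc.select_variable_cpgs(once)
        assert once.n_loci == twice.n_loci
        np.testing.assert_array_equal(once.P, twice.P)

    def test_individual_permutation_permutes_rows_only(self, small_matrix):
        perm = list(reversed(small_matrix.ids))
        out1 = qc.select_variable_cpgs(small_matrix)
        out2 = qc.select_variable_cpgs(small_matrix.subset_individuals(perm))
        assert out2.ids == perm
        pd.testing.assert_frame_equal(out1.loci, out2.loci)
        np.testing.assert_array_equal(out1.P[::-1], out2.P)


class TestStates:
    def test_canonical_values(self):
        assert list(qc.classify_states([0.05, 0.5, 0.95])) == ["hypo", "semi", "hyper"]

    def test_boundaries_closed_middle(self):
        states = qc.classify_states([1 / 3, 2 / 3])
        assert list(states) == ["semi", "semi"]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            qc.classify_states([1.2])


class TestPhenotypeCleaning:
    RULES = {"concentration": {"upper": 10000.0, "replace_upper": 10000.0}}

    def test_outlier_winsorized(self):
        tab = pd.DataFrame({"id": ["a", "b"], "concentration": [13536.0, 2000.0]})
        out, log = qc.clean_phenotypes(tab, self.RULES)
        assert out.loc[0, "concentration"] == 10000.0
        assert len(log) == 1 and log.loc[0, "old"] == 13536.0

    def test_no_change_when_within_bounds(self):
        tab = pd.DataFrame({"id": ["a"], "concentration": [900.0]})
        out, log = qc.clean_phenotypes(tab, self.RULES)
        pd.testing.assert_frame_equal(out, tab)
        assert len(log) == 0

    def test_log_rows_equal_modified_cells(self):
        tab = pd.DataFrame(
            {"id": list("abcd"), "concentration": [20000.0, 15000.0, 100.0, 11000.0]}
        )
        out, log = qc.clean_phenotypes(tab, self.RULES)
        assert len(log) == 3
        assert (out["concentration"] <= 10000.0).all()
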