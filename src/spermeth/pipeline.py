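"""End-to-end pipeline: simulate -> read -> QC -> filter -> decay -> relationship
matrices -> regions -> comethylation networks -> cluster scan.

``run_pipeline`` takes a nested configuration dict (YAML-friendly), runs the
enabled stages in order and writes every stage's outputs plus a
machine-readable ``report.json`` of deterministic counts.  Volatile run
metadata (wall time, library versions) goes to ``run_meta.json`` so two runs
with the same seed produce byte-identical output trees apart from that one
file.
"""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import decay as decay_mod
from . import io as io_mod
from . import network as net_mod
from . import qc as qc_mod
from . import regions as reg_mod
from . import relmat as rel_mod
from . import scan as scan_mod
from .core import MethMatrix, SpermethError
from .simulate import SimConfig
from .study import simulate_study

TRAIT_CLEANING_RULES = {"concentration": {"upper": 10000.0, "replace_upper": 10000.0}}


def default_config(seed: int = 0, outdir: str = "spermeth_run") -> dict:
    return {
        "seed": seed,
        "outdir": outdir,
        "simulate": {"enabled": True, "overrides": {}},
        "stages": {
            "qc": True,
            "decay": True,
            "relmat": True,
            "regions": True,
            "network": True,
            "scan": True,
        },
        "filter": {"methsd_min": 0.1, "coverage_min": 10},
        "decay": {
            "short_sizes": [100, 200, 300, 400, 500, 600, 700, 800, 900, 1000],
            "medium_sizes": [
                10000, 20000, 30000, 40000, 50000, 60000, 70000, 80000, 90000, 100000,
            ],
            "n_bins": 500,
        },
        "regions": {"methsd_min": 0.05, "coverage_min": 10, "shore_width": 2000},
        "network": {
            "features": ["promoter", "cpg_island", "first_intron"],
            "n_pcs_to_adjust": 0,
            "min_module_size": 10,
            "cut_height": 0.995,
        },
        "scan": {"traits": ["concentration", "vcl"], "k": 20, "flank": 50000},
    }


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    _deep_update(cfg, user)
    return cfg


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def run_pipeline(config: dict) -> dict:
    """Run the configured stages; returns the report dict."""
    t0 = time.time()
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    report: dict = {"seed": seed, "stages": {}}
    stage = "simulate"
    try:
        # ---- synthetic study ------------------------------------------------
        fixture_dir = outdir / "fixture"
        if config["simulate"]["enabled"]:
            sim_cfg = SimConfig(seed=seed, **config["simulate"]["overrides"])
            manifest = simulate_study(sim_cfg, fixture_dir)
        else:
            with open(Path(config["inputs"]["manifest"])) as fh:
                manifest = json.load(fh)
            fixture_dir = Path(config["inputs"]["manifest"]).parent
        chrom_sizes = {k: int(v) for k, v in manifest["chrom_sizes"].items()}
        sample_ids = manifest["samples"]
        report["stages"]["simulate"] = {
            "n_samples": len(sample_ids),
            "n_sites": manifest["n_sites"],
            "n_variable_truth": manifest["n_variable_sites"],
        }

        # ---- read -----------------------------------------------------------
        stage = "read"
        sample_tables = {}
        control_tables = {}
        for sid in sample_ids:
            cov_tab = io_mod.read_bismark_cov(fixture_dir / manifest["files"][f"cov:{sid}"])
            ncpg_tab = io_mod.read_bismark_cov(
                fixture_dir / manifest["files"][f"noncpg:{sid}"], dialect="cytosine_report"
            )
            sample_tables[sid] = pd.concat([cov_tab, ncpg_tab], ignore_index=True)
            ctrl = io_mod.read_bismark_cov(
                fixture_dir / manifest["files"][f"controls:{sid}"]
            )
            control_tables[sid] = (
                ctrl[ctrl["chrom"] == "pUC19_control"],
                ctrl[ctrl["chrom"] == "lambda_control"],
            )
        report["stages"]["read"] = {
            "n_samples_read": len(sample_tables),
            "sites_per_sample": int(len(next(iter(sample_tables.values())))),
        }

        # ---- sample QC ------------------------------------------------------
        stage = "qc"
        qc_report = qc_mod.build_sample_qc(sample_tables, control_tables)
        excluded = qc_mod.detect_outlier_samples(qc_report)
        analysis_ids = [s for s in sample_ids if s not in set(excluded["id"])]
        qc_report.to_csv(outdir / "sample_qc.csv", index=False, float_format="%.6g")
        excluded.to_csv(outdir / "excluded_samples.csv", index=False)
        report["stages"]["qc"] = {
            "n_excluded": int(len(excluded)),
            "n_analyzed": len(analysis_ids),
            "median_cpg_pct": round(float(qc_report["cpg_pct"].median()), 4),
        }

        # ---- site matrix + filters -----------------------------------------
        stage = "filter"
        cpg_tables = {
            sid: tab[tab["context"] == "CpG"]
            for sid, tab in sample_tables.items()
            if sid in set(analysis_ids)
        }
        matrix = MethMatrix.from_site_tables(cpg_tables)
        transitions = io_mod.read_vcf_transition_sites(
            fixture_dir / manifest["files"]["vcf"]
        )
        matrix, n_snp_dropped = qc_mod.exclude_snp_cpgs(matrix, transitions)
        fcfg = config["filter"]
        variable = qc_mod.select_variable_cpgs(
            matrix, methsd_min=fcfg["methsd_min"], coverage_min=fcfg["coverage_min"]
        )
        io_mod.write_bed(
            variable.loci.assign(
                start=variable.loci["pos"], end=variable.loci["pos"] + 2,
                label="variable_cpg", strand=".",
            )[["chrom", "start", "end", "label", "strand"]],
            outdir / "variable_cpgs.bed",
        )
        report["stages"]["filter"] = {
            "n_sites_read": int(matrix.n_loci + n_snp_dropped),
            "n_snp_overlap_dropped": int(n_snp_dropped),
            "n_variable_cpgs": int(variable.n_loci),
        }

        # ---- traits ---------------------------------------------------------
        traits_raw = io_mod.read_phenotypes(fixture_dir / manifest["files"]["phenotypes"])
        traits, change_log = qc_mod.clean_phenotypes(traits_raw, TRAIT_CLEANING_RULES)
        traits = traits[traits["id"].isin(analysis_ids)].reset_index(drop=True)
        change_log.to_csv(outdir / "phenotype_changes.csv", index=False)

        # ---- decay ----------------------------------------------------------
        if config["stages"].get("decay", True):
            stage = "decay"
            dcfg = config["decay"]
            prof_short = decay_mod.decay_profile(
                variable, dcfg["short_sizes"], n_bins=dcfg["n_bins"],
                seed=seed + 101, chrom_sizes=chrom_sizes,
            )
            prof_med = decay_mod.decay_profile(
                variable, dcfg["medium_sizes"], n_bins=dcfg["n_bins"],
                seed=seed + 202, chrom_sizes=chrom_sizes,
            )
            prof_short.to_csv(outdir / "decay_short.csv", index=False, float_format="%.6g")
            prof_med.to_csv(outdir / "decay_medium.csv", index=False, float_format="%.6g")
            lam_hat = None
            if prof_short["mean_abs_r"].notna().sum() >= 3:
                fit = decay_mod.fit_decay(
                    prof_short["bin_size"], prof_short["mean_abs_r"],
                    model="trimodal", n_individuals=len(analysis_ids),
                )
                if fit.converged and not fit.flat:
                    lam_hat = round(fit.decay_length, 2)
            def _num(x):
                return round(float(x), 6) if np.isfinite(x) else None

            report["stages"]["decay"] = {
                "short_mean_abs_r_first": _num(prof_short["mean_abs_r"].iloc[0]),
                "short_mean_abs_r_last": _num(prof_short["mean_abs_r"].iloc[-1]),
                "fitted_decay_length_bp": lam_hat,
            }

        # ---- relationship matrices -----------------------------------------
        if config["stages"].get("relmat", True):
            stage = "relmat"
            M, kept, dropped = rel_mod.standardize_methylation(variable.P)
            mrm = rel_mod.compute_mrm(M, variable.ids)
            ped = io_mod.read_pedigree(fixture_dir / manifest["files"]["pedigree"])
            amat = rel_mod.compute_amat(ped).subset(analysis_ids)
            geno, snp_sites = io_mod.read_vcf_genotypes(
                fixture_dir / manifest["files"]["vcf"]
            )
            grm = rel_mod.compute_grm(geno.loc[analysis_ids])
            io_mod.write_relationship_csv(mrm, outdir / "mrm.csv")
            io_mod.write_relationship_csv(amat, outdir / "amat.csv")
            io_mod.write_relationship_csv(grm, outdir / "grm.csv")
            r_amat, table_a = rel_mod.offdiag_concordance(mrm, amat, pedigree=ped)
            r_grm, _ = rel_mod.offdiag_concordance(mrm, grm)
            table_a.to_csv(outdir / "mrm_amat_pairs.csv", index=False, float_format="%.6g")
            report["stages"]["relmat"] = {
                "n_loci_in_mrm": int(M.shape[1]),
                "mrm_amat_offdiag_r": round(float(r_amat), 4),
                "mrm_grm_offdiag_r": round(float(r_grm), 4),
            }

        # ---- regions + networks --------------------------------------------
        if config["stages"].get("regions", True):
            stage = "regions"
            rcfg = config["regions"]
            genes, exons, gff_report = io_mod.read_gff_features(
                fixture_dir / manifest["files"]["gff"]
            )
            promoters = reg_mod.derive_promoters(genes, chrom_sizes)
            gene_feats = reg_mod.derive_gene_features(genes, exons, chrom_sizes)
            islands = reg_mod.detect_cpg_islands_fasta(
                fixture_dir / manifest["files"]["fasta"]
            )
            shores = reg_mod.derive_shores(islands, chrom_sizes, width=rcfg["shore_width"])
            feature_sets = {
                "promoter": promoters,
                "cpg_island": islands,
                "first_intron": gene_feats["first_intron"],
                "shore": shores,
                "gene": gene_feats["gene"],
                "exon": gene_feats["exon"],
                "intron": gene_feats["intron"],
                "intergenic": gene_feats["intergenic"],
            }
            for kind, regs in feature_sets.items():
                io_mod.write_bed(regs, outdir / f"regions_{kind}.bed")
            report["stages"]["regions"] = {
                **{f"n_{k}": int(len(v)) for k, v in feature_sets.items()},
                "n_exons_skipped": gff_report["n_exons_skipped"],
            }

            if config["stages"].get("network", True):
                stage = "network"
                ncfg = config["network"]
                net_report = {}
                for kind in ncfg["features"]:
                    regs = feature_sets[kind]
                    rmm = reg_mod.aggregate_region_methylation(variable, regs)
                    rmm = reg_mod.filter_regions(
                        rmm, methsd_min=rcfg["methsd_min"], coverage_min=rcfg["coverage_min"]
                    )
                    if rmm.n_regions < 3 * ncfg["min_module_size"]:
                        net_report[kind] = {"n_regions": int(rmm.n_regions), "skipped": True}
                        continue
                    nconf = net_mod.NetworkConfig(
                        n_pcs_to_adjust=ncfg["n_pcs_to_adjust"],
                        min_module_size=ncfg["min_module_size"],
                        cut_height=ncfg["cut_height"],
                    )
                    X = net_mod.adjust_top_pcs(rmm.V, nconf.n_pcs_to_adjust)
                    beta, r2, fallback = net_mod.select_soft_power(X, nconf)
                    labels = net_mod.detect_modules(X, beta, nconf)
                    eig = net_mod.compute_eigennodes(rmm.V, labels, rmm.ids)
                    assoc = net_mod.module_trait_association(eig, traits)
                    members = rmm.regions.copy()
                    members["module"] = labels
                    members.to_csv(outdir / f"modules_{kind}.csv", index=False)
                    eig.to_csv(outdir / f"eigennodes_{kind}.csv", float_format="%.6g")
                    assoc.to_csv(
                        outdir / f"module_trait_{kind}.csv", index=False, float_format="%.6g"
                    )
                    net_report[kind] = {
                        "n_regions": int(rmm.n_regions),
                        "soft_power": int(beta),
                        "n_modules": int(len({m for m in labels if m != net_mod.GRAY})),
                        "n_significant_cells": int(assoc["significant"].sum()),
                    }
                report["stages"]["network"] = net_report

        # ---- cluster scan ---------------------------------------------------
        if config["stages"].get("scan", True):
            stage = "scan"
            scfg = config["scan"]
            scan_report = {}
            for trait in scfg["traits"]:
                res = scan_mod.run_scan(matrix, traits, trait, k=scfg["k"])
                res_out = res.drop(columns=[], errors="ignore")
                res_out.to_csv(
                    outdir / f"scan_{trait}.csv", index=False, float_format="%.6g"
                )
                manh = res[["chrom", "start", "p"]].copy()
                manh["neg_log10_p"] = -np.log10(np.maximum(manh.pop("p"), 1e-300))
                manh.to_csv(
                    outdir / f"manhattan_{trait}.csv", index=False, float_format="%.6g"
                )
                hits = res[res["p_bh"] < 0.05]
                if config["stages"].get("regions", True) and len(hits):
                    ann_hits = scan_mod.annotate_hits(hits, genes, flank=scfg["flank"])
                    ann_hits.to_csv(
                        outdir / f"scan_{trait}_genes.csv", index=False
                    )
                io_mod.write_bed(
                    hits.assign(label="hit", strand=".")[
                        ["chrom", "start", "end", "label", "strand"]
                    ],
                    outdir / f"scan_{trait}_hits.bed",
                )
                scan_report[trait] = {
                    "n_clusters": int(len(res)),
                    "n_bh_hits": int((res["p_bh"] < 0.05).sum()),
                    "n_bonferroni_hits": int(res["bonferroni_significant"].sum()),
                }
            report["stages"]["scan"] = scan_report
    except Exception as exc:
        raise SpermethError(f"pipeline failed at stage '{stage}': {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    meta = {
        "wall_time_s": round(time.time() - t0, 2),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(outdir / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return report
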