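"""Emit a complete synthetic study to disk: methylomes, controls, annotation,
variants, pedigree, phenotypes and a ground-truth manifest.

File layout under the output directory::

    <id>.cov                  Bismark-coverage CpG calls per individual
    <id>.controls.cov         spike-in control contigs (pUC19-like fully
                              methylated, lambda-like fully unmethylated)
    <id>.nonCpG.CX_report.txt CHG/CHH sites (cytosine-report dialect)
    annotation.gff3, genome.fa, variants.vcf
    pedigree.csv, phenotypes.csv
    amat.csv                  additive relationship matrix (all individuals)
    site_truth.csv            per-CpG truth (variable flag, cluster id)
    manifest.json             everything needed to score recovery
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING_PARENT
from .io import write_bismark_cov, write_cytosine_report, write_relationship_csv
from .regions import derive_promoters
from .simulate import (
    PlantedCluster,
    PlantedModule,
    SimConfig,
    corrupt_targets,
    draw_counts,
    liabilities_to_targets,
    simulate_annotation,
    simulate_liabilities,
    simulate_pedigree,
    simulate_traits,
)


def _write_fasta(sequences: dict[str, str], path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_gff(genes: pd.DataFrame, exons: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples(index=False):
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for e in exons[exons["gene_id"] == g.gene_id].itertuples(index=False):
                fh.write(
                    f"{e.chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t"
                    f"Parent={g.gene_id}\n"
                )


def _write_vcf(
    sites: pd.DataFrame,
    genotypes: np.ndarray,
    sample_ids: list[str],
    chrom_sizes: dict[str, int],
    path: Path,
) -> None:
    """Minimal VCF v4.2 writer; genotypes are 0/1/2 dosages (rows = sites)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(chrom_sizes):
            fh.write(f"##contig=<ID={c},length={chrom_sizes[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for k, s in enumerate(sites.itertuples(index=False)):
            gts = "\t".join(gt_map[int(g)] for g in genotypes[k])
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _gene_drop(
    ped: pd.DataFrame, freqs: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Mendelian genotypes by gene dropping; returns id -> (2, n_snp) alleles."""
    alleles: dict[str, np.ndarray] = {}
    n_snp = len(freqs)
    for row in ped.itertuples(index=False):
        if row.sire == MISSING_PARENT and row.dam == MISSING_PARENT:
            alleles[row.id] = (rng.random((2, n_snp)) < freqs).astype(np.int8)
        else:
            pick = rng.integers(0, 2, size=(2, n_snp))
            pa = alleles[row.sire][pick[0], np.arange(n_snp)]
            ma = alleles[row.dam][pick[1], np.arange(n_snp)]
            alleles[row.id] = np.stack([pa, ma]).astype(np.int8)
    return alleles


def simulate_study(config: SimConfig, outdir) -> dict:
    """Generate and write the full synthetic study; returns the manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(8)
    rng_ann, rng_meth, rng_mod, rng_trait, rng_counts, rng_snp, rng_ctrl, rng_ncpg = (
        np.random.default_rng(s) for s in seeds
    )

    # ----- pedigree ---------------------------------------------------------
    ped, A_full, sample_ids = simulate_pedigree(config)
    good_ids = sample_ids[: len(sample_ids) - config.n_corrupted]
    corrupted_ids = sample_ids[len(sample_ids) - config.n_corrupted :]
    idx_full = {s: i for i, s in enumerate(A_full.ids)}
    rows = [idx_full[s] for s in sample_ids]
    A_samples = A_full.values[np.ix_(rows, rows)]

    # ----- annotation -------------------------------------------------------
    ann = simulate_annotation(config, rng_ann)
    chrom_sizes = ann["chrom_sizes"]
    chroms = sorted(chrom_sizes)

    # ----- CpG positions ----------------------------------------------------
    per_chrom = config.n_cpg // config.n_chrom
    pos_by_chrom: dict[str, np.ndarray] = {}
    for c in chroms:
        pos_by_chrom[c] = np.sort(
            rng_meth.choice(chrom_sizes[c] // 2 - 1, size=per_chrom, replace=False) * 2
        )

    # planted clusters: explicit runs of tightly spaced CpGs
    cluster_truth = []
    for ci, pc in enumerate(config.planted_clusters):
        c = chroms[int(rng_meth.integers(0, len(chroms)))]
        anchor = int(rng_meth.integers(1000, chrom_sizes[c] - 5000)) // 2 * 2
        gaps = rng_meth.integers(20, 60, size=pc.n_cpgs - 1) * 2
        run = anchor + np.concatenate(([0], np.cumsum(gaps)))
        pos_by_chrom[c] = np.unique(np.concatenate([pos_by_chrom[c], run]))
        cluster_truth.append(
            {
                "cluster_id": f"pc{ci + 1}",
                "chrom": c,
                "start": int(run[0]),
                "end": int(run[-1]) + 2,
                "trait": pc.trait,
                "delta": pc.delta,
                "positions": [int(p) for p in run],
            }
        )

    site_tables = {
        c: pd.DataFrame({"chrom": c, "pos": pos_by_chrom[c]}) for c in chroms
    }
    sites = pd.concat(site_tables.values(), ignore_index=True)
    n_sites = len(sites)
    pos_index = {
        (r.chrom, int(r.pos)): i for i, r in enumerate(sites.itertuples(index=False))
    }

    # ----- variable-site mask ----------------------------------------------
    variable = rng_meth.random(n_sites) < config.frac_variable_cpg
    for ct in cluster_truth:
        for p in ct["positions"]:
            variable[pos_index[(ct["chrom"], p)]] = True

    # planted module genes -> their promoter CpGs forced variable
    genes = ann["genes"]
    promoters = derive_promoters(genes, chrom_sizes)
    gene_pool = list(genes["gene_id"])
    rng_mod.shuffle(gene_pool)
    module_truth = []
    taken = 0
    for pm in config.planted_modules:
        chosen = gene_pool[taken : taken + pm.n_genes]
        taken += pm.n_genes
        intervals = promoters[promoters["label"].isin([f"promoter:{g}" for g in chosen])]
        member_sites: list[int] = []
        for iv in intervals.itertuples(index=False):
            pos = pos_by_chrom[iv.chrom]
            lo, hi = np.searchsorted(pos, [iv.start, iv.end])
            base = sum(len(pos_by_chrom[c]) for c in chroms if c < iv.chrom)
            member_sites.extend(range(base + lo, base + hi))
        variable[member_sites] = True
        module_truth.append(
            {
                "name": pm.name,
                "genes": chosen,
                "trait_effects": pm.trait_effects,
                "n_member_cpgs": len(member_sites),
                "member_sites": member_sites,
            }
        )

    # ----- liabilities and targets for variable sites ----------------------
    var_pos_by_chrom = {}
    var_idx = np.flatnonzero(variable)
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    for c in chroms:
        sel = var_idx[chrom_arr[var_idx] == c]
        var_pos_by_chrom[c] = pos_arr[sel].astype(float)
    n_ind = len(sample_ids)
    L = simulate_liabilities(
        rng_meth, var_pos_by_chrom, A_samples, config.heritable_fraction,
        config.decay_length_bp,
    )
    # map global variable-site order -> column of L (chrom-major, like var_idx)
    col_of_site = {int(s): k for k, s in enumerate(var_idx)}

    module_factors: dict[str, np.ndarray] = {}
    for pm, mt in zip(config.planted_modules, module_truth):
        f = rng_mod.standard_normal(n_ind)
        module_factors[pm.name] = f
        cols = [col_of_site[s] for s in mt["member_sites"]]
        w = pm.factor_weight
        L[:, cols] = w * f[:, None] + np.sqrt(1 - w * w) * L[:, cols]
        del mt["member_sites"]  # too bulky for the manifest

    target_var = liabilities_to_targets(L, config, rng_meth)

    # ----- traits -----------------------------------------------------------
    traits = simulate_traits(config, module_factors, sample_ids, rng_trait)

    # ----- cluster planting (hypermethylation in the low-trait group) ------
    good_rows = [sample_ids.index(s) for s in good_ids]
    for ct in cluster_truth:
        tv = traits.set_index("id").loc[good_ids, ct["trait"]].to_numpy()
        order = np.argsort(tv, kind="stable")[: config.extreme_k]
        case_rows = [good_rows[i] for i in order]
        cols = [col_of_site[pos_index[(ct["chrom"], p)]] for p in ct["positions"]]
        target_var[np.ix_(case_rows, cols)] = np.clip(
            target_var[np.ix_(case_rows, cols)] + ct["delta"], 0.005, 0.995
        )

    # ----- full target matrix ----------------------------------------------
    # set the non-variable base level so the POOLED global CpG methylation
    # matches global_meth_mean despite the lower-mean variable fraction
    var_mean = float(np.dot(config.state_freqs, config.state_levels))
    frac_var = float(variable.mean())
    nonvar_mean = np.clip(
        (config.global_meth_mean - frac_var * var_mean) / max(1.0 - frac_var, 1e-9),
        0.55, 0.97,
    )
    base_nonvar = np.clip(
        rng_meth.normal(nonvar_mean, config.global_meth_sd, size=n_sites),
        0.5, 0.99,
    )
    target = np.tile(base_nonvar, (n_ind, 1))
    target[:, var_idx] = target_var
    for cid in corrupted_ids:
        r = sample_ids.index(cid)
        target[r] = corrupt_targets(target[r], config.corruption_failed_fraction)

    cov, meth = draw_counts(
        rng_counts, target, config.mean_coverage, config.coverage_dispersion
    )

    # ----- non-CpG sites ----------------------------------------------------
    n_ncpg = config.n_chg + config.n_chh
    ncpg_pos = np.sort(
        rng_ncpg.choice(chrom_sizes[chroms[0]] // 2 - 1, size=n_ncpg, replace=False) * 2 + 1
    )
    ncpg_ctx = np.array(["CHG"] * config.n_chg + ["CHH"] * config.n_chh)
    rng_ncpg.shuffle(ncpg_ctx)
    ncpg_target = np.full((n_ind, n_ncpg), config.noncpg_level)
    for cid in corrupted_ids:
        r = sample_ids.index(cid)
        ncpg_target[r] = corrupt_targets(ncpg_target[r], config.corruption_failed_fraction)
    ncpg_cov, ncpg_meth = draw_counts(
        rng_ncpg, ncpg_target, config.mean_coverage, config.coverage_dispersion
    )

    # ----- spike-in controls ------------------------------------------------
    nc = config.n_control_sites
    ctrl_pos = np.arange(nc) * 20 + 10
    err = config.conversion_error
    ctrl_targets = {}
    for sid in sample_ids:
        e = err
        if sid in corrupted_ids:
            e = corrupt_targets(np.array([err]), config.corruption_failed_fraction)[0]
        ctrl_targets[sid] = (1.0 - err, e)  # (pUC19-like, lambda-like)

    # ----- genotypes --------------------------------------------------------
    freqs = rng_snp.uniform(0.05, 0.5, size=config.n_snp)
    alleles = _gene_drop(ped, freqs, rng_snp)
    cluster_pos = {(ct["chrom"], p) for ct in cluster_truth for p in ct["positions"]}
    cpg_sets = {c: set(int(x) for x in pos_by_chrom[c]) for c in chroms}
    candidates = [
        int(i) for i in var_idx if (chrom_arr[i], int(pos_arr[i])) not in cluster_pos
    ]
    cpg_cols = rng_snp.choice(
        candidates, size=config.n_snp_on_cpg_transitions, replace=False
    )
    snp_rows = []
    for k in range(config.n_snp):
        if k < config.n_snp_on_cpg_transitions:
            i = int(cpg_cols[k])
            snp_rows.append({"chrom": chrom_arr[i], "pos": int(pos_arr[i]), "ref": "C", "alt": "T"})
        else:
            c = chroms[int(rng_snp.integers(0, len(chroms)))]
            cpg_set = cpg_sets[c]
            while True:
                p = int(rng_snp.integers(0, chrom_sizes[c] - 2))
                # keep clear of both positions of every CpG dyad
                if p not in cpg_set and (p - 1) not in cpg_set:
                    break
            if rng_snp.random() < 0.5:
                ref, alt = ("A", "G") if rng_snp.random() < 0.5 else ("G", "A")
            else:
                ref, alt = ("C", "G") if rng_snp.random() < 0.5 else ("A", "T")
            snp_rows.append({"chrom": c, "pos": p, "ref": ref, "alt": alt})
    snp_sites = pd.DataFrame(snp_rows)
    order = np.lexsort((snp_sites["pos"], snp_sites["chrom"]))
    snp_sites = snp_sites.iloc[order].reset_index(drop=True)
    geno = np.stack([alleles[s].sum(axis=0) for s in sample_ids], axis=1)  # snp x ind
    geno = geno[order]
    # a couple of indel rows exercise the transition reader's filters
    indels = pd.DataFrame(
        [
            {"chrom": chroms[0], "pos": 11, "ref": "AT", "alt": "A"},
            {"chrom": chroms[0], "pos": 31, "ref": "C", "alt": "CAG"},
        ]
    )

    # ----- write everything -------------------------------------------------
    files: dict[str, str] = {}
    for r, sid in enumerate(sample_ids):
        tab = pd.DataFrame(
            {
                "chrom": chrom_arr,
                "pos": pos_arr,
                "count_meth": meth[r],
                "count_unmeth": cov[r] - meth[r],
            }
        )
        path = outdir / f"{sid}.cov"
        write_bismark_cov(tab, path)
        files[f"cov:{sid}"] = path.name

        pm_, pu_ = ctrl_targets[sid]
        ctrl_target = np.vstack([np.full(nc, pm_), np.full(nc, pu_)])
        c_cov, c_meth = draw_counts(
            rng_ctrl, ctrl_target, config.mean_coverage, config.coverage_dispersion
        )
        ctrl = pd.DataFrame(
            {
                "chrom": ["pUC19_control"] * nc + ["lambda_control"] * nc,
                "pos": np.concatenate([ctrl_pos, ctrl_pos]),
                "count_meth": np.concatenate([c_meth[0], c_meth[1]]),
                "count_unmeth": np.concatenate([c_cov[0] - c_meth[0], c_cov[1] - c_meth[1]]),
            }
        )
        cpath = outdir / f"{sid}.controls.cov"
        write_bismark_cov(ctrl, cpath)
        files[f"controls:{sid}"] = cpath.name

        ncpg = pd.DataFrame(
            {
                "chrom": chroms[0],
                "pos": ncpg_pos,
                "strand": "+",
                "count_meth": ncpg_meth[r],
                "count_unmeth": ncpg_cov[r] - ncpg_meth[r],
                "context": ncpg_ctx,
            }
        )
        npath = outdir / f"{sid}.nonCpG.CX_report.txt"
        write_cytosine_report(ncpg, npath)
        files[f"noncpg:{sid}"] = npath.name

    _write_gff(ann["genes"], ann["exons"], outdir / "annotation.gff3")
    _write_fasta(ann["sequences"], outdir / "genome.fa")
    vcf_sites = pd.concat([snp_sites, indels], ignore_index=True)
    vcf_order = np.lexsort((vcf_sites["pos"], vcf_sites["chrom"]))
    vcf_sites = vcf_sites.iloc[vcf_order].reset_index(drop=True)
    vcf_geno = np.vstack([geno, np.zeros((2, n_ind), dtype=int)])[vcf_order]
    _write_vcf(vcf_sites, vcf_geno, sample_ids, chrom_sizes, outdir / "variants.vcf")
    ped.to_csv(outdir / "pedigree.csv", index=False)
    traits.to_csv(outdir / "phenotypes.csv", index=False, float_format="%.6f")
    write_relationship_csv(A_full, outdir / "amat.csv")
    site_truth = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "pos": pos_arr,
            "variable": variable.astype(int),
            "cluster_id": "",
        }
    )
    for ct in cluster_truth:
        for p in ct["positions"]:
            site_truth.loc[pos_index[(ct["chrom"], p)], "cluster_id"] = ct["cluster_id"]
    site_truth.to_csv(outdir / "site_truth.csv", index=False)

    transition_truth = [
        [str(snp_sites.loc[k, "chrom"]), int(snp_sites.loc[k, "pos"])]
        for k in range(len(snp_sites))
        if (snp_sites.loc[k, "ref"], snp_sites.loc[k, "alt"])
        in {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    ]
    manifest = {
        "config": _config_dict(config),
        "files": {
            **files,
            "gff": "annotation.gff3",
            "fasta": "genome.fa",
            "vcf": "variants.vcf",
            "pedigree": "pedigree.csv",
            "phenotypes": "phenotypes.csv",
            "amat": "amat.csv",
            "site_truth": "site_truth.csv",
        },
        "chrom_sizes": chrom_sizes,
        "samples": sample_ids,
        "good_samples": good_ids,
        "corrupted_samples": corrupted_ids,
        "n_sites": int(n_sites),
        "n_variable_sites": int(variable.sum()),
        "n_islands_planted": int(len(ann["islands"])),
        "islands": ann["islands"][["chrom", "start", "end"]].to_dict("records"),
        "planted_modules": module_truth,
        "planted_clusters": cluster_truth,
        "transition_snps_on_cpg": [
            [str(chrom_arr[i]), int(pos_arr[i])] for i in cpg_cols
        ],
        "n_transition_snps_total": len(transition_truth),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["planted_modules"] = [asdict(pm) if not isinstance(pm, dict) else pm for pm in config.planted_modules]
    d["planted_clusters"] = [asdict(pc) if not isinstance(pc, dict) else pc for pc in config.planted_clusters]
    d["state_freqs"] = list(config.state_freqs)
    d["state_levels"] = list(config.state_levels)
    return d
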