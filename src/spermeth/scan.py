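"""Annotation-free CpG-cluster association scan.

Clusters are maximal runs of at least five qualifying CpGs (methSD > 0.1,
coverage >= 10x) with at most 150 bp between consecutive members.  Cases and
controls are the 20 lowest and 20 highest trait values; each cluster's
coverage-weighted mean methylation is compared between groups with Welch's
t-test, followed by Benjamini-Hochberg adjustment and a Bonferroni-corrected
5% significance flag.  Hits are annotated with genes within a 50 kb flank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MethMatrix, ValidationError
from .qc import select_variable_cpgs


# ---------------------------------------------------------------------------
# Cluster formation
# ---------------------------------------------------------------------------

def form_clusters(
    matrix: MethMatrix,
    max_gap: int = 150,
    min_size: int = 5,
    methsd_min: float = 0.1,
    coverage_min: int = 10,
) -> pd.DataFrame:
    """Maximal runs of qualifying CpGs with adjacent-pair gap <= ``max_gap``.

    Loci are first filtered to methSD > ``methsd_min`` and per-individual
    coverage >= ``coverage_min`` (full call rate); runs shorter than
    ``min_size`` are discarded.  Returns one row per cluster with chrom,
    start, end (half-open span), n_cpgs and member locus indices into the
    filtered matrix (column ``member_idx``).
    """
    filt = select_variable_cpgs(
        matrix, methsd_min=methsd_min, coverage_min=coverage_min
    )
    rows = []
    chroms = filt.loci["chrom"].to_numpy()
    pos = filt.loci["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        p = pos[idx]
        order = np.argsort(p)
        idx, p = idx[order], p[order]
        if len(p) == 0:
            continue
        breaks = np.flatnonzero(np.diff(p) > max_gap)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks + 1, [len(p)]))
        for a, b in zip(run_starts, run_ends):
            if b - a >= min_size:
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(p[a]),
                        "end": int(p[b - 1]) + 2,  # cover the final CpG dyad
                        "n_cpgs": int(b - a),
                        "member_idx": idx[a:b].tolist(),
                    }
                )
    clusters = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpgs", "member_idx"])
    clusters.attrs["filtered_matrix"] = filt
    return clusters


def cluster_methylation(filt: MethMatrix, clusters: pd.DataFrame) -> np.ndarray:
    """Per-individual coverage-weighted mean methylation per cluster."""
    out = np.empty((filt.n_individuals, len(clusters)))
    M_counts = filt.P * filt.C
    for j, members in enumerate(clusters["member_idx"]):
        cov = filt.C[:, members].sum(axis=1)
        out[:, j] = M_counts[:, members].sum(axis=1) / cov
    return out


# ---------------------------------------------------------------------------
# Case/control split and testing
# ---------------------------------------------------------------------------

def split_extremes(
    traits: pd.DataFrame, trait_name: str, k: int = 20
) -> tuple[list[str], list[str]]:
    """Ids of the k lowest (cases) and k highest (controls) trait values.

    Boundary ties are broken by stable id order; a fully tied trait still
    yields a deterministic split, with a warning.
    """
    sub = traits[["id", trait_name]].dropna()
    if len(sub) < 2 * k:
        raise ValidationError(
            f"need at least {2 * k} individuals with {trait_name}, have {len(sub)}"
        )
    sub = sub.sort_values([trait_name, "id"], kind="stable")
    vals = sub[trait_name].to_numpy()
    if np.all(vals == vals[0]):
        warnings.warn(f"{trait_name}: all values tied; extreme split is arbitrary")
    cases = sub["id"].iloc[:k].tolist()
    controls = sub["id"].iloc[-k:].tolist()
    return cases, controls


def welch_test(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t-test: (t, df, two-sided p).

    t = (mean_x - mean_y) / sqrt(s_x^2/n_x + s_y^2/n_y) with the
    Welch-Satterthwaite degrees of freedom.  Degenerate inputs: both groups
    constant and equal means -> p = 1; constant with unequal means -> p = 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("Welch test needs >= 2 values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    dmean = x.mean() - y.mean()
    if vx == 0 and vy == 0:
        if dmean == 0:
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return float(np.inf) * np.sign(dmean), float(len(x) + len(y) - 2), 0.0
    se2 = vx / len(x) + vy / len(y)
    t = dmean / np.sqrt(se2)
    df = se2**2 / (
        (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def adjust_pvalues(pvals, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg adjusted p-values plus a Bonferroni flag.

    BH values are the monotone step-up adjustments capped at 1; the
    Bonferroni flag marks raw p < alpha / m.
    """
    p = np.asarray(pvals, float)
    if len(p) == 0:
        return pd.DataFrame(columns=["p", "p_bh", "bonferroni_significant"])
    from statsmodels.stats.multitest import multipletests

    _, p_bh, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {"p": p, "p_bh": p_bh, "bonferroni_significant": p < alpha / len(p)}
    )


def run_scan(
    matrix: MethMatrix,
    traits: pd.DataFrame,
    trait_name: str,
    k: int = 20,
    alpha: float = 0.05,
    max_gap: int = 150,
    min_size: int = 5,
    methsd_min: float = 0.1,
    coverage_min: int = 10,
    methsd_on_extremes: bool = True,
) -> pd.DataFrame:
    """End-to-end case-control scan for one trait.

    Clusters are formed on the case-union-control submatrix (methSD
    recomputed on those 2k individuals unless ``methsd_on_extremes`` is
    False, in which case clusters come from the full cohort).  Direction
    labels methylation in cases (the low-trait group): "hyper_in_cases"
    means more methylated at low trait values.
    """
    cases, controls = split_extremes(traits, trait_name, k)
    sub = matrix.subset_individuals(cases + controls)
    source = sub if methsd_on_extremes else matrix
    clusters = form_clusters(
        source,
        max_gap=max_gap,
        min_size=min_size,
        methsd_min=methsd_min,
        coverage_min=coverage_min,
    )
    if len(clusters) == 0:
        warnings.warn(f"{trait_name}: no clusters formed")
        return pd.DataFrame(
            columns=[
                "chrom", "start", "end", "n_cpgs", "mean_cases", "mean_controls",
                "t", "df", "p", "p_bh", "bonferroni_significant", "direction",
            ]
        )
    filt: MethMatrix = clusters.attrs["filtered_matrix"]
    if not methsd_on_extremes:
        filt = filt.subset_individuals(cases + controls)
    V = cluster_methylation(filt, clusters)
    case_rows = [filt.ids.index(i) for i in cases]
    ctrl_rows = [filt.ids.index(i) for i in controls]
    out_rows = []
    for j in range(len(clusters)):
        t, df, p = welch_test(V[case_rows, j], V[ctrl_rows, j])
        out_rows.append((t, df, p, V[case_rows, j].mean(), V[ctrl_rows, j].mean()))
    res = clusters[["chrom", "start", "end", "n_cpgs"]].copy()
    res["mean_cases"] = [r[3] for r in out_rows]
    res["mean_controls"] = [r[4] for r in out_rows]
    res["t"] = [r[0] for r in out_rows]
    res["df"] = [r[1] for r in out_rows]
    res["p"] = [r[2] for r in out_rows]
    adj = adjust_pvalues(res["p"].to_numpy(), alpha=alpha)
    res["p_bh"] = adj["p_bh"].to_numpy()
    res["bonferroni_significant"] = adj["bonferroni_significant"].to_numpy()
    res["direction"] = np.where(
        res["mean_cases"] >= res["mean_controls"], "hyper_in_cases", "hypo_in_cases"
    )
    res.attrs["cases"] = cases
    res.attrs["controls"] = controls
    return res


def annotate_hits(
    hits: pd.DataFrame, genes: pd.DataFrame, flank: int = 50_000
) -> pd.DataFrame:
    """Genes overlapping each hit's span +/- ``flank`` bp, with distances.

    Distance is 0 for genes overlapping the span itself, else the gap
    between gene and span.  Returns one row per (hit, gene) pair.
    """
    rows = []
    for h in hits.itertuples(index=False):
        lo, hi = h.start - flank, h.end + flank
        sub = genes[
            (genes["chrom"] == h.chrom) & (genes["end"] > lo) & (genes["start"] < hi)
        ]
        for g in sub.itertuples(index=False):
            if g.end <= h.start:
                dist = h.start - g.end
            elif g.start >= h.end:
                dist = g.start - h.end
            else:
                dist = 0
            rows.append(
                {
                    "chrom": h.chrom,
                    "start": h.start,
                    "end": h.end,
                    "gene_id": g.gene_id,
                    "gene_start": g.start,
                    "gene_end": g.end,
                    "distance": int(dist),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "gene_id", "gene_start", "gene_end", "distance"],
    )
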