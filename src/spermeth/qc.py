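"""Sample- and site-level quality control and the variable-CpG filter.

Sample QC rests on the two spike-in control genomes sequenced with every
library: a fully CpG-methylated control (pUC19-like) whose apparent
methylation estimates protection of methylated cytosines, and a fully
unmethylated control (lambda-like) whose apparent methylation estimates the
conversion error rate.  A failed conversion shows up as artificial
hypermethylation both in the unmethylated control and genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MethMatrix, SpermethError, ValidationError


# ---------------------------------------------------------------------------
# Sample-level QC
# ---------------------------------------------------------------------------

def _pooled_level(records: pd.DataFrame) -> float | None:
    cov = float(records["count_meth"].sum() + records["count_unmeth"].sum())
    if cov == 0:
        return None
    return float(records["count_meth"].sum()) / cov


def conversion_qc(
    sample_id: str,
    methylated_control: pd.DataFrame,
    unmethylated_control: pd.DataFrame,
    max_conversion_error: float = 0.02,
    min_protection: float = 0.95,
) -> dict:
    """Score one sample's spike-in controls.

    The unmethylated control's pooled methylation is the conversion-error
    estimate; the methylated control's pooled methylation the protection
    estimate.  A sample fails when error > ``max_conversion_error`` or
    protection < ``min_protection``; zero control coverage fails with
    reason "no control signal".
    """
    err = _pooled_level(unmethylated_control)
    prot = _pooled_level(methylated_control)
    if err is None or prot is None:
        return {
            "id": sample_id,
            "conversion_error": np.nan,
            "protection": np.nan,
            "qc_pass": False,
            "reason": "no control signal",
        }
    ok = err <= max_conversion_error and prot >= min_protection
    reason = ""
    if err > max_conversion_error:
        reason = f"conversion error {err:.4f} > {max_conversion_error}"
    elif prot < min_protection:
        reason = f"protection {prot:.4f} < {min_protection}"
    return {
        "id": sample_id,
        "conversion_error": err,
        "protection": prot,
        "qc_pass": bool(ok),
        "reason": reason,
    }


def global_context_levels(records: pd.DataFrame) -> dict[str, float | None]:
    """Pooled methylation proportion per cytosine context (CpG/CHG/CHH).

    A context with no sites is reported as None (undefined), never as 0.
    """
    out: dict[str, float | None] = {}
    for ctx in ("CpG", "CHG", "CHH"):
        sub = records[records["context"] == ctx]
        out[ctx] = _pooled_level(sub) if len(sub) else None
    return out


def detect_outlier_samples(
    reports: pd.DataFrame, k_mad: float = 5.0
) -> pd.DataFrame:
    """Flag samples failing conversion QC or with outlying global CpG levels.

    A sample is excluded when its control QC failed, or when its global CpG
    methylation lies more than ``k_mad`` median-absolute-deviations from the
    cohort median.  Expects columns id, cpg_pct, qc_pass, reason.  Raises if
    every sample would be excluded.
    """
    if len(reports) < 3:
        raise ValidationError("outlier detection needs at least 3 samples")
    x = reports["cpg_pct"].to_numpy(float)
    med = np.nanmedian(x)
    mad = np.nanmedian(np.abs(x - med))
    rows = []
    for r in reports.itertuples(index=False):
        reason = None
        if not r.qc_pass:
            reason = f"control QC failed: {r.reason}"
        elif mad > 0 and abs(r.cpg_pct - med) > k_mad * mad:
            reason = (
                f"global CpG {r.cpg_pct:.2f}% beyond {k_mad} MAD of cohort median {med:.2f}%"
            )
        if reason:
            rows.append({"id": r.id, "reason": reason})
    excluded = pd.DataFrame(rows, columns=["id", "reason"])
    if len(excluded) == len(reports):
        raise SpermethError("all samples excluded by QC")
    return excluded


def build_sample_qc(
    sample_tables: dict[str, pd.DataFrame],
    control_tables: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    max_conversion_error: float = 0.02,
    min_protection: float = 0.95,
) -> pd.DataFrame:
    """Assemble the per-sample QC report (context levels + control QC)."""
    rows = []
    for sid, tab in sample_tables.items():
        levels = global_context_levels(tab)
        meth_ctrl, unmeth_ctrl = control_tables.get(
            sid, (tab.iloc[0:0], tab.iloc[0:0])
        )
        conv = conversion_qc(
            sid, meth_ctrl, unmeth_ctrl, max_conversion_error, min_protection
        )
        rows.append(
            {
                "id": sid,
                "cpg_pct": 100.0 * levels["CpG"] if levels["CpG"] is not None else np.nan,
                "chg_pct": 100.0 * levels["CHG"] if levels["CHG"] is not None else np.nan,
                "chh_pct": 100.0 * levels["CHH"] if levels["CHH"] is not None else np.nan,
                "conversion_error": conv["conversion_error"],
                "protection": conv["protection"],
                "qc_pass": conv["qc_pass"],
                "reason": conv["reason"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Site-level filters
# ---------------------------------------------------------------------------

def exclude_snp_cpgs(
    matrix: MethMatrix, transition_sites: set[tuple[str, int]]
) -> tuple[MethMatrix, int]:
    """Drop CpG loci whose C or G position carries a transition SNP.

    Loci are recorded at the C position p of the CpG dyad; the G of the
    reverse strand sits at p+1, so both coordinates are checked.  Returns the
    filtered matrix and the number of loci removed.
    """
    chroms = matrix.loci["chrom"].to_numpy()
    pos = matrix.loci["pos"].to_numpy()
    hit = np.fromiter(
        (
            (c, int(p)) in transition_sites or (c, int(p) + 1) in transition_sites
            for c, p in zip(chroms, pos)
        ),
        dtype=bool,
        count=len(pos),
    )
    return matrix.subset_loci(~hit), int(hit.sum())


def select_variable_cpgs(
    matrix: MethMatrix,
    methsd_min: float = 0.1,
    coverage_min: int = 10,
    per_individual_coverage: bool = True,
) -> MethMatrix:
    """Keep high-quality variable CpGs.

    Criteria: across-individual SD of methylation proportions (methSD,
    sample SD) > ``methsd_min``; coverage >= ``coverage_min`` — by default in
    every individual (the strict reading; set
    ``per_individual_coverage=False`` for a mean-coverage reading); and 100%
    call rate.  An empty result is returned (with no error) when nothing
    survives.
    """
    full_call = (matrix.C > 0).all(axis=0)
    if per_individual_coverage:
        cov_ok = (matrix.C >= coverage_min).all(axis=0)
    else:
        cov_ok = matrix.C.mean(axis=0) >= coverage_min
    sd = matrix.methsd(ddof=1)
    with np.errstate(invalid="ignore"):
        sd_ok = np.nan_to_num(sd, nan=0.0) > methsd_min
    return matrix.subset_loci(full_call & cov_ok & sd_ok)


def classify_states(proportions) -> np.ndarray:
    """Trimodal epiallele state per proportion: thirds of the [0,1] range.

    hypo if p < 1/3, semi if 1/3 <= p <= 2/3 (closed middle interval),
    hyper if p > 2/3.
    """
    p = np.asarray(proportions, float)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValidationError("proportions must lie in [0, 1]")
    out = np.where(p < 1.0 / 3.0, "hypo", np.where(p > 2.0 / 3.0, "hyper", "semi"))
    return np.where(np.isnan(p), "undefined", out)


# ---------------------------------------------------------------------------
# Phenotype cleaning
# ---------------------------------------------------------------------------

def clean_phenotypes(
    traits: pd.DataFrame, rules: dict[str, dict]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Winsorize out-of-bound trait values; log every change.

    ``rules`` maps trait name to ``{"upper": bound, "replace_upper": value}``
    and/or ``{"lower": ..., "replace_lower": ...}``; a missing replacement
    defaults to the bound itself.  Returns the cleaned table and a change log
    with one row per modified cell.
    """
    out = traits.copy()
    log_rows = []
    for trait, rule in rules.items():
        if trait not in out.columns:
            continue
        col = out[trait]
        if "upper" in rule:
            repl = rule.get("replace_upper", rule["upper"])
            mask = col > rule["upper"]
            for idx in out.index[mask.fillna(False)]:
                log_rows.append(
                    {
                        "id": out.loc[idx, "id"],
                        "trait": trait,
                        "old": col.loc[idx],
                        "new": repl,
                        "rule": f"> {rule['upper']}",
                    }
                )
            out.loc[mask.fillna(False), trait] = repl
        if "lower" in rule:
            repl = rule.get("replace_lower", rule["lower"])
            mask = out[trait] < rule["lower"]
            for idx in out.index[mask.fillna(False)]:
                log_rows.append(
                    {
                        "id": out.loc[idx, "id"],
                        "trait": trait,
                        "old": traits.loc[idx, trait],
                        "new": repl,
                        "rule": f"< {rule['lower']}",
                    }
                )
            out.loc[mask.fillna(False), trait] = repl
    log = pd.DataFrame(log_rows, columns=["id", "trait", "old", "new", "rule"])
    return out, log
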