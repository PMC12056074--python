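"""Readers and writers for every on-disk format the pipeline touches.

On-disk conventions: Bismark coverage and GFF3 are 1-based inclusive; VCF is
1-based; BED is 0-based half-open.  Everything returned to callers is 0-based
half-open.  The methylation-% column of coverage files is advisory and is
always recomputed from the counts.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    MISSING_PARENT,
    ParseError,
    SpermethError,
    ValidationError,
    validate_site_table,
)

_COV_COLS = ["chrom", "start", "end", "pct", "count_meth", "count_unmeth"]
_CX_COLS = ["chrom", "start", "strand", "count_meth", "count_unmeth", "context", "tri"]


# ---------------------------------------------------------------------------
# Bismark site-level files
# ---------------------------------------------------------------------------

def read_bismark_cov(
    path,
    dialect: str = "cov",
    default_context: str = "CpG",
    default_strand: str = "unknown",
) -> pd.DataFrame:
    """Read a Bismark site-level file into a validated site table.

    Parameters
    ----------
    dialect:
        ``"cov"`` for the coverage dialect (chrom, 1-based start, end,
        methylation %, count methylated, count unmethylated) or
        ``"cytosine_report"`` for the per-cytosine report dialect which also
        carries strand and context columns.
    default_context, default_strand:
        Filled in for the coverage dialect, which records neither.

    Returns a DataFrame with columns chrom, pos (0-based), strand, context,
    count_meth, count_unmeth, proportion (NaN at zero coverage).
    """
    path = Path(path)
    if dialect == "cov":
        names, usecols = _COV_COLS, None
    elif dialect == "cytosine_report":
        names, usecols = _CX_COLS, list(range(7))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        raw = pd.read_csv(
            path, sep="\t", header=None, names=names, usecols=usecols, comment="#"
        )
    except Exception as exc:  # pandas raises several types; unify
        raise ParseError(f"{path}: {exc}") from exc
    if raw.empty:
        return validate_site_table(
            pd.DataFrame(
                columns=["chrom", "pos", "strand", "context", "count_meth", "count_unmeth"]
            ),
            name=str(path),
        )
    for col in ("start", "count_meth", "count_unmeth"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna()
        if bad.any() or vals.isna().any():
            line = int(np.flatnonzero((bad | vals.isna()).to_numpy())[0]) + 1
            raise ParseError(f"{path}: malformed row at line {line} (column {col})")
        raw[col] = vals.astype(np.int64)
    df = pd.DataFrame(
        {
            "chrom": raw["chrom"].astype(str),
            "pos": raw["start"] - 1,  # 1-based on disk
            "strand": raw["strand"].astype(str)
            if dialect == "cytosine_report"
            else default_strand,
            "context": raw["context"].astype(str)
            if dialect == "cytosine_report"
            else default_context,
            "count_meth": raw["count_meth"],
            "count_unmeth": raw["count_unmeth"],
        }
    )
    return validate_site_table(df, name=str(path))


def write_bismark_cov(records: pd.DataFrame, path) -> None:
    """Write a site table in the Bismark coverage dialect (1-based on disk).

    The % column is emitted to 6 significant digits; zero-coverage records
    write 0 there (the column is advisory on re-read).
    """
    path = Path(path)
    if len(records) == 0:
        path.write_text("")
        return
    m = records["count_meth"].to_numpy(np.int64)
    u = records["count_unmeth"].to_numpy(np.int64)
    if (m < 0).any() or (u < 0).any():
        raise ValidationError(f"{path}: negative counts")
    cov = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(cov > 0, 100.0 * m / np.maximum(cov, 1), 0.0)
    start = records["pos"].to_numpy(np.int64) + 1
    with open(path, "w") as fh:
        for c, s, p, mm, uu in zip(records["chrom"], start, pct, m, u):
            fh.write(f"{c}\t{s}\t{s}\t{p:.6g}\t{mm}\t{uu}\n")


def write_cytosine_report(records: pd.DataFrame, path) -> None:
    """Write a site table in the per-cytosine report dialect (keeps context)."""
    path = Path(path)
    with open(path, "w") as fh:
        for row in records.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.strand}\t{row.count_meth}"
                f"\t{row.count_unmeth}\t{row.context}\t...\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff_features(path):
    """Read genes and exons from a GFF3 file.

    Returns ``(genes, exons, report)``: genes as a DataFrame with chrom,
    start, end (0-based half-open), strand, gene_id; exons likewise with a
    ``gene_id`` linking to the parent gene.  Exons whose parent cannot be
    resolved are skipped with a warning and counted in the report.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene"):
        genes.append(
            {
                "chrom": g.seqid,
                "start": g.start - 1,
                "end": g.end,
                "strand": g.strand,
                "gene_id": g.id,
            }
        )
    gene_ids = {g["gene_id"] for g in genes}
    exons, skipped = [], 0
    for e in db.features_of_type("exon"):
        parents = [p for p in e.attributes.get("Parent", [])]
        parent = next((p for p in parents if p in gene_ids), None)
        if parent is None:
            # parent may be a transcript; walk up one level
            for p in parents:
                try:
                    anc = db[p]
                except gffutils.FeatureNotFoundError:
                    continue
                for q in anc.attributes.get("Parent", []):
                    if q in gene_ids:
                        parent = q
                        break
                if anc.id in gene_ids:
                    parent = anc.id
                if parent:
                    break
        if parent is None:
            skipped += 1
            continue
        exons.append(
            {
                "chrom": e.seqid,
                "start": e.start - 1,
                "end": e.end,
                "strand": e.strand,
                "gene_id": parent,
            }
        )
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} exon(s) without resolvable parent")
    genes_df = pd.DataFrame(genes, columns=["chrom", "start", "end", "strand", "gene_id"])
    exons_df = pd.DataFrame(exons, columns=["chrom", "start", "end", "strand", "gene_id"])
    report = {"n_genes": len(genes_df), "n_exons": len(exons_df), "n_exons_skipped": skipped}
    return genes_df, exons_df, report


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def read_vcf_transition_sites(path) -> set[tuple[str, int]]:
    """Positions (chrom, 0-based pos) of SNPs whose REF->ALT is a transition.

    Indels are ignored; multi-allelic rows are decomposed per ALT allele.
    """
    from cyvcf2 import VCF

    out: set[tuple[str, int]] = set()
    for v in VCF(str(path)):
        ref = v.REF.upper()
        if len(ref) != 1:
            continue
        for alt in v.ALT:
            alt = alt.upper()
            if len(alt) != 1 or alt not in "ACGT":
                continue
            if (ref, alt) in _TRANSITIONS:
                out.add((v.CHROM, v.POS - 1))
    return out


def read_vcf_genotypes(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read biallelic-SNP genotypes as a 0/1/2 alt-allele dosage matrix.

    Returns ``(geno, sites)``: geno is individuals x markers (NaN = missing),
    sites has chrom, pos (0-based), ref, alt.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows, sites = [], []
    for v in vcf:
        if len(v.REF) != 1 or len(v.ALT) != 1 or len(v.ALT[0]) != 1:
            continue
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = v.gt_types.astype(float)
        dose = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        rows.append(dose)
        sites.append({"chrom": v.CHROM, "pos": v.POS - 1, "ref": v.REF, "alt": v.ALT[0]})
    geno = pd.DataFrame(np.array(rows).T if rows else np.empty((len(ids), 0)), index=ids)
    return geno, pd.DataFrame(sites, columns=["chrom", "pos", "ref", "alt"])


# ---------------------------------------------------------------------------
# Pedigree and phenotypes
# ---------------------------------------------------------------------------

def toposort_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Return the pedigree reordered so parents precede offspring.

    Raises :class:`ValidationError` naming a cycle if one exists.
    """
    ids = list(ped["id"].astype(str))
    parents = {
        r.id: [p for p in (str(r.sire), str(r.dam)) if p != MISSING_PARENT]
        for r in ped.astype(str).itertuples(index=False)
    }
    known = set(ids)
    order: list[str] = []
    state: dict[str, int] = {}  # 0 = visiting, 1 = done

    def visit(node: str, stack: list[str]) -> None:
        if state.get(node) == 1:
            return
        if state.get(node) == 0:
            cycle = stack[stack.index(node):] + [node]
            raise ValidationError(f"pedigree cycle: {' -> '.join(cycle)}")
        state[node] = 0
        for p in parents.get(node, []):
            if p in known:
                visit(p, stack + [node])
        state[node] = 1
        order.append(node)

    for i in ids:
        visit(i, [])
    pos = {s: k for k, s in enumerate(order)}
    out = ped.copy()
    out["id"] = out["id"].astype(str)
    out["sire"] = out["sire"].astype(str)
    out["dam"] = out["dam"].astype(str)
    return out.sort_values("id", key=lambda s: s.map(pos), kind="stable").reset_index(
        drop=True
    )


def read_pedigree(path) -> pd.DataFrame:
    """Read a pedigree CSV (id, sire, dam; '0' = unknown parent).

    Output is validated (acyclic) and topologically sorted so that parents
    appear before their offspring.
    """
    ped = pd.read_csv(path, dtype=str).fillna(MISSING_PARENT)
    need = {"id", "sire", "dam"}
    if not need.issubset(ped.columns):
        raise ParseError(f"{path}: pedigree needs columns {sorted(need)}")
    if ped["id"].duplicated().any():
        dup = ped.loc[ped["id"].duplicated(), "id"].iloc[0]
        raise ValidationError(f"{path}: duplicate individual {dup}")
    return toposort_pedigree(ped)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype CSV: one ``id`` column plus named real-valued traits."""
    tab = pd.read_csv(path)
    if "id" not in tab.columns:
        raise ParseError(f"{path}: phenotype table needs an 'id' column")
    tab["id"] = tab["id"].astype(str)
    for col in tab.columns:
        if col == "id":
            continue
        tab[col] = pd.to_numeric(tab[col], errors="coerce")
    return tab


# ---------------------------------------------------------------------------
# BED + matrix output helpers
# ---------------------------------------------------------------------------

def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write intervals as BED6 (0-based half-open, as held in memory)."""
    with open(path, "w") as fh:
        for r in intervals.itertuples(index=False):
            name = getattr(r, "label", getattr(r, "gene_id", "."))
            strand = getattr(r, "strand", ".")
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{strand}\n")


def write_relationship_csv(rel, path) -> None:
    rel.to_frame().to_csv(path, index_label="id")


def read_relationship_csv(path, kind: str):
    from .core import RelationshipMatrix

    df = pd.read_csv(path, index_col=0)
    return RelationshipMatrix(ids=[str(i) for i in df.index], values=df.to_numpy(float), kind=kind)
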