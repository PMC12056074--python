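"""Core in-memory containers shared by every analysis stage.

All genomic coordinates held in memory are 0-based half-open.  Conversion to
and from the 1-based inclusive on-disk conventions (Bismark coverage, GFF3,
VCF) happens only inside :mod:`spermeth.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: reserved token for an unknown parent in pedigree files
MISSING_PARENT = "0"

#: closed vocabulary of genomic feature kinds
FEATURE_KINDS = frozenset(
    {
        "gene",
        "exon",
        "intron",
        "first_intron",
        "promoter",
        "intergenic",
        "cpg_island",
        "shore",
    }
)

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "count_meth", "count_unmeth"]


class SpermethError(Exception):
    """Base class for package errors."""


class ParseError(SpermethError):
    """A file could not be parsed; message names the offending line."""


class ValidationError(SpermethError):
    """Input violated a documented invariant."""


def validate_site_table(df: pd.DataFrame, *, name: str = "site table") -> pd.DataFrame:
    """Check a per-cytosine count table against the record invariants.

    Expects columns ``chrom, pos, strand, context, count_meth, count_unmeth``.
    Returns the table with an added float ``proportion`` column (NaN at zero
    coverage -- the undefined-proportion flag).
    """
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{name}: missing columns {missing}")
    neg = (df["count_meth"] < 0) | (df["count_unmeth"] < 0)
    if neg.any():
        i = int(np.flatnonzero(neg.to_numpy())[0])
        raise ValidationError(f"{name}: negative count at row {i}")
    cov = (df["count_meth"] + df["count_unmeth"]).to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(cov > 0, df["count_meth"].to_numpy(float) / cov, np.nan)
    out = df.copy()
    out["proportion"] = prop
    return out


@dataclass
class MethMatrix:
    """Individuals x loci methylation proportions with matching coverage.

    ``P`` holds proportions (NaN where the cell has zero coverage), ``C`` the
    integer coverage; ``loci`` is a DataFrame with at least ``chrom`` and
    ``pos`` (0-based C position of the CpG), sorted by (chrom, pos).
    """

    ids: list[str]
    loci: pd.DataFrame
    P: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        n, m = self.P.shape
        if len(self.ids) != n:
            raise ValidationError("MethMatrix: id count does not match P rows")
        if len(self.loci) != m:
            raise ValidationError("MethMatrix: locus count does not match P columns")
        if self.C.shape != self.P.shape:
            raise ValidationError("MethMatrix: C shape differs from P")

    # ---- shapes -----------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.P.shape[0]

    @property
    def n_loci(self) -> int:
        return self.P.shape[1]

    # ---- per-locus summaries ---------------------------------------------
    def methsd(self, ddof: int = 1) -> np.ndarray:
        """Across-individual standard deviation of proportions per locus."""
        with np.errstate(invalid="ignore"):
            return np.asarray(pd.DataFrame(self.P).std(axis=0, ddof=ddof))

    def locus_mean(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.P, axis=0)

    def call_rate(self) -> np.ndarray:
        """Fraction of individuals with coverage > 0 per locus."""
        return (self.C > 0).mean(axis=0)

    def min_coverage(self) -> np.ndarray:
        return self.C.min(axis=0)

    # ---- subsetting -------------------------------------------------------
    def subset_loci(self, mask: np.ndarray) -> "MethMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return MethMatrix(
            ids=self.ids,
            loci=self.loci.iloc[idx].reset_index(drop=True),
            P=self.P[:, idx],
            C=self.C[:, idx],
        )

    def subset_individuals(self, keep: list[str]) -> "MethMatrix":
        index = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in keep if s not in index]
        if missing:
            raise ValidationError(f"unknown individuals: {missing}")
        rows = [index[s] for s in keep]
        return MethMatrix(ids=list(keep), loci=self.loci, P=self.P[rows], C=self.C[rows])

    # ---- construction -----------------------------------------------------
    @classmethod
    def from_site_tables(
        cls, tables: dict[str, pd.DataFrame], context: str | None = "CpG"
    ) -> "MethMatrix":
        """Assemble a matrix from per-individual site tables.

        The locus set is the union over individuals; cells absent in an
        individual get coverage 0 / proportion NaN.
        """
        frames = []
        for sid, df in tables.items():
            d = df if context is None else df[df["context"] == context]
            frames.append(
                pd.DataFrame(
                    {
                        "sample": sid,
                        "chrom": d["chrom"].to_numpy(),
                        "pos": d["pos"].to_numpy(),
                        "m": d["count_meth"].to_numpy(),
                        "u": d["count_unmeth"].to_numpy(),
                    }
                )
            )
        cat = pd.concat(frames, ignore_index=True)
        ids = list(tables.keys())
        piv_m = cat.pivot_table(
            index="sample", columns=["chrom", "pos"], values="m", aggfunc="sum", fill_value=0
        ).reindex(ids)
        piv_u = cat.pivot_table(
            index="sample", columns=["chrom", "pos"], values="u", aggfunc="sum", fill_value=0
        ).reindex(ids)
        piv_u = piv_u.reindex(columns=piv_m.columns, fill_value=0)
        loci = pd.DataFrame(
            [(c, p) for c, p in piv_m.columns], columns=["chrom", "pos"]
        )
        order = np.lexsort((loci["pos"].to_numpy(), loci["chrom"].to_numpy()))
        loci = loci.iloc[order].reset_index(drop=True)
        M = piv_m.to_numpy(float)[:, order]
        U = piv_u.to_numpy(float)[:, order]
        C = (M + U).astype(np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(C > 0, M / np.maximum(C, 1), np.nan)
        return cls(ids=ids, loci=loci, P=P, C=C)


@dataclass
class RegionMethMatrix:
    """Individuals x regions aggregated methylation.

    ``V`` holds coverage-weighted (or unweighted) mean methylation per region
    per individual; ``COV`` the summed in-region coverage.  ``regions`` must
    carry chrom/start/end/feature_kind/label columns.
    """

    ids: list[str]
    regions: pd.DataFrame
    V: np.ndarray
    COV: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.V.shape[1]

    def region_sd(self, ddof: int = 1) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.asarray(pd.DataFrame(self.V).std(axis=0, ddof=ddof))

    def subset_regions(self, mask: np.ndarray) -> "RegionMethMatrix":
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else np.asarray(mask)
        return RegionMethMatrix(
            ids=self.ids,
            regions=self.regions.iloc[idx].reset_index(drop=True),
            V=self.V[:, idx],
            COV=self.COV[:, idx],
        )


@dataclass
class RelationshipMatrix:
    """Symmetric individuals x individuals similarity matrix."""

    ids: list[str]
    values: np.ndarray
    kind: str  # MRM | AMAT | GRM

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("RelationshipMatrix: shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("RelationshipMatrix: not symmetric")
        self.values = v

    def offdiag(self) -> np.ndarray:
        """Strictly-lower-triangle values in row-major order."""
        i, j = np.tril_indices(len(self.ids), k=-1)
        return self.values[i, j]

    def subset(self, keep: list[str]) -> "RelationshipMatrix":
        index = {s: i for i, s in enumerate(self.ids)}
        rows = [index[s] for s in keep]
        return RelationshipMatrix(
            ids=list(keep), values=self.values[np.ix_(rows, rows)], kind=self.kind
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)
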