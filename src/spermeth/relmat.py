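"""Epigenetic and genetic relationship matrices and their concordance.

The methylation relationship matrix (MRM) is (1/n) M Mᵀ on the standardized
individuals x variable-CpG matrix M; the additive relationship matrix A comes
from the pedigree by the tabular method; the genomic relationship matrix
(GRM) from marker dosages with per-marker variance standardization.
Concordance between two matrices is the Pearson correlation of their strictly
lower-triangular elements.

Standardization uses the sample (n-1) standard deviation; this scales the MRM
by a constant relative to the population-SD convention and leaves every
off-diagonal correlation statistic unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING_PARENT, RelationshipMatrix, ValidationError
from .io import toposort_pedigree


def standardize_methylation(P: np.ndarray, ddof: int = 1):
    """Column-wise z-scores of a complete proportion matrix.

    Returns ``(M, kept, dropped)`` where ``kept``/``dropped`` are column
    indices; zero-variance columns are dropped.  Requires >= 2 individuals
    and no missing cells.
    """
    P = np.asarray(P, float)
    if P.shape[0] < 2:
        raise ValidationError("standardization needs at least 2 individuals")
    if np.isnan(P).any():
        raise ValidationError("standardization requires a complete matrix")
    mu = P.mean(axis=0)
    sd = P.std(axis=0, ddof=ddof)
    kept = np.flatnonzero(sd > 0)
    dropped = np.flatnonzero(sd == 0)
    M = (P[:, kept] - mu[kept]) / sd[kept]
    return M, kept, dropped


def compute_mrm(M: np.ndarray, ids: list[str]) -> RelationshipMatrix:
    """MRM = (1/n) M Mᵀ for standardized M with n loci."""
    M = np.asarray(M, float)
    n = M.shape[1]
    if n == 0:
        raise ValidationError("MRM undefined with zero loci")
    V = (M @ M.T) / n
    V = (V + V.T) / 2.0
    return RelationshipMatrix(ids=list(ids), values=V, kind="MRM")


def compute_amat(ped: pd.DataFrame) -> RelationshipMatrix:
    """Additive (numerator) relationship matrix by the tabular method.

    a_ii = 1 + 0.5 a(sire, dam); a_ij = 0.5 (a(j, sire_i) + a(j, dam_i));
    unknown parents contribute 0.  The pedigree is topologically sorted
    internally; the returned matrix follows the input id order.
    """
    ped = ped.copy()
    ped["id"] = ped["id"].astype(str)
    input_order = list(ped["id"])
    ped = toposort_pedigree(ped)
    ids = list(ped["id"])
    idx = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    sire = [idx.get(s) if s != MISSING_PARENT else None for s in ped["sire"]]
    dam = [idx.get(d) if d != MISSING_PARENT else None for d in ped["dam"]]
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            val = 0.0
            if s is not None:
                val += 0.5 * A[j, s]
            if d is not None:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s is not None and d is not None) else 0.0)
    perm = [idx[s] for s in input_order]
    return RelationshipMatrix(ids=input_order, values=A[np.ix_(perm, perm)], kind="AMAT")


def compute_grm(
    geno: pd.DataFrame,
    maf_min: float = 0.20,
    callrate_min: float = 1.0,
    method: str = "per_marker",
) -> RelationshipMatrix:
    """Realized genomic relationship matrix from 0/1/2 dosages.

    Markers failing the minor-allele-frequency or call-rate filters are
    removed before computation.  ``method="per_marker"`` standardizes each
    marker by its own variance,
    G_ij = (1/m) Σ_k (x_ik - 2p_k)(x_jk - 2p_k) / (2 p_k (1-p_k));
    ``method="vanraden1"`` divides the cross-product by Σ_k 2 p_k (1-p_k).
    """
    X = geno.to_numpy(float)
    ids = [str(i) for i in geno.index]
    callrate = 1.0 - np.isnan(X).mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(X, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = (callrate >= callrate_min) & (maf >= maf_min)
    if callrate_min >= 1.0:
        keep &= ~np.isnan(X).any(axis=0)
    if not keep.any():
        raise ValidationError("no markers survive the MAF/call-rate filters")
    X = X[:, keep]
    p = p[keep]
    W = X - 2.0 * p
    denom = 2.0 * p * (1.0 - p)
    if method == "per_marker":
        G = (W / denom) @ W.T / W.shape[1]
    elif method == "vanraden1":
        G = W @ W.T / denom.sum()
    else:
        raise ValueError(f"unknown GRM method {method!r}")
    G = (G + G.T) / 2.0
    return RelationshipMatrix(ids=ids, values=G, kind="GRM")


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def kinship_classes(ped: pd.DataFrame) -> dict[tuple[str, str], str]:
    """Label each unordered pair by pedigree relation.

    Classes: parent-offspring, full-sib, half-sib, unrelated (anything else,
    including more distant relations).
    """
    ped = ped.astype(str)
    par = {r.id: (r.sire, r.dam) for r in ped.itertuples(index=False)}
    out = {}
    ids = list(par)
    for i, a in enumerate(ids):
        for b in ids[:i]:
            sa, da = par[a]
            sb, db = par[b]
            if a in (sb, db) or b in (sa, da):
                cls = "parent-offspring"
            elif sa != MISSING_PARENT and sa == sb and da != MISSING_PARENT and da == db:
                cls = "full-sib"
            elif (sa != MISSING_PARENT and sa == sb) != (da != MISSING_PARENT and da == db):
                cls = "half-sib"
            else:
                cls = "unrelated"
            out[(b, a)] = out[(a, b)] = cls
    return out


def offdiag_concordance(
    R1: RelationshipMatrix, R2: RelationshipMatrix, pedigree: pd.DataFrame | None = None
):
    """Pearson r between off-diagonal elements of two relationship matrices.

    Returns ``(r, table)``; the table pairs the strictly-lower-triangle
    elements and, when a pedigree is supplied, labels each pair with its
    kinship class.
    """
    if R1.ids != R2.ids:
        raise ValidationError("relationship matrices have different id orderings")
    i, j = np.tril_indices(len(R1.ids), k=-1)
    v1 = R1.values[i, j]
    v2 = R2.values[i, j]
    r = float(stats.pearsonr(v1, v2)[0]) if len(v1) > 1 else float("nan")
    table = pd.DataFrame(
        {
            "id_a": [R1.ids[a] for a in i],
            "id_b": [R1.ids[b] for b in j],
            R1.kind: v1,
            R2.kind: v2,
        }
    )
    if pedigree is not None:
        classes = kinship_classes(pedigree)
        table["kinship_class"] = [
            classes.get((a, b), "unrelated") for a, b in zip(table["id_a"], table["id_b"])
        ]
    return r, table
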