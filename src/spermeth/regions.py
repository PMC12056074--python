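"""Genomic region sets and region-level methylation aggregation.

Feature sets: promoters (1 kb upstream of the TSS, strand-aware), gene
bodies, exons, introns, first introns (nearest the TSS in transcription
order), intergenic complement, CpG islands (sliding-window GC / observed-vs-
expected CpG criteria) and island shores.  Region methylation is the
coverage-weighted mean over member CpGs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MethMatrix, RegionMethMatrix, ValidationError


def _as_regions(rows, kind) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "label"])
    df["feature_kind"] = kind
    return df[["chrom", "start", "end", "strand", "feature_kind", "label"]]


# ---------------------------------------------------------------------------
# Annotation-derived features
# ---------------------------------------------------------------------------

def derive_promoters(
    genes: pd.DataFrame, chrom_sizes: dict[str, int], upstream: int = 1000
) -> pd.DataFrame:
    """Promoter = up to ``upstream`` bp upstream of the TSS, strand-aware.

    For + genes this is [start - upstream, start); for - genes
    [end, end + upstream); truncated at chromosome bounds.
    """
    rows = []
    for g in genes.itertuples(index=False):
        size = chrom_sizes[g.chrom]
        if g.strand == "-":
            s, e = g.end, min(g.end + upstream, size)
        else:
            s, e = max(g.start - upstream, 0), g.start
        if e > s:
            rows.append((g.chrom, s, e, g.strand, f"promoter:{g.gene_id}"))
    return _as_regions(rows, "promoter")


def derive_gene_features(
    genes: pd.DataFrame, exons: pd.DataFrame, chrom_sizes: dict[str, int]
) -> dict[str, pd.DataFrame]:
    """Exons, introns, first introns, gene bodies and the intergenic complement.

    Introns are the gaps between consecutive exons of a gene; the first
    intron is the gap nearest the TSS in transcription order (the LAST gap in
    genomic order for a - strand gene).  Single-exon genes yield no intron.
    """
    gene_rows, exon_rows, intron_rows, first_rows = [], [], [], []
    by_gene = dict(tuple(exons.groupby("gene_id", sort=False)))
    for g in genes.itertuples(index=False):
        gene_rows.append((g.chrom, g.start, g.end, g.strand, g.gene_id))
        ex = by_gene.get(g.gene_id)
        if ex is None or len(ex) == 0:
            continue
        ex = ex.sort_values("start")
        for k, e in enumerate(ex.itertuples(index=False)):
            exon_rows.append((g.chrom, e.start, e.end, g.strand, f"{g.gene_id}:exon{k + 1}"))
        starts = ex["start"].to_numpy()
        ends = ex["end"].to_numpy()
        gaps = [
            (int(ends[k]), int(starts[k + 1]))
            for k in range(len(ex) - 1)
            if starts[k + 1] > ends[k]
        ]
        for k, (s, e) in enumerate(gaps):
            intron_rows.append((g.chrom, s, e, g.strand, f"{g.gene_id}:intron{k + 1}"))
        if gaps:
            first = gaps[-1] if g.strand == "-" else gaps[0]
            first_rows.append(
                (g.chrom, first[0], first[1], g.strand, f"{g.gene_id}:first_intron")
            )
    out = {
        "gene": _as_regions(gene_rows, "gene"),
        "exon": _as_regions(exon_rows, "exon"),
        "intron": _as_regions(intron_rows, "intron"),
        "first_intron": _as_regions(first_rows, "first_intron"),
    }
    out["intergenic"] = _intergenic(out["gene"], chrom_sizes)
    return out


def _intergenic(gene_regions: pd.DataFrame, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    rows = []
    for chrom, size in chrom_sizes.items():
        sub = gene_regions[gene_regions["chrom"] == chrom].sort_values("start")
        cursor, k = 0, 0
        for g in sub.itertuples(index=False):
            if g.start > cursor:
                k += 1
                rows.append((chrom, cursor, g.start, ".", f"{chrom}:intergenic{k}"))
            cursor = max(cursor, g.end)
        if cursor < size:
            k += 1
            rows.append((chrom, cursor, size, ".", f"{chrom}:intergenic{k}"))
    return _as_regions(rows, "intergenic")


# ---------------------------------------------------------------------------
# CpG islands and shores
# ---------------------------------------------------------------------------

def detect_cpg_islands(
    sequences: dict[str, str],
    window: int = 100,
    min_length: int = 200,
    min_gc: float = 0.5,
    min_obs_exp: float = 0.6,
) -> pd.DataFrame:
    """Sliding-window CpG island caller.

    A 100 bp step-1 window (the newcpgreport convention) qualifies when GC
    fraction >= ``min_gc`` and
    observed/expected CpG = (N_CG * L) / (N_C * N_G) >= ``min_obs_exp``
    (undefined when N_C * N_G = 0, which fails the window).  Overlapping
    qualifying windows are merged and the merged segment is trimmed to start
    at its first and end after its last CG dinucleotide; segments shorter
    than ``min_length`` are dropped.

    ``sequences`` maps chromosome name to sequence string; pass
    ``pyfaidx.Fasta`` records via ``str(...)`` or use
    :func:`detect_cpg_islands_fasta`.
    """
    rows = []
    for chrom in sequences:
        seq = str(sequences[chrom]).upper()
        L = len(seq)
        if L < window:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_c = (arr == ord("C")).astype(np.int64)
        is_g = (arr == ord("G")).astype(np.int64)
        is_cg = np.zeros(L, dtype=np.int64)
        is_cg[: L - 1] = is_c[: L - 1] & is_g[1:]
        cc = np.concatenate(([0], np.cumsum(is_c)))
        cg_ = np.concatenate(([0], np.cumsum(is_g)))
        ccg = np.concatenate(([0], np.cumsum(is_cg)))
        starts = np.arange(L - window + 1)
        n_c = cc[starts + window] - cc[starts]
        n_g = cg_[starts + window] - cg_[starts]
        # CG dinucleotides fully inside the window: start positions in
        # [start, start + window - 1)
        n_cg = ccg[starts + window - 1] - ccg[starts]
        gc_ok = (n_c + n_g) >= min_gc * window
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(n_c * n_g > 0, n_cg * window / np.maximum(n_c * n_g, 1), 0.0)
        ok = gc_ok & (oe >= min_obs_exp) & (n_cg > 0)
        if not ok.any():
            continue
        # merge overlapping qualifying windows
        idx = np.flatnonzero(ok)
        breaks = np.flatnonzero(np.diff(idx) > window)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [len(idx) - 1]))
        def window_ok(ws: int) -> bool:
            nc = cc[ws + window] - cc[ws]
            ng = cg_[ws + window] - cg_[ws]
            ncg = ccg[ws + window - 1] - ccg[ws]
            if ncg == 0 or nc * ng == 0:
                return False
            return (nc + ng) >= min_gc * window and (
                ncg * window / (nc * ng) >= min_obs_exp
            )

        k = 0
        for rs, re_ in zip(run_starts, run_ends):
            seg_s = int(idx[rs])
            seg_e = int(idx[re_]) + window
            # shrink each edge until its terminal window itself qualifies
            # (merging extends past the boundary by up to a window)
            while seg_e - seg_s >= window and not window_ok(seg_s):
                seg_s += 1
            while seg_e - seg_s >= window and not window_ok(seg_e - window):
                seg_e -= 1
            if seg_e - seg_s < window:
                continue
            # then trim to CG dinucleotide boundaries
            inside = np.flatnonzero(is_cg[seg_s:seg_e - 1])
            if len(inside) == 0:
                continue
            s = seg_s + int(inside[0])
            e = seg_s + int(inside[-1]) + 2
            if e - s >= min_length:
                k += 1
                rows.append((chrom, s, e, ".", f"{chrom}:island{k}"))
    return _as_regions(rows, "cpg_island")


def detect_cpg_islands_fasta(fasta_path, **kwargs) -> pd.DataFrame:
    """Run the island caller on a FASTA file (via pyfaidx)."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    return detect_cpg_islands(seqs, **kwargs)


def derive_shores(
    islands: pd.DataFrame, chrom_sizes: dict[str, int], width: int = 2000
) -> pd.DataFrame:
    """Island shores: ``width`` bp flanks on each side of every island.

    Flanks are clipped to chromosome bounds and any overlap with (any)
    island is subtracted, so shores never cover island sequence.
    """
    rows = []
    by_chrom = {c: g.sort_values("start") for c, g in islands.groupby("chrom")}
    k = 0
    for isl in islands.itertuples(index=False):
        size = chrom_sizes.get(isl.chrom)
        others = by_chrom[isl.chrom]
        for s, e in (
            (max(isl.start - width, 0), isl.start),
            (isl.end, min(isl.end + width, size if size is not None else isl.end + width)),
        ):
            segments = [(s, e)]
            for other in others.itertuples(index=False):
                segments = [
                    piece
                    for a, b in segments
                    for piece in _subtract((a, b), (other.start, other.end))
                ]
            for a, b in segments:
                if b > a:
                    k += 1
                    rows.append((isl.chrom, a, b, ".", f"{isl.chrom}:shore{k}"))
    return _as_regions(rows, "shore")


def _subtract(seg, cut):
    (a, b), (c, d) = seg, cut
    if d <= a or c >= b:
        return [(a, b)]
    out = []
    if c > a:
        out.append((a, c))
    if d < b:
        out.append((d, b))
    return out


# ---------------------------------------------------------------------------
# Region-level methylation
# ---------------------------------------------------------------------------

def aggregate_region_methylation(
    matrix: MethMatrix, regions: pd.DataFrame, weighted: bool = True
) -> RegionMethMatrix:
    """Aggregate CpG methylation per region per individual.

    Weighted (default): region value = Σ count_meth / Σ coverage over member
    CpGs, i.e. each CpG contributes in proportion to its coverage.
    Unweighted: plain mean of member proportions (defined cells only).
    Regions with no member CpGs get NaN values and zero coverage.
    """
    n_ind = matrix.n_individuals
    n_reg = len(regions)
    V = np.full((n_ind, n_reg), np.nan)
    COV = np.zeros((n_ind, n_reg), dtype=np.int64)
    M_counts = np.where(matrix.C > 0, matrix.P * matrix.C, 0.0)
    loci_chrom = matrix.loci["chrom"].to_numpy()
    loci_pos = matrix.loci["pos"].to_numpy()
    chrom_index: dict[str, np.ndarray] = {}
    for chrom in np.unique(loci_chrom):
        chrom_index[chrom] = np.flatnonzero(loci_chrom == chrom)
    for j, reg in enumerate(regions.itertuples(index=False)):
        idx = chrom_index.get(reg.chrom)
        if idx is None:
            continue
        pos = loci_pos[idx]
        lo = np.searchsorted(pos, reg.start, side="left")
        hi = np.searchsorted(pos, reg.end, side="left")
        members = idx[lo:hi]
        if len(members) == 0:
            continue
        cov = matrix.C[:, members].sum(axis=1)
        COV[:, j] = cov
        if weighted:
            meth = M_counts[:, members].sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                V[:, j] = np.where(cov > 0, meth / np.maximum(cov, 1), np.nan)
        else:
            with np.errstate(invalid="ignore"):
                V[:, j] = np.nanmean(matrix.P[:, members], axis=1)
    return RegionMethMatrix(ids=list(matrix.ids), regions=regions.reset_index(drop=True), V=V, COV=COV)


def filter_regions(
    rmm: RegionMethMatrix, methsd_min: float = 0.05, coverage_min: int = 10
) -> RegionMethMatrix:
    """Keep regions with methSD > ``methsd_min`` and per-individual summed
    in-region coverage >= ``coverage_min`` (and no undefined cells)."""
    sd = rmm.region_sd(ddof=1)
    with np.errstate(invalid="ignore"):
        keep = (
            (~np.isnan(rmm.V).any(axis=0))
            & (np.nan_to_num(sd, nan=0.0) > methsd_min)
            & (rmm.COV >= coverage_min).all(axis=0)
        )
    return rmm.subset_regions(keep)
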