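"""Weighted comethylation networks on region methylation.

The construction mirrors weighted gene-coexpression network analysis applied
to methylation: optional removal of top principal components, soft
thresholding of |Pearson r| chosen for approximate scale-free topology,
topological-overlap dissimilarity, average-linkage hierarchical clustering
with a static cut, module eigennodes (first principal component of the
module's standardized members), and module-trait Pearson correlation with a
Bonferroni family over all heatmap cells.  Regions not assigned to any
module form the reserved "gray" module, which is carried through the trait
association like any other (its eigennode is tested too).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import ValidationError

GRAY = "gray"


@dataclass
class NetworkConfig:
    n_pcs_to_adjust: int = 0
    candidate_powers: tuple = tuple(range(1, 21))
    r2_min: float = 0.8
    # scale-free R^2 rises indefinitely with the power while the network
    # thins out; powers whose mean connectivity falls below this floor are
    # not eligible (standard soft-threshold guidance)
    min_mean_connectivity: float = 2.0
    min_module_size: int = 10
    # static cut on the 1-TOM dendrogram: genuine modules merge far below 1,
    # while unassigned regions attach within O(chance TOM) of the ceiling at
    # 1, so the cut sits 2% below it
    cut_height: float = 0.98
    # soft-power eligibility window (see select_soft_power): chance edges may
    # contribute at most this much total connectivity per region ...
    max_chance_connectivity: float = 0.5
    # ... while a genuine correlation of strong_r must keep at least
    # min_strong_adjacency of adjacency
    strong_r: float = 0.7
    min_strong_adjacency: float = 0.02
    min_eigennode_var_explained: float = 0.0


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def adjust_top_pcs(V: np.ndarray, k: int) -> np.ndarray:
    """Residualize each region on the top-k principal component scores.

    PCs are computed on the column-standardized individuals x regions
    matrix; k = 0 returns the input unchanged.
    """
    V = np.asarray(V, float)
    if k == 0:
        return V.copy()
    if k >= V.shape[0]:
        raise ValidationError("cannot remove as many PCs as individuals")
    X = _standardize(V)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k]  # orthonormal PC score directions
    return X - scores @ (scores.T @ X)


def soft_power_fit(X: np.ndarray, beta: int, n_bins: int = 10) -> float:
    """Signed scale-free-topology fit R^2 for one candidate power."""
    R = np.corrcoef(X, rowvar=False)
    A = np.abs(R) ** beta
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=0)
    return _scale_free_r2(k, n_bins)


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    if np.allclose(k, k[0]):
        return float("nan")
    # equal-width connectivity bins: frequency per bin vs mean connectivity
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(max(k[sel].mean(), 1e-12)))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return float("nan")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r**2)


def eligible_power_window(n_individuals: int, n_regions: int,
                          config: NetworkConfig | None = None) -> tuple[int, int]:
    """Powers for which noise is crushed but real signal survives.

    A chance correlation scales like r0 = 2/sqrt(n-1); the lower bound is
    the smallest beta with m * r0^beta <= ``max_chance_connectivity`` (chance
    edges contribute less than that much connectivity per region), the upper
    bound the largest beta keeping ``strong_r``^beta >=
    ``min_strong_adjacency`` (a genuinely comethylated pair keeps a usable
    edge).  Both bounds depend only on problem size, never on the data.
    """
    config = config or NetworkConfig()
    r0 = min(2.0 / np.sqrt(max(n_individuals - 1, 2)), 0.99)
    lo = int(np.ceil(np.log(config.max_chance_connectivity / max(n_regions, 2))
                     / np.log(r0)))
    hi = int(np.floor(np.log(config.min_strong_adjacency) / np.log(config.strong_r)))
    lo = max(lo, 1)
    hi = max(hi, lo)
    return lo, hi


def select_soft_power(X: np.ndarray, config: NetworkConfig | None = None):
    """Smallest eligible power with signed scale-free fit >= threshold.

    Candidate powers are intersected with the eligibility window of
    :func:`eligible_power_window`; among those the smallest with R^2 >=
    ``r2_min`` wins, else the one with the best fit.  Falls back to beta = 6
    (with a warning flag) when connectivity is degenerate at every power.
    Returns ``(beta, r2, fallback)``.
    """
    config = config or NetworkConfig()
    n, m = X.shape
    lo, hi = eligible_power_window(n, m, config)
    powers = [b for b in sorted(config.candidate_powers) if lo <= b <= hi]
    if not powers:
        powers = [min(sorted(config.candidate_powers), key=lambda b: abs(b - lo))]
    R = np.abs(np.corrcoef(X, rowvar=False))
    np.fill_diagonal(R, 0.0)
    fits: dict[int, float] = {}
    for beta in powers:
        k = (R**beta).sum(axis=0)
        r2 = _scale_free_r2(k)
        if not np.isfinite(r2):
            continue
        fits[int(beta)] = float(r2)
        if r2 >= config.r2_min:
            return int(beta), float(r2), False
    if not fits:
        return 6, float("nan"), True
    best = max(fits, key=lambda b: fits[b])
    return int(best), float(fits[best]), False


def topological_overlap(A: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix of an adjacency with zero diagonal."""
    L = A @ A
    k = A.sum(axis=0)
    kmin = np.minimum.outer(k, k)
    T = (L + A) / (kmin + 1.0 - A)
    np.fill_diagonal(T, 1.0)
    return T


def detect_modules(
    X: np.ndarray, beta: int, config: NetworkConfig | None = None
) -> np.ndarray:
    """Assign each region a module label from TOM-based clustering.

    adjacency = |cor|^beta; dissimilarity = 1 - TOM; average linkage; static
    cut at ``config.cut_height``; clusters below ``min_module_size`` merge
    into "gray".  Labels "M1", "M2", ... are ordered by decreasing size.
    """
    config = config or NetworkConfig()
    if X.shape[1] < 2:
        raise ValidationError("module detection needs at least 2 regions")
    R = np.corrcoef(X, rowvar=False)
    R = np.nan_to_num(R, nan=0.0)
    A = np.abs(np.clip(R, -1, 1)) ** beta
    np.fill_diagonal(A, 0.0)
    D = 1.0 - topological_overlap(A)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=config.cut_height, criterion="distance")
    labels = np.full(X.shape[1], GRAY, dtype=object)
    sizes = pd.Series(raw).value_counts()
    big = [c for c in sizes.index if sizes[c] >= config.min_module_size]
    big.sort(key=lambda c: (-sizes[c], c))
    for rank, c in enumerate(big, start=1):
        labels[raw == c] = f"M{rank}"
    return labels


def compute_eigennodes(V: np.ndarray, labels: np.ndarray, ids: list[str]) -> pd.DataFrame:
    """Per-module eigennode: PC1 score vector of standardized member columns.

    The sign is fixed so the eigennode correlates positively with the
    module's mean methylation; a single-region module's eigennode is that
    region's standardized vector.  The gray module is included.
    """
    out = {}
    for mod in _ordered_modules(labels):
        cols = np.flatnonzero(labels == mod)
        Xm = _standardize(V[:, cols])
        if Xm.shape[1] == 1:
            e = Xm[:, 0].copy()
        else:
            U, s, _ = np.linalg.svd(Xm, full_matrices=False)
            e = U[:, 0] * s[0]
        mean_m = V[:, cols].mean(axis=1)
        if np.std(mean_m) > 0 and np.corrcoef(e, mean_m)[0, 1] < 0:
            e = -e
        out[mod] = e
    return pd.DataFrame(out, index=ids)


def eigennode_variance_explained(V: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    out = {}
    for mod in _ordered_modules(labels):
        cols = np.flatnonzero(labels == mod)
        Xm = _standardize(V[:, cols])
        _, s, _ = np.linalg.svd(Xm, full_matrices=False)
        out[mod] = float(s[0] ** 2 / (s**2).sum())
    return out


def _ordered_modules(labels: np.ndarray) -> list[str]:
    mods = sorted({m for m in labels if m != GRAY}, key=lambda m: int(m[1:]))
    if GRAY in labels:
        mods.append(GRAY)
    return mods


def module_trait_association(
    eigennodes: pd.DataFrame, traits: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson correlation of every eigennode with every trait.

    Two-sided p-values from the t distribution with n-2 df; Bonferroni over
    all defined (module, trait) cells of the heatmap.  Zero-variance traits
    give undefined cells excluded from the family size.
    """
    ids = list(eigennodes.index)
    T = traits.set_index("id").loc[[str(i) for i in ids]] if "id" in traits.columns else traits.loc[ids]
    rows = []
    for mod in eigennodes.columns:
        e = eigennodes[mod].to_numpy(float)
        for trait in T.columns:
            y = T[trait].to_numpy(float)
            ok = np.isfinite(e) & np.isfinite(y)
            n = int(ok.sum())
            if n < 3 or np.std(y[ok]) == 0 or np.std(e[ok]) == 0:
                rows.append(
                    {"module": mod, "trait": trait, "r": np.nan, "p": np.nan, "n": n}
                )
                continue
            r, p = stats.pearsonr(e[ok], y[ok])
            rows.append({"module": mod, "trait": trait, "r": float(r), "p": float(p), "n": n})
    res = pd.DataFrame(rows)
    m = int(res["p"].notna().sum())
    res["p_bonferroni"] = np.minimum(res["p"] * max(m, 1), 1.0)
    res["significant"] = res["p_bonferroni"] < alpha
    res.loc[res["p"].isna(), "significant"] = False
    return res


def score_module_recovery(true_labels, found_labels) -> float:
    """Adjusted Rand index between a planted and a recovered partition."""
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(list(true_labels), list(found_labels)))
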