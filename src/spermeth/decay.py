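"""Comethylation and its decay with physical distance.

Comethylation within a genomic bin is the mean absolute Pearson correlation
over all unordered pairs of in-bin variable CpGs (correlation taken across
individuals).  The decay profile samples random bins of increasing size;
because larger bins hold pairs at larger distances, mean |r| falls with bin
size when methylation is regionally correlated.

Two decay models are fitted.  ``model="exp"`` is the plain exponential
a*exp(-d/lambda) + c with d the profile's distance coordinate.  For profiles
indexed by bin size the expected mean pair correlation in a bin of size s is
NOT exp(-s/lambda): pair distances within a bin of uniformly scattered sites
follow a triangular density, giving a*g(s/lambda) + c with
g(u) = 2 (u - 1 + e^{-u}) / u^2.  ``model="binned"`` fits that kernel and is
the consistent estimator of the generative decay length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import MethMatrix, SpermethError, ValidationError


def sample_bins(
    chrom_sizes: dict[str, int], bin_size: int, n_bins: int, seed: int
) -> pd.DataFrame:
    """Sample ``n_bins`` bins of exactly ``bin_size`` bp, with replacement.

    Chromosomes are chosen with probability proportional to their number of
    valid start positions (L - bin_size + 1), then starts uniformly.
    """
    chroms = sorted(chrom_sizes)
    mass = np.array([max(chrom_sizes[c] - bin_size + 1, 0) for c in chroms], float)
    if mass.sum() <= 0:
        raise ValidationError(f"bin size {bin_size} exceeds every chromosome")
    rng = np.random.default_rng(seed)
    probs = mass / mass.sum()
    picks = rng.choice(len(chroms), size=n_bins, p=probs)
    starts = np.array(
        [rng.integers(0, int(mass[k])) for k in picks], dtype=np.int64
    )
    return pd.DataFrame(
        {
            "chrom": [chroms[k] for k in picks],
            "start": starts,
            "end": starts + bin_size,
        }
    )


def bin_mean_abs_correlation(matrix: MethMatrix, chrom: str, start: int, end: int):
    """Mean |Pearson r| over unordered pairs of loci inside one bin.

    Returns None (undefined) when fewer than two finite-variance loci fall in
    the bin.  Zero-variance loci are dropped from the pair set rather than
    counted as r = 0.
    """
    sel = (
        (matrix.loci["chrom"].to_numpy() == chrom)
        & (matrix.loci["pos"].to_numpy() >= start)
        & (matrix.loci["pos"].to_numpy() < end)
    )
    X = matrix.P[:, sel]
    if X.shape[1] < 2:
        return None
    sd = X.std(axis=0)
    X = X[:, sd > 0]
    if X.shape[1] < 2:
        return None
    R = np.corrcoef(X, rowvar=False)
    iu = np.triu_indices(R.shape[0], k=1)
    return float(np.abs(R[iu]).mean())


def decay_profile(
    matrix: MethMatrix,
    bin_sizes,
    n_bins: int = 1000,
    seed: int = 0,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean within-bin |r| at each bin size.

    Bins with <2 usable loci are undefined and excluded; a size where every
    bin is undefined is reported with ``n_bins_used`` = 0 and NaN mean.
    """
    if chrom_sizes is None:
        chrom_sizes = {
            c: int(matrix.loci.loc[matrix.loci["chrom"] == c, "pos"].max()) + 2
            for c in matrix.loci["chrom"].unique()
        }
    loci_by_chrom = {}
    for c in matrix.loci["chrom"].unique():
        idx = np.flatnonzero(matrix.loci["chrom"].to_numpy() == c)
        loci_by_chrom[c] = (idx, matrix.loci["pos"].to_numpy()[idx])
    rows = []
    for si, size in enumerate(sorted(bin_sizes)):
        bins = sample_bins(chrom_sizes, int(size), n_bins, seed=seed + si)
        vals = []
        for b in bins.itertuples(index=False):
            idx, pos = loci_by_chrom.get(b.chrom, (np.array([], int), np.array([], int)))
            lo = np.searchsorted(pos, b.start, side="left")
            hi = np.searchsorted(pos, b.end, side="left")
            members = idx[lo:hi]
            if len(members) < 2:
                continue
            X = matrix.P[:, members]
            sd = X.std(axis=0)
            X = X[:, sd > 0]
            if X.shape[1] < 2:
                continue
            R = np.corrcoef(X, rowvar=False)
            iu = np.triu_indices(R.shape[0], k=1)
            vals.append(float(np.abs(R[iu]).mean()))
        rows.append(
            {
                "bin_size": int(size),
                "n_bins_sampled": n_bins,
                "n_bins_used": len(vals),
                "mean_abs_r": float(np.mean(vals)) if vals else np.nan,
                "sd_abs_r": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Decay-model fitting
# ---------------------------------------------------------------------------

def _g_binned(u):
    u = np.asarray(u, float)
    small = u < 1e-8
    u_safe = np.where(small, 1.0, u)
    g = 2.0 * (u_safe - 1.0 + np.exp(-u_safe)) / u_safe**2
    return np.where(small, 1.0, g)


def trichotomization_attenuation(
    state_freqs=(0.4, 0.1, 0.5), state_levels=(0.05, 0.5, 0.95), n_grid: int = 41
):
    """Pearson correlation of three-state-mapped bivariate normals vs latent rho.

    When methylation proportions sit at three discrete state levels reached by
    thresholding a latent Gaussian, the observable Pearson correlation m(rho)
    is a nonlinear (attenuated) function of the latent correlation rho.
    Returns an interpolator for m on [0, 1].
    """
    from scipy.interpolate import PchipInterpolator
    from scipy.stats import multivariate_normal, norm

    f = np.asarray(state_freqs, float)
    l = np.asarray(state_levels, float)
    t1, t2 = norm.ppf(f[0]), norm.ppf(f[0] + f[1])
    mu = float((l * f).sum())
    var = float((l * l * f).sum() - mu**2)
    thresholds = np.array([-np.inf, t1, t2, np.inf])

    def cdf2(a, b, rho):
        if a == -np.inf or b == -np.inf:
            return 0.0
        if a == np.inf and b == np.inf:
            return 1.0
        if a == np.inf:
            return float(norm.cdf(b))
        if b == np.inf:
            return float(norm.cdf(a))
        return float(
            multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf([a, b])
        )

    rhos = np.linspace(0.0, 0.995, n_grid)
    ms = np.empty_like(rhos)
    for k, rho in enumerate(rhos):
        P = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                P[i, j] = (
                    cdf2(thresholds[i + 1], thresholds[j + 1], rho)
                    - cdf2(thresholds[i], thresholds[j + 1], rho)
                    - cdf2(thresholds[i + 1], thresholds[j], rho)
                    + cdf2(thresholds[i], thresholds[j], rho)
                )
        ms[k] = ((np.outer(l, l) * P).sum() - mu**2) / var
    return PchipInterpolator(rhos, np.clip(ms, 0.0, 1.0))


def _folded_mean_abs_r(mu, n_individuals):
    """E|r_hat| for a sample correlation around mu with ~Gaussian noise."""
    from scipy.stats import norm

    mu = np.asarray(mu, float)
    sigma = (1.0 - mu**2) / np.sqrt(max(n_individuals - 1, 2))
    z = mu / sigma
    return mu * (2.0 * norm.cdf(z) - 1.0) + 2.0 * sigma * norm.pdf(z)


@dataclass
class DecayFit:
    amplitude: float
    decay_length: float
    floor: float
    model: str
    converged: bool
    flat: bool


def fit_decay(
    distances,
    values,
    model: str = "exp",
    n_individuals: int | None = None,
    state_freqs=(0.4, 0.1, 0.5),
    state_levels=(0.05, 0.5, 0.95),
) -> DecayFit:
    """Least-squares fit of a decay curve to profile points.

    ``model="exp"``: a*exp(-d/lambda) + c with d the distance coordinate.
    ``model="binned"``: a*g(d/lambda) + c with the within-bin pair-distance
    kernel g (use when distances are bin sizes).
    ``model="trimodal"``: liability-scale fit for bin-size profiles of
    trimodal (three-state) methylation: the latent spatial correlation
    exp(-d/lambda) is pushed through the trichotomization attenuation and
    the |r| sampling fold (which supplies the profile's floor), so lambda
    estimates the latent decay length rather than the faster apparent one;
    requires ``n_individuals`` and the state composition.

    Constraints: a, lambda > 0, c >= 0.  A flat profile (no decrease beyond
    noise) is flagged rather than fitted confidently.
    """
    d = np.asarray(distances, float)
    y = np.asarray(values, float)
    ok = np.isfinite(d) & np.isfinite(y)
    d, y = d[ok], y[ok]
    if len(d) < 3:
        raise ValidationError("decay fit needs at least 3 profile points")
    span = float(y.max() - y.min())
    flat = span < 1e-3
    if model == "exp":
        fun = lambda x, a, lam, c: a * np.exp(-x / lam) + c
    elif model == "binned":
        fun = lambda x, a, lam, c: a * _g_binned(x / lam) + c
    elif model == "trimodal":
        if n_individuals is None:
            raise ValidationError("model='trimodal' requires n_individuals")
        m_interp = trichotomization_attenuation(state_freqs, state_levels)
        nodes, weights = np.polynomial.legendre.leggauss(24)

        def fun(x, a, lam, c):
            x = np.atleast_1d(np.asarray(x, float))
            out = np.empty_like(x)
            for i, s in enumerate(x):
                dd = 0.5 * s * (nodes + 1.0)  # map [-1,1] -> [0,s]
                dens = 2.0 * (s - dd) / s**2
                mu = np.clip(a, 0.0, 1.0) * m_interp(np.exp(-dd / lam))
                vals = _folded_mean_abs_r(mu, n_individuals)
                out[i] = 0.5 * s * np.sum(weights * dens * vals) + c
            return out
    else:
        raise ValueError(f"unknown decay model {model!r}")
    # multi-start over a geometric grid of decay lengths; keep the best fit
    best, best_sse = None, np.inf
    lam_grid = np.geomspace(max(d.min() / 10.0, 1e-6), d.max() * 10.0, 12)
    for lam0 in lam_grid:
        p0 = (max(span, 1e-3), float(lam0), max(float(y.min()), 0.0))
        try:
            popt, _ = curve_fit(
                fun,
                d,
                y,
                p0=p0,
                bounds=([1e-12, 1e-9, 0.0], [np.inf, np.inf, 1.0]),
                maxfev=20000,
            )
        except Exception:
            continue
        sse = float(np.sum((fun(d, *popt) - y) ** 2))
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is not None:
        converged = True
        a, lam, c = (float(v) for v in best)
    else:
        converged = False
        a, lam, c = float("nan"), float("nan"), float("nan")
    return DecayFit(
        amplitude=a, decay_length=lam, floor=c, model=model, converged=converged, flat=flat
    )
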