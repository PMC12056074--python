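"""Synthetic in-silico study generator.

Every downstream stage of the pipeline is exercised against data produced
here, with a manifest of ground truth sufficient to score recovery.  The
generator emulates the structure of a sperm EM-seq study in a two-generation
fish breeding design:

* a pedigree of full-sib families whose sires are shared across dams, so
  both full-sib and paternal half-sib pairs exist;
* a hypermethylated CpG landscape (global mean ~0.86) in which a minority of
  CpGs are variable, with per-individual trimodal methylation states
  (hypo ~0.05 / semi ~0.5 / hyper ~0.95);
* regional comethylation: variable-CpG liabilities follow a Markov process
  along each chromosome with autocorrelation exactly exp(-d/lambda) at
  distance d;
* kinship coupling: a fraction h_m of liability variance is shared according
  to the pedigree's additive relationship matrix;
* binomially sampled counts at negative-binomial coverage, fully methylated
  and fully unmethylated spike-in control genomes, and one deliberately
  corrupted sample emulating a failed cytosine conversion;
* trait vectors with planted module and cluster associations, with opposite
  signs for sperm concentration versus motility/velocity traits.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING_PARENT, RelationshipMatrix, ValidationError
from .relmat import compute_amat

TRAIT_SCALES = {
    # trait: (mean, sd, lower clip, upper clip)
    "length_cm": (54.78, 2.93, 30.0, 90.0),
    "weight_kg": (2.94, 0.61, 0.5, 8.0),
    "concentration": (2841.0, 1961.6, 100.0, 10000.0),
    "total_motility": (0.84, 0.13, 0.0, 1.0),
    "total_progressive": (0.46, 0.22, 0.0, 1.0),
    "total_rapid": (0.13, 0.11, 0.0, 1.0),
    "total_medium": (0.33, 0.14, 0.0, 1.0),
    "vcl": (85.36, 19.66, 5.0, 200.0),
    "vap": (60.78, 18.52, 5.0, 200.0),
    "vsl": (44.62, 15.06, 5.0, 150.0),
}

MOTILITY_TRAITS = [
    "total_motility", "total_progressive", "total_rapid", "total_medium",
    "vcl", "vap", "vsl",
]


@dataclass
class PlantedModule:
    name: str
    n_genes: int = 15
    factor_weight: float = 0.8
    # trait -> target correlation of the trait with the module factor
    trait_effects: dict = field(default_factory=dict)


@dataclass
class PlantedCluster:
    trait: str
    delta: float = 0.3
    n_cpgs: int = 6


@dataclass
class SimConfig:
    """Study conditions for the synthetic data generator."""

    # pedigree: full-sib families, sires shared across dams_per_sire dams
    n_families: int = 8
    offspring_per_family: int = 6
    dams_per_sire: int = 2
    n_samples: int = 47          # sequenced fish (n_families*offspring >= this)
    n_corrupted: int = 1         # failed-conversion samples among the last ids

    # genome + methylome
    n_chrom: int = 2
    chrom_length_bp: int = 1_000_000
    n_cpg: int = 100_000
    global_meth_mean: float = 0.86
    global_meth_sd: float = 0.03
    frac_variable_cpg: float = 0.10
    decay_length_bp: float = 200.0
    heritable_fraction: float = 0.8
    state_freqs: tuple = (0.4, 0.1, 0.5)      # hypo, semi, hyper
    state_levels: tuple = (0.05, 0.5, 0.95)
    target_jitter_sd: float = 0.01
    mean_coverage: float = 30.0
    coverage_dispersion: float = 60.0         # NB size parameter (mild overdispersion)
    conversion_error: float = 0.005
    corruption_failed_fraction: float = 0.9
    n_control_sites: int = 400
    n_chg: int = 8_000
    n_chh: int = 8_000
    noncpg_level: float = 0.003

    # annotation
    n_genes_per_chrom: int = 120
    n_islands_per_chrom: int = 25

    # genetics
    n_snp: int = 400
    n_snp_on_cpg_transitions: int = 7

    # planted effects
    planted_modules: list = field(default_factory=lambda: [
        PlantedModule(
            name="modA",
            n_genes=15,
            trait_effects={"concentration": 0.6, "vcl": -0.6, "vap": -0.55, "vsl": -0.5},
        ),
        PlantedModule(
            name="modB",
            n_genes=12,
            trait_effects={"total_motility": -0.5, "total_progressive": -0.45},
        ),
    ])
    planted_clusters: list = field(default_factory=lambda: [
        PlantedCluster(trait="concentration", delta=0.3),
        PlantedCluster(trait="concentration", delta=0.3),
        PlantedCluster(trait="vcl", delta=0.3),
    ])
    extreme_k: int = 20
    plant_concentration_outlier: bool = True

    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.heritable_fraction <= 1:
            raise ValidationError("heritable_fraction must lie in [0, 1]")
        if self.decay_length_bp <= 0:
            raise ValidationError("decay_length_bp must be positive")
        if not 0 < self.global_meth_mean < 1:
            raise ValidationError("global_meth_mean must lie in (0, 1)")
        if abs(sum(self.state_freqs) - 1.0) > 1e-9:
            raise ValidationError("state_freqs must sum to 1")
        per_trait: dict[str, float] = {}
        for pm in self.planted_modules:
            for trait, r in pm.trait_effects.items():
                if abs(r) >= 1:
                    raise ValidationError(f"module {pm.name}: |r| >= 1 for {trait}")
                per_trait[trait] = per_trait.get(trait, 0.0) + r * r
        for trait, s in per_trait.items():
            if s >= 1.0:
                raise ValidationError(f"trait {trait}: summed squared effects >= 1")
        if self.n_families * self.offspring_per_family < self.n_samples:
            raise ValidationError("family design yields fewer offspring than n_samples")


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimConfig):
    """Two-generation design: sires shared across dams create paternal half-sibs.

    Returns ``(pedigree, A, sample_ids)`` where A covers all individuals
    (founders + offspring) and ``sample_ids`` are the sequenced offspring in
    id order.
    """
    config.validate()
    n_sires = -(-config.n_families // config.dams_per_sire)  # ceil
    sires = [f"S{i + 1}" for i in range(n_sires)]
    dams = [f"D{i + 1}" for i in range(config.n_families)]
    rows = [(s, MISSING_PARENT, MISSING_PARENT) for s in sires]
    rows += [(d, MISSING_PARENT, MISSING_PARENT) for d in dams]
    offspring = []
    for fam in range(config.n_families):
        sire = sires[fam // config.dams_per_sire]
        dam = dams[fam]
        for j in range(config.offspring_per_family):
            child = f"F{fam + 1}_{j + 1}"
            rows.append((child, sire, dam))
            offspring.append(child)
    ped = pd.DataFrame(rows, columns=["id", "sire", "dam"])
    A = compute_amat(ped)
    return ped, A, offspring[: config.n_samples]


# ---------------------------------------------------------------------------
# Annotation + sequence
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimConfig, rng: np.random.Generator):
    """Genes (>=2 exons each, so first introns exist), CpG islands, FASTA.

    Island segments get CG-rich iid sequence (GC ~80%, obs/exp ~1) on a
    CG-poor background (GC ~40%), so the island caller can rediscover them.
    Returns a dict with genes, exons, islands DataFrames, sequences and
    chrom_sizes.
    """
    L = config.chrom_length_bp
    chroms = [f"LG{i + 1}" for i in range(config.n_chrom)]
    gene_rows, exon_rows, island_rows = [], [], []
    sequences = {}
    for chrom in chroms:
        # --- genes ---
        cursor = int(rng.integers(2000, 6000))
        for gi in range(config.n_genes_per_chrom):
            glen = int(rng.integers(2000, 8000))
            if cursor + glen + 2000 > L:
                break
            start, end = cursor, cursor + glen
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"{chrom}_g{gi + 1}"
            gene_rows.append((chrom, start, end, strand, gid))
            n_ex = int(rng.integers(2, 5))
            # 2*n_ex - 2 interior boundaries, exons at both gene ends
            cuts = np.sort(rng.choice(np.arange(start + 100, end - 100), size=2 * n_ex - 2, replace=False))
            bounds = [start, *cuts.tolist(), end]
            for k in range(n_ex):
                es, ee = bounds[2 * k], bounds[2 * k + 1]
                exon_rows.append((chrom, int(es), int(ee), strand, gid))
            cursor = end + int(rng.integers(2000, 12000))
        # --- islands (non-overlapping, away from each other) ---
        starts = np.sort(rng.choice(L // 2000 - 2, size=config.n_islands_per_chrom * 2, replace=False)) * 2000
        kept = []
        for s in starts:
            if kept and s - kept[-1][1] < 1000:
                continue
            ilen = int(rng.integers(600, 1000))
            kept.append((int(s), int(s) + ilen))
            if len(kept) == config.n_islands_per_chrom:
                break
        for k, (s, e) in enumerate(kept):
            island_rows.append((chrom, s, e, ".", f"{chrom}:planted{k + 1}"))
        # --- sequence ---
        # background GC ~34% (windows essentially never reach GC >= 50%);
        # island GC ~60% keeps the caller's boundary overshoot small while
        # passing all three criteria (iid sequence has obs/exp CpG ~ 1)
        base = rng.choice(
            np.frombuffer(b"ACGT", dtype=np.uint8), size=L, p=[0.33, 0.17, 0.17, 0.33]
        )
        for s, e in kept:
            base[s:e] = rng.choice(
                np.frombuffer(b"ACGT", dtype=np.uint8), size=e - s, p=[0.2, 0.3, 0.3, 0.2]
            )
        sequences[chrom] = base.tobytes().decode()
    cols = ["chrom", "start", "end", "strand", "gene_id"]
    genes = pd.DataFrame(gene_rows, columns=cols)
    exons = pd.DataFrame(exon_rows, columns=cols)
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end", "strand", "label"])
    islands["feature_kind"] = "cpg_island"
    return {
        "genes": genes,
        "exons": exons,
        "islands": islands,
        "sequences": sequences,
        "chrom_sizes": {c: L for c in chroms},
    }


# ---------------------------------------------------------------------------
# Liabilities, states, counts
# ---------------------------------------------------------------------------

def _ou_rows(rng: np.random.Generator, n_rows: int, pos: np.ndarray, lam: float) -> np.ndarray:
    """Rows of unit-variance Gaussians with corr exp(-d/lam) along positions."""
    m = len(pos)
    X = np.empty((n_rows, m))
    X[:, 0] = rng.standard_normal(n_rows)
    if m > 1:
        phi = np.exp(-np.diff(pos) / lam)
        sig = np.sqrt(1.0 - phi**2)
        eps = rng.standard_normal((n_rows, m - 1))
        for j in range(1, m):
            X[:, j] = phi[j - 1] * X[:, j - 1] + sig[j - 1] * eps[:, j - 1]
    return X


def simulate_liabilities(
    rng: np.random.Generator,
    pos_by_chrom: dict[str, np.ndarray],
    kinship: np.ndarray | None,
    h_m: float,
    lam: float,
) -> np.ndarray:
    """Kinship-correlated + independent liabilities with exp(-d/lam) decay.

    Rows are individuals, columns the concatenated variable CpGs in
    chromosome order.  With kinship matrix A, cov between individuals is
    h_m * A (plus (1-h_m) I), identical at every site; cov between sites at
    distance d is exp(-d/lam) within a chromosome.
    """
    blocks = []
    n = kinship.shape[0] if kinship is not None else None
    chol = None
    if kinship is not None and h_m > 0:
        chol = np.linalg.cholesky(kinship + 1e-8 * np.eye(kinship.shape[0]))
    for chrom in pos_by_chrom:
        pos = np.asarray(pos_by_chrom[chrom], float)
        if n is None:
            raise ValidationError("kinship matrix required")
        E = _ou_rows(rng, n, pos, lam)
        if chol is not None:
            G = chol @ _ou_rows(rng, n, pos, lam)
            blocks.append(np.sqrt(h_m) * G + np.sqrt(1.0 - h_m) * E)
        else:
            blocks.append(E)
    return np.concatenate(blocks, axis=1)


def liabilities_to_targets(
    L: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Map liabilities through two thresholds to trimodal target proportions."""
    from scipy.stats import norm

    f_hypo, f_semi, _ = config.state_freqs
    t1 = norm.ppf(f_hypo)
    t2 = norm.ppf(f_hypo + f_semi)
    lv = config.state_levels
    target = np.where(L < t1, lv[0], np.where(L <= t2, lv[1], lv[2]))
    target = target + rng.normal(0.0, config.target_jitter_sd, size=target.shape)
    return np.clip(target, 0.005, 0.995)


def draw_counts(
    rng: np.random.Generator,
    target: np.ndarray,
    mean_coverage: float,
    dispersion: float,
):
    """Negative-binomial coverage, binomial methylated counts."""
    size = dispersion
    p_nb = size / (size + mean_coverage)
    cov = rng.negative_binomial(size, p_nb, size=target.shape)
    meth = rng.binomial(cov, target)
    return cov.astype(np.int64), meth.astype(np.int64)


def corrupt_targets(target: np.ndarray, failed_fraction: float) -> np.ndarray:
    """Failed conversion: a fraction of unmethylated calls read as methylated."""
    return 1.0 - (1.0 - target) * (1.0 - failed_fraction)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def simulate_traits(
    config: SimConfig,
    module_factors: dict[str, np.ndarray],
    ids: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """CASA-like trait table with planted module effects.

    Each planted effect contributes r * factor to the trait's z-score; the
    remainder is a shared motility factor (inducing mutual positive
    correlation among motility/velocity traits, and a mild negative loading
    for concentration) plus independent noise, rescaled to realistic ranges.
    """
    n = len(ids)
    u_motility = rng.standard_normal(n)
    u_growth = rng.standard_normal(n)
    effects: dict[str, dict[str, float]] = {}
    for pm in config.planted_modules:
        for trait, r in pm.trait_effects.items():
            effects.setdefault(trait, {})[pm.name] = r
    out = {"id": ids}
    for trait, (mu, sd, lo, hi) in TRAIT_SCALES.items():
        planted = effects.get(trait, {})
        z = np.zeros(n)
        var_used = 0.0
        for mod, r in planted.items():
            z = z + r * module_factors[mod]
            var_used += r * r
        if trait in MOTILITY_TRAITS:
            base = 0.6 * u_motility + np.sqrt(1 - 0.36) * rng.standard_normal(n)
        elif trait == "concentration":
            base = -0.3 * u_motility + np.sqrt(1 - 0.09) * rng.standard_normal(n)
        elif trait in ("length_cm", "weight_kg"):
            base = 0.7 * u_growth + np.sqrt(1 - 0.49) * rng.standard_normal(n)
        else:
            base = rng.standard_normal(n)
        z = z + np.sqrt(max(1.0 - var_used, 0.0)) * base
        out[trait] = np.clip(mu + sd * z, lo, hi)
    traits = pd.DataFrame(out)
    if config.plant_concentration_outlier and n >= 3:
        top = traits["concentration"].idxmax()
        traits.loc[top, "concentration"] = 13536.0
    return traits


# ---------------------------------------------------------------------------
# Focused fixtures for single-stage tests
# ---------------------------------------------------------------------------

def simulate_variable_matrix(
    n_individuals: int = 46,
    n_sites: int = 3000,
    chrom_length_bp: int = 600_000,
    decay_length_bp: float = 200.0,
    kinship: np.ndarray | None = None,
    heritable_fraction: float = 0.0,
    mean_coverage: float = 30.0,
    seed: int = 0,
    n_chrom: int = 1,
):
    """Variable-CpG MethMatrix with known decay length and kinship coupling.

    Returns ``(matrix, truth)`` where truth holds positions, targets and the
    kinship matrix used.  When no kinship is given, individuals are
    unrelated (identity).
    """
    from .core import MethMatrix

    cfg = SimConfig(
        decay_length_bp=decay_length_bp,
        heritable_fraction=heritable_fraction,
        mean_coverage=mean_coverage,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    if kinship is None:
        kinship = np.eye(n_individuals)
    per = n_sites // n_chrom
    pos_by_chrom = {}
    for c in range(n_chrom):
        pos = np.sort(
            rng.choice(chrom_length_bp // 2 - 1, size=per, replace=False) * 2
        )
        pos_by_chrom[f"LG{c + 1}"] = pos
    L = simulate_liabilities(
        rng, pos_by_chrom, kinship, heritable_fraction, decay_length_bp
    )
    target = liabilities_to_targets(L, cfg, rng)
    cov, meth = draw_counts(rng, target, mean_coverage, cfg.coverage_dispersion)
    cov = np.maximum(cov, 1)
    meth = np.minimum(meth, cov)
    loci = pd.DataFrame(
        [(c, int(p)) for c in pos_by_chrom for p in pos_by_chrom[c]],
        columns=["chrom", "pos"],
    )
    P = meth / cov
    ids = [f"I{i + 1}" for i in range(n_individuals)]
    mm = MethMatrix(ids=ids, loci=loci, P=P, C=cov)
    truth = {
        "pos_by_chrom": pos_by_chrom,
        "targets": target,
        "kinship": kinship,
        "decay_length_bp": decay_length_bp,
    }
    return mm, truth


def simulate_region_modules(
    n_individuals: int = 40,
    n_modules: int = 3,
    regions_per_module: int = 20,
    n_noise_regions: int = 40,
    within_r: float = 0.8,
    seed: int = 0,
):
    """Region-level matrix with planted comethylation modules.

    Member regions of a module share a latent factor so that the expected
    within-module correlation is ``within_r``; noise regions are
    independent.  Returns ``(V, labels, factors)`` with labels "mod1"...,
    "noise" and per-module factor vectors.
    """
    rng = np.random.default_rng(seed)
    cols, labels = [], []
    factors = {}
    w = np.sqrt(within_r)
    for k in range(n_modules):
        f = rng.standard_normal(n_individuals)
        factors[f"mod{k + 1}"] = f
        for _ in range(regions_per_module):
            cols.append(w * f + np.sqrt(1 - within_r) * rng.standard_normal(n_individuals))
            labels.append(f"mod{k + 1}")
    for _ in range(n_noise_regions):
        cols.append(rng.standard_normal(n_individuals))
        labels.append("noise")
    V = np.column_stack(cols)
    return V, np.array(labels, dtype=object), factors


def simulate_cluster_matrix(
    n_individuals: int = 46,
    n_clusters: int = 200,
    n_planted: int = 3,
    delta: float = 0.3,
    cpgs_per_cluster: int = 5,
    extreme_k: int = 20,
    seed: int = 0,
):
    """MethMatrix of well-separated CpG clusters with planted group effects.

    The ``n_planted`` first clusters are shifted by +``delta`` target
    methylation in the ``extreme_k`` lowest-trait individuals (cases).
    Returns ``(matrix, traits, planted_cluster_spans)``.
    """
    from .core import MethMatrix

    rng = np.random.default_rng(seed)
    trait = rng.standard_normal(n_individuals)
    low = np.argsort(trait, kind="stable")[:extreme_k]
    pos_list, chrom_list = [], []
    cursor = 1000
    spans = []
    targets = np.empty((n_individuals, n_clusters * cpgs_per_cluster))
    col = 0
    for c in range(n_clusters):
        # base levels low enough that base + delta stays inside [0, 1]:
        # otherwise clipping would silently shrink the planted difference
        base = rng.uniform(0.15, 0.55)
        indiv = np.clip(base + rng.normal(0, 0.15, size=n_individuals), 0.02, 0.98)
        if c < n_planted:
            indiv = indiv.copy()
            indiv[low] = np.clip(indiv[low] + delta, 0.02, 0.98)
        start = cursor
        for _ in range(cpgs_per_cluster):
            pos_list.append(cursor)
            chrom_list.append("LG1")
            jitter = rng.normal(0, 0.02, size=n_individuals)
            targets[:, col] = np.clip(indiv + jitter, 0.01, 0.99)
            col += 1
            cursor += int(rng.integers(40, 120))
        spans.append(("LG1", start, pos_list[-1] + 2))
        cursor += 500  # > max_gap so clusters never merge
    cov = 10 + rng.poisson(20, size=targets.shape)
    meth = rng.binomial(cov, targets)
    loci = pd.DataFrame({"chrom": chrom_list, "pos": pos_list})
    ids = [f"I{i + 1}" for i in range(n_individuals)]
    mm = MethMatrix(ids=ids, loci=loci, P=meth / cov, C=cov.astype(np.int64))
    traits = pd.DataFrame({"id": ids, "trait": trait})
    return mm, traits, spans[:n_planted]
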