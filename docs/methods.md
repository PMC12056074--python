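# Methods

This note records the models, defaults and numerical choices behind each
stage, what the synthetic data do and do not emulate, and the known
limitations.

## Data model and conventions

All in-memory coordinates are 0-based half-open; conversion to the 1-based
inclusive on-disk conventions (Bismark coverage, GFF3, VCF) happens only in
`spermeth.io`. A CpG locus is recorded at the C position `p` of the dyad;
the reverse-strand G sits at `p+1`, and both positions are checked when
excluding SNP-overlapping CpGs. CpG records on opposite strands are not
collapsed by the readers (site counts stay auditable); methylation
proportions are always recomputed from the methylated/unmethylated counts —
the percent column of coverage files is advisory only. Pedigrees use "0"
for an unknown parent and are topologically sorted on read; cycles are
rejected with the offending path named.

## Sample QC

The spike-in controls give per-sample error estimates: the unmethylated
(lambda-like) control's pooled methylation estimates the conversion error
(threshold 2%), the methylated (pUC19-like) control's pooled methylation
the protection rate (threshold 95%). A failed enzymatic conversion shows up
jointly as high "methylation" on the unmethylated control and artificial
genome-wide hypermethylation. Because an unattended pipeline cannot exclude
outliers by eye, samples are additionally excluded when their global CpG
level lies more than 5 median-absolute-deviations from the cohort median;
k = 5 is deliberately permissive so that only gross failures (not
biological variation of a point or two) trigger it.

## Variable-CpG filter

High-quality variable CpGs satisfy methSD > 0.1 (sample SD across
individuals, n−1 denominator), coverage ≥ 10 and 100% call rate. The
coverage criterion is read as *per-individual* minimum coverage — the
strictest reading, consistent with demanding a 100% call rate — with a flag
(`per_individual_coverage=False`) for the mean-coverage reading. Trimodal
epiallele states are thirds of [0,1]; the middle interval is closed on both
ends (a fixed, documented tie-break).

Phenotype cleaning winsorizes configured out-of-bound values (by default a
sperm-concentration cap of 10,000 ×10⁶ cells/mL) and logs every change.

## Comethylation decay

Comethylation within a bin is the mean |Pearson r| over all unordered pairs
of in-bin variable CpGs; zero-variance loci are dropped from the pair set
rather than scored r = 0, and bins with fewer than two usable loci are
undefined (excluded from the per-size mean, never imputed). Bins are
sampled with replacement, chromosomes in proportion to their valid start
mass; 500–1,000 bins per size keeps per-size Monte-Carlo error around
0.005 at fixture scale.

Three decay models are fitted by least squares (multi-start over a
geometric λ grid):

* `exp`: a·exp(−d/λ) + c — for profiles indexed by actual distance;
* `binned`: a·g(s/λ) + c with g(u) = 2(u − 1 + e^−u)/u², the expected
  exp-decay correlation averaged over the triangular pair-distance density
  inside a bin of size s — for profiles indexed by bin size;
* `trimodal`: the latent exp(−d/λ) is pushed through the exact Pearson
  attenuation m(ρ) of three-state (trimodal) methylation — computed from
  bivariate-normal rectangle probabilities at the state thresholds — and
  through the sampling fold E|r̂| (which generates the profile's floor, so
  no free floor parameter is needed). Hard trimodal states make the
  apparent correlation decay ~40% faster than the latent one; only this
  model estimates the latent decay length consistently, and it is what the
  pipeline reports. It needs the number of individuals and the state
  composition (defaults: frequencies 0.4/0.1/0.5 at levels 0.05/0.5/0.95,
  both estimable from the observed state histogram in real data).

## Relationship matrices

M standardizes each variable-CpG column to mean 0, SD 1 (n−1 convention;
zero-variance columns dropped and reported). MRM = (1/n)·M·Mᵀ; the n−1
convention scales the diagonal to (n_ind−1)/n_ind of the population-SD
version, and every off-diagonal correlation statistic is invariant to that
scale. The A-matrix uses the tabular method (a_ii = 1 + 0.5·a(sire,dam);
a_ij = 0.5·(a(j,sire_i) + a(j,dam_i)); unknown parents contribute 0). The
GRM standardizes each marker by its own variance,
G_ij = (1/m)·Σ_k (x_ik − 2p_k)(x_jk − 2p_k)/(2p_k(1−p_k)), after requiring
MAF ≥ 0.20 and a 100% call rate (so no imputation policy is needed);
VanRaden's method 1 is available behind `method="vanraden1"`. Concordance
is the Pearson r over strictly-lower-triangle elements, with pairs labeled
by pedigree class (parent–offspring, full-sib, half-sib, unrelated) when a
pedigree is supplied.

## Region features and networks

Promoters are the 1 kb upstream of the gene's TSS (strand-aware, clipped at
chromosome bounds; gene start is used when no transcript structure is
available). Introns are gaps between consecutive exons; the first intron is
the gap nearest the TSS in transcription order — the last genomic gap for a
minus-strand gene. CpG islands come from a step-1 sliding window (default
100 bp, the newcpgreport default) requiring GC ≥ 50% and observed/expected
CpG = N_CG·L/(N_C·N_G) ≥ 0.6; qualifying windows are merged, edges shrunk
until the terminal window itself qualifies, boundaries trimmed to CG
dinucleotides, and segments under 200 bp dropped. Recovery of planted
islands is overlap-based — the window mechanics of existing callers are not
reproduced bit-for-bit. Shores are 2 kb flanks (a community convention; the
width is configurable) minus any island overlap.

Region methylation is the coverage-weighted mean over member CpGs
(Σ meth counts / Σ coverage; an unweighted flag exists). The pipeline
aggregates over the *variable-CpG* matrix: regions containing no variable
CpGs carry no usable between-individual signal and would only dilute the
network. Regions are kept when their methSD exceeds 0.05 and every
individual has summed in-region coverage ≥ 10.

Networks are unsigned: adjacency |cor(region_i, region_j)|^β, topological
overlap dissimilarity, average-linkage clustering with a static cut
(reproducible, no dynamic-cut heuristics), clusters under 10 regions
assigned to the reserved "gray" label. The soft power β is the smallest
candidate reaching scale-free fit R² ≥ 0.8 within an eligibility window
derived from problem size alone: chance correlations scale like 2/√(n−1),
so the lower bound makes m·r0^β ≤ 0.5 (chance edges contribute at most half
a unit of connectivity) and the upper bound keeps 0.7^β ≥ 0.02 (a genuinely
comethylated pair keeps a usable edge). Without the window, scale-free R²
keeps rising with β while the network thins until modules dissolve. The
static cut sits at 0.98 on the 1−TOM scale: genuine modules merge far below
1 while unassigned regions attach within O(chance TOM) of the ceiling, so a
cut 2% below it separates robustly.

Eigennodes are PC1 score vectors of the module's standardized members, sign
-aligned with the module's mean methylation; the gray module gets an
eigennode and enters the trait association like any other. Module–trait
cells use Pearson r with two-sided t-tests (n−2 df) and a Bonferroni family
of all defined cells per feature analysis (promoters, islands and first
introns are separate families); zero-variance traits yield undefined cells
excluded from the family size. Removal of top principal components before
network construction is available (`n_pcs_to_adjust`), defaulting to 0.

## Cluster scan

Clusters are maximal runs of ≥ 5 qualifying CpGs with adjacent-pair gaps
≤ 150 bp ("within 150 bp of each other" is read as the adjacent-gap
condition; the all-pairs reading would forbid clusters longer than 150 bp,
contradicting the 5-member minimum at realistic spacing). The methSD filter
is recomputed on the 2k extreme individuals actually tested (flag to use
the full cohort). The per-cluster statistic is Welch's t on the cluster's
coverage-weighted mean methylation per individual; degenerate inputs
(both groups constant) return p = 1 at equal means and p = 0 otherwise,
flagged. Boundary ties in the extreme split break by stable id order and
are logged. BH step-up and a Bonferroni flag at 5% are both reported, and
hits are annotated with genes within ±50 kb (±10 kb variant for
island-based hits).

## The synthetic study

Defaults are the study conditions: 8 full-sib families (2 dams per sire, so
paternal half-sibs exist), 6 offspring each, 47 sequenced samples of which
1 is corrupted; 2 chromosomes of 1 Mb; 100,000 CpGs, 10% variable; global
CpG methylation 0.86 (the non-variable base level is solved so the *pooled*
global mean hits this despite the lower-mean variable fraction); decay
length λ = 200 bp; heritable liability fraction h_m = 0.8; mean coverage
30× with mild negative-binomial overdispersion (size 60 — low-coverage
cells exist and exercise the filters, while a 6-CpG cluster still survives
the per-individual coverage ≥ 10 rule often enough to be analyzable);
conversion error 0.5%; 400 SNPs gene-dropped through the pedigree, 7 placed
as C→T transitions on CpGs.

Variable-CpG liabilities are Gaussian with two exactly-controlled
covariance layers: along each chromosome a Markov (Ornstein–Uhlenbeck)
process gives corr(d) = exp(−d/λ) *exactly* between sites at distance d
(a moving-average kernel would imply a slower, non-exponential
autocorrelation and make decay-length recovery ill-posed); across
individuals the liability is √h_m·(kinship-correlated part, via the
Cholesky factor of A) + √(1−h_m)·noise. Liabilities map through two fixed
thresholds to trimodal target proportions {0.05, 0.5, 0.95} with state
frequencies 0.4/0.1/0.5 (the middle mode kept deliberately small) plus
small jitter; counts are binomial at negative-binomial coverage. The
corrupted sample's targets are transformed as 1−(1−p)(1−φ) with φ = 0.9,
the signature of a failed conversion, on genome, non-CpG sites and its
unmethylated control alike.

Traits follow realistic CASA ranges (concentration ~2,800 ± 1,960 ×10⁶
cells/mL, VCL ~85 ± 20 μm/s, motility proportions clipped to [0,1]); the
motility/velocity traits share a latent factor (mutual positive
correlation), concentration loads mildly negatively on it, and planted
module effects contribute r·factor to the trait z-score with opposite signs
for concentration versus velocity (a resource trade-off pattern). One
concentration value is replaced by 13,536 to exercise the winsorization
rule. Planted differential clusters shift the target methylation of the 20
lowest-trait individuals by +Δ (default 0.3), with base levels kept low
enough that clipping at 1 cannot silently shrink the planted difference.

What the generator does *not* emulate: read-level data (counts are drawn
directly, so mapping artifacts, strand asymmetries and duplicate reads are
absent); sequence-coupled methylation (CpG coordinates are drawn
independently of the emitted FASTA, which only serves the island caller);
chromatin-state or feature-specific methylation differences beyond the
planted modules; sex chromosomes; genotype–methylation cis effects (the
kinship coupling is induced at the liability level, not through alleles).
Passing recovery tests therefore demonstrates the statistical machinery on
data with the declared covariance structure, not robustness to alignment
or sequence-context artifacts.

## Problem sizes and determinism

All randomness flows from explicit seeds (`numpy` `SeedSequence` spawning);
with a fixed seed, fixture trees and pipeline outputs are byte-identical
across runs, which the test suite asserts at the default study scale. The
recovery benchmarks use focused fixtures (5,000 variable CpGs for kinship
coupling, 3,000 sites for decay recovery, 100 regions for module recovery,
203 clusters for the scan), averaged over 5–20 seeds; these sizes give
stable averages while keeping the whole suite and the acceptance script in
the low minutes. Volatile run metadata (wall time, versions) is written to
a separate file (`run_meta.json`) so output trees remain comparable.

## Known limitations

* The static dendrogram cut is coarser than dynamic tree cutting; closely
  correlated planted modules can merge, and module counts are
  data-dependent (recovery, not counts, is the validated quantity).
* The trimodal decay model assumes the state composition is the same at
  every variable CpG; site-to-site composition differences in real data
  would blur the attenuation correction.
* The GRM's 100%-call-rate requirement discards markers rather than
  imputing; with sparse genotyping this can leave few markers.
* Strand merging of CpG dyads is available but off by default; whether to
  merge is a study-level choice the package does not make for you.
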