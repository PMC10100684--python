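# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model

An `OtuTable` is a taxa × samples matrix of non-negative integer counts with
optional taxonomy strings and a per-taxon domain flag (prokaryote vs
microeukaryote), round-tripping through plain TSV (domain encoded as a
`prok|`/`euk|` prefix on the taxonomy column). Sample metadata carries
salinity (psu), temperature (°C) and a region label. All analyses treat the
table as compositional only where stated (relative abundances for the
neutral model and the abundance filter); diversity and networks run on raw
counts by default.

## Synthetic communities

All four generators share a stick-breaking (GEM) metacommunity abundance
vector with concentration 5 — long-tailed, like observed amplicon
rank-abundance curves — and a single root seed split into named substreams
so each stage is independently reproducible. Zero inflation arises from the
sampling models themselves; there is no extra dropout layer, which keeps the
ground truth analytically tractable.

* **Neutral** (`simulate_neutral`): per taxon and sample, local relative
  abundance ~ Beta(Nmp, Nm(1−p)) around metacommunity frequency p with
  N = library size and m = migration rate, then counts ~ Binomial(N, ·).
  This is the generative twin of the fitted neutral model, so parameter
  recovery is a meaningful end-to-end check.
* **Niche** (`simulate_niche_gradient`): samples split across gradient
  groups whose salinity means/sds default to the three-region estuarine
  design (13.15 ± 0.93, 17.28 ± 0.56, 29.17 ± 0.24 psu); each taxon has a
  salinity optimum (uniform over the gradient span by default;
  `optima_skew > 1` crowds optima toward the freshwater end, producing the
  richness decline toward high salinity typical of river-fed systems) and a
  shared Gaussian response width (default 3 psu); counts are one
  multinomial draw per sample. Temperature declines with salinity with mild
  noise.
* **Dispersal** (`simulate_dispersal_structured`): each taxon has an
  occupancy probability (Beta(1.5, 1.5) unless given); presence is an
  independent Bernoulli per site, abundance conditional on presence is
  i.i.d. log-normal. All structure lives in the taxon margin — the pattern
  a taxon-totals-preserving null reproduces.
* **Block network** (`simulate_block_network`): modules share a latent
  per-sample factor; a taxon's log abundance is baseline + loading × factor
  + noise, counts Poisson. Module factors form a chain with neighbour
  correlation 0.65 and the last `n_modules − 1` taxa are gatekeepers
  loading equally on two adjacent modules. Two deliberate choices here:
  (a) a taxon cannot correlate above 1/√2 with two independent factors, so
  some between-module factor correlation is a mathematical precondition for
  connected modular networks with gatekeepers — which is what observed
  co-occurrence networks look like; 0.65 keeps member–member cross-module
  correlations (~0.6) and gatekeeper–gatekeeper correlations (~0.8 × rank
  attenuation) at or below the 0.8 edge threshold while gatekeeper–member
  correlations (~0.88) clear it. (b) The factor innovations are whitened so
  the realised factor geometry is exact rather than subject to
  n_samples-sized sampling drift; without this, occasional factor draws
  cross-correlate whole modules and the ground-truth edge set no longer
  describes the data actually generated. Gatekeepers receive
  upper-middle-rank abundances: never dominant, but deeply enough sampled
  that Poisson noise cannot sever their edges.

What the generators do **not** emulate: sequencing error, chimeras, primer
bias, compositional coupling between domains, taxon–taxon interactions
beyond shared latent factors, and temporal dynamics. Passing tests therefore
demonstrate statistical correctness of the pipeline on idealised data, not
robustness to those artefacts.

## Diversity

Shannon is reported in nats and Simpson as Gini–Simpson (1 − Σp²), both
bounded and conventional; Pielou is H′/ln S (0 for S = 1). Chao1 is the
bias-corrected form S + F₁(F₁−1)/(2(F₂+1)), finite when doubletons are
absent; ACE uses the standard rare-taxon cutoff of 10, falling back to
bias-corrected Chao1 for the degenerate case where every rare taxon is a
singleton (where ACE is undefined). Indices are computed on raw counts by
default — rarefaction curves are provided as a saturation diagnostic, not as
normalisation; a caller who wants rarefied indices can rarefy explicitly.
Bray–Curtis accepts an explicit transform (`none`, `log1p`, `sqrt`);
ordination *requires* naming one, because "log-transformed" and "square
root-transformed" are both defensible conventions for community data and a
silent default would hide the choice. Environment correlations use Spearman
with average ranks and the two-sided t approximation; constant inputs yield
flagged rows rather than errors.

## Ordination and PERMANOVA

PCoA uses Gower double-centering and a symmetric eigendecomposition;
negative eigenvalues (non-Euclidean input) are retained and summarised, with
coordinates built from positive-eigenvalue axes only. CAP follows the
PCoA → m axes → canonical discriminant construction: when m is not given it
minimises leave-one-out misclassification (linear discriminant classifier;
smallest m on ties), and δ² values are squared canonical correlations
between the centred m-axis coordinates and centred group indicators,
computed via orthonormal bases and an SVD for numerical stability.

PERMANOVA uses the direct formulation: SS_total = Σ_{i<j} d²ᵢⱼ/n,
SS_within summed per group, pseudo-F on (a−1, n−a) degrees of freedom,
p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1) so p is never zero. Ties at the
observed statistic count as exceedances (conservative). One-way designs
only. A calibration property (type-I error within [0.03, 0.07] at α = 0.05
under a no-effect simulation) is asserted in the acceptance suite.

## Neutral model fit

N is the mean library size; the fit minimises squared error of observed
occurrence frequencies against 1 − I_d(Nmp, Nm(1−p)) over a bounded
one-dimensional search in m (tolerance 1e-8, deterministic). Taxa with zero
mean abundance or zero occupancy are excluded and counted. The default
detection limit is **d = ln 2/N**: under binomial sampling of N reads a
taxon at relative abundance a is detected with probability 1 − (1−a)^N,
which crosses ½ at a = ln 2/N, so this is the abundance at which the step
approximation should place the threshold. The one-read convention d = 1/N
overstates the detection limit and biases fitted m upward on data generated
by the model itself (verifiable with `detection_limit=1/N`); it remains one
argument away for comparability with other implementations. The 95 % band
is a Wilson score interval around the predicted frequency at the observed
number of samples; classification uses a 1e-9 tolerance at the band edges
because the upper bound is algebraically 1 when the prediction is 1.

## PER-SIMPER and DNCI

SIMPER decomposes mean between-group Bray–Curtis on presence/absence into
per-taxon contributions (pairs of empty sites excluded); profiles are the
descending-sorted contribution percentages. E = log₁₀ Σ_rank (obs − perm)²,
floored at −12 for exactly-zero deviation. Null schemes: taxon totals fixed
(uniform site assignment), site totals fixed (uniform taxon identity), both
margins fixed by checkerboard-swap MCMC with burn-in 10 × fill and thinning
fill/2 attempted swaps (seeded; a matrix admitting no swap returns copies
with a warning). SES_x = (mean E_x − mean E_both)/sd(E_both) and
DNCI = SES_dispersal − SES_niche, with the scheme→process mapping
(dispersal = taxon totals, niche = site totals) isolated in one constant.
With more than two groups the index is reported per pair plus an overall
mean, since a single pooled value would average heterogeneous contrasts.

**Known limitation.** Because SIMPER contributions are per-taxon quantities,
the sorted profile of a presence/absence matrix is largely determined by its
taxon-occupancy multiset, which the dispersal-type null preserves exactly.
Tables whose group discrimination is carried by *consistent taxon
identities* — e.g. Gaussian salinity sorting, where the same specialists
recur across the sites of their group — are therefore reproduced better by
the dispersal-type null and score DNCI < 0 even under strong niche sorting.
Positive DNCI arises when between-site structure is carried by the site
margin (richness contrasts with quasi-exchangeable identities, as under
harshness filtering). The acceptance suite asserts the conventional
expectation (niche-sorted tables → DNCI > 0) and currently documents this
limitation as a failing test rather than weakening the check; the
accompanying E-value outputs let users inspect which null tracks their data.

## Networks and stability

Edges require |Spearman r| ≥ 0.8 (closed threshold; the open/closed
distinction is immaterial at float precision) and p < 0.01 from the t
approximation with average ranks; no multiple-testing correction by default
(matching the raw-threshold convention for these networks), with
Benjamini–Hochberg behind a flag. The 0.01 % mean-relative-abundance filter
is applied to the samples entering the specific network. Constant-abundance
OTUs have undefined rank correlations and produce no edges; isolated nodes
are excluded from the graph. Domain-restricted subnetworks run the same
code path on the restricted table.

Topology: diameter on the largest component; average path length over
connected pairs only (otherwise undefined on fragmented graphs); modularity
from seeded Louvain communities on the unsigned graph — the partition
algorithm is a documented choice, made for determinism, since threshold
networks are usually partitioned by whatever a GUI tool ships.

Fragmentation f = log(CL)/log(N) is base-invariant, 0 when connected, 1
when fully atomised, undefined below 2 nodes. Attacks rank nodes by
betweenness, degree, abundance, or randomly (seeded); static ranking on the
intact network is the default ("top k" semantics), adaptive re-ranking is a
flag; ties break lexicographically by taxon id; f is recomputed after each
removal with N = remaining nodes, and nodes isolated by removals remain in
the graph so f can reach 1.

## Pipeline

`PipelineConfig` (YAML) validates thresholds before any stage runs and
requires a seed; every stochastic stage derives a logged substream seed by
hashing (root seed, stage name). The manifest records config hash, seed and
every artifact; identical configs reproduce byte-identical outputs. A stage
failure halts the run with the failing stage named; partial outputs and the
manifest (with the failure recorded) are retained.

## Problem sizes

The validation suite uses 500-taxon / 30-sample / 20 000-read tables for
neutral-model recovery, 40-taxon / 16-site tables at 199 permutations for
DNCI, 43-taxon (4 × 10 members + 3 gatekeepers) / 30-sample tables for
network recovery and attacks, and 500 replicates of 12-sample tables at 199
permutations for PERMANOVA calibration — sizes at which each property is
statistically decidable while the whole suite stays fast enough to run on
every change.
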