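# Methods

`amphisel` implements the comparative-genomics workflow used to screen for
convergent molecular adaptation during vertebrate water-to-land
transitions: branch-site tests of positive selection under three foreground
designs, classification of the resulting genes and sites (PSG partition,
TAAS, EAASPS), and a birth-death analysis of gene-family expansion and
contraction with convergent-contraction calls. This note records the
models, the tunable parameters, the numerical choices, and what the
synthetic-data experiments do and do not demonstrate.

## Branch-site codon model

Substitution follows a Goldman-Yang style Markov process on the 61 sense
codons of the standard code. The unscaled generator is

    q_ij = pi_j                  synonymous transversion
         = kappa * pi_j          synonymous transition
         = omega * pi_j          nonsynonymous transversion
         = omega * kappa * pi_j  nonsynonymous transition

for codon pairs differing at exactly one position, zero otherwise, with
`pi` the F3x4 equilibrium frequencies (product of position-specific
nucleotide frequencies, stop codons excluded and renormalized; codons
unobserved in a gene are floored at 1e-6 and renormalized so the generator
stays irreducible).

Model A assigns each site to one of four classes:

| class | proportion | background ω | foreground ω |
|-------|-----------|--------------|--------------|
| 0     | p0        | ω0 ∈ (0,1)   | ω0           |
| 1     | p1        | 1            | 1            |
| 2a    | (1−p0−p1)·p0/(p0+p1) | ω0 | ω2 ≥ 1 |
| 2b    | (1−p0−p1)·p1/(p0+p1) | 1  | ω2 ≥ 1 |

"Foreground" branches are flagged in the Newick input with the `#1` suffix
(on a leaf name or after an internal node's closing parenthesis). The three
study designs flag the tetrapod ancestral branch, the mudskipper terminal
branch, or both; in the combined design both branches share one ω2.

Generators are normalized so one unit of branch length equals one expected
substitution per codon site averaged over site classes on background
branches; the simulator uses the identical convention, making it the exact
generative twin of the likelihood.

Site likelihoods are computed by Felsenstein pruning over the 61-state
space, with gap/ambiguous codons marginalized (all-ones partials),
alignment columns compressed to unique site patterns, and transition
matrices obtained by eigendecomposition of the symmetrized reversible
generator (`scipy.linalg.expm` is the fallback if the decomposition fails).
Per-node rescaling against underflow is enabled automatically for trees
with more than 40 nodes; smaller problems use raw products (float64 has
ample headroom at this depth) and fall back to the rescaled path if a site
underflows anyway.

### Maximum-likelihood fitting

Free parameters: κ, (p0, p1), ω0, ω2 (alternative model only; the null
fixes ω2 = 1), and a per-gene tree-scale factor. Branch lengths are the
species tree's relative lengths multiplied by that single per-gene ML scale
— a deliberate design choice over free per-branch lengths: at desk-scale
alignment lengths per-branch lengths are weakly identified, and the shared
topology/relative-length assumption matches how a species-tree-based
screen treats its genes. All parameters are optimized on log/logit scales
with bounded L-BFGS-B (ω0 ∈ [1e-6, 0.9999], ω2 ∈ [1, 999], κ ∈ [0.05, 50],
scale ∈ [1e-3, 100]; ftol 1e-8).

Multi-start policy: the null model starts from a fixed heuristic point
plus random restarts (2 starts by default). The alternative starts from
(i) the null optimum with ω2 barely above 1 — which guarantees
lnL_alt ≥ lnL_null for the nested pair by construction — (ii) the
independent heuristic point, and (iii) the null's κ/ω0/scale with
(p0, p1) = (0.45, 0.30) and ω2 = 6. Start (ii) and (iii) matter because
the null optimum is frequently degenerate (p0 + p1 at a boundary, e.g. the
null absorbing foreground *relaxation* by putting all sites in class 2a
with foreground ω = 1); from such a point ω2 has a flat or misleading
local gradient. Two-start and four-start fits agree to ~1e-6 lnL on
simulated batteries; the default was chosen as the smallest battery that
also escapes the degenerate-null trap described above.

### LRT, FDR, and the PSG partition

The test statistic is 2ΔL = 2(lnL_alt − lnL_null), compared with a χ²(1)
upper tail. This is conservative under the null (the true boundary null is
a 50:50 mixture of χ²(0) and χ²(1)); the suite asserts empirical rejection
≤ 0.08 at raw p < 0.05, and observes ~0-2%. Negative statistics (optimizer
artifacts) are recorded unclamped, get p = 1, and fail the 2ΔL > 0 gate.
BH-FDR (via `statsmodels`) is applied separately within each of the three
model batteries — the configurable choice documented in the pipeline; a
gene is a PSG when q < 0.1, 2ΔL > 0 and ω̂2 > 1.

Partition rule: union = called in the combined design, or called in both
single-foreground designs; a gene called only in one single-foreground
design is lineage-specific. The three sets are disjoint by construction.
Note an operational consequence verified in the synthetic batteries: a
gene with *strong* selection on one lineage is usually also detected by
the combined design (the shared ω2 still improves on its null), which
routes it to the union set. Lineage-specific sets fill up in the weaker,
realistic signal regime. Planted-truth tests therefore accept
{lineage-specific, union} for single-lineage plants and {union} for
shared plants.

### Bayes empirical Bayes site posteriors

BEB averages the per-site class posterior over a uniform discrete prior on
(p0, p1, ω0, ω2): the (p0, p1) pair on the triangular simplex grid, ω0 on
(0,1), and ω2 uniform on (1, 11], each with `grid_size` points (default
10; 5 is a documented speed setting used by the end-to-end pipeline
tests). Grid weights are the normalized data likelihoods. κ, branch
lengths, codon frequencies — and the generator normalization — are held at
the alternative-model MLE; freezing the normalization is what lets the
site-class likelihood factorize over grid dimensions (121 pruning passes
instead of 5500). Positively selected sites (PSS) are columns with
posterior(class 2a + 2b) strictly greater than 0.95.

Site-level detection is information-limited: each foreground branch
contributes only its end state, so a site can only be confidently called
when substitutions actually occurred on the foreground branches and the
empirical class-2 mass is appreciable. The planted-site battery is
therefore built in an informative regime — foreground branches scaled to
~3 expected substitutions per selected site (factor 2.5 over the default
tree), ω2 = 8, 600 codons, and a planted 300-column block of class-2a
sites. In that regime >80% of planted sites exceed 0.95 posterior while
null alignments flag <2% (observed ~0%). On the default tree with mixture
sampled classes, recovery is 30-50% — the expected behavior of the
statistic, not a defect; gene-level LRT power is much higher than
site-level power throughout.

## TAAS / EAASPS

A column is a TAAS when the target-lineage and background residue sets are
disjoint after removing gaps, `X` and `*` (classes 1-4 by whether each side
is fixed for a single residue). EAASPS are PSS∩TAAS columns whose
exclusive pattern holds in an extended ortholog panel: the fraction of
extended target species carrying a target-set residue AND the fraction of
extended background species carrying a non-target residue must each
strictly exceed 0.9 (the stricter both-sides reading of the >90% rule;
`require="either"` is available). Species with gaps or missing residues
are excluded from the denominators; empty panels are an error rather than
a vacuous pass. Domain annotation is interval containment on 1-based
inclusive protein coordinates.

## Birth-death gene families

Gene copies are gained and lost at a single rate λ per gene per million
years (equal birth and death) along the time-calibrated 13-taxon tree
(elephant shark outgroup included). The parent→child size transition has
the classical closed form in α = λt/(1+λt); size 0 is absorbing. The
matrix builder vectorizes the alternating series with binomial lookup
tables — it matches `expm` of the truncated generator to ~1e-12 even at
α = 0.8.

Family likelihoods: pruning over count states 0..C_max with
C_max = 2·max(observed) + 10, root size marginalized over a uniform prior
on 1..C_max conditional on a non-extinct root (the range is configurable,
and analyses of simulated matrices pass the known simulation root range).
λ is estimated by bounded scalar ML over all families jointly (tolerance
<0.1% relative). Per-family p-values are Monte-Carlo tail probabilities:
under the fitted single-rate model the null likelihood distribution is the
same for every family, so one shared pool of `n_sim` simulated families
(default 1000) is scored once and each observed family's p is its
ECDF position with the add-one correction p ≥ 1/(n_sim+1). Branch-level
expansion/contraction calls come from most-probable ancestral counts
(max-product DP, first-maximum tie-break; ties in inferred counts give
"none"). Convergent contractions are families with p < 0.05 and
"contraction" on both named branches. No numeric agreement with any
specific CAFE release is claimed; the Monte-Carlo definition is chosen for
transparency and testability.

## Synthetic data

The default study mirrors a 12-taxon vertebrate design — human, mouse,
cattle, chicken (tetrapods), coelacanth, mudskipper, and six aquatic
teleosts, plus elephant shark for family analyses — on a time tree with
TimeTree-style round divergence times (root 465 My). For selection
analyses the tree is rescaled to a total length of 3.0 expected
substitutions per codon site, a realistic vertebrate-wide coding
divergence. Default simulation mixture: p0 = 0.5, p1 = 0.3, ω0 = 0.1,
κ = 2, uniform codon frequencies; family simulations default to uniform
root sizes on 1..10.

Codon alignments are evolved by exact transition sampling from the same
eigendecomposed matrices the likelihood uses (not Gillespie); family
matrices by sampling the closed-form birth-death law branch by branch.
Planted truths (site classes, defective CDS, TAAS/EAASPS columns with
chosen conservation fractions, family contractions) are returned as
machine-readable tables, and all randomness flows from a single integer
seed.

What the generators do not emulate: indels and alignment error (alignments
are simulated gap-free; the trimmer is exercised on constructed cases),
ortholog-inference error, codon-frequency variation across genes,
among-branch rate variation beyond the single per-gene scale, and
lineage-specific λ variation. Passing tests therefore demonstrate
correctness of the statistics and the pipeline's mechanics under the
model's own assumptions, not robustness to real-data misspecification.

## Problem sizes and runtime

The shipped batteries are desk-scale by design: 100 null genes × 200
codons for LRT calibration; 20 genes × 500 codons at ω2 = 4 for power and
recovery; 3+3 genes × 600 codons for BEB; 500 families for λ recovery and
20 planted replicates for contraction calls; a 20-gene end-to-end battery
(16 null × 300 codons, 4 selected × 500 codons) run twice to assert
byte-identical reproducibility. A full branch-site fit (null +
alternative, 12 taxa, 500 codons) takes a few seconds on one CPU.

## Known limitations

- The per-gene tree-scale parameterization cannot express per-branch rate
  variation; strongly heterotachous genes would be better served by free
  branch lengths (not implemented).
- χ²(1) rather than the boundary mixture null makes the LRT conservative;
  the df is configurable in `lrt`.
- BEB's frozen generator normalization and the ω2 ≤ 11 grid cap are
  approximations; both are configurable knobs.
- The Monte-Carlo family p-value is conditional on the fitted λ and the
  declared root prior; it is not CAFE's (undocumented) exact procedure.
- Lineage-specific vs union PSG assignment is an operational rule on
  detection patterns, not a biological ground truth; see the partition
  discussion above.
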