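# Methods

This note documents the models, estimators and numerical choices behind
`arctos`, and what the synthetic-data experiments do and do not establish.

## Genotype model and filtering

Genotypes are biallelic diploid codes {0 hom-ref, 1 het, 2 hom-alt, −1
missing}; haploid calls can be promoted to homozygous diploid codes so that
haploid and diploid panels share one code path.  VCF coordinates are 1-based;
all window arithmetic is 0-based half-open, converted only at I/O
boundaries.  SNP filtering runs individuals-first (default max 10% missing
per sample), then sites (max 1% missing, minor allele count ≥ 2), then
thins to at most one SNP per 20 kb window.  The thinning keeps the *first*
SNP of each window: the choice is arbitrary in principle, so a deterministic
and idempotent rule was preferred over a seeded draw.  Multi-allelic records
are dropped, not decomposed.

## Windowed heterozygosity and ROH calling

He per window is n_het/(n_hom + n_het) over called sites in non-overlapping
20 kb windows.  ROH calling is seed-and-merge: seeds are maximal runs of
windows below the He threshold; adjacent seeds separated by at most
`max_gap_windows` (default 2) above-threshold or undefined windows merge
*iff* the merged region's called-site-weighted mean He stays below the
threshold; segments spanning ≥ `min_windows` (default 10, i.e. ≥ 200 kb)
are reported.  A "below-average-He region" criterion cannot be implemented
by a pure per-window rule, hence the region-mean guard; setting
`max_gap_windows=0` recovers strict per-window behaviour.  Windows without
called sites are treated as gaps: they can be bridged and count toward the
gap budget, because an assembly gap is evidence of nothing.

Defaults: threshold 0.05% for empirical data; 0.0025% for simulated
error-free data (20× lower — simulated genotypes carry no error floor).
F_ROH divides total ROH length by the *callable* genome (windows with ≥ 1
called site), not the nominal assembly length.  The across-chromosome
standard deviation of F_ROH separates recent chance inbreeding (long ROHs
on a few chromosomes → high sd) from long-term small Ne (uniform → low sd).
The residual heterozygosity expected inside an identity-by-descent tract of
age t generations is 2·u·t (two branches of length t accumulating mutations
at rate u).

## Distances, clustering and residual diagnostics

The uncorrected distance d estimates the mean per-site difference of two
randomly drawn haplotypes — hence d(i,i) = He_i/2 exactly, and the diagonal
is meaningful rather than zero.  The allele-sharing distance (ASD,
mean |g_i − g_j|/2) instead scores het/het pairs as zero difference: d is
the coalescent-facing quantity (used for D_XY), ASD the genotype-facing one
(used for clustering).  Euclidean distances use pairwise-complete sites
rescaled by n_total/n_joint so missingness does not shrink distances.

PCoA is plain Gower double-centering + eigendecomposition; negative
eigenvalues are reported and their axes dropped.  BioNJ follows the
variance-weighted neighbour-joining update (variances initialised to the
distances, convex-combination weight λ clamped to [0,1]); ties in the
selection criterion break by the lowest original-label-index pair, making
output deterministic.  On additive matrices BioNJ reproduces the generating
topology and branch lengths exactly; this is tested, together with
topological agreement with an independent NJ implementation under small
perturbations.  Path-length residuals are patristic distance minus observed
distance; admixed samples show positive residuals (attraction) toward both
donor clades, because no tree can be as close to two clades at once as an
admixed genome is.  The Mantel isolation-by-distance test regresses D_XY on
haversine great-circle distances between population centroids and obtains p
by seeded permutation of population labels (999 by default).

## f-statistics

f3(A;B,C) = mean over sites of (a−b)(a−c), bounded in [−0.25, 1] per site;
negative iff a is intermediate, and the extreme −0.25 corresponds to fully
diverged donors contributing equally.  The heterozygosity-normalised
variant divides the summed numerator by the summed target heterozygosity
2a(1−a) (ratio of sums).  Two facts only hold on the normalised scale, so
windowed scans default to it: (i) window scores can exceed ±5, which the
raw statistic never can, so the ±5 window-exclusion rule only bites there;
(ii) post-admixture drift raises the normalised score linearly by 1/(4·Ne)
per generation, giving the zero-crossing time −b·4·Ne for an initial score
b.  Windows are anchored at coordinate 0 per chromosome, 50 kb wide, last
partial window retained; windows beyond ±5 are excluded from the genome
mean but still count toward the proportion-negative metric.  Fst is the
Weir & Cockerham (1984) θ, aggregated as a ratio of sums over sites, with
negative estimates reported as-is.  No small-sample bias correction is
applied to f3/f4 (none is standard for these scan-style uses); block
jackknife errors are out of scope.

## Quartet discordance and the ingroup-score

For each population quartet, each gene tree is weighted by the fraction of
one-tip-per-population combinations inducing each unrooted topology —
exact enumeration up to 10⁴ combinations, seeded uniform sampling of 10⁴
beyond that.  The topology of a combination is read off with the four-point
condition on edge-count (topological) distances; exact ties (polytomies)
split their weight.  The species topology q1 comes from pruning a reference
population tree (equivalent to minimising Robinson–Foulds distance over the
three candidates, which is cross-checked in the tests).  t2/t3 labels are
fixed on *genome totals* before per-chromosome D values are computed —
re-ranking per chromosome would bias |D| and hence z upward.  z uses the
sample (n−1) standard deviation across chromosome blocks; sd = 0 yields an
infinite z, reported as such.  Genome-total ties t2 = t3 resolve by
lexicographic order of the induced ingroup pairs and give D = 0.

The ingroup-score of a pair (x,y) is n_t2/n_alt: rejected quartets in which
the pair forms an ingroup of the favoured alternative, over quartets in
which the pair does not group in q1 (n_alt + n_t1 = C(npops−2, 2), verified
internally).  With few populations the denominator is tiny and the
*complementary* pair of a rejected quartet (q2 has two ingroups) can tie
the score of the truly introgressed pair; the raw n_t2 count is the more
robust ranking in small panels, and the demo test uses it.  At realistic
panel sizes (dozens of populations) the dilution makes the score behave as
intended.

## Microsatellite genotyping

A read contributes a repeat count only if it starts ≥ 1 bp before the
repeat and extends ≥ 1 bp past the end of the repeat *as observed in the
read* (so expansions are measurable); reads ending inside the repeat, or on
a partial motif, are truncated and discarded; a motif or anchor mismatch at
the expected position is discordant and tallied separately.  Scoring:
alleles below depth 3 are dropped; 0/1/2 surviving alleles give
missing/homozygote/heterozygote; with > 2 alleles the two deepest are kept
unless the 2nd and 3rd tie, which scores the locus homozygous for the best
allele.  A residual tie between the 1st and 2nd deepest prefers the smaller
repeat count (determinism).  The read simulator adds optional per-base
errors and ±1-unit stutter; it is a fixture generator, not part of scoring.

## The Wright–Fisher engine

Haplotypes are sorted arrays of derived-allele positions on one linear
chromosome.  Each generation, every population synchronously draws, per
child: a source population (backward migration — the child is an immigrant
with probability given by its row of the migration matrix; the convention
differs from forward migration at second order in m), two parents from the
source, and one recombinant gamete per parent (Poisson(r·L) crossovers at
uniform positions; Poisson(µ·L) new mutations).  Census size is used as Ne.
Gene conversion, selection and sex chromosomes are not modelled.

Multi-allelic handling is exact: a mutation event landing on a position that
ever carried an allele receives a tiny fractional offset (integer part =
genomic site, so recombination ordering is preserved), and a site is
excluded from outputs only when two origins actually coexist at observation
time.  An earlier draft flagged positions permanently on collision; that
over-excluded long-lived common sites and biased diversity down by up to
~25% at larger scaled Ne — the exact rule leaves equilibrium He unbiased
(−1.0% ± 1.4% over 20 replicates against 4Neµ).  Sites fixed in the whole
metapopulation are pruned periodically (every 64 generations) and recorded.

Every population owns an independent seeded random substream (keyed by the
scenario seed and the population name), so with m = 0 a joint run is
site-for-site identical to solo runs — a tested invariant.  Observation
(sampling individuals, trajectory Fst) uses a separate stream and never
perturbs the dynamics.  Fixed seed ⇒ bit-identical results.

Multi-chromosome datasets are produced as independent engine runs with
per-chromosome derived seeds.  This reproduces free interchromosomal
assortment and between-chromosome genealogical variation but not a shared
pedigree; for the long-timescale statistics used here the approximation is
inconsequential, and it parallelises trivially.

### Scenario families and desk-scale profiles

Builders encode four experiment families with full-scale defaults
(Ne = 5000, L = 50 Mb, µ = 1.2×10⁻⁸, r = 1×10⁻⁸ per site per generation,
25 000 burn-in generations):

- `scenario_stepping_stone_split(m, ...)` — ancestor → two isolated
  populations → each splits in two, forming the chain p11–p21–p22–p12
  (peripheral p11/p12; the adjacency places p12 next to p22, so gene flow
  regroups old sisters apart) with per-link backward rate m.
- `scenario_star_to_chain(m, ...)` — five populations split simultaneously
  and drift in isolation (the star: equal pairwise divergence), then chain
  migration starts.  Adjacent divergences collapse within ~1/m generations
  while distant ones persist, so in-between populations transiently look
  admixed: f3(pX;pY,pZ) < 0 exactly when Y < X < Z.  This is a *transient*:
  at small desk-scale Ne the pattern erodes again within a few 1/m, so the
  tests observe the (1/m, 2/m] window.  (A symmetric-migration star phase
  was tried and rejected: at its migration–drift equilibrium the in-between
  triplets settle slightly positive, and the sign rule never appears.)
- `scenario_pulse_admixture(a, ...)` — two diverged sources found an
  admixed population in one generation; with gene flow stopped, the
  normalised f3 recovers at 1/(4·Ne) per generation.
- `scenario_bottleneck_roh(ne_new, t, ...)` — size reduction for ROH
  equilibration.

`rescale(scn, Q)` maps Ne→Ne/Q, generations→/Q, µ,r,m→×Q, preserving
θ = 4Neµ, ρ = 4Ner and Ne·m exactly.  Drift becomes coarser, so Q must not
push any census size below 20 diploids.  The test suites run at scaled
sizes chosen for Monte-Carlo precision: equilibrium-He at Ne = 100, 1 Mb,
µ = 6×10⁻⁷ (θ matched to the full-scale profile) over 20 replicates;
f4/Fst decay at m = 0.02, Ne = 100, 0.4 Mb over 4 replicates; the pulse
slope at Ne = 200, 0.8 Mb over 6 replicates; the star-to-chain sign rule at
Ne = 100, 1.2 Mb over 10 replicates (the in-between f3 expectations near
the chain ends are tiny, so this suite needs the most genome); ROH
equilibria at Ne ∈ {50, 200, 1000} on 2 Mb with µ and r ×5, forked from a
single burned-in Ne = 1000 ancestor.

### What the synthetic data do not show

The generator produces neutral, error-free, fully called, equally covered
genotypes on equal-length chromosomes with uniform recombination.  Real
resequencing panels add genotype error (which floors window He — the reason
the empirical ROH threshold is 20× the simulation one), missingness,
reference bias, selection and variable recombination.  Passing simulation
suites therefore validates the estimators and the demographic algebra, not
robustness to those artefacts.

## Pipeline and reproducibility

Stages are pure functions from named artifacts to files; each stage writes
a manifest (parameters, derived seed, SHA-256 of inputs and outputs,
package version), so reruns are verifiable and any stage can be reproduced
in isolation.  The global seed is split into per-stage substreams by
hashing the stage name — adding a stage does not perturb the others.  The
demo dataset (6 populations × 10 diploids, 12 × 85 kb chromosomes, one
pulse, one bottleneck) is byte-identical for a fixed seed and gives every
downstream stage a detectable signal.
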