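# Methods

## Model and scope

`ychrono` operates downstream of variant calling: its input is a joint
multi-sample VCF of haploid Y-chromosome genotypes, a BED mask of callable
territory, sample metadata, and optionally a rooted Newick topology and an
ISOGG-style catalog of known SNPs. Upstream read alignment and genotype
calling, and maximum-likelihood tree search with bootstrap, are out of
scope — an externally computed topology can be supplied and annotated
instead.

The genealogical model is the standard one for the NRY: no recombination,
so all variants are consistent with a single rooted tree; under infinite
sites each mutation hits a fresh position and every site's derived-allele
carrier set is exactly the tip set of one branch. Recurrent mutation
(e.g. a position hit independently on two unrelated branches) violates
this and is detected, flagged and reported rather than modeled.

## Filter cascade

Stage order is fixed and documented: (1) mask/indel removal, (2) depth,
(3) missingness, (4) monomorphic removal.

* The depth stage converts genotypes with known depth strictly below
  `min_depth` (default 2) to missing rather than deleting sites. This
  keeps the stages composable: site removal is then governed entirely by
  the missingness stage. A matrix without per-genotype DP passes the
  stage unchanged with a logged warning.
* Missingness uses a strict inequality (`fraction > max_missingness`,
  default 0.1), so a ten-sample site with exactly one missing call is
  kept.
* Monomorphism is evaluated over non-missing calls only and runs last,
  because the depth stage can render a site monomorphic.

The cascade is idempotent, and its report satisfies
`sites_out = sites_in − Σ sites_removed` with stage-to-stage chaining.

## Polarization and tree construction

The outgroup's allele defines the ancestral state; where the outgroup
carries ALT the site's polarity flips. Sites with a missing outgroup call
and sites left with no derived ingroup call are dropped and counted.
Heterozygous diploid genotypes on the haploid Y are treated as missing
(conservative; they are most plausibly artifacts), and multi-allelic
records are reduced to the major ALT with minor-ALT carriers set missing,
so the internal model stays strictly biallelic with one site per position.

`build_tree` constructs the perfect phylogeny directly from carrier sets:
distinct derived sets are accepted largest-first while they remain a
laminar family (pairwise nested or disjoint); each accepted set becomes a
node nested by containment; samples attach to the smallest accepted set
containing them. Identical samples therefore share a node, unresolved
orders appear as polytomies, and sets conflicting with an accepted set
(recurrence, genotyping error) are left for parsimony placement. Missing
calls are treated as ancestral for set definition only.

`assign_snps_to_branches` is a two-state Sankoff/Fitch dynamic program,
vectorized across sites, with the root fixed to the ancestral state and
missing tips unconstrained. At cost ties the traceback prefers the
derived state, which places gains on the earliest (most rootward) branch
consistent with the minimum score — a deterministic tie-break. Sites with
minimum score ≥ 2 are recorded as recurrent.

## Dating

rho for a node is the arithmetic mean, over its eligible descendant tips,
of mutation events on the tip-to-node path; `T = rho / (L·mu)`.

* `mu` defaults to 0.76e-9 mutations/site/year with 95% bounds 0.67e-9
  and 0.86e-9; `L` defaults to the mask's effective length (10.45 Mb in
  the default mask) and both are configurable.
* The primary 95% interval propagates only the rate interval:
  `t_low = rho/(L·mu_hi)`, `t_high = rho/(L·mu_lo)`. The sampling
  variance of rho itself is reported separately as the star-genealogy
  standard error `sigma_rho = sqrt(rho/n)` and never alters the interval.
  This choice reproduces published interval behavior for this class of
  analyses; its known cost is that intervals understate total uncertainty
  when `n` is small.
* Display rounding is half away from zero, one decimal for values
  ≥ 1 kya and two below. Note that rescaling a *rounded* point estimate
  by the rate ratios does not always reproduce an interval computed from
  unrounded internals — a ±0.05 kya wobble at one printed decimal — so a
  handful of published intervals differ in the last digit from
  `rescale_by_rate_bounds` of their printed point values; the function is
  exact for the instances asserted in the acceptance suite.
* Eligibility: with `high_coverage_only` (default) only tips whose
  metadata marks them as high-coverage complete sequences enter rho,
  because low-coverage VCF-only samples systematically miss derived
  calls and would bias rho downward. Nodes with fewer than two eligible
  tips are listed as undated, never silently dropped.

## Simulator

The generator produces the conditions the pipeline is designed for, with
known truth:

* **Tree**: lineages start at the tips and are joined pairwise at `n−2`
  uniform random ages below the root age, the last join fixed at the root
  age (default 20,000 years, 20 tips). This is clock-like and ultrametric
  by construction; it is *not* a coalescent with an effective population
  size — the dating model consumes only branch durations, and arbitrary
  demographies can be supplied as an aged Newick tree.
* **Mutations**: per branch `Poisson(mu·L·branch_years)` with `mu` and
  `L` at the pipeline defaults (0.76e-9, 10.45 Mb), positions uniform
  without replacement within the mask. `recurrent_fraction` reuses a
  position from an unrelated branch to inject infinite-sites violations.
* **Corruption**: missingness and low-depth (DP = 1 vs 30) applied per
  call at configurable rates, for stressing the filter cascade.
* All randomness derives from one seed through fixed per-stage
  substreams, so datasets are reproducible and stages independently so.

What the simulator does not emulate: reference/alignment artifacts,
sequencing error producing false derived singletons, rate variation along
the chromosome or among lineages, ancient-DNA damage, and correlated
missingness (real low-coverage samples miss calls in blocks). Passing
tests therefore demonstrate correctness of the algorithms under the
stated model, not robustness to every real-data pathology.

## Problem sizes and numerical choices

The test and acceptance workloads use 20-tip trees, 200 mutation
replicates for estimator bias, 50 simulations for topology recovery, and
an exhaustive parsimony oracle up to six tips — sizes chosen to give
stable Monte-Carlo checks (3 standard-error bands) in seconds on one CPU.
Parsimony DP uses a large finite penalty (1e9) instead of infinities;
scores are exact integers recovered by rounding. Rounding of reported
times is half away from zero via `decimal`. Degenerate inputs (empty
matrix, empty clade, zero-length mask interval, absent outgroup, tip
without data) raise `InputError` rather than propagating silently.

## Known limitations

* The clade partition is defined relative to the loaded sample set;
  "private" means a single carrier among the analyzed samples, not
  absence from all databases.
* Placement uncertainty of recurrent/incompatible sites is not modeled;
  they are flagged with their parsimony score and listed, mirroring the
  practice of drawing such branches as provisional.
* The rate-interval CI ignores rho sampling noise (reported separately);
  for nodes with few tips the true uncertainty is larger.
* The VCF reader accepts diploid-encoded haploid calls but does not joint
  re-genotype; GVCF handling and liftover are out of scope.
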