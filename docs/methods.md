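# Methods

## The model

`esrtree` infers, for every branch of a fixed rooted population tree, the
effective sex ratio (ESR)

    xi = Nef / (Nef + Nem),

the female share of the effective population, from the joint analysis of
autosomal (A) and X-linked (X) SNP allele counts.  The statistical engine
is a hierarchical Bayesian model of allele-frequency drift:

* **Leaves.** Observed reference-allele counts `y_ij` are binomial draws
  of `n_ij` genes given the latent leaf frequency `x_ij` (Hardy–Weinberg
  sampling).
* **Branches.** Along the branch above node `i`, the frequency evolves by
  pure drift for `tau_i = t_i / (2 Ne_i)` diffusion-time units.  The
  transition law is Kimura's time-dependent diffusion solution: a
  continuous Gegenbauer/Jacobi eigen-series on (0,1) plus absorption atoms
  at 0 (loss) and 1 (fixation).  There is no mutation, selection or
  migration in the inference model.
* **Root.** Root frequencies follow Beta(alpha, beta), re-parameterized as
  `mu = alpha/(alpha+beta) ~ U(0,1)` and `nu = alpha+beta ~ Exp(1)`, both
  estimated.
* **Two genetic systems.** Each system has its own frequencies, branch
  lengths, sample sizes and root-beta parameters.  Wright's sex-specific
  effective sizes,

      Ne_A = 4 Nf Nm / (Nf + Nm),     Ne_X = 9 Nf Nm / (2 Nf + 4 Nm),

  tie the two drift times of one branch to a single ESR:

      xi_i = 2 - (9/8) tau_X,i / tau_A,i ,

  so 0 < xi < 1 confines the pair to the wedge
  `9 tau_X/16 < tau_A < 9 tau_X/8`.  The joint prior on
  `(tau_A,i, tau_X,i)` is uniform on this wedge intersected with
  `[1e-4, 10]^2`.
* **Polymorphism conditioning.** SNP tables contain only sites segregating
  in the pooled sample; the fraction of sites lost to fixation carries
  information about branch lengths.  The likelihood of each layer is
  therefore divided per site by `P(polymorphic | x_rj, tau, n)`, computed
  from the distribution of the number of ancestral lineages surviving to
  the root: each leaf starts with its sample size, lineage counts are
  thinned along branches and convolved at internal nodes, and a site is
  monomorphic exactly when all surviving root lineages carry the same
  allele, giving `P(poly | x_r) = 1 - sum_k P(k)[(1-x_r)^k + x_r^k]`.
  Following the convention that makes this term depend on the latent root
  frequency, the beta prior is read as the root-frequency distribution of
  polymorphic sites.  The same maximum sample size is used at every site
  (the observed per-population maximum), so one lineage-count distribution
  per system serves all sites.

Posterior per-branch ESR draws are transformed per MCMC iteration, never
from ratios of posterior means.  The support statistic `S = 1 - 2|p - 0.5|`
(`p` = fraction of draws with `xi > 0.5`, ties counted as "not greater")
quantifies evidence against a balanced ESR: S = 0.05 means 97.5% of draws
fall on one side.  `Q = tau_A/tau_X` (0.75 under balance) is reported from
posterior means for comparability.  Topologies and likelihood variants are
ranked by DIC = `2*Dbar - D(theta_bar)`; the deviance is the conditional
binomial log-likelihood, recorded at thinning points, and `D(theta_bar)`
uses running means of all latent frequencies (kept online instead of
storing latent snapshots).

## Numerical choices

* **Eigen-series.** Jacobi polynomials `P_n^(1,1)` are generated by a
  division-free three-term recurrence; the series is truncated once
  `i(i+1) tau > 72` (tail < 1e-15 relative; doubling the order changes
  values by < 1e-8).  Below `tau = 0.005` the series cancels
  catastrophically and the kernel switches to a truncated Gaussian with
  matched mean `p` and variance `p(1-p)tau`, tails assigned to the atoms.
  The series coefficients and absorption-mass series were validated
  against an exact Wright–Fisher transition-matrix oracle (N = 200; total
  variation <= 0.002 plus machine-precision conservation, martingale and
  variance identities).
* **Atoms as boundary strips.** The sampler works on continuous
  frequencies in [0,1]; the absorption atoms are represented by strips of
  width `w = 1/(2 n_max)` at each end, carrying `mass/w` density.  A value
  inside a strip *is* the absorbed state: it is read as exactly 0/1
  wherever it enters the binomial likelihood or serves as an ancestral
  value of a drift kernel.  This exact-reparameterization reading matters:
  if strip values are instead treated as small interior frequencies, the
  sampled model can emit polymorphic counts from "absorbed" populations
  while the conditioning term assumes absorption implies monomorphism, and
  that inconsistency rewards inflated drift times without bound (we
  measured internal-branch estimates 2–3x too long before adopting the
  strict reading; a brute-force quadrature posterior on a one-SNP instance
  confirmed the sampler targets the corrected model exactly).
* **Lineage counts.** Production code uses a normal approximation binned
  at half-integers: the mean is computed by an exact, numerically stable
  positive series, the variance by Griffiths' asymptotic formula; for 12
  or fewer lineages the exact alternating (Tavaré) series is safe in
  double precision and used directly.  Total variation against the exact
  distribution is <= 0.03 over the method's operating range (checked for
  i <= 25, tau in [0.1, 0.5]).  Distributions are truncated at cumulative
  upper-tail mass 1e-10 before convolution, and the leaf-to-root recursion
  is cached per node so a branch-length proposal recomputes only the path
  from the changed branch to the root.
* **Proposals.** Frequencies: per-node vectorized reflected uniform walks
  (sites are conditionally independent).  Hyper-parameters: reflected walk
  for `mu`, log-scale walk with Jacobian for `nu`.  Branch pairs: the
  autosomal component is reflected into the wedge section allowed by the
  current X value, then the X component into the section allowed by the
  proposal, and both are accepted together.  Because each component's
  support depends on the other component, the proposal is not symmetric;
  the Metropolis–Hastings ratio includes the exact reflected-proposal
  densities (reflection-image counts).  Omitting this correction is an
  easy mistake to make and measurably tilts weakly-identified branches.
  Single reflections suffice at tuned scales but folding is iterated for
  safety.
* **Adaptation.** 20 pilot runs of 500 iterations (defaults) multiply each
  block's half-width by 1.25 (or its inverse) whenever acceptance leaves
  [0.25, 0.40]; scales are frozen afterwards, preserving detailed balance
  for the main run.  Chain state continues from the pilots into burn-in.
* **Schedule and reproducibility.** Per iteration: one frequency sweep per
  system (leaves, internal nodes, root), one `(mu, nu)` update per system,
  one joint branch-pair update per branch, in fixed order, driven by a
  single seeded generator; identical seeds give bit-identical chains.

## The simulators

The *forward* mode draws root frequencies from a beta distribution and
propagates binomial Wright–Fisher sampling with `2 Ne^(sys)` genes per
generation along every branch, rejecting sites monomorphic in the pooled
sample — exactly the inference model's data-generating process, used to
isolate sampler correctness from model mismatch.

The *coalescent* mode mirrors the study design the method targets: sampled
gene lineages are traced backward through the population tree,
generation-by-generation in distribution — within a population, a pair of
lineages coalesces with the per-generation probability `1/(2 Ne^(sys))`
implied by Wright's formulas, and waiting times between events are drawn
from the matching exponential race (no pedigree is constructed; loci are
strictly independent).  Sex-specific migration between two designated
leaves moves autosomal lineages at rate `(m_f + m_m)/2` and X lineages at
`(2 m_f + m_m)/3` (an X lineage resides in a female two-thirds of the
time).  Census sizes may change instantaneously at stated generations;
expected drift times then use the harmonic-mean size along the branch.
Each retained locus carries exactly one mutation (Poisson-thinned on total
genealogy length, placed uniformly), making every site bi-allelic and
polymorphic; ancestral/derived maps to reference/alternate with
probability 1/2.  Pairwise coalescence times were validated against
`2 Ne_A` and `2 Ne_X` and the generated counts against closed-form drift
moments (heterozygosity decay and pairwise divergence within 1%).

What the coalescent mode shares with real data: tree-shaped divergence,
sex-specific inheritance, ascertainment of polymorphic sites, mutation-
generated U-shaped root spectra, finite samples.  What it omits: linkage
between sites, recurrent mutation, selection, gene flow beyond a single
leaf pair, and genotyping error — so passing recovery tests demonstrate
statistical correctness under the model's assumptions plus the stated
violations (size changes, migration, ascertainment), not robustness to
everything real data can do.

Discovery-panel ascertainment draws ghost-individual gene counts
hypergeometrically (genes within a population are exchangeable), keeps
sites polymorphic among pooled ghost genes and removes the ghosts from the
returned counts.  Pseudo-replicates are uniform without-replacement
subsamples, independent across replicates.

## Study designs and problem sizes

The canonical scenarios (`esrtree.scenarios`) fix the study conditions: a
50,000/50,000 ancestral population (polymorphism overwhelmingly ancestral),
50 diploid females sampled per population (100 genes in both systems), and
5,000 SNPs per system by default.  Three-population designs split at
200/400 generations (mutation rate 5e-7), four-population designs at
1,000/3,000 or 2,000/4,000 generations (1.5e-7), with branch censuses
setting the per-branch ESR.

The test suite and the acceptance script run these designs at reduced
scale — 400–2,000 SNPs per system, one to three replicates, pilot runs of
5–6 x 120–150 iterations, burn-in 1,500–2,000 and 2,500–3,000 sampling
iterations thinned every 10 — sizes chosen so a replicate's posterior-mean
ESR scatters with a standard deviation of roughly 0.05–0.10 around the
truth (measured: 0.06/0.10/0.03/0.15 across the four branches of the
three-population biased design at 1,500 SNPs) and averages over replicates
land within the stated tolerances.  Internal branches are the least
identified and dominate the residual spread.

## Known limitations

* The polymorphism conditioning assumes the equal-maximum-sample-size
  convention; strongly site-varying sample sizes are approximated.
* Migration during divergence, recent mutation in small ancestral
  populations, and sex-biased dispersal bias the ESR in the directions the
  robustness tests document (female-biased dispersal inflates xi).
* The normal lineage-count approximation degrades for very small drift
  times combined with moderate lineage counts (TV up to ~0.04 near
  tau = 0.05, i = 10); the exact small-i path bounds the effect in the
  recursion.
* DIC comparisons between the conditional and unconditional likelihood
  variants compare different likelihood functions, as is conventional for
  this model family; differences should be read directionally.
* Single-chain inference: convergence beyond trace inspection and the
  pilot acceptance log is the user's responsibility (the chain TSV makes
  any external diagnostic possible).
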