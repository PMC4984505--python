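# Methods

`matriflow` asks whether a nominally panmictic marine population hides
maternally founded breeding units ("matrilines") that exchange migrants
asymmetrically.  It combines five analysis layers — mtDNA haplotype
diversity, a weighted median-joining haplotype network with matriline
assignment, microsatellite diversity/differentiation statistics,
structured-coalescent Bayesian inference of gene flow, and
heterozygosity–fitness correlations on a relative condition index —
plus a synthetic-data generator that provides ground truth for every
layer.  This note records the models, the defaults that matter, the
numerical choices, and what the synthetic tests do and do not show.

## Sequence diversity (mtdna)

Haplotypes are collapsed from an aligned mtDNA fragment (355 bp by
default in the generator).  Haplotype diversity uses Nei's unbiased
estimator `Hd = n/(n−1) (1 − Σ p_i²)`; nucleotide diversity is the mean
pairwise difference per site over all sequence pairs.  Differentiation
between groups is a one-level AMOVA F_ST on haplotype identity (0/1
distances), which reduces to comparing haplotype frequencies; its
p-value is a label permutation test with `p = (hits + 1)/(n_perm + 1)`.
Gaps and ambiguity codes are rejected by default; `on_ambiguity="mask"`
drops affected columns instead.

## Haplotype network and matrilines (haplonet)

Distances weight transversions `tv_weight` (default 8) times a
transition.  The median-joining construction relaxes the minimum
spanning network by epsilon (default 35): an edge is admitted when its
weight is within epsilon of the level at which its two clusters first
join under Kruskal growth.  Median vectors come from connected triplets
by position-wise majority consensus; a candidate is admitted when its
three-way connection cost is within epsilon of the best candidate, the
construction iterates to fixation (cap 10 rounds, logged), and median
vectors left with degree ≤ 2 are deleted as obsolete.  Because the
weighted consensus median can occasionally be costlier than a direct
link, the final network is unioned with the epsilon-relaxed minimum
spanning network of the observed haplotypes, so MSN containment holds
by construction.

Maximum-parsimony post-processing keeps exactly the nodes and edges
used by at least one minimum-length Steiner tree over the observed
haplotypes: median-vector subsets are enumerated (≤ 16 medians;
beyond that the full node set is used and a warning logged) and
spanning trees are walked in increasing weight, capped at 10,000 trees.
Matrilines anchor on the three most frequent haplotypes; each satellite
is assigned, within every shortest tree, to the main haplotype it
reaches without passing through another main, and the most frequent
connection across trees wins.  Ties break by smaller mean path weight,
then larger main-haplotype frequency, then node name — fully
deterministic, so assignment is invariant to input order.  Divergence
between haplotypes is reported in unweighted base pairs even though the
network is built on the weighted metric.

## Microsatellite statistics (msat)

* **He** is Nei's unbiased expected heterozygosity; **Ar** is
  hypergeometric rarefaction to a common gene count; **F_IS** and
  **F_ST** are Weir & Cockerham (1984) estimators (multilocus sums of
  the variance components), with permutation p-values.
* **AMOVA** decomposes allele-identity variance over
  groups/demes/within; F_CT is tested by permuting demes among groups
  and F_SC by permuting individuals among demes within groups.
* **IR** (internal relatedness) sums the frequencies of *all* alleles
  the individual carries — this is the convention under which a fully
  heterozygous carrier of rare alleles scores negative; a
  `homozygous_only` switch restricts the sum to homozygous loci.
  **HL** weighs each homozygous locus by its expected heterozygosity:
  `HL = ΣE_hom/(ΣE_hom + ΣE_het)`.  Both use allele frequencies of the
  individual's own deme (including the focal individual by default;
  `include_self=False` removes it), and individuals typed at < 50% of
  loci are excluded.  The **R_IR/R_HL diagnostic** correlates deme-mean
  IR and HL with deme F_IS across demes; under asymmetric migration
  immigrant rare alleles weaken the IR correlation more, so
  R_HL > R_IR is the expected signature.
* **Null alleles**: Dempster EM with one null allele; observed
  homozygotes are mixtures of true homozygotes and visible/null
  heterozygotes, blanks optionally count as null homozygotes;
  convergence at 1e-6.
* **Bottleneck test**: per polymorphic locus the mutation-drift
  equilibrium He is simulated under a two-phase model conditional on the
  observed allele count (coarse theta search, then rejection on the
  allele count; 1000 retained simulations by default).  `p_smm` is the
  fraction of mutations forced to single-step and defaults to 0.10,
  following the source convention for this analysis even though
  stepwise-dominant (0.9) is the more common parameterisation — the
  switch is exposed.  A one-tailed Wilcoxon signed-rank across loci
  tests heterozygosity excess; the pooled allele-frequency spectrum is
  checked for a mode shift out of the rare-allele class.
* **Neutrality scan**: neutral loci are simulated with msprime under a
  symmetric island model (12 demes by default) whose migration rate
  matches the trimmed-mean observed F_ST, floored at 0.01 because the
  implied migration rate -- and hence simulation cost -- explodes below
  that while the envelope is indistinguishable from the near-panmictic
  band.  Each simulated ancestry carries several independent mutation
  layers (pseudo-loci), and each observed locus gets the empirical
  quantile of its F_ST among simulated loci of similar He (nearest-He
  window), flagged outside the central 95% band.  Note the null is a
  *symmetric* island model: strongly asymmetric true structure
  overdisperses per-locus F_ST and legitimately raises the flag rate.
* **Evanno ΔK**, **Narum's FDR** (`alpha / Σ 1/i`), a **Mantel test**
  (exact permutation enumeration when n! fits the budget), and a
  genotypic-LD G-test screen complete the panel.

## Structured-coalescent migration inference (migration)

Model I is panmixia (one mutation-scaled size theta); model II is a
k-island model with per-deme theta_i and asymmetric mutation-scaled
immigration rates M[j→i], priors Uniform(0, 200) and Uniform(0, 1000).
Time is mutation-scaled: coalescence at rate 2/theta_i per same-deme
pair, backwards migration of a deme-i lineage to j at rate M[j→i].
Microsatellites follow a single-step ladder on the observed allele range
plus a 10-step buffer; branch transition probabilities come from the
spectral decomposition of the symmetric tridiagonal generator, and the
root state is uniform on the ladder.

The sampler is Metropolis–Hastings over per-locus genealogies and
parameters:

* **Single-lineage re-threading** (the workhorse): detach the branch
  above a random node, splice its sibling through, and re-simulate the
  branch's migration path and coalescence point from the conditional
  prior given the rest of the genealogy (event-driven sweep over the
  remaining lineages' recorded paths).  The acceptance ratio is the
  likelihood ratio.
* **Time rescaling**: all event times multiplied by a log-symmetric
  factor, accepted on likelihood × prior × Jacobian (s^events);
  this equilibrates total tree length quickly.
* **Resimulation above a uniform time cut**, occasional **full
  redraws** of one locus from the prior, and a rare **global redraw**
  of every parameter and genealogy from the prior (its auxiliary
  migration draw integrates out exactly, so the acceptance is the
  likelihood ratio; it is what lets prior-only chains mix).
* **theta updates** are near-Gibbs draws from the conditional
  `theta^−C exp(−T2/theta)` on a log grid with an MH correction.
* **M is integrated out analytically**: with uniform priors each entry
  contributes `Γ(G+1)/T1^(G+1) · P(G+1, M_max·T1)/M_max` to the
  marginal prior of the migration histories, where G is the total
  migration-event count over loci and T1 the lineage-time exposure.
  Genealogy proposals are simulated at a working migration matrix that
  adapts during burn-in (conditional mean) and is then frozen, with the
  proposal density corrected in the acceptance ratio, so the recorded
  phase is an exact chain.  The reported M posterior is sampled from
  its truncated-Gamma conditional at every recorded step.  This
  collapse removes the near-reducible random walk that otherwise pins M
  to its starting value through the migration-event counts.
* theta is initialised at the within-deme moment estimate
  (mean squared pairwise allele-size difference), which removes most of
  the tree-length burn-in drift.
* Migration histories are truncated at 20,000 events per genealogy
  (proposals beyond the cap are rejected); the cap only binds at
  extreme migration rates where the island model is effectively
  panmictic.

Marginal likelihoods are harmonic means of the recorded data
likelihoods, averaged over replicate chains, plus a stabilised variant
that drops the lowest 10% of likelihood values.  The log Bayes factor
is Mlog(island) − Mlog(panmixia).  The harmonic-mean estimator is kept
for comparability with the standard workflow despite its known
instability: it is dominated by the lowest retained likelihoods, so
under-converged chains bias it toward whichever model equilibrates
faster.  The default schedule (5000 recorded steps, thinning 100, three
replicates) matches the standard workflow; tests and the acceptance
script run reduced schedules (hundreds of recorded steps, thinning 10,
sample sizes of 5–10 diploids per deme and 6–8 loci) to stay
desk-scale, which is also why their Bayes factors are order-of-magnitude
smaller than a full-scale analysis would produce.  Effective migrant
numbers are `Nem[j→i] = M[j→i]·theta_i/4` from posterior modes.
Chains failing basic diagnostics (all acceptance rates < 1% or
likelihood ESS < 50) raise instead of returning silently.

## Skyline demography (skyline)

Pairwise distances are maximum-likelihood under HKY with kappa fixed
from configuration (default 8, matching the transition bias used for
the network weights) and empirical base frequencies; optional discrete-
gamma rates and invariant sites mix into the transition matrix.  The
genealogy is UPGMA (ultrametric, heights = distance/2).  The classic
skyline estimates Ne·tau on each inter-coalescent interval as
`gamma_i · i(i−1)/2`; the generalized variant pools short adjacent
intervals tipward until each spans epsilon, with epsilon chosen by
small-sample AIC over a quantile grid when not supplied.  This is a
deliberate point-estimate stand-in for a full Bayesian skyline: the
genealogy is not resampled, so the profile carries no phylogenetic
uncertainty, and only qualitative growth-phase signals should be read
from it.  Times are in substitutions/site; a helper converts to years
given a rate in substitutions/site/My (the configured default is
0.946e-5 with SD 0.196e-5, treated purely as configuration constants).

## Condition index and HFC (condition)

log10(W) is regressed on log10(L) (base-10 by convention; the slope is
base-invariant), with an ANCOVA testing slope×group interactions before
a common line is used.  `Kn = W/(a·L^b)` with `a = 10^intercept`, so
the sample mean of Kn is 1 when fitted on the same data.  The
heterozygosity–fitness model regresses Kn on Rds (the residual of
HL ~ IR, orthogonal to IR by construction), IR, cohort, and matriline
nested in cohort, using sequential (type-I) sums of squares computed in
a fixed term order by incremental least squares; F statistics use the
full-model residual mean square.  HL enters only through Rds.

## Synthetic data (simulate)

The generator emulates the study conditions: three matrilines sampled in
three cohorts (default deme×cohort sizes 82/35/33, 58/35/32, 62/32/27),
22 microsatellites, and allometric phenotypes.

* **mtDNA**: each matriline descends from one of three founding
  haplotypes 0/1/2 transitions apart on a random 355-bp background.
  The within-matriline genealogy is a coalescent in an exponentially
  growing population (default growth 0.5/generation, i.e. near-star
  trees), and the locus mutation rate is scaled so a root-to-tip path
  carries 0.5 expected mutations; mutations are transition-biased
  (kappa 8).  These defaults were set from the printed per-cohort
  diversity of the source data (Hd ≈ 0.82–0.86, π ≈ 0.004–0.005,
  ≈ 31–34 haplotypes per cohort, three dominant haplotypes) before any
  acceptance checks were run.  With growth 0 and `mt_sat_rate=None`
  the module is a plain constant-size coalescent with haploid
  theta = 2Nμ, used for the Watterson-consistency test.
* **Microsatellites**: msprime structured coalescent with diploid
  Ne_i = theta_i/(4μ), μ = 5e-4 per generation, backwards migration
  rate M[j→i]·μ, and msprime's SMM (or TPM) mutation model on a ladder
  1–120 rooted at 60.  All cohorts share one structured draw per
  dataset -- cohorts are temporal samples of the same demes, so
  between-cohort differentiation is ~0 while the matriline structure
  persists within every cohort; simulating cohorts independently would
  fabricate between-cohort F_ST.  Default theta = (2.6, 2.067, 4.2) and
  asymmetric Nem (A the net source: A→B 10, A→C 20, reverse 0.3)
  mirror the magnitudes of the study's island-model estimates; the
  realized cohort-level W&C F_ST lands in the weak 0.001–0.01 band.
  Fully isolated configurations get a distant common-ancestor split so
  the coalescent terminates.
* **Phenotypes**: lengths are cohort-mean normal (66.59/69.0/71.60 mm,
  SD 3.5); log10 weight follows the allometric line (b = 3.397,
  intercept −3.813 on the mg scale) plus a cohort condition factor
  (0.95/1.00/1.06) and normal noise (SD 0.05).

What passing synthetic tests show: estimator implementations are
correct, the inference chain recovers the generator's structure, and
diagnostics are calibrated under the model's own assumptions.  What
they do not show: robustness to genotyping artefacts (stutter, allelic
dropout beyond the null-allele model), departures from the mutation
models, within-matriline substructure, or selection — real-data
behaviour on those axes is untested.

## Known limitations

* The haplotype-network median generation uses majority consensus, not
  the full quasi-median closure; very dense networks may differ from
  reference implementations in the median vectors retained (the MSN
  containment and MP pruning guarantees still hold).
* Harmonic-mean model comparison at desk scale is noisy and sensitive
  to convergence asymmetry between models; Bayes factors from reduced
  schedules should be read as directional, not as evidence magnitudes.
* The skyline stage is a point-estimate profile, not a posterior.
* Steiner-tree enumeration is exponential in the number of median
  vectors and is capped; the cap is logged when hit.
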