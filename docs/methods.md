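# Methods

This note records what `infdom` computes and how, in enough detail to rederive
the implementation.  Notation: a diploid individual `i` has parents `i[1]`,
`i[2]`; at each locus it carries two genes, one per parent.  `F_i` is the
inbreeding coefficient (probability the two genes at a locus are identical by
descent, IBD), and `F_ij` the kinship (probability a random gene from `i` and
a random gene from `j` are IBD).

## 1. Identity coefficients (`infdom.ibd`)

### Generalized IBD functionals

All identity probabilities used here are expectations of products of
indicator functions over gene draws.  We compute them with a single exact
recursion over *blocks of gene draws*: a state is a multiset of blocks, each
block being a set of (individual, meiosis-slot) gene positions required to be
IBD within the block.  For a non-founder gene the recursion expands the gene
into "same parental gene" and "other parental gene" branches with probability
1/2 each; founder genes terminate the recursion (distinct founder genes are
never IBD).  States are canonicalized and memoized, so the recursion is exact
rational arithmetic carried out in floating point, and terminates because
every expansion moves genes strictly up the pedigree.

### Condensed coefficients by Möbius inversion

For an ordered pair `(a, b)` consider the four genes (two from each).  The 15
set partitions of these four genes define 15 "detailed identity states".  The
recursion above gives, for each partition `π`, the probability `ζ(π)` that
*at least* the blocks of `π` are IBD (i.e. the probability of the event "all
genes within each block of `π` are IBD", with no constraint across blocks).
These are related to the exact-partition probabilities `p(π)` by the zeta
transform of the partition lattice; solving the triangular linear system
(`numpy.linalg.solve` on the 15×15 zeta matrix) yields `p(π)`.  Grouping the
15 detailed states by Jacquard's condensation (ignoring which of the two
genes within an individual came from which parent) gives Δ1–Δ9.

The derived quantities are linear in the Δs, e.g.

```
Fab    = Δ1 + (Δ3 + Δ5 + Δ7)/2 + Δ8/4          (kinship)
Faabb  = Δ1 + Δ2                                (both pairs IBD within)
F̃abab = Δ1 + Δ7 + Δ8/4 − cross-terms …
```

and are implemented once, in `pair_identities`, with the exact linear
combinations; `kinship` and `inbreeding` are also available through the
classical two-gene recursion as an independent cross-check.

### Parental identity sets and selfing

For predicting a family (offspring of `i[1] × i[2]`) we need the identity
set of the *parent pair*: `F11, F22, F12`, the three-gene probabilities
`F112, F122` (a random gene from one parent IBD to *both* genes of the
other), the four-gene `F1122`, and the two phased four-gene quantities
`F̃1212, F̃1122`.  All are linear in the Δs of the parent pair.

A selfed offspring has `i[1] = i[2] = p`, and drawing "one gene from each
parent" becomes drawing twice *with replacement* from the same parent's two
genes.  Carrying that through each definition gives the degenerate set

```
F11 = F22 = F112 = F122 = F1122 = F_p
F12 = (1 + F_p)/2,   F̃1212 = (1 − F_p)/2,   F̃1122 = (1 − F_p)/4.
```

### Gene-drop oracle

`gene_drop_oracle` estimates every identity quantity by simulating unique
founder gene labels through the pedigree and averaging the defining
indicator events, with binomial standard errors.  It shares no code with the
recursion and serves as the arbiter in the tests.

## 2. The ancestral trait model (`infdom.trait_model`)

A locus with alleles at frequencies `ν = (ν_1, …)` and raw genotype values
`w_{jk}` is reparameterized by least squares into

```
w_{jk} = μ + η_j + η_k + φ_{jk},
```

with `E[η] = 0`, `E[φ | either allele] = 0` under random mating
(`normalize_effects`).  Summing `M` independent loci and scaling effects by
`1/√M` defines the trait.  Six ancestral summaries drive every closed form
(`variance_components`):

```
σ²_A  = 2 Σ E[η²] / M           additive variance
σ²_D  =   Σ E[φ²] / M           dominance variance
ι     =   Σ E[d]  / √M          inbreeding depression (d = φ on homozygotes)
ι*    =   Σ E[d]² / M
σ²_DI =   Σ (E[d²] − E[d]²)/M   identity disequilibrium variance
σ_ADI = 2 Σ E[η d] / M          additive × homozygous-dominance covariance
```

For bi-allelic loci `σ²_D = ι*` identically (checked in the tests).

### Default generating recipe

`make_biallelic_dominance_model(M, seed, c_H, freq_dialect)` draws, per
locus: genotype values ±1 with the heterozygote equal to one homozygote
(complete dominance), the favored direction `+` with probability
`H = 1/2 + c_H/√M` (default `c_H = 1`, giving a weak systematic dominance
bias and hence `ι < 0` typically); and an allele frequency from one of two
dialects:

* `"sample_counts"` (default): frequency on the grid `i/60`,
  `i ∈ {1, …, 59}`, with weights `∝ (i(60−i))^(ε−1)`, `ε = 0.001` — a
  near-neutral site-frequency spectrum conditioned on segregating in a
  reference sample of 60 genes;
* `"continuous"`: logit-uniform on (0, 1) by rejection to a bounded support.

Both dialects are retained because the component values they generate differ
noticeably at `M = 1000` (the grid dialect concentrates σ²_A near 0.28, the
continuous one near 0.31).

## 3. Exact Mendelian decomposition (`infdom.mendel`)

Founders get genotypes drawn i.i.d. from the ancestral model.  For each
non-founder and each locus, inheritance indicators `X, Y ∈ {0, 1}` pick which
of each parent's two genes is transmitted.  Writing the parental genes of
individual `i` at a locus as `(g¹_1, g¹_2)` and `(g²_1, g²_2)`:

```
A_i  = (2√M)⁻¹ Σ_loci [η(g¹_1) + η(g¹_2) + η(g²_1) + η(g²_2)]
D_i  = (4√M)⁻¹ Σ_loci [φ(g¹_1,g²_1) + φ(g¹_1,g²_2) + φ(g¹_2,g²_1) + φ(g¹_2,g²_2)]
RA_i = (√M)⁻¹  Σ_loci [(X−½)(η(g¹_2)−η(g¹_1)) + (Y−½)(η(g²_2)−η(g²_1))]
RD_i = (√M)⁻¹  Σ_loci [φ(transmitted pair) − average over the four pairings]
```

so that `Z_i = z̄_0 + A_i + D_i + RA_i + RD_i + E_i` holds *exactly* for
every individual in every replicate (a tested machine-precision identity).
`A + D` is the family-shared part (a function of the parents' genotypes
only); `RA + RD` is the Mendelian-sampling residual, mean zero given the
parents.  Founders carry their whole deviation in `RA + RD` by convention.

`truncation_selection_sim` generates `n_candidates` offspring per slot from
the same parent pair and keeps the best by trait value (noise either
independent per candidate or shared within the family); `n_candidates = 1`
reproduces the neutral gene drop with an identical random stream, enabling
exactly paired selected/neutral comparisons.

## 4. Closed-form predictions (`infdom.infinitesimal`)

In the many-locus limit the shared and residual components become Gaussian
with moments linear in the parental identity set:

* **Shared component** `A + D` of a family: mean
  `ι (F11 + F22)/2`… (dominance depression of the parents' gene pairs) and a
  variance combining `σ²_A` through pairwise kinships, `σ²_D`/`ι*`/`σ²_DI`
  through four-gene identities, and `σ_ADI` through the three-gene terms
  (`shared_moments`).
* **Residual variance** of the Mendelian-sampling component
  (`residual_variance`), which depends on the parent pair only through its
  identity set; `family_residual_components` splits it exactly as
  `VRA = σ²_A (1 − (F11+F22)/2)/2`, `VRA_RD = (σ_ADI/2)(F12 − (F112+F122)/2)`,
  `VRD = residual − VRA − 2·VRA_RD`.  The split sums to the residual variance
  identically for arbitrary components; for bi-allelic components
  (`σ²_D = ι*`) `VRD` reduces to its familiar explicit form.
* **Trait moments** of an individual (`trait_moments`): `E[Z] = z̄0 + ι F`,
  and a variance that interpolates between `σ²_A + σ²_D` (outbred) and the
  fully inbred limit; the identity
  `shared variance + residual variance = trait variance` (with the
  individual's inbreeding read off the parental set as `F = F12`) holds to
  machine precision and is enforced by a test.
* **Covariances** between relatives (`trait_cov`, `cross_family_cov`,
  `parent_offspring_shared_cov`) from the pair identity set of the two
  individuals; the additive–dominance cross covariance of an outbred pair
  vanishes, as in the classical theory.
* **Conditioning**: `conditional_shared_moments` performs the bivariate
  Gaussian update of a family's shared component on the two observed parental
  trait values (univariate for a selfing family, where the parental "pair" is
  one observation); `joint_trait_mvn` + `mvn_condition` provide the same
  operation for any set of individuals and observations, and the two routes
  agree to machine precision on families.

A subtlety: the conditional *mean* is a linear regression, and linear
regression coefficients depend only on second moments — which the identity
formulas give exactly at finite `M`.  Only the Gaussian shape (and hence,
e.g., conditional normality) is an `M → ∞` statement.  The tests exploit
this: conditional means are checked by regression against finite-`M`
simulations at Monte Carlo accuracy, without a large-`M` bias term.

## 5. The exactly solvable toy model (`infdom.experiments`)

`M` unlinked bi-allelic loci, allele frequency 1/2, effects `±1/M` with
complete dominance; the favored direction is `+` with probability
`H = 1/2 + c/√M`.  The trait is then a rescaled sum of `M` i.i.d.
three-point variables, whose exact distribution we build by repeated
convolution (`numpy.convolve`), with no appeal to the closed forms.
Conditioning on the trait value `k/M`:

* the single-locus posterior/prior ratios are exactly
  `(1 ± k/M)/(1 ± c/√M)` (homozygotes) and the matching mixture for the
  heterozygote — an `O(k/M + 1/√M)` perturbation of the prior;
* the two-locus joint posterior minus the product of marginals is exactly
  `(1/16)(1 + k/M)((k−1)/(M−1) − k/M)/(1 + c/√M)² = O(1/M)`.

So observing the trait leaves the per-locus ancestral distribution intact to
`O(1/√M)` and induces only `O(1/M)` linkage disequilibrium — the reason the
infinitesimal closed forms can condition on trait values without updating
the ancestral components.  Both identities are verified against the
convolution pmf at many `(M, k)` and against a full `4^M` brute-force
enumeration at `M = 4`.

## 6. Experiments (`infdom.experiments`)

All experiments are driven by a frozen `ExperimentConfig` and a single seed.
`numpy.random.SeedSequence(seed).spawn(…)` derives one child stream for the
pedigree, one for the ancestral model, and one per replicate; the replicate
streams are shared between the neutral and selected arms of
`selection_experiment`, so the two arms differ only through selection.
Monte Carlo standard errors are batch means over replicate batches.

* `neutral_experiment`: across-replicate moments of `A+RA`, `D+RD`, `G` per
  generation and per individual vs the closed forms at each individual's
  inbreeding coefficient; also descriptive population-snapshot variances
  (total vs genic, i.e. with and without linkage-disequilibrium terms).
* `family_experiment`: per-family empirical vs predicted residual components
  across random founder pairs (selfing pairs possible; they exercise the
  degenerate identity set).
* `selection_experiment`: paired truncation-selection vs neutral arms; the
  gap between them shrinks as `M` grows (`convergence_experiment` fits the
  log–log slope).
* `normality_diagnostics`: per-group and pooled Kolmogorov–Smirnov tests and
  normal-quantile curves for within-family residuals.

## 7. Reproducibility policy

Every stochastic entry point takes an explicit integer seed and uses
`numpy.random.default_rng`; no global state is touched.  Identical inputs
give bit-identical outputs across runs.  The acceptance script
(`scripts/acceptance.py`) regenerates its targets from scratch at every
invocation from the seed alone.

## 8. Limitations and non-goals

* Loci are unlinked and the base population is in Hardy–Weinberg and linkage
  equilibrium by construction; linkage, mutation and epistasis are out of
  scope.
* The identity-coefficient recursion is exact but exponential in pedigree
  depth in the worst case; it is intended for the moderate pedigrees used
  here (tens of individuals per generation, ~10 generations), not for
  biobank-scale pedigrees.
* Trait prediction under *selection* is only explored empirically (the
  closed forms assume neutrality); the selection experiments document the
  departure rather than predict it.
* There is no command-line interface; the library plus the `examples/`
  scripts are the intended surface.
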