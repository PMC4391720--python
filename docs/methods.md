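# Methods

## Scope and model

`coalabc` implements a complete demographic-inference pipeline for a
two-locus phylogeographic dataset: one haploid mitochondrial locus (668 bp,
130 sequences) and one phased diploid nuclear locus (274 bp, 250 gene
copies), sampled from eight populations nested in four geographical regions.
The pipeline has four layers:

1. **Summary statistics** on aligned sequences: diversity indices (S, H,
   Hd, π), Tajima's D, Fu's Fs, mismatch distributions with Harpending's
   raggedness, pairwise ΦST with permutation tests, hierarchical AMOVA,
   Nei's net divergence D_A and Mantel matrix correlations.
2. **Demographic models**: four scenarios for the four-region system —
   panmixia, simultaneous fragmentation, stepwise north→south colonization,
   and a deep southern break — each crossed with optional symmetric island
   migration and exponential growth, giving 14 models.
3. **Coalescent simulation** of single-locus genealogies without
   recombination under any model, with infinite-sites mutations.
4. **ABC**: reference tables, summary-vector selection on pseudo-observed
   datasets (PODs), hierarchical (within-then-among scenario) model choice
   by rejection / multinomial logistic regression / neural network at two
   tolerances, and posterior parameter estimation by neural-network
   regression adjustment with 95% HPD intervals.

## Units and parameters

* θ is per locus (expected pairwise differences under neutrality); the
  nuclear θ is fixed at 4× the mitochondrial θ, reflecting the four-fold
  effective-size ratio at equal per-locus mutation input. Prior:
  θ_COI ~ U(0.25, 7.0).
* Time is measured in coalescent units in which one pair of lineages
  coalesces at rate 1 and mutations arrive at rate θ/2 per lineage, so
  E[S] = θ·a₁(n) and E[π] = θ under panmixia. Split times: τ1 ~ U(0.01, 4),
  τ2 ~ U(0.001, τ1), τ3 ~ U(0.001, τ2) (nesting by conditional sampling).
* Migration: the prior m ~ U(0.001, 15) is the total scaled emigrant input;
  the per-lineage, per-target-deme rate is m/(n_demes−1), i.e. 0–5 migrants
  per generation per pair with four demes.
* Growth: α ~ U(0.25, 0.9) with deme size N(t) = N(0)·exp(−α·t) backward in
  time, anchored at the deme's founding event (its backward merge time; τ1
  for the root deme and for the panmictic growth model). Past the anchor
  the size is constant at the founding value. This inverts the definition
  α = −(1/τ)·ln(N(τ)/N(0)).

## Coalescent algorithm

The simulator is a standard structured coalescent with competing
exponential events processed segment-by-segment between split times:
within-deme coalescence at rate k(k−1)/2 divided by the deme's current
relative size, per-lineage migration toward each other coexisting deme, and
deterministic lineage relocation at split times. Exponential growth is
handled exactly by inverse-CDF rescaling of the coalescence waiting time
(rate k(k−1)/2·exp(α·t) inside a growing segment); because growth anchors
coincide with split times, every segment is either purely growing or purely
constant. Mutations are Poisson with mean (θ/2)·T_total, placed uniformly
on branches, each creating a new segregating column (infinite sites). The
simulator is validated against closed-form neutral expectations and against
msprime (two-sample KS tests on S under panmixia, a four-deme split, and
exponential growth).

## Statistic definitions and numerical choices

* Pairwise distances use complete-pair deletion: sites with N or a gap in
  either sequence of a pair are skipped for that pair. For haplotype
  identity, N and gap are compared literally as extra states.
* Hd uses the n/(n−1) small-sample correction. Tajima's D follows the 1989
  constants and is undefined (NaN) at S = 0; inside ABC tables undefined D
  is imputed as 0 and flagged in a `d_defined` column so flagged rows can
  be filtered.
* Fu's Fs uses the Ewens sampling formula with θ̂ = mean pairwise
  differences; the unsigned Stirling numbers of the first kind are computed
  by a log-space recurrence (integer arithmetic overflows far below the
  250-sequence nuclear alignment). Fs is undefined when θ̂ = 0 or when
  Pr(K ≥ k_obs) is numerically 0 or 1 (e.g. k_obs = 1).
* Raggedness follows the Arlequin convention r = Σ_{i=1}^{d+1}(x_i−x_{i−1})²
  over relative mismatch-class frequencies 0..d with x_{d+1} = 0.
* ΦST and AMOVA use Excoffier-style variance components on pairwise
  nucleotide distances. Pairwise ΦST restricts the analysis to the two
  populations compared; permutation p-values shuffle labels within that
  pair and include the observed arrangement (p = (hits+1)/(n_perm+1)).
  Negative ΦST estimates are reported as computed.
* D_A(x, y) = π_xy − (π_x + π_y)/2 with π_xy the raw mean between-population
  difference. Note that for finite samples with identical mixed
  compositions this estimator is slightly negative (between-population
  pairs include identical copies; within-population means do not), so the
  "identical populations → 0" intuition holds only at the population level.
* Mismatch significance (parametric bootstrap under a sudden-expansion
  model) is not implemented; only r is reported.
* ABC distances standardize each statistic by its pooled median absolute
  deviation (MAD; zero MADs fall back to 1), the robust default in
  rejection ABC. ⌈tolerance·N⌉ closest rows are kept.
* The multinomial logistic method regresses the model label on centred
  summaries within the accepted set with Epanechnikov distance weights and
  L2 regularization (inverse strength `reg_c`, default 1.0) against perfect
  separation; the neural-network method averages a 5-hidden-unit MLP over
  10 restarts (lbfgs, weight decay 1e−3). Neither sklearn MLP supports
  sample weights, so the neural methods train unweighted on the accepted
  set.
* Parameter estimation is a Blum–François-style nonlinear adjustment:
  bounded parameters are logit-transformed to their prior support, a
  5-hidden-unit MLP (lbfgs, weight decay 1e−2, 10 restarts averaged) is
  fitted on the accepted rows, and the adjusted draws θᵢ − m(sᵢ) + m(s_obs)
  are back-transformed. When the accepted summaries are constant the
  adjustment reduces to plain rejection. The nuclear θ is derived from the
  adjusted mitochondrial θ through the exact 1:4 constraint rather than
  regressed separately. The heteroscedastic variance correction of the full
  Blum–François scheme is not applied.
* HPD intervals are the shortest window containing ⌈mass·n⌉ sorted draws.
* πb, the between-region diversity used in summary vectors, is the raw mean
  between-region π averaged over the six region pairs (not net divergence);
  the net version remains available through `nei_da`.
* Summary vectors concatenate both loci, so the selected three-statistic
  vector (π, πw, πb) has six entries.
* Vector selection scores each candidate by the mean over PODs of
  Pr(true model)/mean Pr(false models) under rejection; the denominator is
  floored at half an accepted draw so perfect classifications stay finite.
* Hierarchical model choice selects the most probable model within each
  scenario and then compares the four winners on their pooled rows; the
  final comparison defaults to rejection at the 0.1% tolerance, with the
  other methods available.

## Synthetic data

The generator emulates the target field-sampling design: the fixed
population/region layout, per-population sample counts (130 + 250), locus
lengths, and the 1:4 θ ratio. Simulated demes are the four regions;
population labels inside a region subdivide that region's samples and carry
no additional structure, so population-level statistics on synthetic data
test bookkeeping, not within-region differentiation. Phased nuclear copies
are emitted as `/1`/`/2` pairs per individual (individuals = copies/2).
Sequences are rendered from the binary segregating-site matrices with
random ancestral/derived base pairs at random positions. The generator does
not emulate sequencing error, missing data, recombination, selection, or
mutation-model complexity beyond infinite sites — passing tests therefore
validate the inference machinery, not robustness to those artefacts of
real data.

## Desk-scale sizes

Full-scale runs use 100 000 simulations per model (the pipeline-config
default). The test-suite and acceptance-script runs use the package's
reduced layout (6 mitochondrial sequences and 8 nuclear copies per
population) with 1000–10 000 simulations per model, 20 replicate synthetic
truths for recovery/coverage checks, and 10 PODs per model for vector
selection; coalescent calibration uses 5000 replicates (n=10, θ=2) and
2000 replicates (n=20, θ=5). These sizes give Monte-Carlo standard errors
comfortably inside the asserted bands while keeping a single-CPU run short.

## Known limitations

* The model-choice probabilities from the regression methods are
  conditional probabilities at the observed point; at tolerance 1 they
  recover the prior only when the summaries are uninformative.
* No recombination, gene conversion, selection or sequencing error.
* Mismatch raggedness has no significance test.
* The absolute-time conversion of τ (generations, years) requires a
  user-supplied effective size and substitution rate; the package works in
  coalescent units throughout.
* Scenario 4's nested topology below its deepest split uses all three τ
  parameters symmetrically with scenario 3 ({region1}, ({region2},
  {region3})); other resolutions of that subtree are plausible.
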