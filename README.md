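# coalabc

Structured-coalescent simulation and Approximate Bayesian Computation (ABC)
for demographic inference from small multilocus phylogeographic datasets —
the kind of data produced by sequencing one mitochondrial and one nuclear
marker across a handful of populations.

The package targets a classic study design: a haploid mtDNA locus (COI-like,
668 bp, 130 sequences) and a phased diploid nuclear locus (ITS2-like,
274 bp, 250 gene copies) sampled from 8 populations nested in 4 geographical
regions. It answers two questions:

1. **What do the sequences say?** Diversity indices (S, H, Hd, π),
   neutrality tests (Tajima's D, Fu's Fs), mismatch distributions with
   Harpending's raggedness r, pairwise ΦST with permutation tests,
   hierarchical AMOVA, Nei's net divergence D_A, and Mantel tests.
2. **Which demographic history explains them?** Fourteen competing models —
   four scenarios (panmixia, simultaneous fragmentation, stepwise
   north→south colonization, deep southern break) crossed with migration
   and exponential-growth variants — are compared by ABC: 4Ne-scaled
   priors (θ_COI ~ U(0.25, 7), θ_ITS2 = 4·θ_COI, nested split times τ3 <
   τ2 < τ1, migration m ~ U(0.001, 15) scaled as m/(n−1) migrants per
   generation per deme pair, growth rate α ~ U(0.25, 0.9)), a custom
   structured-coalescent simulator with infinite-sites mutations, summary
   vectors selected on pseudo-observed datasets by the
   Pr(true)/mean Pr(false) score, hierarchical within-then-among scenario
   model choice (rejection, multinomial logistic, neural network; 0.1% and
   1% tolerances), and posterior parameters by neural-network regression
   adjustment with 95% HPD intervals.

The ABC machinery is exposed as sklearn-compatible estimators
(`ABCModelChoice`, `ABCParameterEstimator`) so it composes with sklearn
tooling; module-level functions (`rejection_choice`, `estimate_parameters`,
…) are thin wrappers. A synthetic-data module generates complete
study-shaped datasets with known truth, so the whole pipeline is testable
without any download.

## Worked example

Simulate a panmictic dataset with known θ, then recover the scenario and
the parameter:

```python
import numpy as np
import coalabc as ca

models = {m.model_id: m for m in ca.enumerate_models()}
layout = ca.REDUCED_LAYOUT          # 6 mtDNA seqs + 8 nuclear copies per population
params = {"theta_coi": 2.0, "theta_its2": 8.0}
aln_coi, aln_its2, popmap, truth = ca.generate_dataset(models[1], params, layout, seed=5)

obs = ca.observed_summaries(aln_coi, aln_its2, popmap)
rng = np.random.default_rng(6)
table = ca.build_reference_table(
    [models[1], models[3]], ca.Priors(), layout.sample_config(), 2000, rng
)
choice = ca.rejection_choice(obs, table, tolerance=0.01, vector=("pi", "pi_w", "pi_b"))
print(choice.probabilities)
post = ca.estimate_parameters(
    obs, table, models[1], ca.Priors(), tolerance=0.05,
    vector=("pi", "pi_w", "pi_b"), random_state=0,
)
print(round(post.point["theta_coi"], 2), [round(v, 2) for v in post.hpd95["theta_coi"]])
```

Output:

```
1    0.9
3    0.1
dtype: float64
1.25 [0.66, 2.2]
```

The rejection step puts 0.9 posterior probability on the true panmictic
model versus the fragmentation alternative, and the adjusted posterior for
θ_COI has median 1.25 with a 95% HPD of (0.66, 2.2) covering the true
value 2.0.

The same pipeline runs from the shell (`coalabc simulate`, `coalabc
sumstats`, `coalabc abc-table`, `coalabc abc-choose`, `coalabc
abc-estimate`, `coalabc fixtures`), driven by a YAML config; see
`docs/methods.md` for the model, unit conventions and numerical choices.

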