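# coaldelim

Coalescent-based species delimitation for single-locus (typically
mitochondrial) data. The package implements the three-stage workflow used to
assess species boundaries in groups of allopatric populations — for example
co-distributed Southeast Asian amphibian lineages sampled for a 16S rRNA
fragment:

1. **Distance screening.** Pairwise *uncorrected p-distances* (proportion of
   differing sites among comparable, unambiguous positions, pairwise deletion)
   are summarized between candidate populations. Non-conspecific pairs whose
   divergence falls below a lower threshold (default 3%) are flagged as
   candidates for *lumping*; conspecific pairs above an upper threshold
   (default 5%) as candidates for *splitting*; ranges touching the 3–5% band
   are reported as a grey zone.
2. **Two-population multispecies-coalescent (MSC) inference.** For each
   flagged pair, sequences evolve under JC69 along a gene tree drawn from the
   structured coalescent: within population *i*, lineage pairs coalesce at
   rate 2/θᵢ until the divergence time τ, after which survivors coalesce in
   the root population (θ_root). All parameters are in expected
   substitutions/site and carry inverse-gamma priors IG(α, β) with mean
   m = β/(α−1) for α > 2. An MCMC sampler (Metropolis-within-Gibbs over gene
   tree and parameters, with conjugate inverse-gamma updates for the θs)
   yields posteriors for (τ, θ_A, θ_B, θ_root); a reversible-jump sampler
   between the merged (single-θ) and split models yields the posterior
   probability of the split, banded as high (pp ≥ 0.95), moderate
   (0.90 ≤ pp < 0.95) or weak (pp < 0.90). Priors come from a fixed 10-row
   sensitivity grid or are calibrated empirically (θ prior mean = average
   within-population nucleotide diversity π; τ prior mean = the pair's node
   height on an ultrametric guide tree).
3. **Genealogical divergence index.** From each posterior draw,
   *gdi* = 1 − e^(−2τ/θ) — the probability that a pair of lineages sampled in
   one population coalesces before the divergence event, looking backward.
   Direction A-vs-B uses θ_A, B-vs-A uses θ_B. Populations with posterior
   mean gdi > 0.7 are treated as distinct species, < 0.2 as a single species,
   and anything between as ambiguous.

A coalescent simulator with matched assumptions (`synthetic_data`) generates
two-population JC69 datasets at known (τ, θ), so the whole pipeline is
testable end-to-end without any sequence download.

## Worked example

```python
import coaldelim as cd
from coaldelim.priors import InverseGammaPrior, PriorSet

# simulate a clearly diverged pair: tau = 5 * theta
spec = cd.SimulationSpec(tau=0.01, theta_a=0.002, theta_b=0.002,
                         theta_root=0.002, n_a=10, n_b=10,
                         length=1000, seed=3)
locus, popmap, truth = cd.simulate_dataset(spec)

# stage 1: divergence summary
m = cd.pairwise_matrix(locus)
print(cd.between_population_summary(m, popmap, "A", "B"))
# (2.3, 2.7, 2.44)   -> 2.3-2.7 % raw divergence

# stage 2: split-vs-merge model choice and parameter posteriors
priors = PriorSet(InverseGammaPrior(3, 0.002), InverseGammaPrior(3, 0.004), "c")
settings = cd.MCMCSettings(samples=1200, burnin=500, thin=3)
res = cd.run_delimitation(locus, popmap, priors, settings, seed=5, n_runs=1)
print(res.pp_split, res.support_band)
# 1.0 high

trace = cd.run_a00(locus, popmap, priors, settings, seed=5, n_runs=1)[0]

# stage 3: gdi in the A-vs-B direction
g = cd.gdi_from_trace(trace, "a_vs_b")
print(round(g.mean, 3), round(g.sd, 3), g.classification)
# 0.998 0.018 distinct
```

The printed numbers mean: the pair shows ~2% raw mitochondrial divergence
(below the classical 3% screening threshold — screening alone would miss it),
yet the MSC model choice puts posterior probability 1.0 on two species and
the gdi posterior (0.998 ± 0.018) is far above the 0.7 "distinct species"
band, as expected when the true divergence time is five times the population
size parameter.

A shell interface mirrors the stages
(`coaldelim screen | priors | a00 | delimit | gdi | simulate | run`); see
`coaldelim --help`.

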