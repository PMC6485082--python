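# Methods

## Model

`coaldelim` analyses one haploid locus under the two-population multispecies
coalescent (MSC). Populations A and B diverged from a root population at time
τ; within population *i*, each pair of lineages coalesces at rate 2/θᵢ, so a
gene tree with within-population coalescences truncated at τ and root
coalescences thereafter has density

    ∏_pop (2/θ_pop)^{c_pop} · exp(−S_pop/θ_pop),

where c_pop counts coalescences in that population and
S_pop = Σ k(k−1)Δt integrates the pair intensity over inter-event intervals.
All times and θs are in expected substitutions per site (a haploid heredity
scalar of 1 is assumed throughout, appropriate for mtDNA). Sequences evolve
along the gene tree under JC69 with stationary frequencies ¼; the likelihood
is computed by Felsenstein pruning on site patterns with per-node rescaling,
and IUPAC ambiguity codes (and gaps) contribute partial likelihood one over
their compatible states.

The merged (one-species) model is the same coalescent with a single θ and no
τ. Both τ and every θ carry inverse-gamma priors IG(α, β), parameterized so
the prior mean m = β/(α−1) exists for α > 2; α = 3 acts as a diffuse shape
and α = 21 as an informative one.

## Priors

Two construction routes:

* **Sensitivity grid** (`prior_grid`): ten fixed (θ-prior, τ-prior) rows —
  five θ priors {IG(3, 2·10⁻⁴), IG(3, 2·10⁻³), IG(3, 2·10⁻²), IG(21, 2·10⁻²),
  IG(21, 0.2)} at τ ~ IG(3, 4·10⁻³), and five τ priors {IG(3, 4·10⁻⁴),
  IG(3, 4·10⁻²), IG(21, 4·10⁻³), IG(21, 4·10⁻²), IG(21, 0.4)} at
  θ ~ IG(3, 2·10⁻³) — spanning two orders of magnitude in the prior mean.
* **Empirical calibration**: m for θ is the average within-population
  nucleotide diversity π (mean pairwise uncorrected p-distance, pairwise
  deletion; populations with fewer than two samples carry no information and
  are skipped, with a configurable fallback when every population is a
  singleton); m for τ is the focal pair's MRCA height on a user-supplied
  ultrametric guide tree in substitutions/site. β = m(α−1) with α = 3.
  Where no guide tree exists (simulated data), the test-suite and acceptance
  experiments use half the mean between-population p-distance as the
  two-taxon ultrametric height, which estimates τ + θ_root/2.

## Sampler

`run_a00` is a Metropolis-within-Gibbs sampler over the gene tree and
(τ, θ_A, θ_B, θ_root). Per sweep:

* sliding-window age updates for every coalescence node (reflected into the
  valid interval; the root age uses a multiplicative proposal on its offset
  above the older child); a node joining lineages of both populations is
  constrained to ages ≥ τ, and −∞ density enforces the constraint elsewhere;
* fixed-height subtree regrafts (detach a subtree, reattach among lineages
  alive at the same height and, below τ, in the same population; the
  candidate set is invariant under the move, so the Hastings ratio is 1 and
  the coalescent density cancels);
* one whole-tree independence refresh from the coalescent prior (accepted on
  the likelihood ratio; in prior-only mode this is an exact Gibbs update and
  gives near-i.i.d. mixing);
* conjugate Gibbs draws θ_pop ~ IG(α + c_pop, β + S_pop);
* five multiplicative random-walk updates of τ;
* one joint rescale of all ages and parameters (the mixing move), with the
  appropriate Jacobian.

Step sizes are auto-tuned toward acceptance 0.2–0.4 during burn-in only and
frozen afterwards, preserving detailed balance for the recorded draws.
Chain-length defaults follow the published protocol (100 000 recorded
samples, burn-in 10 000, sampling frequency 5, four independent runs with
seeds seed+run_index); tests and the acceptance script use shorter chains
(≈1200–1500 recorded draws, burn-in 500–600, thin 3) that the convergence
diagnostics show are sufficient at the 10+10 × 1000 bp scale.

`run_delimitation` adds a reversible-jump move between the merged and split
models (equal prior model probabilities). The gene tree is untouched by the
jump, so the sequence likelihood cancels; the auxiliary τ is proposed
uniformly on (0, M), where M is the smallest cross-population coalescence age
the current tree carries — the largest τ it can support — with the τ prior
density entering the acceptance ratio explicitly; θ_root maps one-to-one onto
the merged θ, and the daughter θs are drawn from (and absorbed back into)
their priors. pp_split is the posterior frequency of the split state; runs
disagreeing by more than 0.05 raise a convergence warning, never a failure.
With no data the sampler sits at pp_split ≈ ½, and under strongly split or
strongly panmictic data the coalescent-density ratio drives near-absorbing
behaviour into the correct model — which is also where the true posterior
mass lies.

`convergence_check` compares independent runs: rank-normalized across-run R̂
(whole chains, floored at 1 — the statistic targets run-to-run consistency),
bulk ESS via arviz, and per-parameter spreads of run means; R̂ > 1.05 or
ESS < 200 raise flags.

## gdi

gdi = 1 − e^(−2τ/θ) is computed per posterior draw (direction A-vs-B with
θ_A, B-vs-A with θ_B) and summarized as mean ± SD plus a Gaussian KDE
(Silverman bandwidth) on a grid clipped to [0, 1). Classification uses the
posterior mean with strict inequalities: distinct above 0.7, same below 0.2,
ambiguous otherwise (boundary values are ambiguous). In floating point the
value is capped at the largest double below 1, preserving the open upper
bound. Both directions are always computed; the evidence verdict treats
"at least one direction distinct" as gdi support for a split and "both
directions same" as support for a lump.

## Screening

Uncorrected p-distances use pairwise deletion: a site is comparable only when
both symbols are unambiguous bases, and ambiguity codes are excluded rather
than fractionally matched — reproducible and standard practice. Between-
population ranges (min/max/mean over all cross pairs, in percent) are
compared to the 3–5% band with exclusive boundaries for lump/split calls and
inclusive boundaries for the grey zone; grey-zone pairs are reported and
analysed but never auto-resolved. Conspecificity always comes from an
explicit user taxonomy table.

## Synthetic data

The generator draws gene trees from the same structured coalescent the
inference assumes and evolves i.i.d. JC69 sites from a uniform root state;
output is single-locus, haploid and gap-free. Defaults mirror the motivating
study's scale: 10 samples per population, 1000 bp, τ and θ of order
10⁻³–10⁻². τ = 0 yields the panmictic null. It deliberately omits features of
real mitochondrial data — indels and alignment error, rate variation across
sites, non-JC substitution biases, selection, and multi-locus discordance —
so passing tests demonstrate correctness of the inference machinery under
its own assumptions, not robustness to model violation. A cross-check
against an independent coalescent simulator (msprime, haploid population
size θ/2, JC69 mutations at unit substitution rate) verifies the pairwise
mismatch-count distribution.

## Numerical choices and degenerate inputs

Site patterns are compressed before pruning and the pruning/coalescent
kernels are JIT-compiled. Zero comparable sites between two sequences, ragged
alignments, non-ultrametric guide trees (tolerance 10⁻⁸), zero empirical
prior means and α ≤ 2 with the mean formula all raise typed errors. Distances
are reported to two decimals in percent while full precision is kept
internally. The report writer emits tab-separated UTF-8 with one header row.

## Known limitations

Single locus and exactly two populations per analysis (multi-pair studies
iterate over pairs); no migration or isolation-with-migration; JC69 only; the
joint species-tree analogue of the delimitation analysis over many lineages
is out of scope. Credible-interval coverage at a fixed true parameter value
is near 90% (not the nominal 95%) for the θ parameters at this data scale:
with θ·L ≈ 2 a population carries only a handful of segregating sites, so
the mutation process sometimes fails to record the underlying coalescent
times, an information limit of single-locus data rather than a property of
the sampler (whose calibration is exact when truth is drawn from the prior,
as the simulation-based calibration in the test suite shows indirectly via
prior reproduction and the conjugate oracle).
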