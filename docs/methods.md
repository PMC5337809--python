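# Methods

## The model

`gcsim` simulates a single germinal-center reaction (GCR) as a hybrid of
deterministic population dynamics and stochastic mutation events.  Every
B-cell subclone *i* — a BCR variant with a fixed absolute affinity σ_i —
owns four coupled ODE compartments: centroblasts (CB, proliferating
dark-zone cells), centrocytes (CC, light-zone cells under selection), memory
(M) and plasma (P) output cells:

    dCB_i/dt = ρ_CB · D(CB_tot) · CB_i + η_CC→CB · CC_i
               − (1 − S_d(σ_rel,i)) · η_CB→CC · CB_i
    dCC_i/dt = (1 − S_d(σ_rel,i)) · η_CB→CC · CB_i − η_CC→CB · CC_i
               − (1 − S_a(σ_rel,i)) · μ_CC · CC_i − η_CC→M · CC_i
               − η_CC→P · σ_i · CC_i
    dM_i/dt  = η_CC→M · CC_i − μ_M · M_i
    dP_i/dt  = η_CC→P · σ_i · CC_i − μ_P · P_i

with

* **Density-limited proliferation** `D(x) = A^h / (x^h + A^h)`: non-specific
  resource competition that throttles CB division as the dark zone
  approaches its carrying capacity A (default 8 000 cells, Hill exponent
  h = 20, a near-switch).  Computed as a logistic in log space,
  `expit(−h·(ln x − ln A))`, which is exact and overflow-safe.
* **Affinity-dependent selection** through two sigmoids of the *relative*
  affinity σ_rel,i = σ_i / max_j σ_j (the current best binder sits at 1):
  `S(x) = x^n / (k^n + x^n)` with (k = 0.06, n = 1) gating CB→CC
  differentiation and (k = 0.1, n = 4) gating CC apoptosis.  High signal
  means *less* differentiation and *less* apoptosis — strong binders stay
  longer in the dark zone and survive selection.  Because σ_rel is scaled by
  the population maximum, every affinity improvement anywhere in the
  population weakens everyone else.
* **Affinity-weighted plasma output** `η_CC→P · σ_i`: plasma production uses
  the *absolute* affinity, so output is small early and grows with
  maturation.

The reaction runs 21 days in 6-h steps (one CB division).  Three founder
cells (σ = 0.1, 0.3, 0.5 µM-scaled) expand monoclonally for the first 4
days, during which both signals are clamped at 0.9; at day 4 the clamp lifts
and somatic hypermutation (SHM) begins.  Each step alternates (1) ODE
integration over 6 h with signals frozen at their interval-start values,
(2) the stochastic SHM sweep, (3) pruning of subclones with CB+CC < 0.1
cell (their accumulated M and P are banked, not discarded).

## Somatic hypermutation

Daughters of dividing CBs acquire `m ~ Poisson(λ = 0.6)` mutations (600-nt
receptor × 10⁻³ mutations/bp/division).  Each mutation is routed through a
fate tree: framework region (FWR) with probability α else CDR; replacement
with probability β (FWR) or γ (CDR) else silent; an FWR replacement is
lethal with probability δ; a CDR replacement is affinity-changing with
probability ε else neutral.  The branch probabilities are not well pinned by
data; the defaults (α = 0.75, β = γ = 0.75, δ = 0.5, ε = 0.5) are
plausible literature-style values and deliberately exposed as first-class
configuration — conclusions that depend on them should be checked by sweep.

A daughter with any lethal hit dies (parent CB − 1).  A surviving mutated
daughter founds a new subclone (CB = 1, parent CB − 1) — at the
*nucleotide* tracking level for any mutation, at the *peptide* level only
for CDR replacements (optionally only affinity-changing ones).  An
affinity-changing daughter draws one increment regardless of how many
affinity mutations it carries:

    Δσ = X − µ − 0.1 · σ_parent,   X ~ InvGamma(s = 3, scale r = 0.3),
    µ = E[X] = r/(s−1) = 0.15

The centering makes the increment zero-mean for weak parents; the
inverse-gamma right tail leaves a small chance of large "key mutation"
jumps; the parent-affinity shift makes improvement increasingly unlikely for
strong binders.  Affinities are clamped at a floor of 10⁻³ so relative
scaling and the plasma term stay defined; "rate" is read as the scale of
the inverse gamma (`rate_is_scale=False` selects the reciprocal reading),
and µ is always computed from the configured parameterization.

Sampling granularity (`shm_sampling`): the default `per_cell` draws a
mutation count for every one of floor(CB_i) daughters; subclones whose CB is
below 1 cannot mutate (no subclones may be founded by fractional cells).
`per_subclone` (one daughter per subclone per step) and `poisson_events`
(~Poisson(λ·floor(CB)) single-mutation daughters) are alternatives for
sensitivity experiments.

## Numerical choices

* Integrator: `scipy.integrate.solve_ivp` RK45 at rtol 10⁻⁶ / atol 10⁻⁸ on
  a single stacked state vector (4N equations).  The contract is the
  tolerance, not the algorithm; the per-interval system (rates ≤ 10/day
  over 0.25 day, signals frozen) is not stiff, and stiff solvers would form
  dense Jacobians on 10³–10⁵ dimensions.  Tiny integrator undershoots below
  zero are clipped.
* Signals, the scaling maximum and the population composition are
  piecewise-constant within each 6-h interval (operator splitting);
  affinities only change at SHM events.
* SHM switches on at the first step *starting* at ≥ day 4; the clamp covers
  steps starting before day 4.
* The relative-affinity maximum runs over all living subclones, including
  those below one cell but above the pruning floor.
* One `numpy.random.Generator` per replicate, seeded explicitly; every
  output table records its seed, so (parameters, seed) reproduce every table
  bit-for-bit.  The vectorized SHM sweep (per-cell Poisson counts plus
  per-cell multinomial leaf counts) is distributionally identical to
  classifying each mutation sequentially.

## Repertoire statistics

Sequencing is assumed to sample CCs (CBs express little surface BCR), so
counts are rounded final-step CC values; zeros are unobservable and dropped.
The expansion threshold T is the lowest count c ≥ 1 whose histogram
frequency F(c) falls below p (default p = 1: the first gap); counts > T are
expanded.  The affinity cutoff is the 75th percentile (linear interpolation)
of the affinities of *every subclone ever produced*, pruned ones included.
Abundance–affinity association is Spearman's ρ with average-rank ties over
observable subclones.  Clonal size is a subclone's count over the total.

Lineage clustering of annotated reads: group by (V, J), connect read pairs
with ≤ 2 nucleotide differences (Hamming for equal lengths, Levenshtein
otherwise; N matches anything), take connected components — membership is by
chaining, not clique.  The same procedure runs on CDR3 peptides.  Pairwise
comparison is O(n²), adequate for the few hundred reads per V–J family this
pipeline targets.

## The synthetic repertoire generator

Real lymph-node repertoires mix lineages from many GCs and are not
redistributable, so `gcsim.lineages.generate_synthetic_repertoire` plants a
known structure: a few V–J families, each with a small number of lineages;
lineage founders drawn independently (two random 300-mers differ at ~75% of
positions, far outside any clustering radius); members within ≤ 2
substitutions of their founder, which is always emitted so the lineage is
connected through it; read counts from a truncated Zipf (a = 2.5), so most
subclones are singletons and a few are strongly expanded.  What passing
recovery tests show: the clustering is correct on well-separated lineages.
What they do not show: robustness to indel sequencing error, shared
mutations between lineages, or borderline founder distances — real-data
behavior must be judged per sample.

## Known limitations

* **The published parameterization is self-undermining at late times.**
  Per-cell SHM at λ = 0.6 removes a daughter from its parent subclone
  (death or new-subclone foundation) with probability 0.45 per 6-h step at
  the nucleotide level — an unavoidable ~1.8/day per-capita drain on every
  subclone large enough to mutate, independent of the fate-tree
  probabilities.  Subclones below one CB cell are exempt from SHM, so they
  enjoy exactly that fitness advantage.  The long-run attractor is a
  population of tens of thousands of sub-unit "dust" subclones in which no
  clone holds a whole CC cell: late-reaction diversity, expansion and
  rank-correlation statistics degenerate.  The reported mid-reaction
  dynamics (peak size/timing, CB/CC band, day-10 mutation loads, the
  75th-percentile affinity) are reproduced; the late-reaction subclone
  structure of the original report is not reachable under these stated
  mechanics, and its published description gives no further detail to
  resolve the discrepancy.  The `subunit_mutation_loss` option applies the
  same expected mutation outflow to sub-unit clones deterministically
  (they still never spawn), which removes the refuge and restores
  persistent expanded clones; it is off by default because it is this
  package's own construction.
* Mutation depth grows with clone survival time; maximum mutation loads at
  day 21 exceed typical reported single-GC values under per-cell sampling.
* No GC shutdown, no spatial dark/light zones, no explicit antigen, FDC or
  Tfh agents, no explicit BCR sequence (hence no back-mutations and no
  CDR1/2/3 distinction) — all deliberate scope choices of the underlying
  model.
* Continuous compartments stand in for small integer cell numbers; the
  floor/rounding conventions (floor(CB) mutating daughters, rounded CC
  counts, the 0.1-cell pruning floor) are documented interpretations.

## Problem sizes

Default analyses use 5 nucleotide-level replicates for population-dynamics
summaries and 15 peptide-level replicates for abundance–affinity summaries
(the out-of-15 top-quartile count keeps its natural denominator); a
replicate takes a few seconds to ~a minute on one CPU depending on how many
subclones the run spawns.
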