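# Methods

## Model

Repeated categorization data are arranged as a respondent-entry × item
binary matrix for each category.  Each session of each two-session
participant is one entry, treated as exchangeable with the single-session
archival entries; this deliberately ignores the within-participant
dependence between sessions, because the question of interest is precisely
whether the two sessions of one person behave like two *different*
categorizers.

For entry *p* and item *i*:

- z_p ~ Categorical(π), π ~ Dirichlet(1, …, 1) over G groups (G = 2 by
  default; no model selection over G is attempted),
- β_{g,i} ~ Normal(0, 1): the scale value of item i under group g's
  criterion,
- μ_g ~ Normal(0, 1), θ_p ~ Normal(μ_{z_p}, 1): thresholds ("precision 1"
  is unit variance throughout),
- α_g half-normal with unit variance: steepness of the response curve,
- x_{pi} ~ Bernoulli(r_{pi}), with r = logistic(α_g (β_{g,i} − θ_p)).

The logistic form is the standard two-parameter choice satisfying the three
qualitative constraints on the response curve: S-shape, asymptotes at 0 and
1, and probability exactly .50 at β = θ.  A probit link would be an almost
indistinguishable alternative; nothing downstream depends on the
difference.

*Unknown* answers are missing completely at random from the model's point
of view: their cells contribute nothing to the likelihood and are never
imputed.  Entries that answered *unknown* everywhere are retained (their
group assignment then follows the prior and the threshold hyper-structure).

## Sampler

Metropolis-within-Gibbs, three chains by default (protocol configurable;
the conventional production protocol is 3 × 10,000 sweeps with 4,000
burn-in; the tests and the acceptance script use 3 × 3,000 with 1,000
burn-in, which the convergence diagnostics show to be sufficient at the
370 × 24 scale):

- **z**: exact Gibbs from its closed-form categorical conditional
  (likelihood row + threshold-prior term + log π).
- **π**: conjugate Dirichlet(1 + counts).
- **μ**: conjugate normal (the full conditional given θ and z is Gaussian,
  so an exact draw is used rather than a random-walk step).
- **β, θ**: componentwise Gaussian random walks; all β_{g,i} are
  conditionally independent given (z, θ, α) and are updated in parallel,
  likewise all θ_p.
- **α**: random walk on log α with the Jacobian correction.
- **Translation group-move**: the likelihood depends on β_{g,i} − θ_p only,
  so a common shift of (β_g, μ_g, θ_{z=g}) is a prior-constrained flat
  direction that componentwise walks cross only diffusively — slowly enough
  that chains otherwise stall at visibly different locations (split R-hat
  far above 1.1 on most parameters).  The shift's conditional under the
  β and μ priors is Gaussian, δ_g ~ Normal(−(Σ_i β_{g,i} + μ_g)/(I+1),
  1/(I+1)), and is sampled exactly once per sweep.

Proposal scales adapt toward ~0.4 acceptance with a diminishing step, and
adaptation is confined to burn-in so the retained draws come from a fixed
kernel.  Chain c uses seed (master seed + c); identical inputs reproduce
identical draws bit for bit.

## Label switching and assignment

The mixture posterior is invariant under group relabeling.  Relabeling is
two-stage: a provisional pass aligns every draw (all chains) with a pivot
draw by maximizing the summed Pearson correlation of β rows over group
permutations; the first chain's posterior-mean β, groups ordered by μ, then
serves as the reference for the final pass.  The provisional stage matters
when labels switch *within* a chain, in which case the raw chain mean is a
mixture of labelings and useless as a reference.  Exact ties (numerically
indistinguishable β rows) fall back to ordering by μ.  Relabeling permutes
π, β, μ, α and z consistently, leaves every draw's likelihood unchanged,
and is idempotent.

Each entry's group is the posterior mode of z_p over draws pooled across
chains; assignment probabilities are the corresponding draw fractions.
Exact ties are flagged and broken toward the lower group index.  A
participant counts as a criterion change when the modal groups of their two
session entries differ — a relabeling-invariant comparison.

## Synthetic studies

The generator emulates a two-session categorization study of 60 completers
plus 250 archival single-session respondents answering 24 items per
category (370 × 24 after merging), with three mechanisms of between-session
change:

- **Criterial switching**: a fixed fraction (default 0.2) of participants
  move to a different group in session 2 and draw a fresh threshold from
  the new group's hyper-distribution (a new criterion plausibly resets the
  threshold's frame of reference; keeping θ is available via
  `redraw_thresholds=False` semantics below).
- **Degree drift**: non-switchers' thresholds take a stationary AR(1) step,
  θ₂ = μ + ρ(θ₁ − μ) + √(1−ρ²)·ε with ρ = 0.98, which preserves the
  Normal(μ, 1) marginal the model assumes; ρ = 0 is a fresh redraw and
  `redraw_thresholds=False` keeps θ exactly (in which case sessions differ
  by Bernoulli response noise alone, with per-cell disagreement 2p(1−p)).
- **Unknown contamination**: each cell independently becomes *unknown*
  with probability 0.02.

Remaining defaults: π = (0.5, 0.5), μ = (−0.5, +0.5), α = (6, 6), β rows
standard normal with between-group correlation 0.5.  The steepness and the
between-group correlation were calibrated, by direct simulation before any
model fitting, so that the realized two-session inconsistency rate lands in
the 10–25% band characteristic of repeated category-membership tasks
(realization mean ≈ 0.20, 5–95% range ≈ 0.18–0.23): shallower curves or a
full threshold redraw push disagreement above 35–40%, which no repeated
categorization study reports.  Correlation 0.5 also reflects that rival
criteria agree on clear members and clear non-members and disagree mainly
on borderline items — independent criteria would make a group switch flip
half of a participant's answers, far more destruction than observed
switch rates permit.  Note the generating α = 6 sits in the tail of the
analysis model's half-normal prior; the fitted α is accordingly shrunk
(posterior means near 4–5), a deliberate prior-data tension that leaves
the scale-free summaries (item-scale correlations, group assignments)
untouched.

What the generator does **not** emulate: item content and real item
difficulty structure, participant-level response styles, any systematic
(non-MCAR) mechanism for *unknown* answers, or session-order effects.
Passing recovery tests therefore shows the estimator is consistent with its
own assumptions at realistic dimensions, not that those assumptions hold
for human data.

## Numerical choices and edge cases

- Bernoulli log-likelihoods use −softplus(∓η); probabilities never
  round-trip through exp, so extreme α cannot produce log(0).
- Boundary simplexes are nudged 1e−12 inside the support before density
  evaluation.
- Degenerate (constant) chains are reported as `degenerate` in the
  diagnostics table rather than dividing by zero; split R-hat and ESS come
  from ArviZ.
- Merged matrices order items lexicographically so β indexing is
  reproducible; missing cells serialize as `NA`.
- An entry present in only one session, a duplicated response row, or an
  unmapped category all fail fast with a named offender.

## Operating characteristics

At the default study dimensions with 3 × 3,000 draws, repeated simulation
shows per-group item-scale correlations with truth ≥ 0.98, entry-level
assignment accuracy 0.95–1.00, and switch-detection specificity ≥ 0.97.
Sensitivity is typically 0.83–1.00 but can dip lower for an unlucky
realization: a switcher whose fresh threshold lands where the two criteria
imply similar answers is genuinely hard to detect from 24 binary responses.
Occasional realizations also leave a few ambiguous entries' thresholds
bimodal across chains (split R-hat above 1.1 on those θ while all
group-level parameters converge).  These are properties of the inference
problem at this data size, not of the sampler.

## Open design choices

- Whether unknown/unknown session pairs belong in inconsistency
  denominators is not settled by the task design; they are *included* by
  default (the participant did answer, twice, identically) and excluded via
  `include_unknown_pairs=False`.
- Assignment pools draws across chains after relabeling rather than using a
  single chain; with converged chains the two coincide.
- Criterion-change prevalence is reported with both denominators (all
  participants, and participants with ≥ 1 inconsistency in the category),
  since only inconsistent responders can reveal a criterion change.
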