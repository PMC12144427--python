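# Methods

`ratplay` analyses play-partner preferences in groups of familiar juvenile
rats.  The observational unit is a *playful nape attack*: one rat's snout
contacts (or is aimed at) the nape of a groupmate's neck, the canonical
target of rat rough-and-tumble play.  A study consists of `G` groups of
`k` co-housed animals (defaults `G = 8`, `k = 6`), each filmed in 20-minute
sessions on scored days 1, 3, 5 and 8 of an eight-day window spanning the
peak juvenile play period (roughly postnatal days 30–40).

## Data model

Every attack is one row: group, day, onset time, initiator, recipient, the
recipient's defensive response (`no_response`, `evasion`, `pin`, `box`),
whether the defender achieved a *role reversal* (a successful
counterattack — the turn-taking measure), and how many of the initiator's
`k − 1` potential partners were free at that moment.  Attacks aggregate per
group-day into a directed count matrix `B` with `B_ij` = attacks `i → j`
and row totals `B_i`; row-normalising gives the proportion matrix used for
networks and the randomness screen.  Overlapping bouts are timestamped at
bout onset; only days {1, 3, 5, 8} are accepted unless explicitly
overridden, and dominance-rank ties (equal tube-test wins) are broken by
animal label and flagged.

## Preference index

For each directed dyad the preference index compares observed play against
the equal-partner expectation:

    I_ij = B_ij / (B_i / (k − 1))

`I = 1` is chance-level use of partner `j`; `I ≥ 2` is classified a strong
preference, `1 < I < 2` a (weak) preference, `I ≤ 0.25` avoidance.  Two
identities follow from the definition and are asserted to 1e−12 in tests:
uniform play gives `I = 1` exactly for every dyad, and each initiator's
indices average exactly 1 whenever `B_i > 0`.  Initiators that never
attacked get flagged-undefined indices.

The index is implemented in its observed-over-expected form,
`I_ij = B_ij (k − 1) / B_i`, the only reading consistent with the
chance/strong/avoided thresholds above.

## Randomness screen (Mantel permutation test)

Before indices are computed, each group-day is screened: does the observed
distribution of play differ from what equal partner use would give?  Both
the observed and a hypothetical matrix are reduced to symmetric dyadic
dissimilarities `d_ij = max_sym − (m_ij + m_ji)/2`, their upper triangles
are correlated (Pearson `r`), and significance comes from jointly permuting
the row/column labels of the observed matrix (9 999 permutations by
default, one-sided on `r`, add-one estimator so `p ≥ 1/(n_perm + 1)`).
A *significant* correlation means play matches the equal-use expectation —
no preferences — and the group-day is excluded from all preference
analyses.

Two construction choices matter and are deliberate:

* The observed side uses the **proportion** matrix, so that between-animal
  variation in play output does not masquerade as structure.  With raw
  counts, the dyadic dissimilarities of any group inherit the row-total
  pattern and correlate with the hypothetical matrix even when strong
  preferences are present; in pilot runs this "excluded" 25–49% of
  preference-laden group-days.  On proportions, planted-preference
  group-days are excluded at ~5% and uniform-play group-days at ~4%
  (frozen regression constant 0.040 ± 0.03, 500 replicates) — i.e. the
  screen operates near its nominal level, which matches the observed
  behaviour of such screens on real group-play data (2 of 32 days
  excluded, both at chance-compatible r ≈ 0.5).
* The hypothetical side spreads each animal's observed total evenly,
  `H_ij = B_i/(k − 1)`.  Using the equal-use expectation on the proportion
  scale would make the hypothetical dissimilarities constant and the
  correlation undefined; preserving row totals keeps the test well-posed.
  A matrix whose dissimilarities are constant anyway (e.g. exactly uniform
  integer play) raises a typed `DegenerateMatrixError` rather than
  returning NaN.

## Symmetry, popularity, stability, dominance

* **Play symmetry** of a dyad: `1 − |B_ij − B_ji| / (B_ij + B_ji)`;
  1 = perfectly reciprocal, 0 = one-sided; undefined (flagged) for dyads
  that never played.
* **Popularity**: the percentage of each rater's play received by each
  groupmate (row-normalised ×100); per rater the percentages sum to 100.
* **Daily z-scores** of play initiated, per group-day across animals
  (sample SD, ddof = 1); `|z| ≥ 1.96` (configurable) flags animals playing
  significantly above/below the group's daily mean.  A zero-SD day yields
  z = 0 with an undefined flag, since all deviations are zero but
  significance is not assessable.
* **Rank-change stability**: per animal, partners are ranked 1 (favourite)
  to `k − 1` by proportion of play directed at them (ties broken by label,
  flagged).  Between consecutive scored days, favourite change =
  yesterday's rank of today's favourite − 1; least-favourite change =
  `(k − 1)` − yesterday's rank of today's least favourite.  Both live in
  {0, …, k − 2}.  Day ranking uses proportions rather than raw counts,
  consistent with the proportion-based networks; counts would conflate
  output changes with preference changes.
* **Tube test**: five trials per unordered pair; a win scores one point,
  ties none; ranks descend by tally with label-order tie-breaks, flagged.

## Networks

Directed play networks have node size = total attacks initiated and edge
weight = proportion of the initiator's play (so out-weights of active
animals sum to 1).  The undirected variant weighs each dyad by its total
play in both directions.  The preference network keeps only strong
(`I ≥ 2`, solid) and avoided (`I ≤ 0.25`, dashed) dyads.  Sub-group
structure is scored by greedy weighted-modularity maximisation (CNM);
significance permutes the observed edge weights across the fixed set of
`k(k−1)/2` dyads and compares maximised modularity, add-one corrected.
Eigenvector centrality is computed on the undirected weighted projection,
normalised to max 1, per connected component with a disconnection flag
(a 20-minute session can lack dyads).  Layouts are deterministic
(circular), so exports are byte-reproducible.

## Repeated-measures ANOVAs

Popularity ("are some animals consistently favoured?") is a one-way
within-subjects ANOVA over target identity; because a target cannot rate
itself, the `k − 1` raters are mapped to slots by label order among the
target's partners, making each (slot, day) a repeated unit — `k = 6` and
4 days give df (5, 95).  Day-to-day popularity of one animal uses day as
the within factor (df (3, 12) at the default design), and group totals use
group as the within factor with days as subjects (df (7, 21)).  Sums of
squares are computed from the balanced-table identities so degenerate
inputs return F = 0 rather than 0/0; agreement with `statsmodels.AnovaRM`
is asserted to 1e−8 in tests.  No sphericity correction is applied by
default (a Greenhouse–Geisser option exists).  Bonferroni pairwise
comparisons use the full family of level pairs (m = 15 for six targets),
recorded in the output.

## Mixed-effects logistic models

Two binary models contrast strongly preferred (outcome 1) against avoided
(outcome 0) dyad-days.  Model 1 uses play style/quality: the partner's
attacks toward the focal animal and the percentages of its responses
(no response, evasion, pin) and role reversals, with a random intercept for
initiator identity.  Model 2 uses dyadic measures — play symmetry,
proximity seconds, weight difference and dominance-rank difference — with
crossed random intercepts for initiator and recipient.  Predictors enter
untransformed, so odds ratios are per unit (per percentage point, per
second, per gram, per rank).

Estimation maximises the Laplace-approximated marginal likelihood (damped
Newton for the conditional modes of the random effects; L-BFGS-B over
fixed effects and log-SDs; Wald SEs from the numerically differentiated
Hessian).  This is the same approximation `lme4::glmer` uses by default,
and the two agree to ~1e−3 on a shared dataset in the test suite.
Confidence intervals are `estimate ± 1.96 SE` on the log-odds scale (as
such model tables conventionally print them) with `OR = exp(estimate)`.
A random-effect variance estimating at the boundary (0) has a flat
likelihood direction; such factors are dropped and the model refit, and if
every factor is at the boundary the fit collapses to ordinary logistic
regression, reported with an explicit flag.  Complete separation raises a
typed error recommending a penalised fit rather than reporting meaningless
Wald statistics.  Calibration on synthetic rows (200 rows, 20 clusters,
random-intercept SD 1): a planted role-reversal effect of 0.08 per
percentage point is recovered with p < 0.05 in ≥ 90% of replicates, and
null-effect 95% Wald CIs cover 0 in ~95.6% of 500 fits.

Rows whose focal animal never attacked the partner that day have undefined
tactic percentages and are dropped with a log entry.

## Availability correction

Since two playing rats are unavailable to others, preferences could be
availability artefacts.  Counts are therefore recomputed using only
attacks launched when all `k − 1` partners were free; the retained
fraction is reported.  For each classified dyad, the adjusted count is
compared with the initiator's median adjusted count across its partners:
preferred dyads should sit above, avoided below.  Ties at the median count
as failures (conservative) and are flagged.  Successes are tested with the
exact two-sided binomial sign test, `p = min(1, 2·min{P(X ≤ s),
P(X ≥ s)})` with `X ~ Bin(n, ½)` — verified against exact
fraction-arithmetic enumeration for all n ≤ 20.

## Synthetic-study generator

The generator emulates the study design so every stage is testable without
video: per animal a latent attack rate (uniform on 20–60 attacks/session)
and a partner-weight vector over its `k − 1` groupmates drawn from a
symmetric Dirichlet (concentration 4.0 by default).  Each day's weights
are a logistic-normal jitter of the animal's stable baseline —
`normalize(base · exp(drift · ε))`, fresh ε per day, `drift = 0.5` — so
day-to-day favourites change without variance accumulating across the
study.  Defaults were chosen once, by pilot, to give a study-scale
structure of the same order as real group-play data: median favourite
rank change 1 (observed: favourites typically become the second or middle
favourite), tens of strong/avoided classifications per study, and
near-zero randomness-screen exclusions.  `planted_dyads` force chosen
directed dyads to a fixed weight (0.6 by default), guaranteeing
recoverable strong preferences (index ≈ 3 in expectation).

Responses are drawn from tactic profiles anchored at the observed means
for preferred partners (no response 29.6%, evasion 31.6%, pin 30.5%, role
reversal 47.3% of attacks) and non-preferred partners (14.8% / 29.6% /
11.1% / 2.4%), linearly blended by the recipient's weight between 0.05 and
0.40; role reversals are only drawn on defended attacks (an ignored attack
cannot be counterattacked), with the conditional probability set so the
overall percentage matches the profile.  Partner availability is an
independent per-attack draw: all partners free with probability 0.6, and
otherwise a distribution over 0–4 free partners chosen so that ≥ 2
partners are free in 98.8% of attacks — matching the study-design
marginals the correction needs.  Proximity seconds are drawn per dyad-day
(normal, mean 287 s, SD 60 s, clipped to the session); body weights are
normal (105 ± 10 g, juvenile-male scale); tube-test trials use latent
strengths with win probability `expit(s_a − s_b)` and a 5% tie rate.

What the generator does **not** emulate: spatial movement (proximity is
drawn, not derived from trajectories), within-session nonstationarity,
bout structure beyond onset times, and any correlation between an animal's
rate and its popularity.  Passing tests therefore demonstrate that the
statistical machinery recovers planted structure of realistic magnitude —
not that real rats obey the generator's distributions.

## Numerical and reproducibility choices

All randomness flows from `numpy.random.default_rng` seeds; per-stage
sub-seeds are derived by hashing (master seed, stage, group, day), so
stages are independently reproducible and reruns are byte-stable.  Every
permutation p-value uses the add-one estimator.  Index thresholds
(2, 1, 0.25), α = 0.05, the z cutoff 1.96 and the Wald multiplier 1.96 are
configurable but default to the conventional values above.  Problem sizes
in the test suite (100 planted group-days for recovery, 500 replicates for
coverage and screen calibration, 9 999 permutations in the pipeline
default and 199–999 in tests) were chosen as the smallest sizes at which
the binomial/KS tolerances in use are meaningful.

## Known limitations

* The Laplace approximation can bias variance components downward in
  small-cluster binary data; fixed-effect coverage is calibrated in tests,
  variance components are not.
* The randomness screen has, by construction, little power against
  *proportionally* uniform play with heterogeneous output — it operates at
  its nominal exclusion level; it exists as an exclusion gate, not a
  powerful test of uniformity.
* The popularity ANOVA's rater-slot construction treats slots, not
  animals, as the repeated unit; this reproduces the (5, 95) design dfs
  but, as in the original design, the "subjects" are not physically
  identical across levels.
* Day-ranking ties (equal proportions to two partners) are broken by
  label; with heavy play this is rare but flagged when it occurs.
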