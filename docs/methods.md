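# Methods

This note documents the models implemented in `moodnet`, the assumptions
behind them, the defaults that matter, and what the synthetic-data tests do
and do not establish about real data.

## Data model

Input is a JSON-Lines log of scored messages (author, UTC timestamp,
mentioned users, per-measure sentiment scores).  Three combined sentiment
measures are supported: an integer scale `MC` in −25…+25, a
SentiStrength-style `SS = pos − neg` with components in 1…5 (so `SS` in
−4…+4), and a LIWC-style `L = posemo − negemo` in −100…+100.  An absent
score is represented as absent, never as zero; a zero score is read as
"neutral or not detected".  Sentiment scoring itself is upstream of this
package, and scores are treated as a noisy signal: every statistic here
averages over many messages or users.

Each message mentioning `k` distinct other users induces `k` directed
mention edges.  Self-mentions are dropped and duplicate mentions within one
message collapse, so mention networks connect distinct users and daily
adjacency snapshots are binary with zero diagonal.  Day boundaries sit at
00:00 UTC; windows are half-open.  Message multiplicities are retained on
edge lists (weighted conductance and agent-graph construction need counts);
snapshots are binarised (communicability is defined on adjacency).

Outlier screening removes *celebrities* (more distinct inbound mentioners
than a cap) and *bots* (more distinct outbound mentionees than a cap).  Both
caps default to 5000 per observation window and are deliberately
configurable and reported rather than silent: appropriate thresholds depend
on the corpus, and including such accounts degenerates the network (a
two-hop path exists between most user pairs via one hub).

## Dynamic communicability

For snapshots `A_1 … A_n` the communicability matrix is the ordered product
of Katz resolvents `Q = ∏_t (I − αA_t)⁻¹`.  Expanding each resolvent shows
`Q[i,j]` is the sum over all time-respecting walks from `i` to `j` —
snapshots used in non-decreasing time order, any number of consecutive hops
per snapshot — weighted `α^L` for total length `L`.  Small `α` favours
short paths; `α` must satisfy `α < 1/max_t ρ(A_t)` (largest eigenvalue
magnitude), which is validated strictly.  An explicit `rescale` flag maps
`α ← α/ρ_max` for exploratory sweeps; it is never applied silently.

Numerics: `Q` is accumulated left-to-right by one linear solve per
snapshot (`Q ← solve((I − αA_t)ᵀ, Qᵀ)ᵀ`), never by inverting a product.
Empty snapshots contribute identity factors and are skipped, so missing
days need no special casing.  Up to 5000 nodes `Q` is dense; above that
only broadcast/receive vectors are computed by propagating a ones vector
through the same resolvents (right-to-left for row sums, left-to-right
transposed for column sums).  The two paths agree to 1e−10 on overlapping
cases in the test suite.  The unit-test oracle is an independent dynamic
programme that counts `α^L`-weighted walks directly, truncated at length 25
so its geometric tail (at `α·ρ < 0.3`) is below 1e−14 — far under the 1e−8
comparison tolerance.

## User-level sentiment attributes and group comparison

Seven attributes summarise a user's outgoing edges per measure: mean
sentiment; mean absolute sentiment (for `MC` the mean of `|score|`; for
`SS`/`L`, where signed components exist, the mean over edges of the sum of
the components' absolute values); positive/zero/negative fractions; and
average positive/negative strengths, each normalised by the *total*
outgoing-edge count so that `avg_pos − avg_neg = mean` exactly.

Group-vs-population comparisons (e.g. top-`k` broadcasters against all
users, `k` ∈ {500, 1000, 5000}) use one-sided randomization tests: the null
distribution is the means of uniformly drawn same-size subsets, and
`p = (r+1)/(n_resamples+1)` with ties counted as exceedances.  This
estimator is conservative and never returns zero; the number of resamples
is configurable (default 999).  Under a random-group null the realised
type-I rate at the 5% level is verified to sit within binomial error of
5%.  Rank-trend curves use a plain moving average over rank-ordered
attribute vectors (window on the order of 1000 observations for corpora
with 10⁵ users; any window ≥ 1 is accepted).

## Community metrics

Conductance and weighted conductance are computed on the symmetric exchange
graph (`W_ij + W_ji` messages between `i` and `j`), implemented on
networkx cut/volume primitives with an explicit zero-cut guard.  Mean
community sentiment is edge-weighted (per mention), not per-user.  The
non-zero-sentiment fraction — used in practice to screen out non-English
communities whose tweets score zero — treats absent scores as zero.
Connectedness is evaluated on the undirected internal graph over all
members, so an isolated member marks the community disconnected.
Participation percentages bin into [0,20), [20,40), [40,60), [60,80),
[80,100]: a 100% participant lands in the top bin.  The user loss factor is
(members active in window 1) / (members active in window 2), where *active*
means incident to at least one internal mention; a factor of 1 means full
retention and a zero second-window count raises a "community dissolved"
error.  Daily sentiment series flag days whose mean deviates from the
series mean by more than `z` population standard deviations (default
`z = 2.5`); attribution of flagged days to real-world events is left to the
analyst.

## The agent-based model

Agents sit on a static undirected graph connecting pairs who exchanged
strictly more messages than the *neighbour frequency threshold*.  The six
global parameters are: iterations (steps) per day; mean messages per burst;
contagion factor; sentiment reset probability; sentiment noise level; and
the neighbour threshold.  Each agent has five constants — initiation,
reply and propagation probabilities and baseline/neutral sentiment levels —
and two state variables: current sentiment and last step's senders.

Per synchronous step, from end-of-previous-step states:

1. **Actions.**  An agent with no recent senders *initiates* with
   probability `p_init`, sending one burst to one uniformly chosen
   neighbour.  An agent with recent senders *replies* with probability
   `p_reply` (a burst to each recent sender) and independently *propagates*
   with probability `p_prop` (a burst to one uniformly chosen non-sender
   neighbour).  The exact send rule was a genuinely open design point; one
   decision per behavioural context was chosen because it makes the
   estimators below exactly unbiased: the frequency of "sent, given no
   recent receipt" windows converges to `p_init` itself, not to a
   degree-dependent transform of it, and likewise for replies and
   propagations.  The rule is isolated in one loop so alternatives (e.g.
   per-neighbour independent sends) can be swapped in.
2. **Bursts.**  `1 + Poisson(mean_burst − 1)` messages (guaranteeing ≥ 1
   with the configured mean), sharing one sentiment: sender's current
   sentiment plus `N(0, noise_sd)`, clamped to the measure range.  Burst
   size is drawn per (sender, receiver, step).
3. **Contagion.**  A receiver of messages with message-count-weighted mean
   sentiment `m` updates `current += contagion · (m − s_neutral)`; the mean
   (rather than the sum) keeps the update bounded regardless of volume.
   Current sentiment is clamped to the measure range.
4. **Reset.**  With probability `reset_prob` the agent's sentiment snaps
   back to its baseline.  Recent-sender sets are then reassigned.

Initial state: sentiment at baseline, no recent senders.  Identical inputs
and seed give a byte-identical log.

**Newly introduced users.**  Scenario analysis adds one agent wired to
chosen members.  Incumbents treat a newcomer as a *passive target*: they
reply to its messages but do not spontaneously initiate or propagate
towards it (a newcomer is not yet in anyone's routine contact set).  This
is a deliberate modelling choice: under any rule where incumbents initiate
towards arbitrary neighbours, wiring in a completely silent newcomer would
measurably perturb activity (absorbing or attracting initiations), whereas
a null intervention should be null.  With this rule a silent newcomer
leaves the dynamics exactly unchanged, which the tests verify by a Welch
test over 200 paired runs.

**Estimation.**  Historical time is split into windows of one step's
length.  `p_init` = (windows with no receipt in the previous window in
which the agent sent) / (windows with no receipt in the previous window);
`p_reply` and `p_prop` use windows with previous-window receipt as
denominator and "sent to ≥ 1 previous sender" / "sent to ≥ 1 non-sender
neighbour" as numerators.  Zero denominators yield probability 0 plus a
warning flag, and per-agent sample sizes are reported.  Baselines are
per-user mean message sentiment; the neutral level is the community-wide
mean, shared by all agents.  Window indices use integer-microsecond
arithmetic with sub-microsecond slack so boundary timestamps never leak
into the preceding window.

## Calibration and scenarios

A run is scored against data by
`ρ = α Σ|⟨C_i⟩−⟨Ĉ_i⟩| + β Σ|std C_i − std Ĉ_i| + γ |⟨E_c⟩−⟨Ê_c⟩| + δ |std E_c − std Ê_c|`
over per-user daily message counts `C_i` and daily message-weighted
community sentiment `E_c` (population standard deviations; days with no
messages count zero towards activity and are excluded from the sentiment
series).  Default constants `(1, 0.1, 10, 100)` emphasise matching
sentiment volatility most and activity volatility least.

Calibration is an iterative grid search: each zoom evaluates the full grid
(default 4 points per free dimension; integer parameters on integer grids),
averaging ρ over seeded runs per point (default 50), then re-centres on the
incumbent best with the span halved, clipped to the original ranges —
chosen for determinism and monotone refinement.  Default zoom count is 5.
Per-combination seeds derive from (master seed, zoom, grid coordinate), so
combinations are independent and re-runs reproducible.  Shipped default
ranges bracket plausible fits (iterations/day 96–3072, burst mean 1–4,
contagion 0–0.5, reset 0–0.3, noise 0–12).  The neighbour threshold shapes
the agent graph and the estimated characteristics, both of which
`calibrate` receives pre-built, so it is a structural input here; to search
it, rebuild graph + characteristics per candidate value and compare best
scores.  Because the objective is stochastic, self-consistency — the
calibrated optimum scoring no worse than the generating parameters, within
one standard error of the score estimate — is the guaranteed property;
exact parameter recovery is not.

The new-user scenario sets the newcomer's probabilities to a multiple
(default 3×, capped at 1) of the community maxima and both its sentiment
levels to the community level (the mean neutral level of existing agents —
the baseline assignment is standard, using it for the neutral level as well
is a documented choice).  Neighbour rules: top/bottom `n` (default 3) by
baseline sentiment or by reply probability, ties broken by user id.  The
four reported metrics (activity mean/SD, sentiment mean/SD) are averaged
over seeded runs (default 100) for baseline and modified models.

## Synthetic data

The generator emulates: bursty per-user messaging with reply structure (it
*is* the ABM, run on a sampled ring-plus-chords connected graph), per-user
baseline sentiment plus noise (Beta-distributed probabilities with
configurable means — initiation and reply independent by default, matching
the empirically observed lack of correlation between the two roles — and
truncated-Normal baselines), and planted event days that shift all of a
day's scores.  It does not emulate message text, follower/retweet
mechanics, realistic degree distributions, network growth, or the
celebrity/bot contamination the filters target (tests plant those
explicitly).  Passing tests therefore establish internal consistency of
the pipeline and estimators under the model's own assumptions — not that
the model captures any particular real community.

## Problem sizes and numerical choices

The test suite and acceptance script use desk-scale problems chosen to make
the statistical checks sharp: 50 random 6-node, 4-snapshot networks for the
walk oracle; 15-agent communities with 10⁴ estimation windows and 10 seeds
for parameter recovery (each probability within 3 binomial standard errors
for ≥ 95% of agent–parameter pairs); a 2-parameter, 4-point, 3-zoom
calibration at 20–50 runs per point; 100-run scenario averages; 2000
repetitions for randomization-test calibration.  Tolerances: 1e−8 for the
walk oracle (the oracle's own truncation tail is < 1e−14); exact equality
for degenerate ABM invariants; 3σ bands for stochastic closed forms.
Degenerate inputs raise typed errors rather than returning sentinels:
empty networks, empty communities, `S = V` conductance, zero-message
summaries, dissolved communities, out-of-bound penalties.

## Known limitations

Sentiment scores are consumed, never computed; non-English content appears
as zero scores.  The exact burst-decision equations of the original
formulation were reconstructed (see Actions above) and alternatives may fit
some communities better.  Estimation assumes window length equals the
generating step length; misspecified `iterations_per_day` biases the
probability estimates.  Calibration cost grows exponentially in the number
of free parameters (full grid per zoom); freeze parameters you can fix.
The agent graph is static: joining/leaving dynamics beyond the single
new-user scenario are out of scope.
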