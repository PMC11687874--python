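# Methods

This note documents the models behind `stanceform`, the stated world of the
synthetic generator, the numerical choices, and what a green test does and
does not establish.

## Timelines

The window is 5 calendar months from June 2021 (configurable), each month
split into periods 1–10, 11–20, 21–end-of-month; short months simply end the
third period at the month's last day. Timestamps are Japan Standard Time and
period membership is decided by calendar date.

Per user and period, stance is the plurality of tweet labels; ties resolve
by a configurable priority defaulting to pro > neutral > anti (the
downstream classifier's per-class precision order). Tweets carrying only a
class-probability triple are first labeled through the anti-threshold rule.
Unobserved periods after the first observation carry the last observed
stance forward; leading gaps take the first observed stance. Provenance
(observed / carried_forward / backfilled) is kept per slot. Users with posts
in fewer than 4 distinct months are excluded before filling.

Two per-period stance-count views exist on purpose: counts over *observed*
users only (all posters, no fill — the all-users view) and counts over
*filled* active-user timelines (the longitudinal view). The original figures
are ambiguous about which they use; both are exported.

Fleiss' kappa ships as an annotation-QC statistic (delegating to
statsmodels) for rater-by-item tally tables; it is not used by the pipeline
itself. The published agreement of 0.74 is not reproducible here because the
annotations were never deposited.

## Modified Random Walk Controversy

Per period the undirected retweet graph joins two users when either
retweeted the other (weight = count, self-loops dropped, non-retweet
reactions excluded by default but selectable). The degree filter is applied
once, not iteratively; the analysis default is `min_degree=1` — the
original's ≥ 30 filter was a depiction choice and ships as a preset.

Louvain at resolution 2 (networkx implementation, seeded) partitions the
graph; the three largest communities are stance-labeled by member majority,
with ties going to neutral (conservative: a tie never manufactures a
pro/anti side).

RWC between the pro- and anti-labeled communities: absorbing nodes are the
k = 10 highest-degree nodes within each side (ties by ascending node id);
walks start uniformly at random from the non-absorbing nodes of the start
side and hop to a uniformly random neighbor (edge weights ignored by
default; a weighted-walk variant exists behind a flag). Every other node —
in particular the whole neutral community — is traversable but never
absorbing. `P_xy` is the probability of absorption on side *y* conditional
on absorption, pooled over the start distribution; walks trapped in
components without absorbing nodes are excluded from the conditioning and
reported as an unreachable fraction, and a start side with *no* path to any
absorbing node raises a disconnection error. The original description fixes
only the start sides, the absorbing set, and k; start distribution,
neighbor-uniform steps and conditioning-on-absorption are this package's
documented choices, following the original RWC construction.

The exact method solves the absorbing-chain system (I − Q)X = R with a
sparse LU solve, restricted to components containing absorbing nodes. The
Monte-Carlo method runs vectorized walks (default 10⁵ per side) and reports
a standard error for RWC; because each P-matrix row sums to 1,
RWC = P_pp + P_aa − 1 and its variance is the sum of two binomial variances.

**Desk-scale caveat.** "Label the three largest communities" assumes the
anti community ranks in the top three by node count. That held at the
original corpus scale (~300k active users); at 2000 users, resolution-2
modularity caps community sizes well below the pro/neutral group sizes, so
those groups fragment and the minority community surfaces in only part of
the periods. `rwc_series` therefore reports per-period "undefined" markers
rather than failing, and the homophily-monotonicity tests use explicit
stance-labeled sides on planted graphs, where the property is actually
stated.

## Transitions and cohorts

The transition matrix counts users by (stance at period 0, stance at period
14) over filled timelines — fill precedes the cohort analysis by
construction. Retention/shift percentages follow the original presentation:
rounded to whole percent at ≥ 10%, one decimal below 10% (half-up).
Recomputing the published 3×3 table reproduces every narrative percentage
except pro retention: 110,817/153,410 = 72.24%, which rounds to 72, not the
printed 73. The package reports the arithmetic value.

Cohorts are judged on the filled 15-slot trajectory: exactly one change
point, from neutral to pro (or anti), held to the end; remaining-neutral is
neutral in all 15 slots; everything else (including non-neutral starts) is
"other". The earliest possible change is period 1, and the change month is
the 0-based month offset containing the change period.

## Sharing enrichment

For a comparison month *m*: changers whose change month is *m* contribute
events from their change period plus the three prior periods (clipped at
period 0 for changes before period 3, where a full window does not exist);
remaining-neutral users contribute the literal month by default, with a
4-period symmetric window behind a flag (the original text reads as the
literal month). Incidence is binary per (user, item) within the window —
repeats never count twice. Items are reaction-target accounts (replies,
retweets and quotes all count as "referring"), registrable URL domains
(full-path identity behind a flag), or headline tokens (whitespace +
lowercase tokenizer by default; any `str -> list[str]` callable, e.g. a
Japanese morphological analyzer restricted to nouns, can be plugged in).

Each item's 2×2 table (cohort referring / not × reference referring / not)
gets a Pearson chi-squared test of independence, 1 df, no continuity
correction by default (counts in the emulated regime are large; a Yates
flag exists). Tests are per-item at α = 0.05 with no multiplicity
correction, mirroring the original design; Benjamini–Hochberg is available
behind a flag but off, to stay faithful while flagging the limitation.
Survivors are ranked by distinct cohort users (ties lexicographic), top 30.
Candidate items are the union of both groups' items so that swapping group
and reference selects identical item sets. `alpha >= 1` disables the filter
entirely, including items whose table has a zero margin (p undefined).

## Reaction features

Per period, spreaders are the top-K users by outgoing reaction count and
senders the top-K by incoming count (ties by ascending user id). The RA
tensor for (user, period) counts reactions between the user and each
indexed account over the three periods up to and including the period,
split by window slot × role (spreader/sender) × direction (user→account /
account→user) × rank: dimensionality 3·2·2·K. K defaults to 100 at desk
scale (the study used 10,000). Direction is kept explicit because the
original description is ambiguous about it; no deduplication happens at the
feature level (duplicating the stream doubles counts). The published raw
dimensionality (95,016) is not derivable from any single convention over
3 × (10K + 10K); likely overlap-dedupe between the top lists — recorded,
not resolved.

The anti threshold: argmax over (p_pro, p_neutral, p_anti), except an anti
argmax is demoted unless p_anti ≥ τ (default 0.7, which in the original
experiments traded anti recall 0.688→0.438 for precision 0.524→0.700). The
demotion target is the larger of pro/neutral (ties → pro); the original
never states the fallback, so it is isolated in one function and swappable.
Training any text encoder is out of scope; a trivial prior-frequency
classifier satisfies the classifier contract for end-to-end runs.

## The synthetic world

Defaults (one stated world, chosen once):

| parameter | default | why |
| --- | --- | --- |
| n_users | 2000 | desk scale for the ~300k active-user corpus |
| n_months / start | 5, 2021-06 | the study window |
| posting_rate | 2.0 tweets/user/period | makes the 4-month activity filter behave like the real active core |
| initial_stance_probs | (0.46, 0.46, 0.08) | pro ≈ neutral at the start, anti a small minority; 8% rather than the corpus's 0.9% so the minority community is detectable at 2000 users (a pure scale concession, see below) |
| monthly hazards | pro (0.939, 0.060, 0.001); neutral (0.150, 0.845, 0.005); anti (0.02, 0.08, 0.90) | neutral→pro 0.15/month compounds to ≈ 54% over the window; direct pro↔anti exchange negligible; anti sticky so the anti community persists as in the polarization figures |
| homophily | diag 1.0; pro–neutral 0.03, neutral–anti 0.006, pro–anti 0.002 | sparse pro–anti edges; neutral users' cross-edges go overwhelmingly to pro |
| label_noise | 0.05 | small classifier error, uniform over the other classes |
| reaction_prob / types | 0.8; retweet 0.70, quote 0.15, reply 0.15 | retweet-dominant reaction mix |
| popularity_exponent | 2.5 | Zipf weights (ranked within each initial stance group) emulate hub-dominated retweet graphs; without hubs, resolution-2 Louvain shreds the stance groups |
| stance_activity | (1, 1, 2.5) | the anti minority is vocal: consistently present in the retweet graph |
| share_prob | 0.15 | one shared link per ~7 tweets |
| site preferences | pro/neutral: mass media + web news heavy; anti: video hosting + BBS/blog heavy | the documented contrast in information sources |

Latent stances live on months: month 0 is drawn from the initial simplex,
then one hazard step per month boundary (4 steps over 5 months — the
closed-form oracles in the tests use matrix powers with this convention).
Tweet timestamps are uniform within periods (only period membership matters
downstream). One event carries at most one reaction and one shared URL.
Ground truth goes to a sidecar, never into the stream. Generation is
bit-reproducible under a fixed seed (single PCG64 generator, fixed
consumption order).

What the generator does **not** emulate: tweet text (headlines are token
templates), bursty news-driven volume, bot clients, the waning of
pro/neutral activity after September, follower structure, or a corpus-scale
0.9% anti share. A green pipeline test therefore establishes correct
mechanics on a structurally faithful stream, not corpus-level numbers.

Known measurement limitation: with label noise and few tweets per period,
majority votes with the pro-first tie-break inflate plug-in estimates of
the neutral→pro hazard (≈ +0.036 at noise 0.05, ~2 tweets/period). The
parameter-recovery tests run at label_noise = 0 to isolate the Markov
dynamics; estimating hazards from noisy labels would need a
misclassification-aware estimator, which is out of scope.
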