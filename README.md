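# stanceform

Stance-formation analysis for vaccine-discourse event streams.

During Japan's 2021 COVID-19 vaccination campaign, most initially neutral
social-media users who later committed to a stance became pro-vaccine, almost
none anti-vaccine — and the two committed camps barely talked to each other.
`stanceform` reimplements that analysis pipeline as a tested library: from a
labeled tweet/reaction stream to per-period user stances, polarization
trajectories, stance-transition cohorts, and enrichment analysis of what the
stance-changers were reading and sharing. Because the original corpus is
proprietary, a synthetic-stream generator with the same statistical structure
(neutral→pro drift, homophilous hub-dominated reactions, a small vocal anti
minority, per-stance site preferences) stands in for it, so every stage runs
and is testable offline.

## The model in brief

- **Periods.** Each month is cut into three periods (days 1–10, 11–20,
  21–end): 15 periods over the five-month window.
- **Timelines.** A user's per-period stance ∈ {pro, neutral, anti} is the
  majority vote over their labeled tweets in that period (ties:
  pro > neutral > anti); empty periods carry the last observed stance
  forward, or backfill from the first observation. Users posting in < 4 of
  the 5 months are dropped.
- **Polarization.** Per period, an undirected retweet graph is partitioned
  with Louvain (resolution 2); the three largest communities are
  stance-labeled by member majority. Controversy between the pro and anti
  communities is the modified Random Walk Controversy

      RWC = P_pp · P_aa − P_pa · P_ap ∈ [−1, 1],

  where `P_xy` is the probability that a random walk started on side *x* is
  absorbed at one of the k = 10 highest-degree nodes of side *y*; the
  neutral community is traversable but never absorbing. An absorbing-chain
  linear solver gives exact values; a vectorized Monte-Carlo walker
  cross-checks them.
- **Cohorts.** From the filled timelines: users neutral at period 0 who
  changed stance exactly once and kept it (neutral-to-pro / neutral-to-anti,
  with the change month), or stayed neutral throughout (remaining-neutral).
- **Enrichment.** Per change month, the accounts / URL domains / headline
  tokens referred to by a cohort inside its 4-period change window are
  compared against remaining-neutral users with per-item 2×2 chi-squared
  tests (α = 0.05, uncorrected, as in the original design), then ranked
  top-30 by distinct referring users.
- **Reaction features.** Top-K information spreaders/senders per period,
  3-period reaction-count (RA) feature tensors, and the precision-oriented
  anti-class threshold (argmax anti is kept only if p_anti ≥ 0.7).

## Worked example

```
python analysis/01_simulate.py --seed 1      # stream + ground truth -> scratch/
python analysis/02_aggregate_timelines.py    # timelines + stance counts -> results/
python analysis/03_polarization.py           # RWC per period -> results/rwc.csv
python analysis/04_formation.py              # transition matrix + cohorts
python analysis/05_sharing.py                # chi-squared enrichment tables
```

With seed 1 the drivers print (abridged):

```
2000 active users (of 2000 posters)
  period 0 : {'pro': 920, 'neutral': 893, 'anti': 187}
  period 14: {'pro': 1161, 'neutral': 713, 'anti': 126}

RWC defined in 8/15 periods ... mean RWC 0.988

          pro  neutral  anti  Total
pro       717      194     9    920
neutral   410      466    17    893
anti       34       53   100    187
Total    1161      713   126   2000

cohorts: {'neutral_to_pro': 317, 'neutral_to_anti': 11, 'remaining_neutral': 299, ...}
```

Read: the pro camp grows at the neutral camp's expense while direct
pro↔anti exchange stays negligible (9 + 34 users); the defined-period RWC
near 1 means random walks essentially never cross between the pro and anti
communities; and the neutral-to-anti cohort is tiny, mirroring the
asymmetry the analysis is about. Periods where the three largest
communities miss the small anti community report RWC as "undefined" — see
`docs/methods.md` for why that is a desk-scale effect.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch at the default scale — simulation,
serialization round trip, timelines, exact RWC series, transition matrix,
cohorts, one enrichment table — printing a summary and writing the results
JSON to `--out`.
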