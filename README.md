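# clearwater

Detection and causal-structure analysis of **clear-water phases (CWP)** in
weekly limnological monitoring series.

A clear-water phase is a spring/early-summer episode in mesotrophic and
eutrophic lakes in which water transparency rises sharply while
phytoplankton biomass collapses, usually driven by grazing of filter-feeding
zooplankton (Cladocera, notably *Daphnia*). `clearwater` is aimed at
limnologists and monitoring agencies who hold weekly multivariate reservoir
series (transparency, turbidity, nutrients, plankton counts, hydrology) and
want to (1) find CWP episodes with a reproducible rule, (2) quantify
before/after contrasts, and (3) learn which environmental factors the
optical response is most sensitive to.

## What it computes

**Event rule.** A week-to-week transition *t → t+1* qualifies iff

- secchi depth SD(t+1) > SD(t),
- chlorophyll-a Chl(t+1) < Chl(t),
- total zooplankton Z(t+1) > Z(t),

all strict. A maximal run of ≥ 2 consecutive qualifying transitions is a
candidate event, confirmed iff turbidity shows a net decrease over the run
(TUR(end) < TUR(onset)). Events are disjoint and never span missing weeks.

**Statistics.** Per-event (before, after) = (onset-week, end-week) values
feed a paired t-test, t = d̄ / (s_d / √n) with d = after − before and
n − 1 df; variable screening uses Pearson product-moment correlations with
pairwise deletion.

**Networks.** Variables are min–max normalized, cut into 3 ordered states
by exact variance-minimizing 1-D clustering, and a discrete Bayesian
network is learned by BDeu-scored hill-climbing (equivalent sample size 50,
≤ 8 parents per node, random restarts) under **temporal tiers**: an edge
u → v is legal only if tier(u) ≤ tier(v), where tiers order meteorology (1),
hydrology and dissolved nutrients (2), plankton densities (3), community
totals/relative abundances (4), bulk nutrients and chl-a (5), and the
optical responses SS/SD/TUR (6). Exact variable elimination then supports
k-fold validation, per-node **sensitivity** of a target marginal (max
|∂P(target = s)/∂θ| under proportional co-variation) and per-edge
**strength of influence** (mean Euclidean distance between the child's
conditional distributions as one parent's state varies, weighted by
co-parent frequency).

Because raw monitoring series of this kind are rarely deposited, the
package ships a seeded synthetic generator (`clearwater.synthetic`) that
emulates the study conditions — 4 sites × 104 weekly records, monsoon
rainfall with ~63% concentrated in June–August, hydraulic retention time of
order 10–20 d, spring Cladocera emergence — and plants grazing pulses with
a known answer key (`GroundTruth`), so every stage is testable end to end.

## Worked example

```python
from clearwater import (SimParams, emulate_dataset, detect_events,
                        summarize_events, extract_pairs, paired_t_test)

params = SimParams(seed=11, noise_sd=0.05)        # 4 sites x 104 weeks
weekly, daily, truth = emulate_dataset(params)

series = weekly["lake_deep"]
events = detect_events(series)
summary = summarize_events(events, series)
print(f"{series.site}: {summary.n_events} events, by duration {summary.counts_by_duration}")
print(f"mean secchi-depth increase: {summary.mean_delta['delta_secchi']:.2f} m")

pairs = extract_pairs(events, series, "secchi_depth")
c = paired_t_test(pairs, variable="secchi_depth", site=series.site)
print(f"paired t on secchi depth: t = {c.t:.3f}, df = {c.df}, p = {c.p_two_sided:.4f}")
```

prints

```
lake_deep: 6 events, by duration {2: 4, 3: 2}
mean secchi-depth increase: 2.95 m
paired t on secchi depth: t = 8.929, df = 5, p = 0.0003
```

i.e. six clear-water episodes detected at the deep lake site (four lasting
two qualifying transitions, two lasting three), a mean transparency gain of
about 3 m from onset to end, and a strongly significant onset→end increase
(positive t, since differences are after − before).

Learning the pooled tier-constrained network and ranking what transparency
is sensitive to:

```python
import pandas as pd
from clearwater import learn_structure, fit_cpts, sensitivity_analysis
from clearwater.discretize import discretize_frame
from clearwater.columns import DEFAULT_TIERS, MODELED_VARIABLES

pooled = pd.concat([s.data for s in weekly.values()], ignore_index=True)
disc, _ = discretize_frame(pooled, MODELED_VARIABLES)
net = fit_cpts(learn_structure(disc, tiers=DEFAULT_TIERS, ess=50,
                               restarts=5, seed=11), disc)
for node, score in sensitivity_analysis(net, "secchi_depth").ranking[:5]:
    print(f"  {node:<14s} sensitivity {score:.3f}")
```

```
  water_temp     sensitivity 0.563
  cladocera      sensitivity 0.184
  total_phyto    sensitivity 0.171
  green_algae    sensitivity 0.165
  rotifera       sensitivity 0.163
```

— water temperature (which drives both Cladocera emergence and
phytoplankton growth in the generator) dominates, followed by the grazer
and the phytoplankton pool, exactly the causal pathway the generator wires.

## Command line

```bash
clearwater simulate --seed 3 -o out/            # synthetic dataset + ground truth
clearwater detect out/weekly.csv -o events.csv  # CWP events
clearwater stats out/weekly.csv -o stats/       # before/after + correlations
clearwater network out/weekly.csv -o net/       # pooled tiered network
clearwater report config.yaml                   # full pipeline from a config
```

Weekly CSVs use ISO-8601 dates and the canonical column names of
`clearwater.columns`; standard abbreviations (SD, TUR, PRECI, CL-Ind, …)
are accepted as header aliases.

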