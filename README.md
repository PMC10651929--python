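# mobifood

Smartphone mobility data — streams of timestamped GPS "pings" — can reveal
which food outlets people actually visit as they move through their day,
rather than only what sits near their home. `mobifood` implements, end to
end, an analysis pipeline that turns raw geolocation pings into
neighborhood-level fast-food (FF) exposure measures and links them, as
contextual variables, to individual health-survey respondents to model
self-reported FF intake and diet-related disease (obesity, diabetes).

It is written for quantitative epidemiologists and computational social
scientists who want a tested, reusable implementation of the full chain:

1. **Stay detection** — greedy sequential clustering of each user's pings
   into dwell events ("stays"): a ping joins the current cluster iff the
   maximum haversine distance from any member to the coordinate-wise-median
   centroid stays below a roaming distance *d*<sup>roam</sup> = 50 m; a stay
   needs ≥ 2 pings and ≥ 5 min.
2. **POI attribution** — each stay is linked to the nearest point of
   interest within *d*<sup>max</sup> = 200 m; food outlets come from a
   category set, FF outlets from a validated chain-brand list (McDonald's,
   Taco Bell, Pizza Hut, …) matched on normalized names.
3. **User metrics** — *FF visits/time* (% of observed daily periods —
   before 11:00, 11:00–16:00, after 16:00 — containing an FF visit),
   *FF visits/food* (% of food-outlet visits that were FF), *trips/day*,
   and a home neighborhood inferred from 22:00–06:00 activity.
4. **Aggregation & linkage** — user metrics averaged within neighborhoods,
   rescaled to 0–10 (one unit = 10 percentage points), and attached to
   survey respondents by residential neighborhood.
5. **Models** — multinomial logistic regression of four-level FF intake
   (reference "never") and binary logistic regressions of obesity/diabetes
   on the scaled exposures, adjusted for age group, gender, race/ethnicity,
   education and income; non-nested models compared by Akaike weights
   w<sub>i</sub> = exp(−Δ<sub>i</sub>/2) / Σ<sub>k</sub> exp(−Δ<sub>k</sub>/2)
   with Δ<sub>i</sub> = AIC<sub>i</sub> − min AIC.
6. **Sensitivity** — census-tract demographic change between two years,
   outlier tracts by Tukey fences and the 2-SD rule, model refits without
   respondents in outlier tracts (|OR change| > 10% flagged), and a
   trips/day confounder check.

Because the real mobility and survey feeds of such studies are
access-restricted, the package ships a first-class **synthetic world
generator** with planted parameters — per-neighborhood FF visit
propensities, multinomial/logistic outcome coefficients (defaults OR 1.35
for frequent intake and 1.16 for obesity per scaled unit), outlier tracts —
so every stage is validated by parameter recovery. See `docs/methods.md`
for the generative model and its limitations.

## Worked example

```python
import warnings
from mobifood.pipeline import PipelineConfig, run_all, validate_recovery
from mobifood.synthetic_world import WorldConfig

cfg = PipelineConfig(
    world=WorldConfig(n_neighborhoods=6, n_users=90, days=5, n_respondents=2000, seed=3),
    seed=3,
)
art = run_all(cfg, "artifacts")
print(art["neighborhood_metrics"][
    ["neighborhood_id", "n_users", "mean_ff_time_pct", "mean_ff_food_pct", "scaled_ff_food"]
].round(2).to_string(index=False))
```

prints the recovered neighborhood exposure table (planted propensities rise
from 0.05 in N00 to 0.35 in N05; the measured FF share of food visits
tracks them):

```
neighborhood_id  n_users  mean_ff_time_pct  mean_ff_food_pct  scaled_ff_food
            N00       15              2.48              5.78            0.58
            N01       15              3.11              9.78            0.98
            N02       15              5.08             12.35            1.23
            N03       15              9.77             22.83            2.28
            N04       15             13.49             26.62            2.66
            N05       15             13.26             28.26            2.83
```

The fitted unadjusted multinomial model (`art["table2"]`) gives, for this
run, an odds ratio of 1.55 (95% CI 1.33–1.81) of frequent-vs-never FF
intake per scaled unit of FF visits/food, and the recovery report confirms
the chain:

```python
report = validate_recovery(art, art["world"].truth)
print(report.rank_correlation, report.passed)   # 1.0 True
```

The same run is available from the shell:

```sh
mobifood all --out artifacts --seed 3
mobifood simulate --out sim --seed 1      # synthetic inputs only
mobifood stays --pings sim/pings.csv --out stays.csv --d-roam 50
```

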