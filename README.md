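# bacterivory

Quantitative analysis of bacterial-prey-amendment experiments with natural
heterotrophic nanoflagellate (HNF) communities: who eats the bacteria in
freshwater plankton, how fast the grazers grow on different prey, and how
badly amplicon read counts misrepresent the cell counts of the grazers.

The package is aimed at aquatic microbial ecologists working with
microcosm grazing experiments: epifluorescence counts of bacteria and HNFs
over time, fluorescently-labelled-bacteria (FLB) uptake assays,
food-vacuole contents, 18S amplicon read tables and CARD-FISH counts.

## What it computes

**Biovolume calculus** — cells as prolate spheroids, V = (π/6)·L·W²;
community biovolume; biovolume-equalised prey additions (equal added
biovolume across strains of very different cell size).

**Growth kinetics** — from HNF time courses: maximum growth rate µ (h⁻¹) by
log-linear fitting (classical steepest-window rule, or a pooled
lag/exponential/plateau fit across replicates), doubling time DT = ln 2/µ,
lag phase (intercept of the growth line with the zero-time abundance),
volumetric gross growth efficiency GGE = ΔBV_HNF/(−ΔBV_bacteria), and
relative growth rates anchored to the fastest treatment (= 100 %).

**Bacterivory budgets** — community cell-specific uptake from FLB assays,
U = (tracer cell⁻¹ / t) · (total prey / tracer prey); group-specific rates
scaled by food-vacuole content; total grazing rates (TGR = IGR × abundance
× 24) and percent of the bacterial standing stock removed per day.

**Composition comparison** — read fractions vs CARD-FISH cell fractions per
group, log2 read/cell bias, and relative rRNA copy-number factors
(geometric mean 1) explaining the bias.

**Synthetic microcosms** — a generator with known ground truth (lagged
exponential growth on a depletable prey pool, Holling type II ingestion
with satiation, lognormal counting noise, copy-number-distorted multinomial
reads, binomial FISH detection) used to validate every estimator.

## Worked example

Build the time-zero bacterivory budget of a reservoir HNF community from
its group counts, food-vacuole contents and a community FLB uptake rate of
13.7 bacteria HNF⁻¹ h⁻¹:

```python
from bacterivory.grazing import (T0_STANDING_STOCK, build_grazing_budget,
                                 format_budget, load_grazing_fixture)

budget = build_grazing_budget(load_grazing_fixture(),
                              community_flb_rate=13.7,
                              bact_conc=T0_STANDING_STOCK)
print(format_budget(budget).to_string(index=False))
```

```
       group  abundance_1e3_per_ml  pct_of_hnf  vacuole_content  igr  tgr_1e6_per_ml_per_day  standing_stock_pct  pct_of_total_tgr
     All HNF                  5.40       100.0              2.9 13.7                    1.78                54.2             100.0
  All Crypto                  3.38        62.6              3.1 14.6                    1.19                36.3              66.9
CRY1 lineage                  0.10         1.9              1.8  8.5                    0.02                 0.6               1.1
```

Reading the table: flagellates ingest 13.7 bacteria per cell per hour on
average, removing 54 % of the bacterial standing stock per day;
Cryptophyta — usually assumed autotrophic — are 63 % of the HNF community,
graze slightly faster than the average cell (14.6 h⁻¹), and account for
two-thirds of total bacterivory, while the small CRY1 lineage contributes
~1 %.

The same workflow is scriptable: `bacterivory simulate | growth | grazing |
compare` are thin CLI wrappers, and `analysis/01...04` are narrative
drivers that simulate a five-treatment experiment, estimate growth
parameters (doubling times 8.5–12.6 h, lags 0.6–3.7 h, GGE 0.31–0.37 on
the default seed), rebuild the budget above, and quantify the
amplicon-vs-FISH mismatch (Katablepharidophyta 2^4.9 ≈ 29× overrepresented
in reads).

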