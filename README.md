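# nutlim

Meta-analysis toolkit for ocean nutrient-addition bioassay experiments:
which nutrient limits phytoplankton growth where, how strongly growth
responds when one, two or three nutrients are supplied together, and how
well simple seawater-chemistry rules predict the experimental outcome.

It is written for marine microbial ecologists and biogeochemists who work
with factorial enrichment experiments (natural seawater amended with
combinations of N, P, Fe, Mn, Co, Zn, Si or vitamin B12, incubated against
an unamended control) and want a tested, reproducible pipeline instead of
per-study spreadsheets.

## What it computes

**Growth metrics.** The response metric is the chlorophyll-a based net
growth rate

    μ_net = ln(Chl_T / Chl_I) / t      [d⁻¹]

with `Chl_I` the initial and `Chl_T` the final (replicate-mean)
chlorophyll-a over an incubation of `t` days. The empirical temperature
envelope

    μ_max(T) = 0.59 · e^(0.0633·T)     [d⁻¹, T in °C]

gives a temperature-normalized relative rate μ_net/μ_max.

**Limitation classification.** A factorial experiment is traversed as an
addition lattice: significant chlorophyll enhancement of a single addition
over the control identifies the primary limiting nutrient; a pair that
responds when neither member does alone is independent co-limitation; and
additions on top of the primary set that stimulate further growth identify
serial (secondary, tertiary) limitation. Tests are one-sided Welch t or
Tukey HSD over all treatments, on raw or log chlorophyll, with an optional
Holm family adjustment. Only positive responses count; declines are never
"limitation".

**Stoichiometric deficiency.** Dissolved concentrations are divided by the
assumed-average phytoplankton requirement
16 N : 1 P : 7.5×10⁻³ Fe : 2.8×10⁻³ Mn : 8×10⁻⁴ Zn : 1.9×10⁻⁴ Co
(quotient q_i = C_i/R_i); the smallest quotient flags the most-deficient
nutrient. Agreement with the experimental outcome is scored into five
exclusive categories (correct / incorrect / limiter-not-measured / replete
/ co-limited-including-predicted). The requirement ratios N:Fe = 2.13
mol:mmol and N:P = 16 mol:mol are the critical reference lines for
response-vs-ratio regressions.

**Dataset trends.** Group means/SDs of μ_net by number of nutrients added
with one-way ANOVA + Tukey compact letters, simple regressions (R², F-test
p), response-vs-log10(N:Fe) and log10(N:P) analyses, and R-style (nrd0
bandwidth) Gaussian kernel densities.

**Upwelled nitrate.** Ekman vertical velocity from wind-stress curl,
w_E = (1/ρ₀)·curl(τ/f) with full spherical metric terms and an equatorial
mask, multiplied by sub-mixed-layer nitrate.

**Synthetic data.** A Liebig-minimum/Monod growth simulator with
stoichiometric drawdown and lognormal replicate noise generates factorial
experiments and station tables with known ground truth, so every pipeline
stage is testable end to end without downloads.

## Worked example

```python
from nutlim import SyntheticConfig, simulate_survey, classify, compute_responses
from nutlim.limitation import summarize_dataset
from nutlim.meta_trends import group_stats

survey = simulate_survey(SyntheticConfig(seed=7, n_experiments=40))
results = [classify(e, method="anova_tukey", scale="log")
           for e in survey.experiments]
hits = sum(r.signature() == survey.truths[e.id].signature()
           for r, e in zip(results, survey.experiments))
print(f"recovered {hits}/{len(results)} planted regimes")

groups, F, p = group_stats(compute_responses(survey.experiments))
for g in groups:
    print(f"n_added={g.key}: n={g.n:3d} mean={g.mean:+.2f} d^-1 "
          f"sd={g.sd:.2f} letter={g.letter}")
```

Output:

```
recovered 40/40 planted regimes
n_added=0: n= 40 mean=+0.14 d^-1 sd=0.22 letter=a
n_added=1: n= 84 mean=+0.57 d^-1 sd=0.61 letter=b
n_added=2: n= 48 mean=+1.15 d^-1 sd=0.58 letter=c
n_added=3: n=  4 mean=+1.89 d^-1 sd=0.14 letter=d
```

Reading it: every planted limitation regime (primary N or Fe, N–Fe
co-limitation, serial chains, replete) was recovered from the noisy
replicates, and mean net chlorophyll growth rises stepwise with the number
of nutrients supplied — each group carries a distinct Tukey letter, i.e.
all group means differ significantly at α = 0.05.

The same pipeline is available from the shell:

```sh
nutlim simulate --seed 7 --n 40 --out sim/
nutlim pipeline --experiments sim/experiments.csv --out run/
```

which persists responses, classifications, regime proportions, deficiency
agreement and trend statistics as CSVs plus a run manifest.

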