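# hetfit

Heterozygosity–fitness correlations (HFC), identity disequilibrium, and
selection on heterozygosity for multi-year mark–recapture studies of wild
populations genotyped at microsatellite panels.

## The scientific problem

In many wild populations, individuals with lower marker heterozygosity have
lower fitness. Such heterozygosity–fitness correlations arise when variance in
inbreeding among individuals creates *identity disequilibrium* (ID) —
correlated heterozygosity across loci — so that a modest marker panel reflects
genomewide inbreeding ("general effect"). The strength of HFC is expected to
be context dependent: selection against homozygous individuals should be
stronger in environmentally harsh years.

`hetfit` implements the full analysis chain for a study design in which a
breeding population is monitored over consecutive years, every adult is
genotyped at a marker panel classified into neutral and putatively functional
loci, and the fitness component is *interannual local recruitment*: an adult
breeding in year *t* is scored 1 if it is recaptured breeding anywhere in the
study area in year *t* + 1, else 0.

## Core statistics

**Homozygosity by locus (HL).** For individual *i*, with per-locus expected
heterozygosity weights E<sub>l</sub> = 1 − Σ p̂² and sums over the loci
actually typed,

    HL_i = Σ_{l homozygous} E_l / ( Σ_{l homozygous} E_l + Σ_{l heterozygous} E_l )

1 − HL is the heterozygosity measure entering all fitness models, computed for
all loci and for the neutral and functional subsets separately.

**Identity disequilibrium, g².** With h<sub>ik</sub> the 0/1 heterozygosity
indicator of individual *i* at locus *k*,

    g2 = A/B − 1,   A = mean over i, k≠l of h_ik h_il,
                    B = mean over i≠j, k≠l of h_ik h_jl

(missing cells drop out of both numerator and denominator). Under a model
where individual inbreeding *f* varies, E[g²] = Var(f)/(1 − E[f])²; g² > 0 is
the prerequisite for general-effect HFC. Significance comes from permuting
each locus column independently among individuals.

**Recruitment models.** Per year, binomial GLMMs (logit link) of recruitment
on 1 − HL plus nongenetic covariates (body condition, fledging success, age)
and fixed factors (plot, sex, local/immigrant origin), with a mating-pair
random intercept fitted by adaptive Gauss–Hermite quadrature. All subsets of
the candidate covariates are ranked by AICc; equivalent models (ΔAICc ≤ 2)
are averaged with Akaike weights, reporting unconditional standard errors and
term importance Σωᵢ. Single-locus scans fit one model per locus with Holm
(sequential Bonferroni) correction, and an F-ratio test asks whether
single-locus heterozygosities explain more than the multilocus summary.

**Selection and environment.** The yearly selection differential is
S = cov(ω, het) with ω = w/w̄ relative fitness, which equals the recruits'
mean heterozygosity minus the population mean. Environmental harshness over
each nonbreeding window (July 1 – March 31) is summarized by days outside the
thermal neutral zone (daily max ≥ 35 °C or daily min ≤ 15 °C),
freezing-degree days (daily min < 0 °C), and accumulated precipitation;
simple linear regressions relate S to each cue and track the temporal trend
of annual mean heterozygosity.

A synthetic-data generator (`hetfit.synthetic_data`) produces genotypes under
a two-point inbreeding mixture with closed-form g², recruitment with a
precipitation-modulated heterozygosity slope, recruit carry-over between
years, and daily Mediterranean weather — so every stage of the pipeline can be
tested against known truth.

## Worked example

```python
import numpy as np
from hetfit import synthetic_data as sd
from hetfit.marker_stats import marker_summary, expected_het_weights
from hetfit.heterozygosity import het_estimates
from hetfit.identity_diseq import g2_test
from hetfit.hfc_pipeline import build_year_datasets, run_multilocus_hfc
from hetfit.selection_env import (selection_series, harshness_table,
                                  selection_vs_harshness)

study = sd.simulate_dataset(sd.SimConfig(seed=1))          # 7-year study
weights = expected_het_weights(marker_summary(study.genotypes))
het = het_estimates(study.genotypes, weights,
                    {n: study.panel.subset(n)
                     for n in ("total", "neutral", "functional")})

res = g2_test(study.genotypes.het_indicator(), B=1000, seed=1)
print(f"g2 = {res.g2_hat:.4f} (p = {res.p_value:.4f}, n = {res.n}, L = {res.L})")

datasets = build_year_datasets(study.individuals, het)
table = run_multilocus_hfc(datasets[2], family="total")    # 2010 -> 2011
print(table.round(3).to_string(index=False))

sel = selection_series(datasets)
harsh = harshness_table(study.weather, sel["year"].tolist())
reg = selection_vs_harshness(sel, harsh)
print(reg[reg.subset == "total"].round(4).to_string(index=False))
```

prints

```
g2 = 0.0096 (p = 0.0010, n = 705, L = 26)
 year             term  estimate   use  sum_weights  ci_low  ci_high  significant
 2010           plot_B    -0.333 0.433        1.000  -1.181    0.515        False
 2010            sex_M     0.127 0.418        1.000  -0.691    0.946        False
 2010     origin_local    -0.534 0.474        1.000  -1.462    0.394        False
 2010        het_total    18.117 3.436        1.000  11.381   24.852         True
 2010   body_condition    -0.861 0.595        0.509  -2.026    0.305        False
 2010 fledging_success     0.049 0.093        0.276  -0.132    0.231        False
subset             metric       r   slope      p
 total           tnz_days  0.8485  0.0054 0.0327
 total                fdd -0.2904 -0.0030 0.5766
 total accumulated_precip  0.9492  0.0001 0.0038
```

The g² estimate is positive and significant (the generator's inbreeding
mixture implies E[g²] ≈ 0.0111), 2010 was the simulation's wettest
(harshest) winter and shows a strong positive heterozygosity effect on
recruitment with the 95% CI excluding zero, and across the six yearly
selection differentials only accumulated precipitation is a strong positive
predictor of S — the generative coupling the analysis is designed to detect.

## Command line

Each subcommand takes a YAML config naming the input CSVs (genotypes, marker
panel, individuals, weather), output directory, seeds and permutation counts:

```bash
hetfit simulate cfg.yaml    # write a synthetic study (plus truth files)
hetfit validate cfg.yaml    # check all inputs
hetfit summarize cfg.yaml   # per-locus A_R, H_O, E_l, HWE screening, ANOVA
hetfit het cfg.yaml         # per-individual HL / 1-HL per marker subset
hetfit g2 cfg.yaml          # per-year, per-subset g2 with permutation p
hetfit hfc cfg.yaml         # per-year + pooled model-averaged HFC tables
hetfit scan cfg.yaml        # single-locus scans with Holm correction
hetfit selection cfg.yaml   # S, harshness metrics, and their regressions
```

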