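# scanstab

Reliability and power analysis for longitudinal, multi-site structural MRI
measures.

Multi-site observational studies and clinical trials increasingly use
scalar measures derived from structural MRI — white-matter diffusivities
(FA/MD/AD/RD), cortical thickness (mm), cortical volume (mm³) — as
endpoints, collected annually on the same people at sites that run
different scanner hardware. Before such a measure can be trusted as an
endpoint, three questions need quantitative answers:

1. **Is the measure stable over time within a person?** (test–retest
   reliability)
2. **How much do scanner type and site shift it?** (systematic hardware
   effects)
3. **What does its reliability cost in statistical power?** (sample-size
   planning)

`scanstab` answers all three for long-format tables of per-subject scalar
measures, and ships a synthetic multi-site cohort generator with *known*
variance components so every stage can be validated end to end. It is a
library first (see `examples/`), with a thin `scanstab` CLI over the same
functions.

## The statistics

**Reliability.** For each measure, subjects missing any visit are listwise
deleted and the n×k matrix (subjects × visits) is decomposed by a two-way
ANOVA into mean squares MSR (rows/subjects), MSC (columns/visits) and MSE
(residual). Treating both subjects and visits as random samples, the
absolute-agreement intraclass correlations are

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))
    ICC(2,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)

ICC(2,k) — the reliability of the k-visit average — equals the
Spearman–Brown step-up `k·r/(1+(k−1)r)` of ICC(2,1), and a measure is
flagged stable when ICC(2,k) ≥ 0.80.

**Scanner and time effects.** A mixed-factorial ANOVA with a
within-subject factor of time (k visits) and a between-subject factor of
scanner type tests systematic variation, with Mauchly's test for
sphericity, Greenhouse–Geisser df correction when sphericity is rejected,
per-effect Bonferroni families across measures, and Fisher's-LSD pairwise
comparisons of the two sites sharing each scanner. The unbalanced-design
behaviour follows the repeated-measures GLM (Type-III) convention and is
validated against R's `car::Anova`.

**Power.** A planned effect size δ assumes error-free measurement; with
single-occasion reliability r (≈ ICC(2,1)) the observable effect shrinks
to `d = δ·√r`. Power for the two-sided two-sample t-test is computed
exactly from the noncentral t distribution (df = 2n−2, ncp = d·√(n/2)),
and the required n/group is the smallest integer meeting the target.

## Worked example

```python
from scanstab import attenuate_effect, required_n, power_two_sample_t

for r in (1.0, 0.92, 0.8, 0.68):
    d = attenuate_effect(0.75, r)
    n = required_n(d, alpha=0.05, target_power=0.80)
    print(f"reliability {r:.2f}: observable d = {d:.2f}, n/group = {n}")
```

prints

```
reliability 1.00: observable d = 0.75, n/group = 29
reliability 0.92: observable d = 0.72, n/group = 32
reliability 0.80: observable d = 0.67, n/group = 36
reliability 0.68: observable d = 0.62, n/group = 43
```

— i.e. a drop in single-occasion reliability from perfect to 0.68 raises
the sample needed to detect a δ = 0.75 group difference at 80% power from
29 to 43 per group. Measurement error is a direct tax on power.

Running the full simulated pipeline (`python examples/reliability_report.py`,
seed 7):

```
CST_AD             n=85  missing=27  ICC(2,k)=0.95 ICC(2,1)=0.87 reliable=True  time F(1.83,152.08)=10.74 p <0.001 GG=True
lh_BA1_thickness   n=85  missing=27  ICC(2,k)=0.96 ICC(2,1)=0.89 reliable=True  time F(2.00,166.00)=20.75 p <0.001 GG=False
lh_BA1_volume      n=85  missing=27  ICC(2,k)=0.97 ICC(2,1)=0.92 reliable=True  time F(2.00,166.00)=29.37 p <0.001 GG=False
```

Each row is one measure: complete cases after listwise deletion, missing
cases against the 112-subject roster, both ICCs (matching the generator's
population values of 0.87/0.86/0.92 to sampling error), and the time main
effect with Greenhouse–Geisser-adjusted dfs where Mauchly's test rejected
sphericity. See `examples/` for cohort simulation, scanner/site effects
and the power-curve grid, and `docs/methods.md` for the model details.

## Command line

```sh
scanstab simulate --seed 7 --out cohort.csv
scanstab icc --input cohort.csv --out reliability.csv
scanstab anova --input cohort.csv --out scanner.csv
scanstab power --delta 0.75 -r 0.68
scanstab power-curve --out curve.csv
scanstab report --seed 7 --out-dir reports/
```

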