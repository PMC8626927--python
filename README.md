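# aipower

Power and type I error calculator for allelic-imbalance (AI) detection in
allele-specific RNA-seq experiments.

## The problem

In a diploid, the two alleles of a gene can be expressed unequally (allelic
imbalance). Given RNA-seq reads assigned to alleles *g1* and *g2*, AI in
condition *i* is measured by θᵢ, the proportion of reads originating from
*g1* (θ = 0.5 is balance). Three null hypotheses are of interest:

* **H1**: θ₁ = 0.5 (balance in condition 1),
* **H2**: θ₂ = 0.5 (balance in condition 2),
* **H3**: θ₁ = θ₂ (equal AI across conditions).

Designing such an experiment raises a budget question: with sequencing ever
cheaper, should you buy **reads or biological replicates**? `aipower`
answers it by Monte-Carlo simulation: it generates allele-specific read
counts for user-defined scenarios (reads × replicates × effect size), tests
each simulated dataset with a hierarchical Bayesian model, and reports
rejection proportions as power or type I error.

## Model

A read drawn in condition *i* comes from *g1* with probability θᵢ and maps
unambiguously to its allele of origin with probability r₉₁ (r₉₂ for *g2*);
otherwise it is ambiguous. Each replicate is a trinomial draw over
(x, y, z) = (unambiguous *g1*, unambiguous *g2*, ambiguous); x + y are the
allele-specific (informative) reads. Effect sizes are relative deviations
ΔAI = |θ − 0.5| / 0.5 within a condition, |θ₂ − θ₁| / θ₁ between conditions.

The test is a hierarchical beta-binomial model: per replicate,
x ~ BetaBinomial(x + y, qᵢν, (1 − qᵢ)ν) with
qᵢ = θᵢr₉₁ / (θᵢr₉₁ + (1 − θᵢ)r₉₂), condition-level θᵢ ~ Uniform(0, 1), and
a replicate-precision parameter ν shared across conditions with a
log-normal prior. Evidence against a null is the two-sided posterior tail
probability (e.g. 2·min{Pr(θᵢ < 0.5), Pr(θᵢ > 0.5)}); the null is rejected
when evidence < 0.05. The posterior is computed by deterministic adaptive
quadrature, so a fit takes milliseconds and results are exactly
reproducible. See `docs/methods.md` for details and design rationale.

## Worked example

Will 960 informative reads per condition, split over 8 replicates, detect a
20% between-condition difference in AI (θ₁ = 0.5 vs θ₂ = 0.6)?

```python
from aipower import Scenario, estimate_scenario, results_frame

s = Scenario(n_sim=200, n_bioreps=8, theta1=0.5, theta2=0.6,
             n_reads_total=960, case="b", seed=42, scenario_id="demo")
df = results_frame(estimate_scenario(s))
print(df[["hypothesis", "interpretation", "rejection_proportion", "mc_se"]]
      .to_string(index=False))
```

```
hypothesis interpretation  rejection_proportion    mc_se
        H1   type_I_error                  0.00 0.000000
        H2          power                  1.00 0.000000
        H3          power                  0.89 0.022125
```

Condition 1 is simulated balanced, so its rejection rate estimates the type
I error of H1 (here 0, comfortably below the 5% level). Condition 2 is
imbalanced: the within-condition test H2 detects it essentially always, and
the harder between-condition test H3 reaches 89% power — this design is
adequate for a 20% AI difference. The `mc_se` column is the Monte-Carlo
standard error of each proportion over the 200 simulated datasets.

The same pipeline is available from the shell:

```bash
aipower grid --out scenarios.tsv            # default reads x reps x effect grid
aipower power --scenarios scenarios.tsv --out results.tsv --seed 42
aipower simulate --scenarios scenarios.tsv --out counts.tsv   # raw count tables
aipower fit --counts counts.tsv --out evidence.tsv --r-g1 0.8 --r-g2 0.8
```

All randomness flows from per-scenario seeds; rerunning any command with
the same inputs reproduces its output byte for byte.

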