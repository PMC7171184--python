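# steppekit

Tools for quantifying the arrival and decline of steppe-related ancestry in
Late Neolithic Central Europe from low-coverage ancient genomes, together
with the companion analyses such a study needs: pairwise-mismatch genetic
diversity, READ-style kinship classification cross-checked against
uniparental markers, and outgroup-f3 / D-statistics with block-jackknife
errors. Everything runs on pseudo-haploid genotype matrices (EIGENSTRAT
format) plus per-individual metadata, and a synthetic-data module generates
cohorts with the same statistical structure so the full pipeline is testable
without any external data.

Intended users are population geneticists and archaeogeneticists working
with radiocarbon-dated ancient-DNA cohorts who want the bespoke pieces of
such an analysis — in particular the admixture-arrival timing model — as
tested, reusable library code.

## The arrival model

Per-individual steppe-ancestry proportions (qpAdm-style estimates) are
modelled as a jump followed by exponential decline. With time *t* in
calibrated years BCE (increasing into the past),

```
f(t) = 0                                   for t > t_e
f(t) = p_e · exp(−λ (t_e − t)),  λ = ln(p_e / p_0) / t_e,   for t ≤ t_e
```

the unique exponential through the pinned points (t_e, p_e) and (0, p_0):
ancestry is absent before the arrival time t_e, jumps to p_e, and decays so
that it would reach p_0 at 0 BCE/CE. Parameters are fitted by bounded least
squares with one asymmetry taken from archaeological reality: individuals
with *zero* steppe ancestry dated *after* the arrival (they demonstrably
existed for centuries) contribute no residual, so they cannot drag the
fitted jump height down.

Radiocarbon uncertainty is propagated by Monte Carlo: each repetition
redraws every individual's date from a truncated normal whose 95% interval
equals the reported date range, refits, discards unstable solutions (no
positive-definite Hessian at data scale), and weights the retained arrival
times by `exp(rss_min − rss_i)` — their Gaussian-likelihood ratio against
the best solution — in a kernel density estimate whose mode is the reported
arrival time.

The other statistics follow field conventions: pairwise mismatch is the
fraction of jointly covered SNPs where two pseudo-haploid individuals
differ (pairs with ≤ 10,000 shared sites are dropped); kinship degrees come
from mismatch rates normalised by the within-group median (≈ 0.5 identical,
0.75 first degree, 1.0 unrelated); f3/D use haploid allele frequencies with
a weighted delete-one block jackknife over contiguous SNP blocks.

## Worked example

```python
from steppekit.cli import run_demo
report = run_demo(seed=0, n_reps=500)
```

simulates a 100-individual cohort (true arrival 2750 calBCE, jump to 60%
steppe ancestry, decline towards 10% projected at time zero, male-biased
admixture 0.3) and runs every stage. With seed 0 it prints:

```json
"arrival":   {"te_mode_calbce": 2725.6, "te_interval_95": [2684.2, 2779.4],
              "te_error_years": 24.4, "retention_fraction": 0.996}
"diversity": {"effect_after_minus_before": 0.01057, "p_value": 0.001}
"kinship":   {"first_vs_unrelated_accuracy": 1.0, "n_pairs_scored": 72}
"sex_bias":  {"f3_autosomes": 0.07347, "f3_x": 0.07146,
              "delta": 0.00201, "delta_z": 1.69}
```

Reading: the weighted-KDE mode places the arrival at 2725.6 calBCE, 24 years
from the generating truth, with a 95% interval of roughly ±50 years; mean
pairwise mismatch rises by ~0.011 after 2700 calBCE (permutation p = 0.001),
the diversity increase expected when a new ancestry source enters a region;
all first-degree and unrelated pedigree pairs are classified correctly; and
the autosomes are more steppe-affine than the X (delta > 0), the signature
of admixture transmitted predominantly through males.

The same stages are available as shell commands
(`steppekit simulate|arrival|mismatch|kinship|fstats|freq|demo`), each
writing TSV/JSON with the configuration echoed in the output.

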