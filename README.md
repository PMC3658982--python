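# tnbcomics

Multi-omic driver-gene analysis for breast-cancer subgroups: copy-number
segmentation and gain/loss calling against a healthy tissue reference,
expression preprocessing (replicate averaging, batch adjustment, noise-floor
filtering), reverse-phase protein array (RPPA) normalisation with
sample-loading correction, cross-layer rank-correlation statistics, and
survival analysis (Cox proportional hazards, Kaplan-Meier, logrank) — plus a
synthetic cohort generator with recorded ground truth so the whole pipeline
is testable without clinical data.

The package is written for computational biologists who need the complete
chain of evidence behind a "gene X is over-expressed in subgroup Y and
matters for outcome" claim as reusable, tested code. The motivating use case
is the profile of the spindle-assembly-checkpoint kinase TTK/hMPS1 across
triple-negative (TNBC), Her2, luminal A and luminal B breast tumors.

## Methods at a glance

- **Segmentation.** Exact minimisation of `RSS + beta * #breakpoints` by
  dynamic programming over least-squares costs (default
  `beta = 2 sigma^2 log n`, robust sigma from first differences), in a
  two-round protocol: discard probes forming singleton segments, re-segment,
  then merge segments under 5 probes into the nearest-mean adjacent
  neighbour. Gain/loss thresholds are the 0.999/0.001 quantiles of pooled
  smoothed healthy signal; calls are strict comparisons of the smoothed
  values.
- **Expression.** Per-feature additive model `value ~ batch + subgroup`
  (least squares) with the batch component removed; features with log2 < 4
  in >= 95% of samples discarded; Welch t tests between subgroups.
- **RPPA.** Dilution series collapsed by `median(log2 intensity + step)`;
  per-array median centring and unscaled-MAD scaling; per-array OLS on the
  per-sample median across arrays (the loading proxy) with the
  proxy-dependent component removed; tumors and cell lines processed
  separately.
- **Integration.** Spearman rho on mid-ranks, exact permutation p for
  n <= 8; Mann-Whitney U with exact enumeration for pooled n <= 20.
- **Survival.** Single-covariate Cox partial likelihood (Breslow ties,
  Newton-Raphson, Wald test), Kaplan-Meier with Greenwood variance, logrank
  test, and median dichotomisation (low group: values <= median). The
  logrank statistic equals the Cox score test at beta = 0 for a binary
  covariate on untied data — used as an internal cross-check.

See `docs/methods.md` for the full model account, parameter defaults and
limitations.

## Worked example

```python
from tnbcomics import CohortDesign, PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1, write_outputs=False))
print(result.summary())
```

prints (abridged):

```
## Driver mRNA mean log2 by subgroup
  TNBC: 9.119
  Her2: 7.579
  LB: 5.986
  LA: 3.452
  healthy: 2.962

## Locus gain frequency by subgroup
  TNBC: 0.8913
  Her2: 0.5455
  LB: 0.25
  LA: 0.08571
  Fisher LA vs TNBC: p = 6.419e-14
  ...

## Cross-layer Spearman concordance
  mRNA~protein [all] n=154: rho = 0.539, p = 5.512e-13
  ...

## Survival (continuous Cox + median-split logrank)
  OS: HR = 0.2063 [0.0987, 0.4311], Wald p = 2.696e-05, logrank p = 0.002011
  ...
```

Reading the output: the synthetic driver gene reproduces the expected
subgroup gradient — highest mRNA in the TNBC-like subgroup (mean log2 9.1 vs
2.96 in healthy tissue), the most frequent locus gain in TNBC (89% of
samples called gained vs 8.6% in luminal A; Fisher p ~ 1e-13), mRNA and
protein concordant at Spearman rho ~ 0.54 across 154 tumors — and, within
the TNBC-like subgroup, higher driver expression predicts better outcome
(hazard ratio 0.21 per log2 unit of expression, Wald p = 2.7e-5). Each
number is computed by the corresponding pipeline stage from the generated
raw tables, not read from the generator.

The same run is available from the shell:

```bash
tnbcomics run-all --out results/run1 --seed 1
```

which writes every intermediate table (probe tracks, SEG segments,
processed expression, normalised RPPA with diagnostics, concordance,
survival results), a `manifest.json` with stage parameters and input hashes,
and `report.txt`. Individual stages are exposed as subcommands
(`simulate`, `segment`, `calibrate`, `call`, `expr-preprocess`,
`rppa-normalize`, `integrate`, `survival`, `report`).

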