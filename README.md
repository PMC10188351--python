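# geroscreen

Multi-cohort expression screening for nominating **dual-purpose therapeutic
targets** — genes implicated as concurrent drivers of a disease *and* of
aging, such that modulating them could benefit both. The package implements
the full screening pipeline as a tested, reusable library with a thin CLI,
and ships a synthetic multi-cohort generator with planted ground truth so
every stage can be exercised and validated end to end.

The motivating use case is an aggressive, age-linked cancer such as
glioblastoma, screened across dozens of public expression cohorts — but the
pipeline is agnostic to disease and data source: it consumes plain
gene-by-sample matrices of normalized log2 expression plus per-sample
clinical metadata (age, case/control group, overall survival).

## What the pipeline computes

1. **Age–expression correlation screen** (`age_correlation`). Per dataset
   *d*, Spearman's rank correlation ρ<sub>g,d</sub> between each gene's
   expression and age on case samples only, with the two-sided p-value
   p<sub>g,d</sub> from the large-sample t approximation. A gene is
   *sign-consistent* when its correlation carries the same sign in at least
   `min_support` of the datasets where it is measured (default: all but
   one, e.g. 11 of 12). Per-dataset p-values are combined with the
   direction-aware Stouffer method,

   Z<sub>g</sub> = Σ<sub>d</sub> sign(ρ<sub>g,d</sub>) · Φ⁻¹(1 − p<sub>g,d</sub>/2) / √k,
   p<sub>g</sub> = 2(1 − Φ(|Z<sub>g</sub>|)),

   and a gene is significant when p<sub>g</sub> < α (default 0.05). UpSet-style
   exact intersection counts across datasets are produced as tables.
2. **Differential-expression meta-analysis** (`expression_meta`). Per
   dataset, log2 fold change = mean(case) − mean(control) with Welch's
   t-test and Benjamini–Hochberg correction; across datasets, mean combined
   LFC, a symmetric minmax-scaled LFC in [−1, 1], Stouffer-combined p (sign
   from each LFC) and BH-adjusted combined q.
3. **Survival screen** (`survival_screen`). Patients with survival data are
   split into young (< 45 y), middle-aged (45–60 y) and senior (> 60 y)
   cohorts; per gene and cohort, a median split (≥ median ⇒ "high")
   defines two arms compared by the Kaplan–Meier estimator and the
   two-group log-rank test (via `lifelines`), with a direction-of-harm call
   from the KM median survival times.
4. **Target-selection strategies** (`strategy_engine`). S1: significantly
   positively age-correlated genes whose high expression significantly
   worsens survival in ≥ 1 cohort; S2: significantly negatively correlated
   genes whose low expression worsens survival; S3: all significantly
   age-correlated genes intersected with a user-supplied aging-target list.
   A transparent, user-configurable weighted ranking orders the candidates.
5. **Orchestration** (`pipeline`, `cli`). `run_pipeline` executes every
   stage, hashes all outputs into a run manifest, and `render_report`
   reconciles a run directory against it.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/02_age_correlation_screen.py` (12 synthetic cohorts, 30
genes planted per correlation sign at |ρ| = 0.5, seed 42) prints:

```
31 genes positively sign-consistent in >= 11/12 datasets, 31 significant (combined p < 0.05)
33 negatively sign-consistent, 33 significant

top of the combined table (smaller combined_p = stronger age trend):
 gene     sign  support  n_pos  n_neg  n_datasets_measured  stouffer_z    combined_p  significant
G0023 positive       12     12      0                   12   21.302276 1.081368e-100         True
G0045 negative       12      0     12                   12  -20.833386  2.156642e-96         True
...
genes positively correlated in all 12 datasets: 30
```

i.e. the screen recovers essentially all 60 planted age-correlated genes
(support column: datasets agreeing on the sign; combined_p: Stouffer-combined
evidence) plus a small number of sign-consistent null genes, as expected at
α = 0.05. `examples/05_strategies_and_ranking.py` continues through the
survival screen to the three strategies and the ranked candidate list, and
`examples/06_full_pipeline.py` shows the same flow through `run_pipeline`.

The equivalent shell workflow:

```bash
geroscreen simulate --out data/                 # default study conditions
geroscreen run-all --config pipeline.yaml       # correlate -> de -> survival -> strategies -> rank
geroscreen report --run-dir run/
```

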