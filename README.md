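# refintervals

Reference-interval (RI) estimation for clinical-pathology panels, in the
ASVCP/CLSI style: iterative outlier screening, normality-gated method
selection by sample-size band, parametric / rank-percentile / min–max
reference limits, percentile-bootstrap confidence intervals of the limits,
and partitioned (e.g. by-sex) reporting. A synthetic-study generator —
parameterized by a packaged panel of published summary rows — makes every
stage testable end to end without raw per-animal data.

## Pipeline

For each measurand × partition (pooled "All" first, then each label):

1. **Outlier screen**, iterated until a pass flags nothing:
   - n > 30: Horn's method — Tukey fences (k = 1.5) on the Box-Cox
     transform of the sample (exponent re-fit by profile likelihood each
     pass);
   - n ≤ 30: Dixon's gap-to-range test — the extreme whose gap/range ratio
     is largest is removed when the ratio ≥ 1/3 (classical critical-value
     table available as a policy option), one value per pass.
2. **Normality** (post-screening n ≥ 40): Shapiro–Wilk, Gaussian iff
   p **strictly** > 0.2.
3. **Method routing** on post-screening n:
   - n ≥ 40 — parametric (mean ± 1.959964·SD) if Gaussian, else
     nonparametric percentile (rank p·(n+1), linear interpolation, clamped);
   - 20 ≤ n < 40 — limits are the sample min/max;
   - 10 ≤ n < 20 — descriptive values only, no RI;
   - n < 10 (or constant data) — no report.
4. **Bootstrap 90% CIs** of both limits (percentile bootstrap, B = 2000,
   parametric and percentile methods only), plus CI-width/RI-width ratios
   with an imprecision flag at ratio > 0.2.
5. **Partition comparison**: two-sided rank-sum (or Welch) test between the
   two partition labels, reported on the pooled row.

All knobs live in `MethodPolicy` (YAML/JSON-loadable); all randomness is
driven by one seed with stable per-(measurand, partition) substreams.

## CLI

```bash
# synthetic study emulating the packaged panel (CSV + ground-truth JSON)
refintervals simulate --out sim --seed 7

# analyze any long-format table (animal_id, sex, measurand, unit, value)
refintervals compute --input sim/study.csv --out report --seed 7 --plots

# both steps in one shot
refintervals reproduce-fixture --out fixture --seed 7
```

`compute` writes `report.csv`, `report.md`, `run_log.json` and optional
`plots/*.png`. Exit codes: 0 ok, 2 input/schema error, 3 config error.

## Library sketch

```python
import refintervals as ri

table = ri.read_study_table("study.csv")
series = ri.extract_series(table, "Hb", "All")
result = ri.analyze_measurand(series, ri.MethodPolicy(rng_seed=7))
print(result.method.label, result.lower_limit, result.upper_limit, result.lrl_ci)

rows = ri.compile_report(table)          # one row per measurand x partition
```

## Notes

- The packaged panel (`refintervals.panel`) freezes published per-row
  summaries only; raw per-animal values were never deposited, so printed
  percentile limits, bootstrap CIs and between-sex p-values of specific
  rows are not exactly reproducible. The test suite substitutes oracle
  equivalence, simulation-based coverage, and parameter-recovery checks.
- Synthetic family labels (normal vs lognormal) are heuristics taken from
  the printed distribution flags; true families are unknowable from
  summaries.
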