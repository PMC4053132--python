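# riskvalid

Validation of absolute-risk prediction models against censored cohort
follow-up with competing mortality.

Clinical breast-cancer risk models (Gail/BCRAT-style, Tyrer-Cuzick/IBIS-
style, and others) assign each woman a probability of diagnosis within a
horizon h (typically 10 years).  Checking such a model against a
prospective cohort is not a simple 2x2 comparison: subjects die of other
causes before they can be diagnosed, and many are censored before the
horizon.  `riskvalid` implements the standard validation workflow for
this setting, for epidemiologists and biostatisticians evaluating risk
models on registry or cohort data.

## What it computes

**Observed risk.**  The h-year absolute risk of a group,

    pi = ∫₀ʰ I_B(t) exp(−∫₀ᵗ (I_B + I_D) du) dt,

with I_B, I_D the cause-specific hazards of breast cancer and competing
death, estimated by the Aalen–Johansen plug-in over Nelson–Aalen hazard
increments, π̂ = Σ Ŝ(t⁻) dΛ̂_B(t).  Without censoring or deaths this is
exactly (events within h)/n.  95% CIs by seeded percentile bootstrap.

**Calibration.**  Quantile groups (quartiles by default) of assigned
risk; per group the mean assigned risk r̄_g vs the observed π̂_g, the
observed/assigned ratio, and the Hosmer–Lemeshow statistic
HL = Σ n_g (π̂_g − r̄_g)²/(r̄_g(1−r̄_g)) on χ²(df = #groups); plus the
same table over covariate-defined subgroups.

**Discrimination.**  Case risk percentiles (CRP: a case's assigned risk
as a mid-rank percentile of the noncase risk distribution; censored-
before-horizon subjects excluded), the Mann–Whitney AUC (= mean CRP
exactly), empirical ROC, sensitivity at a target specificity, and a
paired Wilcoxon signed-rank comparison of two models' CRPs (exact for
≤25 nonzero pairs).

**Synthetic cohorts.**  A seeded generator with known true risks,
constant-hazard competing mortality, administrative + dropout censoring,
and configurable model assigners (calibration factor, noise,
between-model correlation), including a registry-like preset of 1,857
subjects.  See `docs/methods.md` for the model and every convention.

## Worked example

```python
from riskvalid import AnalysisConfig, bcfr_like_config, run_validation, simulate_cohort

sim = simulate_cohort(bcfr_like_config(seed=1))          # 1,857 subjects
report = run_validation(sim.cohort, AnalysisConfig(n_bootstrap=1000, seed=2))

obs = report.overall_observed
print(f"observed 10-year risk: {100*obs['pi_hat']:.2f}% "
      f"(95% CI {100*obs['ci_low']:.2f}-{100*obs['ci_high']:.2f}%)")
for m in ("model_under", "model_cal"):
    cal, disc = report.calibration[m], report.discrimination[m]
    print(f"{m}: HL={cal.hl_statistic:.1f} (df={cal.df}, p={cal.p_value:.3f}), "
          f"AUC={100*disc.auc:.1f}%, sens@80%spec={100*disc.sensitivity_at_target:.1f}%")
wx = report.comparison["wilcoxon"]
print(f"paired Wilcoxon on CRPs: p={wx['p_value']:.4f}")
```

prints

```
observed 10-year risk: 6.33% (95% CI 5.03-7.82%)
model_under: HL=245.5 (df=4, p=0.000), AUC=60.0%, sens@80%spec=30.6%
model_cal: HL=4.2 (df=4, p=0.376), AUC=69.2%, sens@80%spec=41.2%
paired Wilcoxon on CRPs: p=0.0090
```

Reading: the cohort's observed 10-year risk is 6.33%.  `model_under`
(built to under-predict two-fold) fails calibration spectacularly —
HL=245.5 against χ²₄ — while `model_cal` (near-calibrated by
construction) passes (p=0.38).  `model_cal` also discriminates better:
AUC 69.2% vs 60.0%, it catches 41% of future cases at 80% specificity vs
31%, and the paired Wilcoxon on the 85 cases' CRPs confirms the
difference (p=0.009).

The same pipeline runs from the shell on any cohort CSV
(`subject_id,time,outcome,risk_<model>...,cov_<name>...`, outcome in
{BC, DEATH, CENSORED}):

```sh
riskvalid simulate --preset bcfr-like --seed 1 --out cohort.csv
riskvalid validate cohort.csv --seed 2 --out-dir report/
riskvalid validate cohort.csv --seed 2 --out-dir report_b/ --exclude stratum=A
```

writing `calibration_quartiles.tsv`, `calibration_subgroups.tsv`,
`discrimination_summary.json`, `crp_pairs.tsv` and a full-precision
`report.json` (byte-identical across reruns with the same seed).

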