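# hatrial

Target-trial emulation of hearing-aid treatment strategies on plasma
dementia biomarkers (pTau181, NfL, GFAP, Aβ42/Aβ40 × 1000), built as a
tested, reusable pipeline exercised end-to-end on synthetic cohorts with
known ground truth.

The pipeline emulates two trials — (1) new hearing-aid prescription vs
none, (2) never / rarely-sometimes / often-always use — and estimates
survivor-conditional intention-to-treat analogues:

- **TMLE** mean differences (logistic fluctuation on the range-scaled
  outcome, clever covariate `I(A=a)/g_a`, inverse-probability weights
  truncated at `sqrt(n·ln n)/5`),
- **IPW quantile differences** at the 90th percentile (10th for the
  amyloid ratio),
- **MSM effect-modification curves** (restricted cubic splines, knots at
  the 10th/50th/90th percentiles) fit by projecting targeted predictions,
- a **MARS** (degree-2 interactions) nuisance-fit sensitivity variant.

Missing data are handled by chained predictive-mean-matching multiple
imputation with LASSO-selected auxiliary/quadratic/product terms, passive
imputation of derived terms, and NARFCS-style delta adjustment
(±0.05/±0.25 SD shifts of imputed outcomes for participants lost to
follow-up). Inference is bootstrap-then-MI: 250 bootstrap resamples × 2
imputations by default, pooled as the grand mean with a percentile
interval over within-bootstrap means.

## Layout

| module | contents |
|---|---|
| `hatrial.synthetic_cohort` | cohort generator (confounding, death, MAR/MNAR missingness), Monte-Carlo truth oracle |
| `hatrial.trial_emulation` | eligibility criteria, strategy assignment, out-of-sample dementia risk score |
| `hatrial.missing_data` | chained PMM imputation, LASSO auxiliary selection, delta adjustment |
| `hatrial.estimation` | TMLE, IPW quantiles, splines, MSM projection, MARS |
| `hatrial.inference` | bootstrap-MI intervals |
| `hatrial.pipeline_cli` | orchestration + `hatrial` CLI |

## CLI

```bash
# synthetic cohort + JSON truth sidecar
hatrial simulate --seed 1 --n 2842 --out-dir data/

# full emulation (profile ci: n=800, B=50; profile paper: n=2842, B=250)
hatrial run --config config.yaml --seed 1 --out-dir results/ --profile ci

# negative treatment control (skin-exam exposure)
hatrial negctrl --seed 1 --out-dir results/

# pretty-print a results table with reference rows
hatrial report --results results/results.csv
```

Example `config.yaml`:

```yaml
trials: [1, 2]
biomarkers: [ptau181, nfl, gfap, abeta_ratio]
estimators: [tmle_mean, ipw_quantile]
modifiers: [cognition_3ms]
delta_shift_sd: 0.0        # NARFCS sensitivity: 0.05 or 0.25
pta_threshold_db: null     # set 30 for the audiometric-eligibility rerun
mars_nuisance: false
cohort_spec:
  n_participants: 2842
  true_mean_diff: {ptau181: 0.0}
```

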