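# hfreadmit

Prediction of **unplanned 30-day readmission of ICU patients with heart
failure** from electronic health records, combining process mining with a
deep feed-forward classifier — plus a synthetic EHR simulator so the entire
pipeline is testable without access to any restricted clinical database.

## The method

A patient's hospital history is rewritten as an **event log**: per admission,
an admission-type event at the admit time, an insurance event 1 ms later,
mean/std events for four HF-relevant lab analytes (BUN, serum creatinine,
sodium, NT-proBNP), one event per Elixhauser comorbidity group packed just
before discharge, an *artificial event* abstracting the admission's ICD-9
procedure / CPT code sequence (k-means over hashed n-grams, k = 30), and a
discharge event. A Petri net is mined from the training log
(directly-follows construction, pluggable via PNML), and each trace is
replayed with **per-place decay functions**

&nbsp;&nbsp;&nbsp;&nbsp;f_p(t) = max(0, β − α_p · (t − t_last,p)),&nbsp;&nbsp;α_p = β / D_p,

where D_p is the largest token inter-arrival time observed at place p during
training replay. The vector of decay values, cumulative token counts and
marking captured at the **index discharge** (the TSS marker — nothing after
it is ever used) is the timed state sample (TSS). TSS, demographics (age,
gender, ethnicity) and severity scores (Charlson and Elixhauser via the Quan
ICD-9 mappings) feed three branches of a neural network (3 ReLU hidden
layers per branch, batch-norm after the first, 20% dropout, one
post-concatenation layer, 2-unit softmax; Adam, batch size 10). Six
classical baselines (SVM, k-NN, decision tree, random forest, XGBoost,
LightGBM) are grid-searched in both a raw-tabular mode and a TSS mode.
Evaluation: AUROC with DeLong confidence intervals, threshold metrics,
chi-square/t-test cohort comparisons, grouped Monte-Carlo Shapley
attribution and variable/layer ablations.

The label is TRUE iff the next admission after the index discharge is
emergency/urgent and starts within 30 days (boundary inclusive).

## The simulator

`hfreadmit.synthetic_ehr` generates MIMIC-III-shaped tables (PATIENTS,
ADMISSIONS, LABEVENTS, D_LABITEMS, DIAGNOSES_ICD, PROCEDURES_ICD,
CPTEVENTS). Each patient draws a latent severity z ~ N(0,1); for
cohort-eligible patients the probability of unplanned 30-day readmission is
exactly `logistic(logit(0.235) + s·z)` with configurable signal strength
`s`, and the same z shifts lab means and comorbidity prevalences so the
signal is recoverable from the features. With `s = 0` the outcome is
independent of everything — a built-in negative control.

## Worked example

```python
from hfreadmit.config import PipelineConfig, SyntheticConfig, NNConfig
from hfreadmit.pipeline import run_pipeline

cfg = PipelineConfig(
    synthetic=SyntheticConfig(n_patients=600, seed=11, signal_strength=2.0),
    nn=NNConfig(epochs=15, seed=0),
    seed=11,
)
res = run_pipeline(cfg)
m = res["metrics"]
print(f"test AUROC {m.auroc:.3f} [{m.ci_low:.3f}-{m.ci_high:.3f}], "
      f"precision {m.precision:.3f}, sensitivity {m.sensitivity:.3f}")
```

prints (on this 600-patient cohort, ~440 members after selection):

```
test AUROC 0.731 [0.593-0.868], precision 0.632, sensitivity 0.545
```

i.e. with a strong planted signal the classifier separates readmitted from
non-readmitted patients well above chance even at this small size; at
n_patients = 3000 the test AUROC rises to ≈ 0.84. The same run is available
from the shell:

```bash
hfreadmit --seed 11 --outdir runs/demo all     # simulate ... evaluate
hfreadmit --seed 11 --outdir runs/demo shapley # grouped attribution
```

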