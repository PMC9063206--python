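# Methods

## Problem and pipeline

The package predicts unplanned 30-day readmission for ICU patients with
heart failure (HF). The positive class is defined at the *index* admission
— the most recent admission carrying an HF ICD-9 diagnosis (398.91, 402.01,
402.11, 402.91, 404.01/03/11/13/91/93, or any 428.xx) that still has at
least one later admission — and is TRUE iff the next admission is of
emergency or urgent type and begins within 30 days of the index discharge.
The 30-day boundary is inclusive (a gap of exactly 30.0 days counts), a
convention fixed here because "within 30 days" is ambiguous; it is pinned by
an explicit unit test. Members additionally need one prior admission (the
process features need a history) and must not carry a death flag.
When several HF admissions qualify, the latest one with a successor is the
index; treating every qualifying HF admission as a separate instance would
be an alternative design and is deliberately not implemented.

Stages: EHR tables → cohort selection and labeling → event-log conversion →
directly-follows Petri-net discovery → decay replay (timed state samples) →
three-branch neural classifier and six classical baselines → evaluation.

## Event-log conversion

Each admission contributes events in a fixed pattern: admission type at the
admit time; insurance 1 ms later; per analyte a Mean event at the first
measurement time and a Std event either 1 ms after it (single measurement)
or at the last measurement time (repeated); one event per Elixhauser group
scored for that admission, the i-th of m placed at discharge − (m − i) ms
in canonical group order (deterministic and strictly pre-discharge); one
artificial event per admission with a non-empty ICD-9-procedure/CPT code
sequence at the first code observation time + 1 ms, clipped to
discharge − 0.5 ms; and a discharge event at the discharge time.
Timestamps within a trace are strictly increasing; exact collisions (only
constructible adversarially — generated data uses continuous times) are
resolved by deterministic +0.5 ms bumps and raise if they would reach the
discharge anchor. The TSS marker sits at the index admission's discharge
event, and traces simply end there, so no post-index information can reach
any feature; the replay additionally ignores anything after the marker.

Artificial events abstract an admission's ordered procedure + CPT code
sequence: hashed bags of code 1- and 2-grams (crc32, 256 dimensions)
clustered by k-means (k = 30, 10 restarts, seeded), fit on the training
cohort only. The vectorize-then-cluster choice is a replaceable strategy
behind `ArtificialEventModel`; any model exposing `predict_name` can stand
in. Per admission the single cluster label is emitted as one event; a
multi-event variant (one per code) would be a different reading of
"sequence of observations plus 1 ms" and was not chosen because it floods
the log with near-duplicate timestamps. Lab Std events use the
per-admission standard deviation; a single measurement yields std = 0.

## Severity scores

Charlson and Elixhauser indices use the Quan et al. ICD-9-CM mappings,
shipped as CSV tables (prefix match on decimal-stripped codes). Charlson is
the weighted category sum (weights 1/2/3/6, each category once); Elixhauser
defaults to the unweighted count of distinct groups — chosen because the
method contrasts Charlson's severity weighting with Elixhauser treating all
conditions equally — with the van Walraven weighted sum behind a flag.
Scores pool diagnoses from all admissions up to and including the index
admission ("discharge-anchored"), never later ones.

## Discovery and decay replay

The miner counts the directly-follows relation over event names (traces
padded with START/END) and builds: one labeled transition per name, one
place per retained pair (count ≥ threshold, default 1) connecting the
pair's transitions, a source place feeding START and a sink fed by END.
An OTHER transition gives unseen test-time names a routing target
(the event-name vocabulary is frozen on the training log). Transitions
orphaned by pruning are connected from source / to sink so every transition
keeps ≥ 1 input and output place. Replay semantics: firing consumes one
token from the marked input place with the most recent arrival (canonical
place order breaks ties) — inserting and counting a missing token if none
is marked — and produces one token into every output place, resetting its
decay clock and incrementing its arrival counter. These semantics make
every training trace replay with zero insertions at threshold 1, and
insertions occur exactly where pruning removed pairs. Externally mined nets
can be substituted through PNML.

Decay is linear, `max(0, β − α_p·Δt)` with β = 1 for all places (fixing β
makes decay values comparable across places and removes one normalization);
α_p = β/D_p with D_p the largest within-trace token inter-arrival gap at p
over the training replay, falling back to the maximum trace duration for
places activated at most once. Time is measured in days, so the millisecond
ordering offsets contribute ~10⁻⁸ of decay and carry no information. The
timed state sample concatenates decay values, cumulative token counts and
the current marking (each block can be disabled); min-max normalization is
fit on the training matrix only, so test values may leave [0, 1] but are
never NaN. Missing-token counts are kept on the sample but are not a
feature column by default.

## Classifier and baselines

The network has three input branches (TSS, demographics, severity), each
with three fully-connected ReLU hidden layers, batch normalization after
the first hidden layer of each branch, and 20% dropout after the first,
second and third hidden layers; branch outputs are concatenated into one
post-concatenation hidden layer and a 2-unit softmax. Training: Adam,
categorical cross-entropy, batch size 10, 100 epochs by default; the epoch
with the highest validation AUROC is restored. Hidden widths
(128, 64, 32 / 64 post-concat), learning rate (10⁻³) and the loss are
package defaults surfaced in `NNConfig`; layer counts per branch (1–4) and
the presence of the post-concatenation layer are configurable to drive the
layer-ablation study. The implementation is plain numpy — the architecture
is small enough that a dependency on a deep-learning framework buys
nothing — and is exactly reproducible given the seed. Class imbalance
(~24% positive) is left unweighted by default, with an optional flag-free
alternative deliberately out of scope.

Baselines: SVM (RBF, Platt-calibrated), k-NN, decision tree, random forest,
and two gradient-boosted variants (XGBoost and LightGBM). Each is
grid-searched over a modest published-default grid (serialized in
`BASELINE_GRIDS`) and selected by validation AUROC, in two input modes:
`tabular` (admission type, insurance, pooled lab mean/std, Elixhauser
indicators, demographics, severity scores — missing labs mean-imputed with
training values) and `tss` (the NN's exact input, flattened).

## Evaluation

AUROC is the Mann-Whitney statistic with half tie credit; its variance
comes from the DeLong structural components and the 95% CI is the normal
interval clipped to [0, 1] (unit-checked against an exhaustive pairwise
oracle, a bootstrap, and a coverage simulation). Threshold metrics use 0.5
on the positive-class softmax output (the operating point is configurable;
no threshold tuning is performed). Cohort comparison uses chi-square tests
for categorical and two-sided Student t-tests for continuous variables at
p < 0.05. Grouped Shapley attribution partitions the model input into six
families (severity, admission events incl. insurance/discharge,
demographics, artificial events, comorbidity events, lab events; TSS
columns are assigned by the family of the place's source event),
mean-imputes masked groups with training means, and estimates contributions
by permutation sampling — exact for linear models, with a batch-means
Monte-Carlo standard error otherwise. The ablation driver re-executes
conversion → TSS → training with an event category removed or an input
block zeroed (a width-1 constant column keeps the branch structurally
valid), 10 training repeats by default; discharge events can never be
removed because they carry the TSS marker.

## Synthetic data: what it emulates and what it does not

The generator emulates the *relational shape* and the *causal structure*
needed by the pipeline, not clinical realism. Each patient draws a latent
severity z ~ N(0,1). For the configurable eligible fraction (default 85%)
the admission following the index discharge is unplanned-within-30-days
with probability `logistic(logit(0.235) + s·z)` — 0.235 being the target
readmission base rate — realized by the gap/type of that admission
(positives: emergency/urgent, gap U(1, 30) days; negatives: either a gap in
U(31, 365) or an elective admission inside the window, so the label
boundary is exercised from both sides). The same z shifts the four lab
analyte means by 0.8 standard deviations per unit z and the Elixhauser
group prevalences by +0.12 per unit z (clipped; groups with zero baseline
prevalence stay absent), making the signal recoverable through both the
lab-event and the severity/comorbidity paths; procedure and CPT codes are
drawn uniformly from synthetic vocabularies and deliberately carry no
signal. Comorbidity codes are drawn from the Quan mapping prefixes, except
codes that would trigger HF cohort inclusion — the explicitly injected
428.0 in the index admission is the only inclusion trigger, which keeps the
label mechanism exactly calibrated. Non-eligible patients (fewer
admissions, HF codes only in a first admission, 10% death flags, rare
NEWBORN types) exercise every exclusion path. Timestamps live on a
synthetic calendar at 1-second resolution; lengths of stay are U(2, 14)
days. Not emulated: longitudinal code persistence (comorbidities redraw
per admission), realistic lab distributions (NT-proBNP is Gaussian here),
chart events and notes, transfers, and multi-hospital linkage — so green
tests demonstrate that the *pipeline recovers a planted mechanism*, not
clinical performance on real data.

With s = 0 the label is Bernoulli(0.235) independent of all features; the
suite verifies calibration within binomial error and that no model finds
signal. With s = 2 the Bayes-optimal AUROC of the latent severity itself is
≈ 0.86, bounding what any model can reach.

## Problem sizes and numerical choices

The test and acceptance runs use scaled-down study conditions chosen as the
package's defaults: 3000-patient cohorts (≈ 2300 members), 20 training
epochs for the signal-recovery checks, 1000 random toy-net cases for the
replay oracle, 500 simulations for the DeLong coverage check and 2000
bootstrap replicates for the CI cross-check. Degenerate inputs are handled
explicitly: single-class training labels raise; a single-class validation
split records AUROC 0.5; zero-variance variables report p = 1 with a note;
empty code sequences emit no artificial event; admissions with no recorded
data still emit admission-type, insurance and discharge events. Known
limitations: the discovery algorithm is a deterministic DFG construction
(the replayed net, not the miner, is the modeling object — any PNML net can
be substituted); per-feature Shapley values and survival-time modeling are
out of scope; ICD-10 is not mapped.
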