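# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the known limitations of `coagcast`.

## Disease scoring and window labels

SIC and ISTH overt-DIC scores are computed from raw laboratory values with
the published threshold tables as defaults (every cut configurable):

| score | component | 0 | 1 | 2 | 3 |
|---|---|---|---|---|---|
| SIC | platelets (×10⁹/L) | ≥150 | <150 | <100 | — |
| SIC | PT-INR | ≤1.2 | >1.2 | >1.4 | — |
| SIC | SOFA | 0 | ≥1 | ≥2 | — |
| ISTH | platelets (×10⁹/L) | ≥100 | <100 | <50 | — |
| ISTH | D-dimer (mg/L FEU) | <1.0 | — | 1.0–5.0 | >5.0 |
| ISTH | PT prolongation (s) | <3 | 3–6 | >6 | — |
| ISTH | fibrinogen (g/L) | ≥1.0 | <1.0 | — | — |

SIC is positive at total ≥ 4 (an optional flag additionally requires the
platelet + INR subscores to exceed 2, a published variant); ISTH overt DIC
at total ≥ 5. The PT prolongation baseline is a configurable laboratory
reference (default 12.0 s). D-dimer is the preferred fibrin marker with FDP
fallback (bins 10/25 mg/L) when D-dimer is missing at assessment time. The
**two-step sequential rule** (on by default, relaxable by flag) makes an
assessment DIC-positive only if SIC positivity was reached at or before it —
sepsis-associated DIC is modeled strictly on the SIC → DIC path.

A stream is assessed at every timestamp where a scoring variable updates;
each input uses the variable's most recent value within a 24 h staleness
horizon (matching the 24 h sampling window) and is otherwise treated as
missing — a score with missing inputs is *not computable*, never imputed.
Assessments collapse into 8 h windows (latest computable assessment wins);
absent windows between observed ones are interpolated — agreeing flanks
share their label, disagreeing flanks resolve **forward** to the earlier
label, avoiding look-ahead leakage — and trailing windows are forward-filled.
Leading windows before any observation stay absent.

## Irregular-series encoding

Per variable d at row t the encoder produces the observation mask m_t^d and
the interval δ_t^d (time since last observation, accumulated through
unobserved rows; δ_1 = 0), plus the global adjacent step Δ_t = s_t − s_{t−1}
(the per-variable reading of Δ is the δ feature itself, which is always
provided). Windows are half-open [start, start+24 h), slid by 8 h, one
window per position fully in-stay; δ continues across window boundaries
using the full patient history, because the recurrence is defined on the
whole series. Windows with zero observations are retained — their
missingness is signal — as a single all-masked pseudo-row at the window
end. Targets at horizon h are the timeline label of the window containing
window_end + h; windows with no target at any horizon are dropped from
model datasets.

Values are clamped to configurable physiologic reportable ranges (stand-ins
for laboratory reportable ranges) and min-max normalized with statistics
from **training patients only**; transform output is clamped to [0, 1].
Unobserved entries carry fill value 0 after normalization, recoverable
through the mask. The discretized view for tabular models uses three 8 h
cells per window with (last value, observation count) per cell and variable,
concatenated with the per-variable δ at window end — dimension 3·2·D + D.

## Models

Tabular baselines (one independent fit per disease × horizon) are delegated:
scikit-learn logistic regression and RBF-SVM (standardized inputs, balanced
class weights; the SVM subsamples to at most 2,000 training rows for
tractability), XGBoost and LightGBM (150 trees, depth-4 / 31 leaves,
learning rate 0.1, single-threaded and seeded for reproducibility,
inverse-prevalence positive-class weighting).

Sequence models share a trunk and one sigmoid head per (disease, horizon),
on inputs concat(x_t, m_t, δ_t/δ_scale) with δ_scale = 48 h:

* **plain RNN / LSTM** consume the discretization grid (three cells of
  (last value, seen flag) per variable) — by construction they cannot see
  within-cell gap changes;
* **RNN-Decay** decays the hidden state elementwise by
  γ_t = exp(−max(0, w_γ Δ_t + b_γ)) before each update (γ = 1 at zero gap,
  γ → 0 for long gaps);
* **ODE-RNN** integrates dh/dt = f_θ(h), a one-hidden-layer tanh network,
  between observations with classical RK4 at a fixed number of substeps per
  gap (default 4; per-sample step = gap/substeps), then applies the
  recurrent jump update. The dynamics output layer is initialized at small
  scale (0.1/√H) so the untrained model starts near a plain recurrent chain;
  this materially improves trainability. `ode_evolve`/`ode_query` expose
  h(t) at arbitrary times; fixed-step RK4 was chosen over adaptive solvers
  for bit-reproducibility.

Training: masked binary cross-entropy (absent targets contribute nothing),
inverse-prevalence positive weights capped at 50, Adam (default, lr 0.01) or
SGD, gradient-norm clipping at 5, early selection of the epoch with the best
mean validation AUROC. The models run on a compact reverse-mode autodiff
engine over numpy written for this package (`coagcast.autodiff`), verified
against finite differences in the test suite; hidden size 32 and ≤ 20 epochs
are desk-scale CPU defaults.

## Synthetic cohort generator

The generator emulates the qualitative structure of an annotated sepsis
cohort; it is openly synthetic — no distributional facts about real ICU data
beyond the published prevalences (SIC 37.1%, DIC 17.8%) inform it, and every
parameter below is a stand-in chosen for plausibility.

* **Latent path.** Each patient is healthy-sepsis, SIC, or SIC → DIC, drawn
  at the target prevalences (progression strictly sequential; no reversal —
  treatment effects and recovery are out of scope). SIC onset is uniform on
  [24 h, stay − 40 h]; the DIC gap uniform on [16 h, 72 h] capped to fit the
  stay; stays uniform between 96 h and `max_stay_h` (240 h default),
  independent of outcome so that sampling counts are outcome-independent
  when the severity coupling is switched off.
* **Trajectories.** Each variable has state-conditional means (platelets,
  fibrinogen, plateletcrit fall; INR, PT, APTT, D-dimer, FDP, SOFA, lactate
  rise along the progression), drifting piecewise-linearly over a 16 h lead
  window to 45% of the step before onset and settling within 4 h after, with
  multiplicative lognormal noise (σ = 0.08). The pre-onset drift is what
  makes onsets predictable ahead of time; the 45% lead fraction keeps
  pre-onset values on the correct side of the scoring thresholds, so that
  scoring the generated labs recovers the latent state for ≈99% of
  computable assessments at default noise — comfortably above the 90%
  premise the recovery tests rest on.
* **Sampling.** Observations arrive via a thinned-Poisson *blood draw*
  process whose intensity scales as (1 + coupling × severity), severity ∈
  {0, 1, 2} — sicker patients are sampled more often (informative
  missingness). Each draw contains each panel variable with probability 0.7;
  the base per-variable rate is 3 observations / 24 h. A full admission
  panel at t = 1 h guarantees labs in the first day; SOFA is emitted as an
  already-computed daily score (its derivation from organ variables is out
  of scope). Patient substreams derive from (seed, patient index), so
  cohorts are stable under changes of n.
* **Panel.** Default ten variables {PLT, INR, PT, APTT, D-dimer, FDP, FIB,
  SOFA, PCT (plateletcrit), lactate} — the variables that dominate feature
  importance in this prediction problem; the panel is config-extensible.
  `signal_variables` can restrict which variables respond to the latent
  state (used to build one-signal cohorts for interpretation tests).

What passing tests show — and do not. Recovery results on this generator
demonstrate that the pipeline is correct and that the models can exploit
trajectory drift and informative missingness; they say nothing about
real-data performance, where trajectories are noisier, interventions perturb
labels, and the feature panel is far wider.

## Evaluation and interpretation

AUROC is Mann-Whitney with half-credit ties; AUPRC and F1 are delegated to
scikit-learn (F1 threshold default 0.5; sweeps cover 0.10–0.90 in steps of
0.05 plus 0.70). Confidence intervals are percentile bootstrap over 1,000
resamples drawn at the **patient** level (windows of one patient are
correlated; window-level resampling, available by flag, understates
variance). Single-class resamples are skipped and counted; single-class
cells are reported absent with a reason, never as zero. Alarm metrics are
event-level: recall is the fraction of first-onset windows targeted by an
alert (risk ≥ threshold predicted one horizon ahead), precision the fraction
of alerts whose targeted window was truly positive.

Occlusion re-encodes the dataset with one variable never observed (mask
zero, fill values, δ recomputed from the series start) and re-scores the
trained model without retraining — global absence, not value-zeroing, so the
interval semantics stay coherent. Tree attributions are delegated to the
TreeSHAP implementations inside xgboost/lightgbm; additivity (contributions
+ base = margin) is asserted in tests. The Lite panel is the top-k (k ≤ 10)
by mean of the attribution and occlusion rank lists with manual
clinical-practicability overrides.

## Pipeline and reproducibility

Stages (generate → label → encode → train → evaluate → interpret) read and
write artifacts in the run directory with manifests (config hash + input
hashes); unchanged stages are skipped. Splits are 70/10/20 at the patient
level with largest-remainder rounding. All randomness derives from the run
seed; identical runs produce byte-identical evaluation reports (fixed float
formatting, single-threaded tree learners).

Problem sizes are desk-scale choices: the recovery experiment uses 700
patients with 96–120 h stays and horizons {8, 48} h; the acceptance script
uses 400 patients; the reproducibility check 200 patients with a reduced
roster. The CLI's `sweep-window` subcommand reruns the sampling-window
pre-experiment (8/24/48 h) on demand rather than by default.

## Known limitations

* The generator's piecewise-linear trajectories and lognormal noise are the
  simplest mechanism sufficient for scorer recoverability — not a calibrated
  physiologic model; state reversal, treatment effects and vital-sign
  waveforms are not modeled.
* Exact annotation details of clinical deployments (reportable ranges,
  laboratory PT references, scoring variants) differ between hospitals; the
  defaults here are reconstructions from the published scoring tables and
  are configurable and echoed into outputs for provenance.
* The SVM baseline subsamples large training sets; the sequence models are
  small (hidden ≤ 64) and single-seeded by default — no hyperparameter
  search beyond the documented defaults.
* ODE-RNN hidden-state queries between observations use the same fixed-step
  RK4 as training; solver error is bounded by the step choice (tested to
  1e−4 flow-composition consistency at step 0.05 h).
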