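# Methods

`pulsesv` estimates left-ventricular stroke volume (SV) from quantities a
clinician can obtain without a catheter: age, gender, weight, height,
brachial cuff pressures (SBP, DBP, and the derived PP and MAP) and
carotid-femoral pulse wave velocity (cfPWV). Because paired invasive
reference data are scarce, the estimator is trained entirely on synthetic
subjects produced by a 1-D arterial pulse-wave model, and the clinical
evaluation path is exercised on synthetic patient tables with the same
structure as a two-setting catheterization study. This note documents the
models, their assumptions, the defaults, and what the synthetic test
surface does and does not establish.

## 1-D pulse-wave model

Each arterial segment is a tapered, distensible tube carrying the
cross-sectionally integrated continuity and momentum equations

    dA/dt + dQ/dx = 0
    dQ/dt + d(Q²/A)/dx + (A/ρ) dP/dx = −k_f π ν Q/A

with area A, flow Q, pressure P, density ρ = 1050 kg/m³ and viscosity
μ = 0.004 Pa·s. The wall law is linear in pressure by default,
A(P) = A_ref(x)·(1 + D·(P − P_ref)), where D is the distensibility
(10⁻³/mmHg) at the reference pressure P_ref = 90 mmHg; an exponential
stiffening variant (same slope at P_ref, `nonlinearity_coefficient` > 0)
is available but off by default because the linear law is directly
testable against the Bramwell–Hill speed c = √(1/(ρ·D_SI)). The friction
term is a Poiseuille-type profile correction; k_f = 22 by default (k_f = 8
is a parabolic profile; blunter physiological velocity profiles dissipate
more), and the coefficient is exposed in `SolverConfig` because velocity-
profile theory is not part of this package's scope.

The network is a rooted tree. The aortic root receives a prescribed
periodic flow wave (default: half-sine systolic lobe of duration ET, zero
diastolic flow, period integral equal to SV). Every leaf is closed by a
three-element Windkessel (characteristic-impedance-scale proximal
resistance, distal resistance, compliance, venous pressure), integrated
implicitly. Bifurcations enforce conservation of flow and continuity of
static pressure through a small Newton solve each step; a total-pressure
junction rule was considered and not implemented since the static rule is
standard 1-D practice and the momentum correction is negligible at
arterial Mach numbers.

Numerics: two-step Lax–Wendroff (MacCormack) predictor–corrector on a
per-segment uniform grid (target spacing 2 cm, ≥ 3 nodes), time step set
once per run from a conservative wave-speed bound (area evaluated at
280 mmHg plus a 2.5 m/s advective margin) at Courant number 0.8. Boundary
and junction nodes are closed with linearized characteristic
compatibility relations written in (u, P) rather than (u, A) variables —
on tapered segments the pressure is the smooth variable while the area is
not — and they carry the geometric source term ∓u·c·A'_ref/A_ref plus the
friction source along the characteristic. Both choices are load-bearing:
without them, strongly tapered segments (e.g. a 1.1→0.5 cm brachial
path) leak several percent of the cycle volume; with them the whole-tree
cycle volume balance closes to ~0.1% at the default grid.

A run executes cardiac cycles from a quiescent start (P = P_ref, Q = 0)
until the cycle-to-cycle maximum change of root pressure falls below
1×10⁻³ of its magnitude, up to 30 cycles. Typical subjects converge in
9–12 cycles; very compliant young-adult parameter draws need 16–17, which
is why the cap is 30 (a 15-cycle cap made drops common in the youngest
strata). Non-convergence is flagged, never silently returned; NaN or
boundary-Newton failure raises with the cycle and time step identified.

## Reduced arterial tree

The packaged tree has 8 segments: ascending aorta/arch, common carotid,
subclavian–brachial path, thoracic aorta, a lumped visceral branch,
abdominal aorta, an iliac–femoral path and a lumped contralateral iliac.
It preserves every site the pipeline measures (aortic root, left
brachial, carotid, femoral) and the carotid→femoral anatomical path
(0.663 m), while remaining cheap enough for cohort-scale simulation
(~30–50 ms per subject after JIT compilation). Dimensions are typical
adult textbook values; Windkessel resistances distribute a total
peripheral resistance of 1.02 mmHg·s/mL over head (18%), arm (9%),
viscera (45%), and the two legs (16%/12%), with proximal elements near
each terminal's characteristic impedance to limit artificial reflections.
At the reference state (CO 5.5 L/min, HR 75 bpm, ET 0.23 s) the tree
produces brachial 123/67 mmHg (MAP 93) and cfPWV 10.6 m/s. The measured
cfPWV is higher than textbook values for a healthy adult because the
foot-to-foot transit excludes the common-carotid travel time while the
conventional path length does not — the same bias affects clinical cfPWV;
internally the quantity is used only as a stiffness feature, so the
offset is immaterial.

## Synthetic cohort

Subjects are drawn per stratum (6 age decades × 2 genders) from the
packaged population table: independent Gaussians for height, weight,
heart rate, aortic distensibility, total peripheral resistance (TPR) and
MAP. Inter-parameter correlations are deliberately not modelled (the
underlying literature provides only marginals). Draws are redrawn outside
[mean − 3 SD, mean + 3 SD] and below per-parameter positivity floors
(distensibility ≥ 0.3×10⁻³/mmHg, TPR ≥ 0.5 mmHg·s/mL, …): plain ±3 SD
truncation alone still admits non-physical negative distensibility in the
oldest female stratum (1.1 ± 0.8). The floors bind rarely and shift the
affected stratum means by well under one SD.

Derived quantities: CO = MAP/TPR (mL/s), SV = CO·60/HR,
ET = 0.266 + 0.0011·(SV − 82) − 0.0009·(HR − 73) (the Weissler
regression), clamped to (0.05 s, 0.95·period) with a logged warning —
the clamp engages only for implausible tail draws. Per-subject tree
scaling is uniform and multiplicative: lengths by height/180 cm;
diameters by the ratio of a linear aortic-diameter model
(a_gender + 0.008·age + 0.45·BSA, Du Bois BSA) to its reference subject —
the coefficients are package defaults chosen to reproduce typical adult
aortic calibres and trends, and only the ratio matters; distensibilities
and terminal compliances by sampled/reference aortic distensibility
(reference 5.0×10⁻³/mmHg, the packaged tree's aortic value); terminal
resistances by a common factor placing the parallel total exactly at the
sampled TPR. Age enters the feature vector as the stratum midpoint (24.5,
…, 64.5, 75 for ">70"); gender as M→0, F→1.

Features are extracted from the final converged cycle: SBP/DBP/PP as the
brachial waveform extrema, MAP as its time average, and cfPWV as the
carotid→femoral anatomical path length divided by the foot-to-foot
transit time (no 0.8 correction — that factor de-biases tape-measured
surface distances, not exact model path lengths). The training target is
always the imposed inflow volume, never re-derived from waveforms.
Subjects whose simulation fails to converge or whose transit time is
degenerate are dropped with a logged count (~1–2% at defaults, dominated
by extreme independent-draw combinations such as TPR at its floor with
3-SD-low heart rate); more than 20% failures in a stratum aborts.

What the generator does not emulate: measurement noise on the training
side (features are noise-free model outputs), pathology-specific
parameter shifts, inter-parameter physiological correlations, and any
venous/cardiac coupling (the inflow is prescribed, so preload effects are
outside the model). Training-set accuracy therefore bounds what the same
pipeline could achieve on real patients from above.

## Stroke-volume estimator

A gradient-boosted ensemble of regression trees (squared-error loss) on
the 9 features, tuned by exhaustive grid search over n_estimators
{60, 80, 100, 120} × learning_rate {0.2, 0.4, 0.6} × max_depth
{3, 5, 8, 10} × max_features {sqrt} × min_samples_leaf {1, 3, 5} with
shuffled 5-fold cross-validation scored by R², then refit on the full
training set. The search seed is a required, persisted input; the saved
model bundle carries the schema, selected point, CV score and a training
config hash, and prediction refuses tables that do not match the schema.
No fine-tuning on evaluation data ever occurs.

A structural property worth knowing: heart rate is not among the 9
features while SV = CO/HR, so part of the SV variance is irreducible from
the feature vector alone (HR information enters only weakly through
waveform-shape summaries). Recovery accuracy therefore improves with
training-set size toward an intrinsic ceiling rather than toward
perfection; the shipped recovery experiment (2,400 training records)
measures the scaled-down operating point, and the committed pilot record
in `tests/fixtures/pilot_recovery.json` documents the measured values at
both that scale and the full 9,996-record scale.

## Clinical evaluation path

Patient tables mirror a two-setting study: up to three cuff SBP/DBP/HR
repeats at the PWV-assessment setting, two cfPWV readings, up to three
repeats plus thermodilution CO at catheterization. Averaging uses
arithmetic means over available repeats (a single repeat is tolerated);
cuff MAP is DBP + PP/3 (the convention is config-exposed, since cuff
devices differ); the reference SV is thermodilution CO·1000/HR_cath. The
hemodynamic-coherence filter excludes a patient when the relative
difference |x_PWV − x_cath|/x_cath of MAP or HR exceeds 25% (threshold
and denominator convention configurable; the catheterization value is
the denominator because it is the setting of the reference SV).

Agreement statistics: Pearson r with t-distribution p-value (n − 2 df);
MAE; RMSE; nRMSE = RMSE/(max − min) of the reference series; Bland–Altman
bias = mean(predicted − reference) — the sign convention under which an
underestimating predictor yields negative bias — with limits of agreement
bias ± 1.96·SD of the differences. The LoA SD uses the population form
(ddof = 0); descriptive mean ± SD summaries use the sample form
(ddof = 1). Wilcoxon signed-rank uses the exact null for n < 25 and the
continuity-corrected normal approximation otherwise; paired t compares
settings; Welch's unequal-variance t compares the synthetic cohort with a
patient series.

The synthetic patient generator draws ground-truth physiology either from
the cohort sampler plus simulator ("cohort" source — self-consistent
BP/cfPWV/SV triples matching the training distribution) or from plausible
parametric ranges ("parametric" — fast, for filter-level tests). Noise
defaults: repeat SDs 3/2.5/2 (SBP mmHg / DBP mmHg / HR bpm), cfPWV device
SD 0.5 m/s, thermodilution SD 5 mL; between-setting shifts are relative
Gaussians (means +3%/+4%/−4% for SBP/DBP/HR, SD 6%), matching the
direction and size of discrepancies reported for real paired settings; a
configurable fraction of patients receives a deliberate >25% shift. The
default age/gender mix is dominated by the >70 strata, mirroring a
catheterization-lab population. With all noise at zero the averaged table
equals the ground truth exactly and the filter keeps everyone, which is
the basis of the pipeline-consistency tests.

## Problem sizes and determinism

Everything is deterministic given seeds: the solver is pure floating-point
(bit-identical reruns), sampling uses a single `numpy` Generator stream
in fixed stratum order, CV folds and the boosting ensemble take the same
seed. The shipped experiments use a 2,400-record training cohort and a
600-record evaluation cohort (the full 12×833 = 9,996-case generation
runs in about six minutes on one core and is exposed through the same
API and CLI), 24-patient tables, and the full printed hyperparameter
grid (144 points × 5 folds).

## Known limitations

- The reduced 8-segment tree reproduces the measurable surface of a full
  systemic network, not its detailed reflection pattern; absolute
  waveform morphology is schematic.
- The linear wall law admits unphysiologically large pulse pressures for
  the stiffest tail draws (distensibility scale « 1); the cohort keeps
  such cases by design, and the exponential wall option exists for users
  who prefer saturation.
- Uniform distensibility scaling ties muscular-artery stiffness to aortic
  stiffness one-to-one; real ageing stiffens the aorta faster than the
  periphery, so the synthetic cfPWV range stretches wider than clinical
  cohorts at the old end.
- Gaussian, independent parameter sampling produces occasional extreme
  SV values (ratio distributions are heavy-tailed); they are kept unless
  the simulation or feature extraction degenerates.
- All accuracy statements are in-distribution statements about the
  synthetic world; nothing here validates transfer to real patients.
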