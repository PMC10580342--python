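# Methods

This note records the statistical model behind `vnsnet`, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate,
and the numerical decisions that a maintainer would otherwise have to
reverse-engineer from the code.

## Data model and preprocessing

A recording is a continuous 19-channel signal (10–20 montage: FP1 … Pz,
canonical order fixed in `vnsnet.montage`) with annotated seizure onsets.
From each onset a 60 s window is cut; overlapping windows keep the
earlier onset and drop the later one with a warning (the windows are
required to be non-overlapping, and keep-first is the simplest
deterministic resolution). Each second is collapsed to its per-channel
arithmetic mean — at 1000 Hz, a 1000-sample block mean — turning a raw
60 000 × 19 block into a 60 × 19 epoch matrix. This reduction is linear
and exactly invertible for the synthetic generator at zero within-second
noise, which is what makes the preprocessing stage testable analytically.

Patients contribute unequal seizure counts, so each child's epoch list is
balanced to a fixed target (default 56) by bootstrap: every raw epoch is
kept once and the remainder is drawn with replacement from the same
child's raw epochs, values copied verbatim. The alternative reading —
resample all 56 slots — is selectable in principle but was not adopted;
keeping every observed epoch wastes no real data and makes the
"augmentation fabricates nothing" property exactly testable. Balancing
runs after the discovery/testing split but is patient-local, so the order
is immaterial. The split itself is a uniform stratified draw: a fixed
number of responders and nonresponders (default 10 + 6 of 15 + 8) into
discovery, the rest into testing.

Bootstrap duplication means discovery epochs are not independent; see
*Limitations*.

## Connectivity estimation

Within an epoch, the covariance at second t is a Gaussian-kernel-weighted
second-moment matrix over all 60 seconds,

    Σ̂ₜ = Σᵢ ωᵢₜ xᵢ xᵢᵀ / Σᵢ ωᵢₜ,   ωᵢₜ = exp(−((i−t)/h)² / 2),

with weights renormalized over the truncated window at the epoch
boundaries (no padding). The bandwidth default is h = n^⅓ ≈ 3.91 for
n = 60 s — a standard kernel-smoothing scale for this series length; an
effectively infinite h collapses the estimator to the static second-moment
matrix, which is both a unit test and an escape hatch. Rows are centered
by the epoch mean per channel by default; `centering="none"` reproduces
the bare formula (for strict comparability) and `"kernel_mean"` centers
by the local weighted mean. The 60 per-second matrices are averaged
entrywise into one epoch covariance S.

The precision matrix is the graphical-lasso estimate
Θ̂ = argmax log det Θ − tr(SΘ) − λ‖Θ‖₁,offdiag. λ defaults to 0.1; the
per-second sample size (60) is barely above the dimension (19), so some
shrinkage is needed for stable epoch-level estimates, and 0.1 keeps the
planted networks clearly detectable while suppressing the heavy-tailed
outlier epochs that an unpenalized inverse produces. λ = 0 is supported
and returns the exact inverse (used by the estimator-oracle tests).
Solver: scikit-learn's coordinate-descent graphical lasso, with an ADMM
pass (eigendecomposition update + off-diagonal soft-thresholding, duality
gap < 1e-5) taking over on the minority of near-singular epoch
covariances where coordinate descent cycles without closing its duality
gap. Partial correlations are ρᵢⱼ = −Θᵢⱼ/√(ΘᵢᵢΘⱼⱼ), vectorized in fixed
row-major upper-triangle order (171 features; feature k always means the
same electrode pair).

## Differential network (NBS)

Per edge, a two-group GLM on the epoch-level partial correlations — the
pooled-variance two-sample t-test, two-sided p with n − 2 df; an edge
with zero pooled variance is assigned t = 0, p = 1 rather than NaN.
Suprathreshold edges (p strictly below the primary threshold, default
0.05, with 0.01 / 0.005 / 0.001 also run for robustness) induce a graph
on the 19 electrodes; connected components are found by breadth-first
search. The component statistic is *extent* (edge count), not intensity.
Family-wise error is controlled by permutation: group labels are shuffled
(default 5000 times), the edgewise stats and component search are rerun,
and each observed component gets p = (1 + #{perm max ≥ size})/(N + 1) —
the add-one convention, so p is never exactly 0 and never below
1/(N + 1). Components with FWE p < 0.05 form the selected edge set fed to
the classifier; if none is significant the pipeline falls back to the
plain suprathreshold set with a logged warning rather than aborting.

The default exchangeability unit is the epoch. Epochs within a child are
positively dependent (same brain, plus bootstrap copies), so epoch-level
permutation is anti-conservative for patient-level claims; `unit="patient"`
swaps whole patients' labels instead and is the defensible choice when
patients, not epochs, are the inferential unit. Both are exposed; the
epoch default mirrors how the epoch-level feature tables are built.

Hubs are ranked by degree (distinct neighbors) within the selected
network, ties broken by canonical channel order, reported as
"degree/19".

## Classifier

RBF-kernel soft-margin SVM on the selected edges. Features are z-scored
per edge with training-data statistics only (zero-variance columns pass
through unscaled); class weights are set from the group-size ratio
(w_c = n_other/n_c), so the minority class weighs more than 1. The
(cost, γ) grid is searched exhaustively with stratified fivefold CV
maximizing mean held-out AUC; ties prefer the smallest cost, then the
smallest γ. The library default grid is the standard powers-of-two sweep
(cost 2⁻⁵…2¹⁵, γ 2⁻¹⁵…2³); the pipeline config ships a coarser 4 × 3
grid so a complete run stays within minutes — on the planted-effect
cohorts the AUC surface is flat near the optimum and the coarse grid
loses nothing measurable.

The operating cutoff is the Youden-J maximizer computed on *out-of-fold*
discovery scores at the chosen (cost, γ). Resubstitution scores of a
near-separable SVM pile up at the ±1 margins and transfer badly to unseen
data; out-of-fold scores mimic the test-score distribution while touching
no testing-cohort data. Testing epochs are scored once with the frozen
model; sensitivity counts responders as positives. A patient is called
responder iff strictly more than half of their epochs vote responder —
an exact 28/56 tie is called nonresponder (the conservative direction,
since responder is the actionable call).

Folds can alternatively be patient-grouped (`fold_unit="patient"`), which
is the honest cross-validation unit for generalization to new children;
the epoch default reproduces the epoch-level CV design of the reference
analysis.

## Synthetic cohorts

The generator plants the structure every downstream stage must recover.
Two sparse precision matrices share a 20-edge base support
(strength 0.25) and differ exactly on a 10-edge differential set —
five-spoke stars at C3 (to P3, Pz, Cz, T3, O1) and C4 (to P4, Pz, Cz,
T4, O2) — with off-diagonal −0.4 at the default effect size. Diagonals
start at 1.5 and both matrices are boosted equally until positive
definite, preserving the planted difference exactly. Per-second latent
vectors are i.i.d. zero-mean Gaussian draws from the group covariance;
the raw trace repeats each latent value for one second and adds white
noise (sd 1.0 by default), so the 1000-sample block mean recovers the
latent value with sd 1/√1000 — the CLT check in the tests. Seizure
windows are laid out with fixed 5 s gaps filled with unit white noise.
An optional mode blends two covariances linearly across the epoch to
exercise the time-varying estimator; the default is stationary within
epochs because the per-second analysis granularity does not require more.

Study-design defaults: 15 + 8 patients, 4–20 seizures per child
(uniform), 1000 Hz, 60 s epochs, seed-deterministic throughout (a master
seed fans out to stage seeds through a stable hash, so adding a stage
never shifts another stage's stream).

What the generator does **not** emulate: EEG spectral structure (alpha/
beta rhythms), artifacts, volume conduction, non-Gaussian or temporally
autocorrelated sources, per-patient random effects (epochs within a child
are i.i.d. given the group), and any clinical covariate structure.
Passing tests therefore demonstrate the *pipeline's* correctness and the
inference's calibration under the stated model — not that real ictal EEG
carries a recoverable VNS-response signal.

Cohorts round-trip through EDF+C files (16-bit samples, annotations as
EDF+ TAL records; reading via MNE). Physical scaling is fitted per
channel, so values survive with error at most one quantization step
(range/2¹⁶ ≈ 1e-4 at unit signal scale); exact bit-level round-trips are
not possible in EDF and the tests bound the error by the actual step.

## Validation experiments and problem sizes

`vnsnet.experiments` fixes the study-scale runs used by
`scripts/acceptance.py` and the acceptance tests:

* cohort arithmetic at the full design (23 patients, 1000 Hz);
* partial-correlation vs regression-residual oracle, 100 random 4–8
  channel problems at λ = 0 (agreement to 1e-6);
* kernel-covariance vs brute-force loop (1e-12) and the h → ∞ static
  limit (1e-9);
* NBS null calibration: 200 replicate null cohorts, 30 epochs/group,
  500 permutations, features at λ = 0 — the permutation test's validity
  does not depend on the estimator, and the unpenalized path makes 200
  replicates take seconds; the achieved family-wise rate must land in
  [0.01, 0.10] around the nominal 0.05;
* planted-network recovery: 20 replicates, 100 epochs/group at the
  pipeline default λ = 0.1 (the shrinkage that the pipeline actually
  applies roughly triples the observed component size relative to the
  unpenalized features and pins every replicate at the minimal attainable
  FWE p);
* end-to-end runs at the full patient design with a 200 Hz raw rate,
  one NBS threshold and 2000 permutations (a complete run in ~1 minute),
  at planted effects 0.4 and 0.0;
* bit-reproducibility of two identically seeded small runs.

## Known limitations

* Epoch-level CV and epoch-level permutation overstate certainty at the
  patient level; patient-grouped folds and patient-unit permutation are
  implemented and are the right settings for patient-level claims.
* The bootstrap balancing duplicates epochs, further inflating epoch-level
  effective sample size.
* No nested CV: the reported mean CV AUC selects the grid point and is
  therefore optimistically biased as a generalization estimate; the
  testing-cohort metrics are the unbiased ones.
* The graphical-lasso penalty is fixed (default 0.1), not tuned per
  epoch; `select_lambda_ebic` implements extended-BIC selection over a
  log grid for study-level tuning but is deliberately not the default —
  a per-epoch λ would make features incomparable across epochs.
* Amplitude units are arbitrary and no re-referencing is performed; the
  montage is assumed already band-passed.
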