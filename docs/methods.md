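# Methods

`mbondecode` re-implements, as a tested pipeline, an analysis of
learning-induced plasticity at the postsynapses of the five *Drosophila*
mushroom-body γ-lobe output neurons (MBON-γ1pedc>α/β, γ2α′1, γ3/γ3β′1,
γ4>γ1γ2, γ5β′2a/β′2mp; abbreviated g1–g5): fluorescence-trace
quantification, paired pre/post statistics, pseudo-population SVM decoding
of CS+ vs CS− with chance-level controls and leave-one-MBON-out ablation,
and the behavioral learning-index analysis. All stages run end-to-end on a
synthetic-data generator, so every result in the test suite and in
`scripts/acceptance.py` is computed from scratch.

## Synthetic imaging experiments

Each experiment follows the factorial design of the imaging study: 3
conditioning protocols (paired odor+shock, odor only, shock only) × 5 MBON
types × 10 flies per cohort × 3 odors (MCH, 3-octanol, 1-octen-3-ol) × 2
phases (pre-/post-training), one trace per cell — 900 traces. Each fly is
imaged in a single MBON type under a single protocol, which is why the
decoder must build pseudo-populations.

**Traces.** Raw fluorescence is sampled at 4 Hz for 15 s with odor onset at
5 s, baseline level 100 a.u., and additive Gaussian frame noise (SD 2 a.u.,
i.e. ~2% ΔF/F₀). A single transient is a difference-of-exponentials kernel
(rise 0.2 s, decay 1.5 s — consistent with postsynaptically targeted
GCaMP dynamics; the exact kinetics are a free choice) normalized to unit
peak, so the configured amplitude is the peak ΔF/F₀ of the noiseless
response.

**Response structure.** Mean amplitudes per (MBON, odor) encode the
compartment heterogeneity reported for the γ lobe: γ3 responses 4–5× γ1,
MCH stronger than 3-octanol, γ2 responsive mainly to MCH, γ5 responding in
only ~17% of animals (a per-fly × odor Bernoulli responder indicator;
non-responders have amplitude 0 in both phases). A lognormal per-fly × odor
factor (log-SD 0.4) shared between phases produces the individual
variability that makes the paired pre/post design informative.

**Plasticity.** Post-training amplitude = pre-training amplitude × a
(protocol, MBON, CS-role) ratio × a lognormal session jitter (log-SD 0.25).
Default ratios: paired — γ1 CS+ 0.5 (associative suppression confined to
γ1), γ2–γ4 all odors 0.4 (generalized adaptation); odor-only — γ2–γ4 0.4
except γ4 "mock CS+" 0.7; shock-only — γ1 ×1.3 for both trained odors,
γ2–γ4 ×0.85 (weak adaptation). Magnitudes are calibration choices — the
source data report only box-plot AUC distributions — fixed once and not
revisited. The session jitter exists because, without it, both the pooled
and the per-odor shock-only tests are at ceiling power; at log-SD 0.25 the
pooled test (2 pairs/fly, n = 20) rejects in ~99% of simulated experiments
while each per-odor test at n = 10 rejects in ~50%, reproducing the
reporting pattern that motivated pooling. CS+ assignment is counterbalanced
(even-indexed flies: MCH; odd: 3-octanol), which is what puts the
pre-training decoder at chance.

## Quantification

* **F₀** — mean raw fluorescence over the 2 s preceding odor onset
  (half-open window); **ΔF/F₀** = (F − F₀)/F₀. By construction the
  baseline-window ΔF/F₀ averages to zero.
* **AUC** — trapezoidal integral of ΔF/F₀ over the 5 s after onset,
  endpoints included, in (ΔF/F₀)·s. The trapezoid rule is exact for the
  piecewise-linear signal a frame grid defines; a dense-quadrature oracle
  agrees to 1e−9. Negative AUCs (suppression) are retained. Whether the
  original analysis used trapezoid or frame sums is unknowable from the
  text; both windows and the integrator grid are parameters.
* **Normalization** — within each experimental group, interpreted as
  (MBON type × protocol) since cohorts were imaged per-MBON and
  per-protocol, every AUC for an odor is divided by the group's mean
  *pre-training* AUC for that odor. Normalized pre-training responses
  therefore average exactly 1 per stratum. A stratum with no pre-training
  AUCs, or a zero pre-training mean, is an error naming the stratum.
* **Responder call** — a recording is a responder if its peak ΔF/F₀ inside
  the 5 s window exceeds 3.5× the noise SD estimated from all pre-onset
  frames. The source figure reports "% flies responding" without a
  criterion. A peak-over-20-frames statistic is very sensitive to the
  threshold and to SD estimation error: 2 SD from an 8-frame baseline
  fires on pure noise in ~26% of windows, 3 SD in ~14%; 3.5 SD with a
  20-frame pre-onset estimate keeps the familywise false-positive rate
  near 2%, so the detected γ5 fraction tracks the simulated 17% responder
  probability. Threshold and windows are exposed parameters.

## Paired plasticity statistics

The two-sided Wilcoxon signed-rank test is implemented with the
conventions used in the reported statistics: zero differences dropped,
tied |differences| mid-ranked, z from the tie-corrected normal
approximation (sign: positive = post > pre), p exact by full enumeration
of the 2ⁿ sign assignments when the effective n ≤ 15 (doubled smaller
tail, capped at 1), normal approximation otherwise. An enumeration oracle
and scipy serve as independent cross-checks in the tests. Calibration on
the generator defaults: type-I error ~5% (≤ 10% bound) at n = 10; power ≥
80% for the γ1 CS+ suppression at ratio 0.5. Per-stratum tests are
uncorrected (as reported); a Bonferroni option exists. The pooled
shock-only test treats a fly's two trained odors as two pairs (n = 20);
a per-fly-mean alternative (n = 10) is a flag, since the original pooled n
is not stated.

## Pseudo-population decoding

Per animal and phase, the two features are the normalized AUCs of its CS+
and CS− responses. One model = (i) draw one animal per MBON type; its CS+
and CS− five-dimensional vectors form the test set, the remaining 45
samples the pool; (ii) 1000 drawings with replacement, each picking one
pool animal per type and emitting one CS+ and one CS− vector (2000
training vectors); (iii) fit an SVM and classify the two test vectors —
model accuracy 0, 50 or 100%. 100 models (each with an independent random
stream spawned from the master seed) give the mean accuracy and a
one-sample signed-rank test against the 50% chance level.

Classifier: linear kernel, C = 1, per-feature z-standardization fitted on
the training vectors and applied to the test pair (no leakage). The
original work states only "SVM" (scikit-learn); a linear kernel is the
conservative choice for a 5-D, 50-sample problem, and kernel, C and
standardization are config options (rbf available).

Controls: *pre-training* — pre-phase responses keep the labels of the
fly's later CS assignment; *odor-only* / *shock-only* — each fly's two
trained-odor responses are randomly reassigned to classes A/B. Ablation
repeats the whole procedure five times with one MBON type removed
(4-D features).

**Sampling properties measured on the generator defaults.** The per-run
mean accuracy is an average over models that all share one 50-animal
dataset — effectively a leave-one-animal-out estimate at 10 animals per
type — so it carries a dataset-level SD of ~10–13 accuracy points while
being unbiased (pure iid features: 50.5 ± 1.7 over 80 datasets).
Quantities claimed to sit at chance are therefore estimated as grand means
over independent replicate experiments; the replicate count, not the
per-run model count, sets the precision. The pre-training control sits
slightly above 50 (~+3, stable across probes): the test pair is the same
animal's two odor responses, and the odor-asymmetric amplitude/noise
structure leaves residual pair information even with counterbalanced
labels and leakage-free normalization. This mirrors the borderline
elevation of the corresponding control in the source analysis and is left
as-is. With the default γ1-confined effect the full decoder averages
~70–75%; excluding γ1 returns it to chance, while excluding any other
type does not.

## Behavior

A lane of ~30 flies splits between CS+ and CS− arms; PI = (N_CS+ −
N_CS−)/N. Two reciprocally trained lanes average into one learning index,
canceling innate odor bias; a group contributes 8 LIs (8 reciprocal
pairs). The generator draws a pair-level LI from Normal(−0.3, 0.1) —
blocked groups (γ1 and γ5 output silenced at restrictive temperature)
have mean 0 — and realizes it as integer counts. Group statistics:
one-way ANOVA + Tukey HSD, and per-group one-sample t-tests against 0 at
α = 0.05 / divisor; the divisor defaults to the number of groups but is a
parameter, since the original panels use panel-specific divisors (α
0.0083 and 0.0125). Flies that stay in the central carrier are not
modeled.

## What the generator does not emulate

Motion artifacts and their correction, bleaching, dual-channel imaging,
pixel-level structure (the optional TIFF path is tested with uniform
ROIs), trial-to-trial odor-delivery variability within a phase (one trace
per cell), biophysical indicator dynamics, and temperature kinetics of the
synaptic block (blocking is a phenomenological effect on the LI mean).
Passing tests therefore validate the analysis machinery and its
statistical calibration on data with the assumed structure — not the
biological claims themselves on real recordings.

## Numerical choices and degenerate inputs

Onset times snap to the frame grid; baseline membership is half-open at
onset; AUC integration includes both endpoints. Fluorescence is clipped
to stay positive (never triggered at default noise). A feature with zero
training variance gets unit scale in standardization. All-zero paired
differences yield a degenerate signed-rank result (z = 0, p = 1) rather
than an error; strata with < 2 complete pairs are skipped with a warning;
degenerate behavior groups are excluded with a warning. Every output file
carries the master seed and a config hash, and the full pipeline is
bit-reproducible from one seed.

## Problem sizes used in the test suite and reproduction script

Calibration suites use 200 simulated experiments restricted to the
relevant cohort (e.g. γ1/paired). Chance-level decoding checks in the
test suite use 8 replicate experiments × 100 models × 300 bootstrap
draws; `scripts/acceptance.py` uses the full 1000 draws with 50 models
per replicate and 88 (pre-training), 2 × 36 (controls) and 32 (ablation)
replicates. These sizes were chosen so the grand-mean standard error is
~1.6–1.9 accuracy points.
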