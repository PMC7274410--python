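# Methods

`crosstol` re-implements, as a tested pipeline, the computational workflow
of a multi-stress (water, heat, combined) proteome study in soybean leaf:
interaction inference from short abundance time courses, selection and
clustering of stress-responsive proteins (SRPs) from replicated 2-DE spot
densitometry, and relative quantification of transcripts and enzymes.
Because studies of this design publish figures and spot tables rather than
machine-readable densitometry, every stage is exercised on synthetic data
with planted ground truth; this note records the models, the defaults, and
the design decisions that were genuinely open.

## Pairwise power-law interaction model

Each candidate interaction is a uni-regulator restriction of the S-system
formalism of biochemical systems theory:

    dX_t/dt = α · X_r(t)^g − β · X_t^h

where `X_t` is the target's abundance, `X_r(t)` the regulator's observed
profile (piecewise-linear between sampled points — the simplest defensible
reconstruction for 4–8-point courses), `α, β ≥ 0` are production and
degradation rate constants (abundance·day⁻¹ at `g = 0`), `g ∈ [−3, 3]` is
the regulator kinetic exponent, and `h ∈ [0, 3]` the self-degradation
exponent, fixed at 1 by default (first-order decay). The full
multi-regulator S-system is out of scope: with one regulator per equation,
the sign of `g` is the only parameter with a direct regulatory reading,
and it defines the promotive (`g > 0`) / inhibitive (`g < 0`) labels.

Numerical choices: integration uses an adaptive stiff-capable solver
(LSODA) at rtol 1e-8 / atol 1e-10 for simulation — tight enough that the
closed-form checks at rtol 1e-6 retain two orders of headroom — and
rtol 1e-6 / atol 1e-8 inside fitting loops, where optimizer tolerance
dominates. Abundances are floored at 1e-6 of the profile maximum before
exponentiation so non-integer powers stay real; simulated output is
clipped at the same floor.

## Fitting and edge retention

For every ordered pair the free parameters (`α, β, g`; `h` optionally
freed) are estimated by bounded trust-region least squares against the
observed target profile, with the target's first observed value as the
fixed initial condition (one fewer free parameter). Both profiles are
divided by their own time-course mean before fitting — the model is not
scale-invariant, abundances are in arbitrary densitometric units, and R²
is unchanged by this; fitted `α` and `β` are mapped back to the raw scale
afterwards (`α → α·m_t/m_r^g`, `β → β·m_t^{1−h}`).

Twelve deterministic starts per pair (six `g` values `±0.5, ±1, ±2`, two
rate scales derived from the target's mean level and mean absolute slope)
guard against local minima; the sweep short-circuits once a start explains
99.99% of the variance. A pair is retained as an interaction when the fit
converged, R² strictly exceeds the threshold (default 0.9), and
`|g| > 0.05`. The last filter matters more than it looks: a fit with
`g ≈ 0` reduces to regulator-free relaxation, which reproduces any
monotone profile perfectly, so near-zero exponents carry no evidence of
interaction and are labelled `none`.

Two identifiability guards keep the R² threshold meaningful on short
courses: `h` is fixed at 1 by default, and inference refuses to run when
the number of free parameters reaches `len(times) − 1` (with 4 points and
4 free parameters every pair fits perfectly and the threshold is vacuous).

Open points resolved here as configuration: whether the original analysis
thresholded R or R², and whether it fit 3 or 4 free parameters, cannot be
recovered from the published text; both are exposed (`r2_threshold`,
`fix_h`) with the defaults above.

## SRP selection and expression clusters

A spot is stress-responsive when (a) a one-way ANOVA of its replicate
densities across the four conditions (C, WS, HS, WS+HS) gives p < 0.05,
and (b) at least one stress shows a fold change versus the control mean of
≥ 1.5 or ≤ 1/1.5. Both thresholds are inclusive (the published wording
"at least >1.5-fold" is self-contradictory; the inclusive reading is
adopted and config-exposed), and the down threshold is the log-scale
mirror 1/1.5 ≈ 0.667. No multiple-testing correction is applied by
default, matching the raw-p design of the source workflow; a
Benjamini–Hochberg option exists. ANOVA runs across the four conditions
jointly; two-way condition × cultivar designs are out of scope. Spots
missing control replicates are skipped with a log entry rather than
imputed, and a constant spot (zero variance everywhere) is reported as
non-responsive rather than an error.

Directions (up / down / unchanged per stress) map to four expression
classes: I (≥1 up, no down), II (≥1 down, no up), III (all unchanged),
IV (both present). Assignment runs per cultivar. Display ordering uses
agglomerative centroid-linkage clustering (Euclidean distance between
cluster centroids) of the spot × condition fold-change matrix.

## Transcript and enzyme quantification

Relative transcript abundance is 2^−ΔΔCt with actin as reference and the
untreated control as calibrator; ΔCt is averaged per group over
replicates (per-replicate pairing between sample and calibrator is not
defined for independent biological replicates). Significance uses the
classical pooled-variance two-sample t-test — deliberately not Welch, to
match the named test. Enzyme responses are fold change over control, with
a not-detected sentinel (`ND`) producing a flagged zero-fold record (as
for glutathione reductase under combined stress). Transcript–protein
concordance reuses the 1.5-fold neutral band: both folds outside on the
same side → concordant, opposite sides → discordant, exactly one inside →
uncoupled, both inside → concordant (agreement on no change).

## Synthetic data: what it emulates and what it does not

The generators are pure functions of (seed, config); the same seed
regenerates bit-identical data, and ground truth is serialized as a JSON
sidecar.

**Interaction benchmark.** `generate_network` samples a sparse directed
acyclic network (edges respect a random topological order, so the coupled
system always integrates sources-first; cyclic inputs are rejected), with
kinetics drawn from documented ranges (α, β ∈ [0.2, 2], |g| ∈ [0.5, 2],
h = 1) and identities/categories from the packaged 39-spot catalog.
Source nodes follow exogenous stress transients — a gamma-shaped pulse on
a baseline, `a·(1 + m·(t/τ)²·e^{2(1−t/τ)})`, baseline 0.8–1.5, amplitude
0.8–2.5, peak 4–16 days, 30% inverted (transient depletion). Transients,
not monotone ramps, are the deliberate choice here, for two reasons: they
are the canonical acclimation kinetics (induction followed by relaxation),
and they are what gives the R² filter discriminating power — a monotone
profile can be reproduced by regulator-free relaxation from almost any
smooth input, whereas a timed pulse can only be tracked by the regulator
that actually drives it. Targets with several regulators sum their
power-law production terms (generalized-mass-action form) and use the
mean β; at in-degree one this is exactly the pairwise model, so noiseless
single-edge refits are exact. Noise is multiplicative log-normal,
mean-preserving, with CV 0.02 by default. The default grid is 8 points
over 21 days — denser than a weekly 4-point course so that the
3-parameter fit retains residual degrees of freedom; a 4-point grid
triggers the identifiability guard.

**Spot tables.** 50 spots × 4 conditions × 3 replicates, log-normal
replicate scatter at CV 0.1; 10 planted spots receive one direction (up or
down) applied to a random nonempty subset of stresses with fold effects in
[1.8, 3] — beyond the 1.5 threshold so recovery failures indicate
pipeline defects, not borderline draws.

**Ct tables.** 9 transcripts × 4 treatments × 5 biological replicates;
reference Ct has constant mean 20 across treatments; planted ΔΔCt shifts
default to uniform [−2, 2]; Gaussian Ct noise, sd 0.15 cycles. With the
noise at zero the 2^−ΔΔCt estimate equals the plant exactly.

What passing these tests does **not** show about real data: the generator
plants the very model family the fitter assumes (no model mismatch), uses
a shared exact time grid (no missing gels or misaligned sampling), and
its noise is homoscedastic on the log scale (real densitometry has
spot-detection artefacts and saturation). Planted-truth recovery is
therefore a correctness check of the implementation, not a validity claim
for S-system inference on 2-DE data. In particular, false-positive edge
counts on the benchmark are substantial at R² > 0.9 — with 8 time points
and 3 free parameters, many spurious pairs fit well — which is why the
benchmark asserts recall and rank separation (median true-edge R² above
median non-edge R²), not precision.

## Problem sizes

The standing benchmark is 10 nodes / 12 edges / 8 time points / 2% noise
(one all-pairs sweep of 90 fits), the SRP benchmark 50 spots with 10
planted effects, and the demo pipeline 6 proteins / 5 edges — sizes chosen
so a full run of the suite and the acceptance script each complete in
minutes on a single core while still exercising every code path.

## Known limitations

- Only the uni-regulator pairwise model is fit; multi-regulator targets in
  the generator are approximated edge-by-edge, which is the main source of
  missed true edges on the benchmark.
- Reverse edges (fitting the driver from its lagged responder) and
  cascade shortcuts (grandparent→grandchild) can score above 0.9 and are
  not disambiguated; the method ranks, it does not orient.
- The ANOVA is one-way across conditions; cultivar enters only by running
  tables independently per cultivar.
- Amplification-efficiency correction for qPCR is out of scope; the plain
  2^−ΔΔCt formula assumes doubling per cycle.
- Spots absent in one condition raise an error rather than being imputed;
  fold change against zero is undefined by design.
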