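# Methods

This note records the models the package implements, the choices made
where the design was genuinely open, the synthetic data the tests run on,
and what the passing (and failing) properties do and do not show.

## Interval-valued Pythagorean fuzzy numbers

A PFN carries a membership degree μ and a non-membership degree ν with
μ² + ν² ≤ 1; the residual π = √(1 − μ² − ν²) is the hesitancy. The
interval-valued variant replaces each degree by an interval; we enforce the
Pythagorean constraint at the upper bounds, which makes it hold over the
whole interval box. π is computed as √(max(0, 1 − μ² − ν²)) to absorb
floating-point negatives (tolerance 1e−12 in all constraint checks).

**Centroid.** The ratio-of-integrals centroid is evaluated with a uniform
density over each interval — the only density the interval representation
supports without extra assumptions — giving the interval midpoints.

**Crisp–fuzzy distance.** Two algebraic readings of the distance between a
crisp value α and a PFN β are plausible: √((c_μ−α)²/2 + c_ν²) and
√(((c_μ−α)² + c_ν²)/2). Both are implemented (`variant="half_mu"` /
`"half_both"`); the first is the default. They coincide whenever c_ν = 0
and at every reference case used in the tests. Vector versions aggregate
per-coordinate distances root-mean-square, keeping values scale-free in
the dimension.

**Fuzzy–fuzzy distance.** Evaluated at centroids, the distance is
Euclidean in (μ², ν², π²)-space scaled by 1/√2 — this makes it a true
metric with range [0, 1], and is the fact behind the exact FCM-equivalence
oracle used in the clustering tests.

**Operational laws.** The algebraic sum
(μ = √(μ₁²+μ₂²−μ₁²μ₂²), ν = ν₁ν₂) and the scalar law
(μ = √(1−(1−μ²)^λ), ν = ν^λ) are applied bound-wise to intervals; both are
closed under the Pythagorean constraint and monotone, so bound ordering is
preserved.

**Activation.** The exponential activation applies s(t) = exp(t−1) to the
membership bounds (fixed point at 1, image [1/e, 1]) and the dual map
t ↦ 1 − exp(−t) to the non-membership bounds, followed by projection onto
the constraint. The exact exponential operational law this stands in for
is not uniquely fixed in the literature the model family cites; the
projection step makes any monotone choice safe. A consequence worth
knowing: the centroid membership of any activated output is at least
1/e ≈ 0.368, so reconstructions cannot track targets below that level —
see *Limitations*.

**Fuzzification.** Crisp features x ∈ [0, 1] enter fuzzy computations as
degenerate-interval PFNs (μ = x, ν = 1 − x), which are always valid since
(μ + ν)² = 1.

## Water Wave Optimization

WWO is the derivative-free trainer used everywhere. Defaults follow the
original formulation: population 8, h_max = 6, wavelength base α = 1.0026,
initial wavelength 0.5, breaking coefficient annealed 0.25 → 0.001 over
the budget, up to min(12, D/2) solitary waves each perturbing a single
dimension. Two details matter for minimisation: the wavelength-update
exponent is −(f_max − f + ε)/(f_max − f_min + ε) so the *best* wave takes
the shortest steps, and a refraction that improves the wave *shortens* its
wavelength by the cost ratio f_new/f_old. Out-of-range coordinates are
re-drawn uniformly (avoids boundary pile-up). All randomness flows through
one injected generator; an optional patience criterion stops a run when
the best value improves by less than 1e−6 over a window.

On the 10-D sphere with a 20,000-evaluation budget the median best over 20
seeds is ≈ 1e−11, versus ≈ 1e−1 for uniform random search.

## Fuzzy denoising autoencoders

A layer computes yᵢ = s(⊕_d x_d ⊙ W_id ⊕ bᵢ) with PFN weights; the decoder
reuses the transposed weights on the defuzzified (centroid-membership)
hidden vector, so every layer's input is again a crisp vector in [0, 1].
Because both laws are products in log(1−μ²) / log(ν) space, a layer
forward pass is four matrix multiplications. Corruption is classic masking
noise (each coordinate zeroed independently, default level 0.2); the
training objective is the mean squared crisp-vs-fuzzy reconstruction error
of the clean data from corrupted copies (three fixed corrupted replicates
approximate the corruption expectation while keeping the objective
deterministic within a run).

**Genome.** WWO searches a unit box; genes map to PFNs that are valid by
construction. Weight-matrix genes are tempered by the layer fan-in —
log(1−μ²) and log(ν) scale as 1/D_in — so that the product over D inputs
stays in the responsive range. Without this, uniform genes at D = 80 give
log-sums near −11: every unit saturates at μ = 1 and the codes carry no
input information at all. Biases enter each product once and are not
tempered.

**Stacking.** Greedy layer-wise pretraining with the budget split equally
across layers; defuzzified codes feed the next layer. Published widths:
common 80/46/26, group 26/15/9, individual 9/6/7, control 75/49/35/32.

## Pythagorean fuzzy c-means

The classical FCM alternating scheme with the PFN vector distance:
memberships u_ij = 1/Σ_k (d_ij/d_kj)^{2/(m−1)} (full membership split
equally among zero-distance clusters), centroids as membership-weighted
means in squared-degree space — the Fréchet mean under the chosen metric —
emitted as degenerate-interval PFNs. Defaults c = 5, m = 2, tolerance
1e−5 on the membership change, iteration cap 200, membership floor
u_L = 0.1. On data fuzzified from crisp features the algorithm is *exactly*
the crisp FCM run in (μ², ν², π²)/√2 coordinates, which the tests verify to
1e−7 against an independent 30-line FCM.

Initial centroids are either random data points or a WWO search over
flattened centroid coordinates, each candidate scored by the objective
after a short (3-iteration) refinement.

## Behavior Learner

Inputs per 200 ms step: 32 stimulus variables (4 lamps × intensity,
duration, 3 pattern velocities, 3 pattern distances), 34 ambient variables
(temperature, humidity, pressure, O₂, CO₂, two wind speeds, and
duration/intensity/illuminance of nine wavelength bands), the 7 previous
flight parameters and 7 parameters accumulated over the previous three
steps — 80 in total, min-max normalised by declared ranges. Wind above
1.5 m/s is rejected (an uncontrollable regime, not a data error). The
accumulation is an exponentially weighted mean with decay 0.5 over up to
three steps (weights (4, 2, 1)/7), a fixed stand-in for a learned memory
model that preserves the 14-variable interface.

Grouping profiles concatenate three shape descriptors (wing span, body
length, mass) with the topmost-common codes of the moth's mean responses
to a fixed grid of 3 ambient × 12 stimulus probe settings. Shape columns
are min-max normalised individually; the code block is rescaled by one
shared factor (per-column scaling would amplify noise-only columns and
dilute the signal).

Group stacks train on the common codes of the records of moths whose
membership clears u_L, with each record's squared reconstruction error
weighted by the membership degree. Individual-learner inputs are the
membership-weighted mixture Σᵢ u_ij y′(i) over the groups above the floor
(unrenormalised by default; a flag renormalises). Representations are
min-max rescaled to [0, 1] at each hierarchy boundary: every sub-learner's
affine map assumes inputs spanning [0, 1], and without rescaling the
cascade attenuates until the model degenerates to a per-moth mean
predictor.

The per-moth regression head is ordinary least squares per output
dimension (ridge 1e−6 fallback for rank-deficient designs) on the
defuzzified topmost individual code. The importance weights
(0.24, 0.2, 0.2, 0.15, 0.07, 0.07, 0.07) do not affect the per-dimension
fits — the loss decouples — but define the reported error and all model
comparisons.

**Monolithic comparator.** "Equal total parameter count" does not pin down
an architecture, so the comparison experiment holds depth *and* parameters
equal: the hierarchy's path 80/46/26/15/9/6/7 with hidden widths scaled
×1.32 (→ 80/61/34/20/12/8/7) matches the full hierarchy's PFN parameter
count within 1%, gets the same total WWO budget, and carries one shared
regression head.

## Control Learner

Input: required flight parameters (7), ambient (34), previous and
accumulated parameters (7 + 7) and the c-dim group-membership vector —
55 + c values. The stack uses the published hidden widths 49/35/32 (the
published 75-unit input layer is kept as the config default; the estimator
adapts the input width to 55 + c). A linear head on the topmost code emits
the 32 stimulus variables, clipped to [0, 1].

Training: unsupervised pretraining of the stack, then a distal-inverse
warm start — random stimuli from the controllable band are labelled with
the behavior they produce and the stimulus is regressed on the code of the
context-plus-produced-behavior input — followed by WWO fine-tuning of the
head on the closed-loop mixed loss
(Σ_{T_p} ‖req, phys(o_c)‖ + w_m Σ_{T_m} ‖req, model(o_c)‖)/|T_c| with
‖·‖ the RMS deviation over the 7 normalised parameters and
w_m = 1 − Σⱼ J_R(j)/|T_m| clipped to [0, 1]. The physical/model split
defaults to 1:9 (physical trials are expensive) and is configurable.

Success rate: an instruction succeeds when every *relevant* parameter of
the produced response deviates from the requirement by less than 15% of
the normalised full scale (a flag switches to deviation relative to the
expected value). Instructions are maneuver commands; only the parameters a
maneuver sets (horizontal pair / vertical pair / accelerations / all
seven) are relevant.

## Synthetic data

The generator emulates what the learners assume about real flight
records: per-group response matrices A_g = A₀ + separation·B_g (Gaussian
entries, scale 1.6/√80) acting on centred normalised features through a
logistic of slope 2; the horizontal-deflection row carries only the
left-minus-right lamp terms, so symmetric stimulation gives exactly 0.5;
individual offsets N(0, 0.05) per parameter; observation noise
N(0, 0.05); ambient drawn around mid-range with slow within-session drift
and re-drawn at each 50-step recording session; stimuli drawn freshly per
step. At the default separation the mean between-group response contrast
exceeds 3σ_obs (the identifiability margin); at separation 0 grouping is
unrecoverable by construction — the tests check both sides. The default
cohort of 36 moths × 304 records echoes the scale of the corpus the method
family was developed on; studies here use 12 moths × 300 records.

Control instructions draw stimuli from the band [0.3, 0.7] — the regime
where the logistic response is away from saturation, making the
stimulus→behavior map smooth and injective on the instruction set — and
record the noise-free response as the requirement, so every requirement is
achievable. Instruction contexts are simulated mid-flight states, which
carry (noisily) the moth's individual offset.

What the generator does *not* model: aerodynamics, temporal stimulus
aftereffects beyond the 14 history variables, heteroscedastic or
state-dependent noise, sensor drift, unbalanced group sizes. Passing
properties show the machinery works when its assumptions hold; they do not
establish performance on real moths.

## Study problem sizes

All studies run on one core in minutes: metric/closure checks use 10,000
random PFNs; the WWO benchmark 20 seeds × 20,000 evaluations; clustering
equivalence 20 instances of n = 20; the pretraining/denoising studies
single layers and (12, 6, 4) stacks at budgets 1,500–2,000; the hierarchy
study 20 paired replicates of a 12-moth/3-group/300-record cohort with
budgets 160/80/48 per sub-learner (WWO objectives evaluate on fixed
256-row subsamples); the control study 1,000 training and 200 held-out
instructions with budgets 300/1,000. The published budget of 100,000
evaluations is the config default for full-scale runs.

## Limitations

* **Reconstruction is bias-dominated.** With centroid defuzzification
  between layers, transposed shared weights and the monotone operational
  laws, near-optimal reconstructors are close to constant maps: direct
  optimisation of structured solutions beats the best constant
  reconstructor by only ~10–15% even on strongly correlated data, and the
  activation floor at 1/e bounds what the membership channel can track.
  Pretraining therefore reliably beats *random* parameters (ratio ≈ 0.4)
  but converges toward corruption-invariant solutions.
* **The denoising advantage does not materialise.** Because near-optimal
  reconstructors barely depend on the input, masking corruption is almost
  invisible to them, and a stack pretrained with noise beats a noise-free
  twin only at chance level (11/20 paired replicates in the shipped
  study). This is a structural property of the declared operational-law
  stand-ins, not a tuning issue — larger budgets make both stacks *more*
  constant and the gap smaller. The corresponding acceptance property is
  left failing rather than weakened.
* **Prediction quality flows through the heads.** The fuzzy codes carry
  input information as near-linear features; the supervised linear heads
  (per-moth, and the control head) do most of the predictive work, and the
  hierarchy's measured advantage over the matched monolith comes from
  grouping and per-moth heads, not from better reconstruction.
* **Group recovery is not perfect on every cohort.** On ~5–10% of random
  cohorts the encoder blurs one group boundary in the profile space (ARI
  ≈ 0.7 instead of 1.0) even though the raw probe responses separate
  perfectly; the 20-replicate mean stays ≥ 0.9.
* The closed-loop success rate is reported against the deterministic
  ground-truth dynamics (the mean response surface); against the noisy
  responder it drops by ≈ 0.1, and with the default 1:9 physical/model
  split by a further few points — both variants are computed and reported
  alongside the primary number.
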