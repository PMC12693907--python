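# Methods

This note documents the models, the synthetic study generator, the
numerical choices, and the limits of what the test suite demonstrates.

## The prediction chain

The package couples three learned stages into one forecast path:
greenhouse microclimate → fruit surface color → internal/external quality.
The premise is physiological: tomato ripening is driven by cumulative
light–temperature exposure, surface color integrates that history
(chlorophyll loss, carotenoid gain), and several quality traits — lycopene
above all — co-evolve with color. Each stage is usable on its own; the
integrated rollout chains them recursively.

### Environment stage

One single-output forecaster per variable (temperature °C, humidity %RH,
radiation W/m²), each consuming all three min–max-scaled features in
24-step sliding windows (stride 1, horizon 1). Hidden stacks are tuned per
variable: temperature 3 LSTM layers × 100 units, humidity 1 × 160,
radiation 2 × 64. Gates act on the concatenation [H_{t−1}, X_t]; the final
hidden state maps through a dense layer to one scalar. Training: Adam,
learning rate 10⁻³, batch 32, MSE, 150 epochs by default; weights are
initialized uniformly in ±1/√fan-in from a seeded generator, so identical
seeds give bitwise-identical loss histories. Multi-step forecasts are
recursive: each one-step prediction is appended to the window and fed back.

### Color stage

Surface color is observed once per day (one photo per fruit), so this
stage lives on the **daily grid**: windows are T = 24 *days* of six
features — daily-mean scaled environment plus the day's red/yellow/green
surface fractions — and the target is the next day's fractions. An hourly
next-step formulation was rejected: hour-to-hour fraction changes are
≈ 10⁻³, the one-step map degenerates toward the identity, and the
teacher-forcing bias compounds over the ~900 recursive steps an integrated
forecast needs, visibly corrupting the trajectory. On the daily grid a
forecast season is ~20 recursive steps and the rollout stays locked to the
true kinetics.

The encoder is a single GRU layer (64 units by default; the layer count
and width are free parameters here). Attention uses unscaled dot-product
scores between per-state key projections and the query — the projection of
the final hidden state, the standard choice for sequence regression when
only per-element projections are specified. The context vector passes
through a ReLU dense layer and a 3-output linear head. Because the targets
are surface fractions, raw outputs are clipped to [0, 1] and renormalized
to sum 1 (uniform if all three clip to zero). Training: Adam 10⁻³, batch
64, MSE over the three outputs, 150 epochs by default.

### Quality stage

A five-layer fully connected network 1 → 256 → 128 → 64 → 6 with ReLU
hidden activations, linear outputs, and dropout 0.4 after each hidden
layer during training only. The single input is a_n = (a* + 128)/255, the
normalized mean CIELAB a\* over the fruit mask. Targets are standardized
per trait (they span four orders of magnitude across units); predictions
are de-standardized and clamped at zero, since all six traits are physical
quantities. The multi-task loss is Σ λ_k·MSE_k with λ_k ∝ M_k^γ (γ = 0.5,
exposed), M_k an exponential moving average (smoothing 0.8) of task k's
epoch MSE, renormalized to Σλ = 6 — harder tasks are upweighted, equal
errors give unit weights. Training: Adam 10⁻³, batch 16, 100 epochs by
default. An optional step decay (`lr_decay`, `lr_decay_at`) multiplies the
learning rate once late in training; recovery experiments use ×0.1 at 70 %
because dropout keeps gradient variance high and the undecayed
stochastic floor dominates the residual error on noiseless data.

### Integrated inference

At forecast time no future image exists, so the quality network's input
must be derived from the *predicted* fractions. The bridge is a calibrated
monotone map (isotonic regression) from red fraction to image-derived a_n,
fitted on training-plant observations and clipped outside the observed
range. The full chain per forecast day: hourly environment rollout →
daily means → color recursion → maturity grade from red coverage →
red→a_n proxy → six traits.

## Image pipeline

- **White balance** (gray-world): gains s_c = ā_gray/ā_c equalize channel
  means exactly before quantization; output is rounded half-to-even and
  clipped to 8 bits. Balancing a balanced image is the identity up to
  clipping.
- **a\***: sRGB inverse companding (threshold 0.04045, divisor 12.92,
  exponent 2.4), the D65 RGB→XYZ matrix, CIE f(t) with δ = 6/29, and the
  matrix row sums as the reference white — this keeps the achromatic axis
  at exactly a\* = 0 and matches reference colorimetry (pure sRGB red →
  a\* ≈ 80.1). Fruit-level a\* is the arithmetic mean over the mask.
- **Surface fractions**: masked pixels are classified by HSV hue — red
  [0°, 25°) ∪ [330°, 360°), yellow [25°, 70°), green [70°, 170°) — with
  pixels below saturation 0.15 left unclassified; the unclassified share
  is redistributed proportionally so fractions sum to 1. The bands are
  deliberately wide horticultural conventions, not fitted constants.
- **Maturity grade** from red coverage r (and yellow y): level 1 if
  r + y < 0.01, else 2 if r < 0.10, 3 if r < 0.40, 4 if r < 0.70, else 5.
  The published grade table leaves 30–40 % and 60–70 % unassigned;
  half-open contiguous bins make the grading total and monotone.
- **Masks**: LabelMe-style polygon JSON, rasterized boundary-inclusively
  (a pixel belongs to the fruit if the polygon covers its center), with
  multiple polygons unioned and zero-area polygons rejected.

## Sensor preprocessing

Box-plot screening uses sorted-order linear-interpolation quartiles (the
common default; documented so the brute-force oracle in the tests matches).
Flagged outliers become missing. Gap filling distinguishes run length:
runs of ≤ 5 consecutive missing points interpolate linearly between the
bracketing valid points; longer runs (and edge runs without a bracket)
copy, time-of-day aligned, from the nearest prior day whose daily mean of
the same variable lies within one standard deviation of daily means (ties
to the most recent day; fallback to the most recent complete day when the
gap day has no observed points). Min–max scaling is fitted on the training
split only and never clips, preserving invertibility. The plant-wise 7:2:1
split orders plants by first record, reserves the latest ~10 % as the test
set, and drops train/validation records at or after the earliest
test-plant record so every test record strictly postdates the training
period.

## Synthetic study generator

The generator emulates a spring greenhouse campaign: `n_plants = 80`
fruits monitored hourly over 45-day ripening windows with starts staggered
across 20 days. Temperature is a sinusoid peaking at 15:00 (22 ± 6 °C)
with AR(1) noise (φ = 0.7, σ = 0.8 °C); humidity is anti-phase
(65 ± 15 %RH, σ = 3); radiation is a half-sine over a 14-h day peaking at
800 W/m², zero at night, with truncated noise. Missingness is injected in
runs (rate 3 %, runs up to 8 points) so both gap-filling branches are
exercised.

Color kinetics follow thermal time: GDD(t) = Σ max(T − 10 °C, 0)·Δt/24;
the red fraction is logistic in GDD (midpoint 300 °C·d ≈ day 25 at these
temperatures, steepness 0.025 per °C·d), yellow is a transient Gaussian
bump around the midpoint (amplitude 0.25, width 80 °C·d, capped so
red + yellow ≤ 1), green is the remainder. Plants carry ±10 % lognormal-ish
jitter on midpoint and steepness. Fruits are rendered as discs with
angular sectors proportional to the fractions (hue jitter ±4°), and a_n is
*measured from the rendered images* through the package's own color path —
daily, then interpolated hourly — so the image pipeline is part of every
end-to-end run, not an analytic shortcut.

Traits respond to a_n through smooth curves with tomato-typical ranges:
LYC 0.004→0.095 mg/g, SSC 4→6.2 °Brix and SS 14→30 mg/g rising
logistically; FI 6.5→2 kg/cm² and TA 0.65→0.32 % falling; VC a concave
rise-then-fall peaking at 0.26 mg/g mid-ripening; plus per-trait Gaussian
noise (σ ≈ 4–6 % of range, scaled by `trait_noise_scale`) and clamping at
zero.

**What the generator does not emulate:** occlusion, specular highlights
and illumination drift in real images; sensor drift and correlated
multi-day weather; cultivar differences; the weak, multi-pathway coupling
of TA and VC to color that real data show. Passing recovery tests
therefore demonstrate that the implementation can learn the relationships
it is pointed at — not that real-greenhouse accuracy would match.

## Numerical core

All networks run on a small reverse-mode autodiff engine over float64
NumPy arrays (`tomaqual.nn`): broadcast-aware elementwise ops, matmul,
sigmoid/tanh/ReLU, a softmax primitive with its exact Jacobian–vector
product, concatenation and slicing, with iterative topological backward
(sequence graphs exceed Python's recursion limit). Adam uses the standard
β = (0.9, 0.999), ε = 10⁻⁸. Gradients are validated against central
finite differences; every cell's forward pass is validated against
independent scalar (loop-and-sum) oracles to 10⁻¹⁰. Checkpoints are JSON
(config + weight lists), portable across the package's estimators.

## Desk-scale protocol

Tests and the acceptance script run a reduced but structurally identical
study: 12 plants, 40-day windows, all noise sources at zero. Environment
models train 12 epochs (the noiseless diurnal signal converges almost
immediately at the full per-variable architectures), the color model 120
epochs, and the quality network 300 epochs with the ×0.1 step decay —
i.e. to convergence, since the recovery question is representational, not
a statement about the production schedule. Production defaults (150/150/
100 epochs) are unchanged in the estimator signatures.

## Known limitations

- The red→a_n proxy collapses three predicted fractions to one scalar; a
  fruit with unusual yellow transients maps imperfectly.
- Recursive rollouts inherit one-step bias; the daily grid bounds but does
  not eliminate this.
- R² is undefined on constant targets and is reported as an error in that
  case rather than silently coerced.
- The grading bins resolve the published table's unassigned ranges
  (30–40 %, 60–70 % red) by continuity; fruits in those ranges receive the
  lower adjacent grade.
- Naive local timestamps only; no timezone arithmetic.
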