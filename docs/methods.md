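# Methods

## Scope and data model

`mixcal` implements a complete multivariate UV/Vis calibration study for a
ternary antidiabetic mixture — pioglitazone (PIO, 24–36 µg/mL), alogliptin
(ALG, 20–30 µg/mL) and glimepiride (GLM, 3.2–4.8 µg/mL) — on a 200–400 nm
grid at 0.5 nm (401 points). No measured spectra for this system are
publicly deposited, so the package pairs the calibration machinery with a
synthetic-spectra generator that reproduces the *statistical regime* of the
measured system: severe ALG/PIO overlap, a minor GLM component with no
clean channel, and controllable departures from Beer–Lambert linearity.
Everything downstream (preprocessing, PLS, boosted trees, SVR, ANN,
metrics) operates on that data exactly as it would on instrument CSVs, and
the CSV readers accept real data in the same wide format.

## Calibration design

The calibration set is a 5-level, 3-factor, 25-run multilevel design built
from a single 24-element cyclic generator over codes {−2…+2}: run 1 is the
all-centre run and factor *f* reads the generator advanced by *f − 1*
positions for runs 2–25. The construction gives exactly orthogonal coded
columns and 5 occurrences of every level per factor, verified by direct
computation in the tests. The generator ships as a constant (decoded from
the packaged design table) rather than being re-derived from a
difference-vector recipe; the balance/orthogonality invariants validate it
either way, and shipping it guarantees cell-exact agreement with the
packaged fixture under the affine mapping `c = center + step·code` with
PIO (30, 3), ALG (25, 2.5), GLM (4.0, 0.4) µg/mL.

The packaged 43-row fixture adds 6 replicate stability runs (St, all at
27.0/22.5/4.4 µg/mL — deliberately off-centre, preserved verbatim) used
only as a replicate precision check, and 12 test mixtures (T). Two test
rows (T7, T8) carry GLM = 3.06 µg/mL, slightly below the 3.2 µg/mL
calibration minimum; `design_diagnostics` flags them as outside the
calibration bounding box, and evaluation keeps them (mild extrapolation is
realistic for external test sets).

## Synthetic spectra

Pure components are sums of Gaussian bands (center, width, peak
absorptivity per µg/mL). The default library places strong, nearly
coincident ALG/PIO bands in 235–285 nm **plus broad low-absorptivity tails
persisting past 300 nm**, and gives GLM a weak 235 nm band with a broad
330 nm band. The tails matter: narrow Gaussians alone would hand GLM a
private, quasi-orthogonal window above 300 nm, making the minor component
artificially easy — real UV bands decay far more slowly. With the default
library GLM carries ≈ 3 % of total absorbance at the design centre, and
every analyte must be resolved against interferents everywhere.

Distortions are applied per sample in a fixed order:

1. saturation `A → A/(1 + kA)` — a simple, monotone, bounded law standing
   in for detector/stray-light saturation (no functional form is available
   for the measured system);
2. multiplicative slope `N(1, σ²_slope)` and additive offset
   `N(0, σ²_offset)` (scatter);
3. a linear baseline ramp with full-span amplitude `N(0, σ²_drift)`;
4. i.i.d. Gaussian noise per wavelength.

Every draw comes from a counter-based substream `default_rng([seed, i])`
for sample *i*, so datasets are bit-reproducible and adding/removing
samples never perturbs other samples' draws.

Two named study conditions are used throughout the tests and experiments,
chosen once: a **mild regime** (noise 0.002 AU, no saturation) representing
a well-behaved instrument, and a **severe regime**
(`severe_distortion`: saturation_k = 2, noise 0.005 AU) in which the strong
bands sit at `kA ≈ 2–4`, deep in the bounded-saturation region, with
ordinary photometric noise.

What the generator does *not* emulate: instrument line-shape and
wavelength-registration errors, temperature/solvent effects, stray-light
floors, true molar absorptivities, inter-day variability, or dosage-form
excipient (matrix) backgrounds. Passing tests therefore demonstrate the
correctness and behaviour of the algorithms under the stated statistical
regime, not assay performance on any real formulation.

## Preprocessing

Band selection keeps inclusive intervals on the grid — 230.5–245 nm +
260–300 nm for ALG/PIO (111 points) and 230.5–245 nm + 300.5–380 nm for
GLM (190 points); inclusive endpoints are required to reproduce those
column counts. All transforms are fitted on calibration rows only and
carried in a serialisable `PreprocessorState`:

- **MC/AS** — column centring, optionally scaling by the n−1 SD (AS
  refuses zero-variance columns, naming the wavelength);
- **SNV** — row-wise standardisation (n−1), stateless;
- **MSC** — OLS regression of each spectrum on the calibration mean,
  `x ≈ a·ref + b`, corrected as `(x − b)/a`. The exact invariant is
  `MSC(a·x + b) = MSC(x)`: per-sample affine scatter is removed completely;
- **OSC** — per component, the first principal-component score of the
  centred X is iteratively orthogonalised against y and mapped back
  through the least-norm weight `w = X⁺t` (rank cutoff 1e−10, relative
  score tolerance 1e−6, max 100 iterations) until a fixed point; after
  convergence the score is re-orthogonalised exactly once and the rank-one
  component `t pᵀ` removed. For full-rank centred calibration matrices the
  removed score is orthogonal to y to machine precision. If X carries no
  y-orthogonal variation (X = y·sᵀ), fitting stops instead of deflating a
  degenerate component. Default 1 component — the conventional choice when
  no count is known for the target system.

Chains (`fit_chain`/`apply_chain`) insert MC automatically before OSC.

## Models

**PLS (SIMPLS).** PLS1 per analyte, intercept via centring. Cross-
validation is leave-one-out — deterministic and standard at n = 25 — and
the LV count is the fewest-components rule: smallest h with
`PRESS(h) ≤ F₁₋α(n,n) · min PRESS`, α = 0.25 by default, max 10 LVs.
Correctness is pinned by a NIPALS PLS1 oracle (prediction equivalence at
every truncation level) and a univariate OLS identity.

**Gradient-boosted trees.** Authored in full: squared loss (hessian 1),
exact greedy split search over midpoints of consecutive distinct values,
gain with L2 leaf penalty λ (default 1) and split penalty γ (default 0),
`min_child_weight` interpreted as minimum leaf sample count (default 1),
shrinkage η, depth cap, `base_score = mean(y)`. Ties break toward the
lowest feature index then lowest threshold, making fits deterministic
across platforms. Training loss is provably non-increasing for η ≤ 1 and
asserted on every fit. Hyperparameters can be CV-selected over an
(η, depth, rounds) grid with seeded contiguous folds; ties prefer smaller
rounds, then depth, then η. Correctness is pinned by brute-force split
enumeration and prediction agreement with xgboost configured identically.
The shipped per-analyte presets use the stated η/depth pairs (GLM 0.3/4,
ALG 0.5/6, PIO 0.1/1); the boosting round count is not stated anywhere, so
the presets use 300 rounds (past the point where training loss plateaus at
these η values; CV selection is available where a tuned count is wanted).

**nu-SVR.** Delegated to scikit-learn's NuSVR (RBF); the quadratic program
is not this package's contribution. The kernel acts on the features *as
given* — no internal standardisation — because the shipped C/γ presets
(ALG/PIO: C = 100, γ = 0.1; GLM: C = 31.623, γ = 3.162) are meaningful on
the preprocessed-absorbance distance scale, as in the toolbox workflows
this mirrors; ν defaults to 0.5 (no stated value exists). Note that C is a
per-sample penalty (libsvm semantics): duplicating the training set while
halving C reproduces the model exactly, which is the stability contract
the tests assert. SVR features default to PCA scores (k = 4) of the
preprocessed bands — dimensionality reduction is part of the SVR recipe
here, and PCA projection preserves the distances γ acts on.

**ANN.** A single-hidden-layer feed-forward network trained by full-batch
backpropagation on standardised scores and targets, tanh (or sigmoid)
hidden units, linear output, learning rate 0.125, seeded initialisation,
per-epoch loss traces, and early stopping that watches a monitor set's
RMSE with a patience counter and restores the best weights. It is written
in NumPy because the calibration needs the monitor-set early-stop contract
and bit-reproducible traces as first-class, testable behaviour. Inside the
pipeline the monitor is every 5th calibration sample — monitoring the test
set itself (as is sometimes done) would leak the evaluation data, and the
six identical stability runs cannot serve as a monitor. Input compression:
PCA k = 4 for ALG, PLS k = 3 for PIO (GLM, for which no ANN configuration
is documented, defaults to PCA k = 4).

## Evaluation

`metrics` computes RMSEP, per-sample recovery (100·ŷ/y, undefined at zero
nominal), mean and n−1 SD of recoveries, `RPD = sd(y, n−1)/RMSEP` (so
RPD·RMSEP ≡ sd(y)), and R². Model ranking sorts by RMSEP then recovery SD.
`run_pipeline` executes simulate → split → per analyte/model: bands →
preprocessing (fit on M) → compression → fit → predict T and St → metrics,
with a config hash and seed in the report; report JSON uses sorted keys
and 6-significant-digit floats so identical configurations produce
byte-identical artifacts.

## Model-ordering experiments and what they show

Two experiments probe the linear-vs-tree question on non-linear spectra:

- `saturation_sweep`: preset-PLS test RMSEP grows strictly monotonically
  with saturation strength (Spearman ρ = 1.0 on the default grid) — the
  expected failure mode of a linear model leaving the linear regime.
- `pls_gbt_ordering`: replicated preset-PLS vs preset-GBT comparison for
  GLM under the severe regime.

The second experiment deserves honesty about its outcome: boosted trees do
**not** dominate PLS here — win fractions sit near 50–70 % depending on
seed, with very similar mean RMSEPs. Two structural effects cap the tree
model: the 25-run design quantises training targets to five levels, giving
any piecewise-constant regressor an irreducible test-interpolation floor
(≈ 0.11 µg/mL for GLM, ≈ 0.8 µg/mL for ALG/PIO, computable from the test
rows' distances to the nearest level); and a smooth bounded saturation law
leaves low-absorbance band shoulders nearly linear, which a
100-wavelength linear model with CV-chosen extra LVs exploits to
partially linearise the distortion. Under these conditions the two model
classes are close to statistically tied for the minor analyte, while PLS
retains a clear edge for the major analytes. Where trees do show a robust
advantage is *stability under matrix shifts*: a constant absorbance offset
applied to test spectra degrades the narrow-kernel SVR far more than the
GBT (tested), and the GBT's monotone-invariance to per-feature distortions
makes it the defensible choice when spectra drift off the calibration
manifold.

## Numerical choices

- SNV/AS/recovery SD: n−1 denominators throughout.
- OSC pseudo-inverse rank cutoff 1e−10; score tolerance 1e−6; one exact
  re-orthogonalisation at convergence.
- SIMPLS deflation via an orthonormalised loading basis; scores kept
  orthonormal; degenerate covariance (rank exhaustion) raises rather than
  returning junk LVs.
- GBT split ties: first maximum of the gain vector → lowest threshold;
  across features → lowest index.
- Report floats at 6 significant digits; JSON keys sorted.
- All seeds are plain integers; derived streams use `default_rng([seed, i])`.

## Known limitations

- The generator's Gaussian-band spectra and four distortion mechanisms are
  a deliberately small model of instrument physics (see above for what is
  omitted); absolute error magnitudes on real tablets cannot be inferred
  from it.
- The ANN is full-batch gradient descent without momentum or adaptive
  rates — adequate for ≤ 5 features × 25 samples, not a general-purpose
  network.
- nu-SVR inherits libsvm's per-sample-C semantics; users comparing C
  values across differently sized calibration sets should rescale.
- PLS2 (joint multi-analyte) calibration is intentionally absent: each
  component is calibrated separately, which is the workflow this package
  reproduces.
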