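# Methods

## Scope and model

`chromopt` implements the standard chromatographic method-development
loop — three-level Box–Behnken design (BBD), full second-order
response-surface models, Derringer desirability multi-response
optimization — together with the validation metrics used to qualify the
resulting method, and a synthetic gradient-elution instrument for
end-to-end testing. The bundled fixture is the printed dataset of a
method-development study for seven food additives and caffeine: three
factors (%B initial 0–10%, %B end 60–100%, buffer pH 3–7), a 15-run
response table (seven adjacent-pair resolutions plus analysis time, with
`FOP` markers where a pair fully overlapped), the study's reported
coefficient matrix, and the measured concentrations in nine commercial
samples with their regulatory maxima.

## Design construction and coding

For k = 3 factors the BBD edge set is the 12 points with exactly two
coordinates at ±1. The canonical ordering is by factor pair — (x1,x2),
(x1,x3), (x2,x3), each in (−,−), (−,+), (+,−), (+,+) order — with the
center replicates last; run-order randomization is opt-in via a seed and
the analysis is order-invariant. Coding is affine:
uncoded = center + coded × half-range, and `code`/`uncode` are exact
inverses to 1e−12 on the factor box.

## Recovering the run assignment

The fixture's response table lists runs without their factor settings.
`infer_run_assignment` reconstructs the mapping by matching each
non-center run to the BBD edge combination whose reported-model
predictions best explain its responses, as a minimum-cost linear
assignment (`scipy.optimize.linear_sum_assignment`) with squared-error
costs summed over all eight responses. Two details matter:

* **Center detection.** The three center replicates are found as the row
  triple minimizing summed pairwise distance after range-normalizing each
  response column; on the fixture this selects runs 4, 5 and 12, the only
  rows forming near-identical triples.
* **Intercept recentering.** On a coded BBD the least-squares intercept
  of the full quadratic *must* equal the center-run mean, because the
  center indicator 1 − (x1²+x2²+x3²)/2 lies in the model's column span.
  Before computing costs, each reported model's intercept is therefore
  replaced by the detected center mean. This guards against a reported
  constant that is inconsistent with the replicates — which the fixture's
  run-time column exhibits (reported 23.085 vs center mean 17.833).

Under the recovered assignment the refitted models reproduce the reported
coefficient matrix to ~3 decimals and six of eight reported R² values
(including Rs3–4 = 0.7414) to 4 decimals. The run-time column is the
exception throughout: neither its constant nor its coefficients match any
least-squares refit under any assignment, so it is treated as an
inconsistency in the source table and reported as such rather than
forced.

## Model fitting and reduction

Fits are ordinary least squares (via `statsmodels.OLS`) of the 10-term
second-order polynomial on coded variables; 15 runs leave 5 residual
degrees of freedom. FOP cells are encoded as Rs = 0 before fitting — a
fully overlapped pair has no measurable separation, and the fixture
confirms the convention: the Rs5–6 model's reported constant of 0.000
equals the center mean only if its three center FOP cells are zeros.
Per-term p-values are two-sided t-tests of coefficient/standard error on
the residual df (equivalent to single-df partial F tests). `reduce_model`
refits keeping the intercept plus terms with p < α, deliberately not
enforcing hierarchy (a pure quadratic may survive without its linear
parent, as in the source study's reduced models). Zero-residual fits are
flagged degenerate and report p = 0 for nonzero coefficients. R² uses
1 − SSE/SST, SE = √(SSE/df), MAE = mean |residual|, all on the training
data, matching the fixture's reported metrics.

## Desirability optimization

Individual desirabilities are the usual one-sided power ramps (and a
two-sided ramp for target goals) with shape exponent fixed at 1; the
composite is the impact-weighted geometric mean with integer impacts 1–5,
defaulting to 3 for resolutions and 1 for analysis time. The optimizer
scans a 201³ lattice on the coded cube (chunked to bound memory), then
polishes the best cell with Nelder-Mead clipped to the cube; it is
deterministic and seedless, with grid ties resolving to the
lexicographically smallest point.

**Anchor choice.** The resolution ramps run from Rs = 0 (co-elution,
d = 0) to Rs = 1.5 (complete baseline separation, d = 1), saturating
above; time is minimized over its observed range. This is the package
default because it encodes the analytical goal directly — resolution
beyond baseline separation has no value, so the optimizer is not rewarded
for pushing an already-resolved pair from Rs 4 to Rs 9 — and because on
the fixture it places the optimum at coded (0.57, 0.58, 0.81), within
0.15 coded units per axis of the study's reported (0.69, 0.49, 0.88),
i.e. 7.8% vs 8.5% initial organic, 91.6% vs 90.0% final organic, pH 6.6
vs 6.7. The conventional alternative of anchoring at each response's
observed extremes is available (`observed_range_goals`) but drives %B
initial to the cube boundary on this dataset, away from the reported
interior optimum. Because the source study does not state its anchors or
exponents, the agreement achieved here is a calibration result, not an
identity; the residual ~0.12 coded-unit deviation on x1 is reported
as-is. Optimization uses the full 10-term models by default (reduced
models are an option via `PipelineConfig(use_reduced_models=True)`); the
reduced models on this fixture are nearly flat in x1 and cannot localize
it.

## Synthetic instrument

The simulator emulates the statistical structure the pipeline must
handle — smooth, pH-sensitive, interaction-bearing response surfaces with
occasional co-elution events — with known ground truth. It is not
calibrated to the fixture's numbers.

* **Retention.** Linear-solvent-strength: log₁₀ k = log₁₀ kw_eff − S·φ,
  with φ the organic fraction. For ionizable analytes kw_eff is the
  Henderson–Hasselbalch-weighted mix of the neutral and ionized species'
  aqueous retention (ionized acids less retained), so retention shifts
  sigmoidally across pH around pKa; pKa = None means pH-insensitive.
* **Gradient elution.** φ(t) ramps linearly over the 30 min program
  (dead time t0 = 1.5 min, 12 min hold at φ_end), and the migration
  equation ∫₀^{tR−t0} dt/(t0·k(φ(t))) = 1 is solved by the exact
  piecewise closed form of the LSS integral (log k is linear in t along
  the ramp). Tests cross-check it against adaptive quadrature and the
  isocratic closed form tR = t0(1+k) at 1e−6 relative. Analytes that
  would elute after the hold window raise a not-eluted error.
* **Peaks.** Gaussian, base width 4·tR/√N from a per-analyte plate count
  (default 10,000). Optional Gaussian retention jitter (minutes) with a
  per-run seeded substream; pairs with Rs below 0.2 are reported as FOP.
* **Default analytes.** Eight synthetic compounds with log kw 1.6–2.65,
  S 4.5–6.0, and pKa values (2.5, 4.2, 4.8, 1.8, 6.1, 5.0) spanning the
  pH 3–7 window plus two pH-insensitive analytes, chosen so that adjacent
  resolutions fall in the realistic 0.2–10 range, several conditions
  produce co-elution, and all analytes elute within the window across the
  whole design cube. Over the 15-run design this yields 11 FOP cells and
  quadratic fits with R² > 0.96 at zero noise.

The simulator omits real-instrument features — detector noise and
integration error, peak tailing, buffer-capacity and temperature effects,
retention drift — so passing recovery tests demonstrates that the
pipeline's statistics are sound, not that any real separation is
predicted. Its ground-truth optimum is defined by dense grid search
(21³ by default) on the noise-free simulated responses.

## Validation metrics

ICH-style conventions: calibration by simple linear least squares with
LOD = 3.3σ/S and LOQ = 10σ/S, σ the residual standard error (so
LOQ/LOD = 10/3.3 exactly); spike recovery 100·(measured − baseline)/spiked
with an 80–110% acceptance window; precision as percent CV with sample
(n−1) standard deviation, gated at 2% for system-suitability injections
and 10% (AOAC) for intraday/interday precision; and inclusive-at-the-limit
compliance checks of measured concentrations against the bundled
regulatory maxima. The fixture's own LOD/LOQ and recovery figures derive
from replicate instrument data that the printed tables do not contain,
so they are carried as documentation, not asserted.

## Numerical choices and limitations

* FOP encoding 0.0; overlap threshold Rs < 0.2 for marking FOP when
  extracting responses from peak lists.
* All fits on coded variables; reported coefficients are coded-scale.
* Assignment-cost ties broken toward lower run ids / lexicographically
  smaller combinations via an infinitesimal deterministic perturbation.
* Grid 201 per axis for MRO (≈8.1M lattice points, evaluated in
  x1-slices); Nelder-Mead polish with xatol 1e−9, accepted only on
  strict improvement so flat surfaces keep the lexicographic grid point.
* The acceptance computations use the 15-run fixture and the default
  8-analyte simulator at design sizes matching the study (15 runs,
  21³ truth search, 101–201 optimization grids).
* Known limitations: no lack-of-fit test against pure error; no
  blocking or split-plot structure; desirability is single-objective
  (no Pareto enumeration); the simulator's retention model is
  phenomenological and per-analyte-independent of temperature and flow.
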