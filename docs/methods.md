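# Methods

This note records the models, numerical choices and known limitations of
`perturbscreen`, in the spirit of a statistical-software methods appendix.

## Input model and categorization

A screen is a matrix of read-out values (confluency %, apoptosis signal,
impedance) over strictly increasing elapsed times (assumed hours; a CLI
override exists) and condition columns. The condition-header grammar is
positional: leading fields are consumed left to right as chemical
`name, concentration, unit` triples (the unit must be non-numeric, which is
also what rejects a comma used as a decimal separator) or bare genetic
labels; the last two fields are cell line and seeding density. Seeding is
kept as verbatim text and used only as a grouping key. Tab and comma
dialects are auto-detected on the header row; comma-delimited files must
quote the condition cells.

Categorization rules, applied to the branch partition over
(cell line, seeding, genetic condition):

1. genetic label(s) present anywhere together with chemical agent(s) →
   `genetic_chemical` (this rule deliberately subsumes `drug`: an agent
   tested both alone and on a genetic background is a genetic–chemical
   design);
2. genetic labels only → `genetic`;
3. ≥ 2 chemical agents co-applied in at least one condition →
   `drug_combination`;
4. otherwise `drug`.

Controls are vehicle tokens (default set {DMSO, PBS, H2O, untreated,
control}, configurable) or zero-dose conditions; more than one control is
pooled (mean, sample SD, Student-t 95% CI) into a unique control before
normalization. The predicted categorization and control set are meant to be
confirmed by the user (`--yes` auto-accepts); failure writes a
categorization-error file listing the headers.

A missing cell (empty field in the export) invalidates only that
(time, condition) pair and propagates as NaN; it never aborts the run.

## Normalization

Inhibition `1 − x/x_ctrl` or enhancement `x/x_ctrl − 1` against the
*time-matched* pooled control — the only reading consistent with scoring
synergy per time point. Effects are stored as fractions and may leave
[0, 1] here (a condition can outgrow its control); capping to [0, 1]
happens only at the entrance of the synergy module, because the Bliss
product requires fractional effects and negative "inhibition" would
fabricate synergy. When per-condition SDs exist (from replicate pooling),
the rescaled SD is the elementwise quotient by the control SD; both the
rescaled SD and the raw CI are stored since either can be drawn on plots.

## Dose-response model

4PL: `E(x) = E0 + (Einf − E0)·u/(1+u)`, `u = (x/m)^λ`. One parameterization
serves both the per-time-point effect fits and the ZIP machinery.
Initialization: E0/Einf from the responses at the lowest/highest dose, `m`
from the dose whose response is nearest the half-range, λ = 1. The fit
first runs unbounded Levenberg–Marquardt; if it fails or leaves the sane
region (m ≤ 0 or λ outside [0.1, 20]) a bounded trust-region fit with those
bounds is used. Since the curve is even in `m`, a negative LM iterate is
folded to |m|. Flat response vectors are *degenerate* (no metrics, pipeline
continues); non-convergence likewise marks the fit failed rather than
raising.

Derived metrics: relative IC50/EC50 = m; absolute IC50/EC50 solves
`E(x) = 0.5` in closed form, `x = m·((0.5 − E0)/(Einf − 0.5))^(1/λ)`,
undetermined when 0.5 is not strictly between the fitted asymptotes (a
shallow curve whose maximum inhibition stays below 50% has a relative but
no absolute IC50); Emax is reported both observed (response at the highest
tested dose) and fitted. AUC uses the trapezoidal rule on the log₁₀-dose
axis; both the raw area and the area normalized by the tested log-range are
reported, so a constant full effect over any range has normalized AUC 1.
Dose-response fits are made at the main time points {24, 48, 72} h plus the
final time point (overridable), and additionally on control-relative GR
values (the GR_rel50 / GR_abs50 / GR_Emax family, with the 0.5 crossing
defining GR_abs50).

## Growth rates

The read-out is rescaled to its first time point, and
`⟨GR⟩(t) = ln(x(t)/x(0))/t` — the natural logarithm makes the interval mean
exactly the time average of the instantaneous rate `d ln x/dt`; a base-2
toggle expresses rates in doublings per hour for groups that normalize by
doubling time. The instantaneous rate uses the identity
`GR(t) = ⟨GR⟩(t) + t·d⟨GR⟩/dt`, discretized symmetrically over the
bracketing sample points t₁ < t < t₂ (one-sided at the series ends), with
the derivative taken by central finite differences on a least-squares cubic
smoothing spline of ⟨GR⟩. The smoothing target defaults to `n·σ̂²` with σ̂²
estimated from second differences, so noiseless trajectories are
interpolated exactly (constant-rate growth gives GR ≡ ⟨GR⟩ to machine
precision, and a linear-in-time rate `a + bt` is recovered exactly on a
uniform grid). Control-relative GR is the pointwise ratio to the control's
instantaneous rate, NaN wherever the control rate is not strictly positive.
At least 3 time points are needed for the instantaneous rate; ⟨GR⟩ alone is
still reported for shorter series.

## Synergy models

Capping first: effects clipped to [0, 1]. Then per time point and grid
cell:

* HSA: expected = max of the single-agent effects.
* Bliss: expected = `1 − ∏(1 − Dᵢ)`, the product form of the
  inclusion–exclusion expansion (verified exhaustively against the
  enumeration for N ≤ 5 in the tests).
* ZIP: monotherapy curves are fitted as `f(x) = Emax·u/(1+u)` (zero
  baseline, since capped inhibition at zero dose is 0). For each direction
  i, a conditional curve is fitted along agent i's dose axis with its
  minimum pinned at the Bliss expectation of the *fitted* partner effects;
  the delta at a cell is the arithmetic mean of the N conditional fitted
  values minus the Bliss expectation of the fitted monotherapies. For two
  agents this is the classical ZIP delta (checked against an independently
  coded reference implementation); higher orders generalize by averaging
  the N conditional directions. ZIP applies to chemical combinations only
  — a genetic perturbagen has a single "dose", so no conditional curve
  exists, and genetic–chemical screens are restricted to HSA or BI.

Scores > 0 are synergistic, < 0 antagonistic. The onset of synergy is the
first time point where |score| exceeds 0.1 at ≥ 2 consecutive time points
(both configurable); heatmaps clamp to the fixed [−1, 1] scale. Missing
grid cells are skipped, never imputed. Conditional ZIP curves are fitted
per time point, consistent with the per-time-point heatmaps.

## Synthetic screens

The generator emulates the device dialect end to end and is the ground
truth for all calibration tests. The control grows as `c0·exp(K(t))` with
`K(t) = k0·t + slope·t²/2`; the default `k0 = ln2/24 h⁻¹` (one doubling per
day) and a 0–72 h grid sampled every 2 h mirror typical live-cell imaging
runs. Each agent carries a true 4PL inhibition curve; a genetic perturbagen
a fixed rate inhibition. Two effect models:

* `rate` (default for time courses): a condition's growth rate is
  `k(t)·(1 − ΣIᵢ)`. Per-agent survival on the read-out is then
  `exp(−K(t)·Iᵢ)` and combination survival is exactly the product of the
  single-agent survivals — Bliss independence holds identically at every
  time point, and GR ground truth is well defined.
* `direct` (endpoint-style): survival `1 − Iᵢ` multiplies the control
  read-out, so the margin inhibitions are exactly 4PL in dose — the
  configuration under which the ZIP fit family is closed and the ZIP null
  is exact.

Synergy injection multiplies the chosen cell's read-out by `(1 − ε)` from
the onset time onward; the implied BI score is `ε·(1 − H)`, so recovery
checks place the injected cell at low doses where the Bliss expectation H
is small and the score ≈ ε. Noise is multiplicative Gaussian on the
read-out (default SD 5%, the calibration level of the null checks), floored
at zero. Seeded generation is byte-reproducible.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: plate-position/edge effects, heteroscedastic or
autocorrelated imaging noise, confluency saturation, delayed drug action,
drug decay, and mixtures of cell populations. Calibration statements (e.g.
"mean BI score within ±0.02 of 0") hold under the stated simulation
conditions, not universally.

## Problem sizes and determinism

The shipped checks use: a 136-condition × 37-time-point parsing example,
100-seed null calibrations on 7×7 endpoint grids, 200 randomized layouts
for categorization, 10⁴ random vectors for the HSA/BI dominance property,
and 10³ random descriptors for the label round-trip — sizes at which every
statistic is stable while the whole suite runs in well under a minute. All
randomness flows through explicit seeds; `scripts/acceptance.py --seed`
reseeds every generator from the single CLI seed.

## Known limitations

* Bi-modal dose-response shapes are not modelled; the 4PL is the only
  curve family.
* No Loewe additivity, no significance testing of synergy scores, no
  plate-quality metrics (B-score, Z-factor) — out of scope by design.
* IC50 confidence intervals are not bootstrapped; χ²/R² are descriptive.
* The score scale is per-cell and fractional; tools that average scores
  over the whole dose matrix and report percentages will print numbers on
  a different scale for the same data.
* Plate-map (well-position) inputs, Excel workbooks and binary device
  formats are not parsed.
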