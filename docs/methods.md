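# Methods

## Equilibrium model

A speciation model is a set of components (metal, ligand(s), proton) and
species defined by integer stoichiometries and overall formation constants
log β on the molar concentration scale. Conventions:

* **Hydroxide as H₋₁.** Coordinated or free hydroxide is represented by a
  proton coefficient of −1 per OH; water itself is never a component.
  This is why hydrolysis constants (Cu(OH)₂ = −13.13) are negative and why
  reactions written with H₂O balance after the solvent (activity 1) is
  dropped.
* **Conditional constants.** All constants refer to 0.1 M KNO₃ at 20 °C.
  No activity-coefficient model (Davies, SIT) is applied anywhere, matching
  how the constants were determined.
* **Charges are metadata.** Species charges are not stored on species and
  no charge balance is enforced; at constant ionic strength they carry no
  extra information beyond the stoichiometry.
* **pKw = 13.78** by default (concentration-scale autoprotolysis product
  appropriate to the medium); configurable per model.

The five bundled models carry, per system, the ligand protonation ladders,
the binary Cu complexes, the ternary species and Cu(OH)₂. Cu(II) hydrolysis
is included in the binary Cu/Tyr model as well: above pH ~9 it holds a
non-negligible share of copper (≈14 % at pH 10.2 at the standard
conditions), and distribution claims for the binary system are only
reproduced with it present. Only printed constants are bundled; in
particular the third protonation steps of the nucleotides (log K ≈ 0.4–1.7)
are not included — they matter only below the pH 2.5 working window (their
inclusion changes nothing above it, which was checked numerically).

## Fixed-pH speciation solve

Unknowns are log₁₀ of the free concentrations of the non-proton components
([H] is fixed by the pH; a concentration-calibrated electrode is assumed,
so pH = −log₁₀[H]). Newton–Raphson with an analytic Jacobian, step clamp of
1 log unit per component per iteration, and a damping line search that
accepts the first halved step whose scaled residual does not increase
(strict decrease is deliberately not required: when a species overshoots by
many orders of magnitude the max-scaled residual plateaus at 1 while the
iterate walks monotonically home). Convergence requires a scaled mass-balance
residual below 10⁻¹², i.e. well inside the 10⁻¹⁰ relative target, within
200 iterations; failures raise, never pass silently. Species-concentration
exponents are clipped at 10²⁵⁰ so far-from-solution iterates stay finite.
Components with zero totals are eliminated together with their species.

Distribution diagrams solve a uniform inclusive pH grid (default step 0.01
over 2.5–11.0, 851 points) with each point warm-started from its
neighbour. Percentages are 100·ν·c/T_ref against the reference component's
analytical total; free reference is included, so columns sum to 100.

## Titration simulation

The protocol is data: initial volume (30 mL), titrant (≈0.20 M NaOH),
strong-acid content, analytical millimoles per component, and the number of
titratable protons each component carries *as weighed in* (tyrosine enters
as the zwitterion, +2 relative to Tyr²⁻; adenosine neutral, 0; AMP free
acid, ADP monosodium and ATP disodium salts, +2 each; Na⁺/K⁺/NO₃⁻ are
spectators). At titrant volume v all totals are diluted by v0/(v0+v) and
the titratable proton total is (acid + Σ protons − C_NaOH·v)/(v0+v), which
may be negative (excess base). The pH solves the full proton condition
T_H = [H] − Kw/[H] + Σ ν_H·c. Numerically the proton joins the Newton
unknowns (with the Kw/[H] term in its balance row) and each point is
warm-started from the previous one; the first point, or any Newton failure,
falls back to monotone bracketing of the pH on [1.5, pKw − 1.5] with Brent
root-finding on the proton condition.

`design_protocol` chooses the acid content so the curve starts at pH 2.5
and the final volume so it ends at pH 11.0 — the stated working window —
because the actual acid contents and titrant factors of the emulated
experiments are unpublished. Simulated curves are therefore
protocol-parameterized counterparts, not replicas of any published x-axis.
When a complex-forming curve is compared against its metal-free reference
(the onset-of-complexation diagnostic), the reference gets its *own* acid
content so both titrations start at the same pH, as two separate
experiments would; with a shared acid amount the curves differ by a
constant offset from the very first point, which measures starting-pH
mismatch, not complexation.

## Constant refinement

Residuals are formed in pH — the observed variable — on all points of all
curves; unit weights by default, optional 1/σ² weighting from each curve's
recorded noise level. Minimization is Levenberg–Marquardt
(`scipy.optimize.least_squares`, method `lm`) with a central-difference
Jacobian at a fixed absolute step of 10⁻⁴ log units, convergence at
relative Σ change or gradient norm below 10⁻⁸. Replicate curves sharing a
protocol and volume grid reuse one simulation per parameter vector, and all
evaluations are cached, so the finite-difference probes cost one simulation
each. If a parameter vector makes the equilibrium problem unsolvable (the
minimizer can wander arbitrarily along a direction the data do not
constrain), the objective returns a large finite penalty residual (10³ pH
units per point) and the minimizer retreats; only an unsolvable *starting*
model raises.

Standard deviations come from the scaled inverse normal matrix,
σ² = diag((JᵀJ)⁻¹)·Σ/(N−p). A species whose Jacobian column is numerically
zero — it never forms under the data's conditions — is reported with
**infinite sigma** rather than poisoning the normal matrix; a singular
matrix among the *active* columns (true collinearity) raises with the
offending parameters. Σ as defined here (weighted sum of squared pH
residuals) is internally consistent but not numerically comparable to the
Σ printed by other refinement programs, whose weighting schemes differ.

Model selection refines each candidate species set and flags free species
as rejected when sigma exceeds a cap (default 0.1) or when the species'
maximal formation share is below a floor of 2 % — below anything visible
in a distribution diagram — evaluated at the data's initial composition
on a coarse 0.05-pH grid. Ranking is lexicographic: more accepted species,
then lower mean sigma, then lower Σ; this mirrors the practice of keeping
the largest species set that refines with low standard deviations and a
low Σ.

## Synthetic studies

The generator emulates the statistical structure of the potentiometric
experiments behind the bundled constants: 30 mL initial volume, ~0.20 M
NaOH, C_Cu = 10⁻³ M with metal:ligand 1:2 (binary) or 1:1:1 (ternary),
pH 2.5–11.0, 250 readings per curve, six or more replicates. The only
stochastic element is i.i.d. Gaussian noise on pH with σ = 0.005 by default
— an electrode-grade figure chosen here, since the real error magnitude is
unpublished. Burette volumes are exact; there is no electrode drift,
junction-potential or carbonate model, and no systematic bias of any kind.
Replicate seeds derive deterministically from the study seed (seed + curve
index), so studies are reproducible as wholes.

Consequently, passing recovery tests shows that the estimator is correct
and well-calibrated under ideal Gaussian errors; it does not show
robustness to the correlated and systematic errors of real electrode data.

## Problem sizes used in tests

The full-size recovery study (6 curves × 250 points, all four binary
complexes free, starts displaced +0.3) runs in the acceptance layer. The
unit-test layer uses scaled-down studies — typically 2–3 curves of 60–100
points, and 80-point curves for the ternary end-to-end recoveries — which
keep the whole suite at a few minutes while exercising identical code
paths; recovery tolerances (0.05 binary, 0.1 ternary) are unchanged by the
scaling. Oracles are independent by construction: closed forms for the
one-species toys, nested interval bisection for two-component models, and
brute-force bisection of the proton condition for titration points.

## Known limitations and open choices

* Fixed-pH mode never solves the proton mass balance; emf/electrode
  parameters (E₀, slope, junction) are outside scope — data are assumed to
  be calibrated pH readings.
* No polynuclear species beyond those in the bundled sets, and no
  precipitation equilibria: above pH ~10 real Cu(II) systems can exceed
  solubility limits that this model ignores.
* The equimolar ternary ATP distribution computed from the bundled
  constants puts the Cu(Tyr)H₂(ATP) maximum at 74 % of total Cu (pH 5.2),
  with its share falling through 60 % near pH 5.9; accounts that quote
  "60 %" for this species at elevated pH are consistent with the flank,
  not the peak, of the computed curve.
* Temperature and ionic-strength extrapolation of constants is a non-goal;
  models carry the medium as metadata only.
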