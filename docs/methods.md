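# Methods

## Model structure and assumptions

The pathway is an ordinary-differential-equation network of 52 species
and 69 parameters. Intracellular species are counted in molecules per
cell; the extracellular ligand and all drugs are in nM and are clamped
(the culture medium is treated as an infinite reservoir, so ligand and
drug concentrations do not deplete through binding). HGF doses quoted
in ng/ml are converted with a molecular weight of 84 kDa for mature
two-chain HGF (configurable per condition); 40 ng/ml ≈ 0.476 nM.

Assumptions that shape the dynamics:

* **Activation is integrin-independent; trafficking is not.** The
  HGF-occupied receptor autophosphorylates at the same rate with or
  without α5β1, but the phospho-receptor's internalization, endosomal
  degradation and recycling rates all depend on integrin association
  (free pMet: fast in, fast degradation, poor recycling; pMet·Itg:
  slow in, slow degradation, efficient recycling). Constitutive
  trafficking of the *unphosphorylated* receptor is
  integrin-independent, which makes the in-silico integrin knockout
  (zeroing the association rate) preserve the total receptor budget.
* **Ligand-induced endocytosis.** Occupied receptors internalize at the
  induced rates whether or not they have yet autophosphorylated. This
  design choice decouples the speed of receptor internalization (which
  must reach ~50% of the Met pool by 15 min) from the speed of
  activation, which is deliberately slow (kact = 0.08 min⁻¹) so that
  steady-state signaling stays sensitive to the free-ligand
  concentration — the property that makes HGF dose–response curves and
  ligand-sequestering antibody treatment meaningful. With fast
  activation the receptor system converts every binding event,
  steady-state phospho-Met saturates at the receptor-supply limit, and
  ligand depletion has almost no effect.
* **Both receptor pools signal.** Adapter activation (Gab1, Grb2) is
  driven by the sum of all four phospho-Met species, surface and
  endosomal; the model's claim that most signaling originates from
  endosomes is then a statement about pool sizes, not about a separate
  endosomal rate law.
* **Conserved signaling totals.** Every intracellular protein
  interconverts between inactive and active (phosphorylated) forms with
  constant total (PIP2/PIP3 are treated the same way); only Met and
  α5β1 have synthesis and degradation.
* **Feedback set.** RSK ⊣ SOS (strong, negative), pERK → Raf (weak,
  positive), pERK ⊣ Gab1 (negative desensitization), pERK → PI3K (weak
  positive crosstalk), PDK1 → MEK (crosstalk), pAkt ⊣ Raf (Akt-side
  suppression of the ERK arm). Rate-law modifiers implement these as
  multiplicative factors `1 + w·x` or `1/(1 + w·x)` on normalized
  active fractions. The RSK ⊣ SOS loop is what makes MEK-output
  inhibition *raise* pMEK (less pERK → less RSK → disinhibited SOS →
  more flux into MEK), and the pERK ⊣ Gab1 loop is what lets sorafenib
  *raise* steady-state pAkt.
* **Drug mechanisms.** AXT050 binds free α5β1 (Kd 10 µM) and strips it
  from all Met-containing complexes, phosphorylated or not;
  cabozantinib occupies free and integrin-bound Met (Kd 1.3 nM),
  blocking HGF-driven activation while leaving constitutive
  trafficking; rilotumumab is applied as the excess-antibody closed
  form HGF_free = HGF·Kd/(Kd + dose) (Kd 0.5 nM) before simulation;
  node-output inhibitors multiply the rate laws leaving their node by
  1 − s·d/(d + K). For the calibration-time inhibitors (Met, PDK1, MEK,
  PI3K, ERK nodes) K is vanishingly small — strength-scaled full
  blockade at any nonzero dose; for sorafenib K is a model parameter
  (92 nM) so dose–response curves are defined. The ERK-output inhibitor
  is implemented as a throttle on ERK phosphorylation, which reproduces
  the observed pair (pMEK up, pERK down) under ERK blockade.

"Steady state" everywhere means the value at t = 120 min. Every
condition starts from a common basal state obtained by relaxing the
model without stimulus for 20 000 min; the receptor synthesis/
degradation turnover has a ~1000-min time constant, so shorter relax
windows leave a visible drift.

## Reference parameterization

The numeric tables bundled with the package are a synthetic reference
parameterization, constructed by the package authors rather than
measured: protein abundances are round numbers on the scale of
hepatocyte proteomic copy numbers (e.g. 10⁶ ERK, 1.5×10⁵ Akt, 6×10⁴
Met per cell), and rate constants were calibrated so that the published
summary behaviors of this pathway hold simultaneously:

* ≈50% of the Met pool internalized after 15 min of 40 ng/ml HGF;
* ≈73% of total phospho-Met in the endosomal pool at 120 min;
* sorafenib half-maximal on pERK near 200 nM, with near-complete pERK
  blockade and a slight pAkt *increase* at the top dose;
* PDK1 inhibition reducing pAkt far more than MEK inhibition; MEK
  inhibition raising pMEK; integrin knockout reducing pAkt much more
  than pERK (relative drops ≈86% vs ≈28%).

56 of the 69 parameters are flagged free (the calibration set); the 13
fixed ones are the ligand/drug binding constants and the node-inhibitor
strengths. Free-parameter bounds are ±2 decades around the reference
value (inhibition strengths live on [0, 1]).

Because the parameterization is a constructed stand-in, emergent
quantities that depend on fine details of the original calibration —
most visibly the MuSyC potency metrics of the receptor-level drug
combinations — should be read as properties of *this* parameterization.
This model yields essentially additive potency for AXT050 × sorafenib
and mild potency synergy for AXT050 × cabozantinib/rilotumumab; the
efficacy metric β_obs stays below 0.15 except for AXT050 × rilotumumab
on pERK, where the two partial inhibitors genuinely compound.

## Calibration

The objective is the sum over datasets of root-mean-square error
between normalized simulated readouts and dataset means; optional
SD-weighting divides each residual by the reported SD (default
unweighted). Simulated readouts are normalized to the maximum of the
HGF-only control time course per readout (switchable to per-condition
maxima — the convention used by normalized immunoblots is ambiguous, so
both exist). Simulation failures inside the objective return a large
finite penalty (10⁶) so derivative-free search continues.

Optimization is a deterministic generalized pattern search in log10
parameter space: poll ±mesh per coordinate in fixed order, accept the
first improvement, expand the mesh ×2 on success, contract ×0.5 on
failure, stop at a mesh tolerance or evaluation budget. The incumbent
never regresses, and the trace is monotone. Convergence on ridge-like
objectives (activation/deactivation pairs) is slow but reliable; the
test suite demonstrates exact recovery of a 4-parameter cascade from
noise-free data within a 2000-evaluation budget.

Inhibitor strengths are fitted separately on the linear [0, 1] scale
with all other parameters frozen, mirroring the two-stage
calibrate-then-validate design for combination predictions.

## Uncertainty and identifiability

Replicate datasets are drawn log-normally around each observed mean
with σ_log = √ln(1 + cv²), so the median of the draws equals the
observed mean and the coefficient of variation equals the nominal
measurement error (default 10%). Each replicate is refit by pattern
search started at the base fit and bounded to ±1 decade around it. The
desk-scale default is 25 replicates (`n=201` reproduces the full-scale
design). Prediction bands are pointwise 2.5/50/97.5 percentiles across
the refit ensemble; the band is pointwise, not simultaneous.

Local sensitivities are central-difference logarithmic gradients
d log(output)/d log(parameter) with a 1% relative step, evaluated for
the six standard outputs (pMet_total, pAkt, pMEK, pERK, pRSK, ppRSK) at
15 and 120 min. A parameter is practically identifiable when ≥95% of
its ensemble sensitivity distribution keeps one sign for at least one
output; parameters whose sensitivities are numerical noise around zero
(e.g. the binding constant of an undosed drug, or the receptor
synthesis/degradation pair, whose effects cancel at fixed steady-state
abundance) fail the rule.

## Global sensitivity

All free rate parameters and the nonzero protein abundances are varied
simultaneously and uniformly within ±50% of nominal (linear scale) by a
seeded Latin hypercube (scipy's `qmc.LatinHypercube`; one draw per
equal-probability stratum per input). PRCC conditions each input on all
the others: rank-transform, regress input and output on the remaining
inputs, correlate the residuals; significance by
t = r·√((n−2−k)/(1−r²)) with k = p−1 conditioning variables. Reported
heatmap tables zero entries with p ≥ 0.01. The desk-scale default is
n = 500 samples (`--n 5000` for the full design). The characteristic
sign structure — PI3K inactivation strongly negative on pAkt, ERK
abundance strongly positive on pERK, and the phospho-Met outputs moved
only by receptor-module inputs — is asserted in the test suite.

## Synergy

Single-drug curves use a four-parameter Hill fit (E0, Emax, h, C) by
bounded least squares; C is the IC50. Two-drug grids (8×8 log-spaced
doses plus zero anchors; effects normalized to the zero-drug control so
E0 ≈ 1) are fitted with the single-α MuSyC surface given in the README.
β is computed from fitted plateaus, β_obs from the observed corner
responses at the maximum tested doses. Fits are initialized from the
two axis Hill fits and solved with fixed bounds, so they are
deterministic. Isobolograms are computed by root-finding dose pairs at
a fixed fractional inhibition on the fitted (or any callable) surface;
a Loewe-additive construction yields the straight reference isobole.

Conventions: drug 1 is always AXT050 in combination tables; doses keep
their native nM scale (the metrics are invariant to consistent unit
changes, which is tested).

## Virtual cohorts

A patient is a vector of per-protein log2 fold changes (tumor vs
matched normal). Scaling multiplies the protein's total abundance —
initial amounts, plus the synthesis rates for Met and α5β1 — by
2^log2FC and leaves every rate constant untouched; the mRNA→protein 1:1
proxy is a known limitation of this design. The synthetic cohort
generator draws independent normal log2FCs per protein (default n = 50
patients, mean 0, SD 1 — the scale of real tumor/normal expression
ratios); it reproduces the *format* of an expression-derived cohort but
none of the gene–gene correlation structure of real tumors, so cohort
tests validate the pipeline mechanics, not biological covariation.

## Synthetic data and what passing tests show

The time-course generator simulates the four-condition
feedback-resolving design (HGF alone, +MEK inhibitor, +PDK1 inhibitor,
+both) at eight timepoints, normalizes to the HGF-only control maximum,
applies multiplicative log-normal noise (cv 10%), and reports mean ± SD
over three pseudo-replicates — the structure of a normalized
immunoblot dataset. It does not emulate blotting artifacts, saturation
nonlinearity, or between-gel normalization error, so recovery tests
demonstrate correctness of the estimation machinery under the stated
noise model, not robustness to real-blot pathologies.

## Numerical choices

* Stiff integration with LSODA, rtol 10⁻⁸ / atol 10⁻⁶ molecules for
  reported trajectories; analysis loops (objective evaluations, LHS,
  dose grids) use rtol 10⁻⁶ for speed. Conservation-group totals stay
  constant to better than 10⁻⁶ relative along trajectories, and an
  independent fixed-step RK4 integration (dt = 10⁻³ min) agrees with
  the adaptive solver to 0.1% on readouts.
* State is clamped at zero inside rate evaluation, so transient solver
  undershoot cannot produce negative fluxes.
* Pre-incubation is event-free piecewise simulation: drug-only segments
  in decreasing pre-incubation order, then HGF at t = 0.
* Pattern-search polling is strictly ordered with first-improvement
  acceptance; all stochastic components (resampling, LHS, synthetic
  noise, cohorts) take explicit integer seeds and are bit-reproducible.
* The SBML layer writes standard Level-3 core with mass-action MathML;
  modifier semantics ride in a package annotation namespace that the
  reader round-trips exactly. Plain mass-action documents from other
  tools import without annotations; arbitrary kinetic MathML does not.

## Known limitations

* The bundled parameterization is a calibrated synthetic stand-in, not
  a measured one; quantities far from its calibration anchors (notably
  combination-potency metrics) are parameterization-dependent.
* No HGF-independent Met activation by fibronectin-bound α5β1, no
  EGFR/VEGFR crosstalk, no pharmacokinetics, no spatial or
  tumor-growth layer.
* Ligand and drugs are clamped; experiments where ligand depletion by
  cellular uptake matters are outside the model's regime.
* Identifiability is the sign-consistency heuristic, not profile
  likelihood; bands are pointwise percentiles, not simultaneous.
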