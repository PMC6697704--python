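# hgfmet

A mechanistic systems-biology model of HGF/Met signaling with
α5β1-integrin-dependent receptor trafficking, packaged together with the
full analysis workflow built around it: derivative-free global
calibration, Monte-Carlo uncertainty quantification, practical
identifiability, Latin-hypercube/PRCC global sensitivity, MuSyC
drug-combination synergy, and virtual-patient cohorts.

## The problem

Hepatocyte growth factor (HGF) activates the receptor tyrosine kinase
Met, driving the PI3K/Akt and Ras/ERK survival and proliferation
pathways that sustain hepatocellular carcinoma. Met's association with
the α5β1 integrin changes how the activated receptor traffics: the
integrin-bound receptor internalizes and degrades more slowly and
recycles more efficiently, so integrin engagement amplifies and
prolongs downstream signaling. An integrin-binding mimetic peptide
(AXT050) that dissociates the Met–α5β1 complex therefore inhibits the
pathway by a purely trafficking-mediated mechanism, and its value in
combination with Raf inhibition (sorafenib), Met occupancy
(cabozantinib), or HGF sequestration (rilotumumab) is a quantitative
question about the whole network, not any single reaction.

`hgfmet` is aimed at computational biologists who want to simulate and
interrogate this pathway: reproduce the receptor-trafficking behavior,
calibrate the model to normalized phospho-protein time courses, and
score drug combinations patient by patient.

## The model

The network has 52 species and 69 parameters (56 free for calibration).
Mass-action ODEs cover:

* **Surface module** — HGF binding (`Met + HGF ⇌ Met·HGF`,
  `Met·Itg + HGF ⇌ Met·Itg·HGF`), receptor–integrin association,
  activation to pMet (rate independent of integrin binding), and
  trafficking: synthesis, ligand-induced internalization, recycling and
  degradation, with the asymmetry
  `k_int(pMet) > k_int(pMet·Itg)`, `k_deg(pMet_i) > k_deg(pMet·Itg_i)`,
  `k_rec(pMet·Itg_i) > k_rec(pMet_i)`. Both surface and endosomal pMet
  pools signal.
* **Intracellular cascades** — Gab1/PI3K/PIP3/PDK1/Akt and
  Grb2/SOS/Ras/Raf/MEK/ERK/RSK, every intracellular protein conserved
  (`X + pX = const`), with the feedback set: RSK ⊣ SOS (negative),
  pERK → Raf (positive), pERK ⊣ Gab1 (negative), pERK → PI3K (positive
  crosstalk), PDK1 → MEK (crosstalk), and pAkt ⊣ Raf.
* **Drugs** — AXT050 binds α5β1 and strips it from Met complexes;
  cabozantinib occupies Met; rilotumumab depletes free HGF
  (`HGF_free = HGF·K_d/(K_d + dose)` under antibody excess); sorafenib
  and the calibration-time node inhibitors multiply the signal leaving
  their node by `1 − s·d/(d + K)`.

Synergy of a drug pair is quantified on the MuSyC two-dimensional Hill
surface

```
E(d1,d2) = (E0 + E1·a1 + E2·a2 + E3·α·a1·a2) / (1 + a1 + a2 + α·a1·a2),
a_i = (d_i/C_i)^h_i
```

with synergistic potency log₁₀(α₂) > 0 and synergistic efficacy
β = (min(E1,E2) − E3)/(E0 − min(E1,E2)) > 0.

## Worked example

```python
import numpy as np
from hgfmet import build_reference_model, Condition, simulate, basal_state
from hgfmet.reference import met_internalized_fraction, pmet_internal_share
from hgfmet.synergy import (dose_response, fit_ic50, response_grids,
                            MusycModel, default_grid)

model = build_reference_model()
print(f"{model.n_species} species, {model.n_parameters} parameters "
      f"({len(model.free_parameter_names)} free)")
yb = basal_state(model)

times = (0.0, 5.0, 15.0, 30.0, 60.0, 120.0)
traj = simulate(model, Condition(hgf_dose=40.0, output_times=times), y_basal=yb)
frac15 = met_internalized_fraction(model, traj.state[times.index(15.0)])
share120 = pmet_internal_share(model, traj.state[times.index(120.0)])
print(f"Met internalized at 15 min : {100*frac15:.1f}%")
print(f"endosomal share of pMet at 120 min : {100*share120:.1f}%")

dr = dose_response(model, "Sorafenib", np.geomspace(1, 1000, 18), "pERK", 120.0)
print(f"sorafenib IC50 (pERK, 120 min) : {fit_ic50(dr).ic50:.0f} nM\n")

grids = response_grids(model, "AXT050", "Sorafenib", ("pAkt",), t=120.0)
print(MusycModel(grids["pAkt"]).fit().summary())
```

prints

```
52 species, 69 parameters (56 free)
Met internalized at 15 min : 48.3%
endosomal share of pMet at 120 min : 73.4%
sorafenib IC50 (pERK, 120 min) : 204 nM

MuSyC surface fit
========================================
E0=0.9967  E1=0.1353  E2=1.1433  E3=0.1476
h1=1.113  h2=0.999  C1=1050 nM  C2=243 nM
log10(alpha2) = -0.074   (potency synergy if > 0)
beta (fitted) = -0.0143   beta_obs = -0.0155
RMS residual  = 0.002617
```

Reading the numbers: under 40 ng/ml HGF about half of the Met pool is in
endosomes after 15 minutes, and by the 120-minute "steady state" ~73% of
all phospho-Met signals from the internalized pool — receptor traffic,
not surface occupancy, dominates the output. Sorafenib halves pERK near
200 nM. For the AXT050 × sorafenib pair on pAkt, log₁₀(α₂) ≈ −0.07 and
β_obs ≈ −0.02: essentially additive — no potency or efficacy synergy.
(`E2 > E0` reflects the modest *rise* of steady-state pAkt under
sorafenib alone, a feedback effect the model reproduces.)

A CLI wraps the same operations, e.g.:

```bash
hgfmet simulate --out traj.csv
hgfmet synergy --drug2 Cabozantinib --readout pAkt
hgfmet prcc --n 500 --seed 1 --out prcc.tsv
hgfmet cohort --n 10 --seed 1 --out cohort_monotherapy.tsv
```

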