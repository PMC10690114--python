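# petkin

Quantification pipeline for dynamic brain PET with a reversibly binding
radiotracer: compartmental and graphical kinetic modeling of regional
time–activity curves (TACs), test–retest reliability metrics, Lassen-plot
drug-occupancy estimation, and effect-site Emax concentration–occupancy
modeling. It is written for PET pharmacokineticists and pharmacometricians
who need a scriptable, testable alternative to point-and-click kinetic
modeling tools — for example to analyse an enzyme-occupancy study of a brain
target such as cholesterol 24-hydroxylase (CH24H), where an inhibitor's
target engagement is read out by displacement of a selective tracer.

Because raw clinical data for such studies are rarely redistributable, the
package ships a seeded synthetic-data generator that emulates the whole
study — bolus arterial input functions, metabolite (parent-fraction)
kinetics, 2TC-governed regional TACs with frame-dependent noise, test–retest
cohorts, blocking-scan designs and oral-dose drug PK — so every stage of the
pipeline is verifiable end to end against known ground truth.

## Models

**Compartment models.** The serial two-tissue compartment (2TC) model

    dC1/dt = K1·Cp − (k2 + k3)·C1 + k4·C2
    dC2/dt = k3·C1 − k4·C2

is fitted to frame-averaged tissue data by weighted least squares against the
metabolite-corrected arterial input Cp, with V_T = (K1/k2)(1 + k3/k4); k3 = 0
gives the one-tissue (1TC) model with V_T = K1/k2. Model choice uses
AIC = n·ln(RSS/n) + 2k.

**Graphical methods.** Logan graphical analysis (LGA) regresses
∫C_T/C_T on ∫Cp/C_T past an equilibration cutoff t* (default 30 min); the
slope estimates V_T. The noninvasive variant (NI-LGA) replaces the plasma
integral with [∫C_ref + C_ref/k2′]/C_T and its slope is the distribution
volume ratio, BP_ND = DVR − 1. The simplified reference tissue model (SRTM)
supplies k2′ = k2/R1, fitted by a deterministic basis-function expansion.

**Occupancy.** With a region-common nondisplaceable volume V_ND, the Lassen
plot V_T,base − V_T,block = occ·(V_T,base − V_ND) gives the global occupancy
(slope) and V_ND (x-intercept). Regional occupancies follow from
BP_ND = V_T/V_ND − 1 and occ(%) = 100·(1 − BP_ND,block/BP_ND,base). For the
second blocking scan, whose arterial line is not re-drawn, a dose-weighted
surrogate input is built: AIF_b2 = ID_b2·(AIF_base/ID_base + AIF_b1/ID_b1)/2.

**PK–PD.** Occupancy is linked to drug exposure by a sigmoidal Emax model,
occ(%) = Emax·C^γ/(EC50^γ + C^γ) with Emax fixed at 100%, where C is either
the plasma concentration (γ fixed at 1) or the effect-site concentration from
dCe/dt = ke0·(Cp − Ce), which absorbs plasma–brain hysteresis; ke0, EC50 and
γ are then estimated jointly.

**Reliability.** TRT(%) = 100·(test − retest)/[(test + retest)/2], one-way
ICC = (BMS − WMS)/(BMS + WMS), and time-stability tables of V_T bias versus
truncated scan duration.

## Worked example

```python
import petkin as pk

# 1) simulate a study-like baseline scan (putamen kinetics, bolus AIF)
frames = pk.default_frame_schedule()
aif = pk.default_aif(float(frames[1][-1]) + 1.0)
truth = pk.default_ground_truth()["putamen"]
tac = pk.simulate_tac(truth, aif, frames)

# 2) fit the two-tissue compartment model
print(pk.TwoTissueModel(tac, aif).fit().summary())

# 3) Logan graphical analysis of the same curve
print(pk.LoganPlot(tac, aif, t_star=30.0).fit().summary())

# 4) occupancy arithmetic on published reference values
bp_base, bp_block = pk.direct_bpnd(6.4, 1.5), pk.direct_bpnd(2.0, 1.5)
print(f"occupancy {pk.regional_occupancy(bp_base, bp_block):.1f}%")
```

prints

```
2TC compartment model fit
  frames: 34   converged: True
  RSS: 2.11616e-22   AIC: -1808.7433
  V_T: 20.2500 mL/cm3
   K1 = 0.5  (SE 1.37e-13)
   k2 = 0.33333  (SE 2.8e-13)
   k3 = 0.3  (SE 1.29e-13)
   k4 = 0.024  (SE 5.82e-15)

logan graphical fit (t* = 30 min, 19 frames, r^2 = 1.0000)
  V_T = 20.2427  (SE 0.00531)
  intercept = -79.781 min

occupancy 89.8%
```

The 2TC fit recovers the generator's rate constants to machine precision on
noiseless data (V_T = 20.25 mL/cm³ is the programmed putamen value); the
Logan slope agrees with the compartmental V_T to 0.04%, the residual being
the equilibration approximation of the graphical method. The last line is
the BP_ND-ratio occupancy implied by a cerebellar V_T falling from 6.4 to
2.0 mL/cm³ against a nondisplaceable volume of 1.5 mL/cm³.

The same operations are available from the shell:

```sh
petkin run config.yaml            # simulate -> fit -> occupancy -> report
petkin fit-kinetic tacs.csv blood.csv --model 2tc
petkin fit-graphical tacs.csv --method srtm --reference-region cerebellum
```

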