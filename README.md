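# labeldyn

Non-stationary ¹³C metabolic flux analysis by kinetic modelling of
isotopomer dynamics.

When proliferating cells are fed [1,2-¹³C₂]-glucose, the ¹³C labels spread
through central carbon metabolism along routes that leave distinct
fingerprints in the mass-isotopomer distributions (MIDs) measured by GC/MS:
direct glycolysis turns the C1/C2 label pair into m2 lactate, the oxidative
pentose phosphate pathway removes C1 as CO₂ and makes m1 pentoses, and TCA
cycling scrambles label into m1/m3 species.  `labeldyn` estimates the
underlying metabolic flux profile from such data without assuming isotopic
steady state: it simulates the full 48 h labelling transient on top of a
kinetic model of glycolysis, the pentose phosphate pathway and the TCA
cycle, and searches parameter space for the flux profile that reproduces
the measured distributions.

The pipeline follows three steps at metabolic steady state:

1. **Kinetic model.**  dc/dt = N·v(c, p) for the total metabolite
   concentrations; Michaelis–Menten rate laws with a free Vmax per lumped
   reaction, plus explicit elementary-step mechanisms for the enzymes that
   rearrange carbon skeletons (aldolase, transketolase, transaldolase).
   The glucose-uptake flux is pinned to the value measured from medium
   concentrations and cell growth.
2. **Isotope-exchange decomposition.**  Each net rate v is decomposed into
   the directional whole-cycle fluxes u_f, u_r (u_f − u_r = v) and, for the
   skeleton-rearranging enzymes, half-molecule exchange fluxes (e.g. the
   fbp ↔ g3p exchange of aldolase) that move label without moving mass,
   computed from first-passage probabilities of the enzyme-intermediate
   states.
3. **Isotopomer dynamics.**  Every pool holds 2ⁿ positional isotopomers
   encoded as binary numbers (bit = ¹³C, leftmost bit = carbon 1); carbon
   maps act as bit arithmetic (an aldolase split of "010101" yields "010"
   and "101").  Each flux is apportioned over substrate isotopomers by mole
   fraction, u_i = u_t·x_i/C_t, giving an ODE system (~460 states for the
   default network) integrated with a stiff BDF method and an analytic
   Jacobian.

Fitting minimises χ² = Σ((fᵉ−fᵗ)/σᵉ)² by simulated annealing alternated
with coordinate descent, refines the archived local minima with a genetic
algorithm (optionally a damped least-squares polish), and reports per-flux
confidence intervals from all sampled parameter sets within a χ² threshold
of the minimum.

## Worked example

Uptake fluxes from growth and medium measurements (control: glucose
8.66 → 4.76 mM, 0.25 → 0.36 × 10⁶ cells/mL in 48 h):

```bash
$ labeldyn fluxes --data src/labeldyn/data/growth_control.csv
condition  metabolite  rate_umol_per_1e6cells_min  flux_mM_min
control    glucose     0.00448898                  0.0897796
```

Rounded to assay precision that is 0.0045 μmol per 10⁶ cells per min,
i.e. 0.09 mM/min of intracellular volume (0.05 mL per 10⁶ cells) — the
value that pins the hexokinase flux.

Forward simulation at the packaged control-calibrated parameters:

```bash
$ labeldyn simulate --labeling
flux  hk        0.0901118
flux  pdh       0.0582699
flux  citsyn    0.0381224
flux  ppp_ox    0.000132087
...
mid   lactate_m0  0.796961
mid   lactate_m1  0.00916843
mid   lactate_m2  0.192908
mid   lactate_m3  0.00096351
mid   ribose_m0   0.48001
mid   ribose_m1   0.277198
...
```

Lactate is ~79% unlabelled and ~19% m2 (glycolysis of the 50%-enriched
tracer), with the small m1 fraction reporting TCA-cycle recycling; the
ribose m1 fraction reports the oxidative pentose phosphate branch.  A fit
(`labeldyn fit --condition control --seed 1 --out fit.json`) adjusts the
29 free parameters until the predicted MIDs match a measured dataset, and
`labeldyn ci` turns the sampled parameter sets into per-flux confidence
intervals.  Synthetic benchmark data with known ground truth come from
`labeldyn synth`.

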