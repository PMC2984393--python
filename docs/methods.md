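# Methods

## Model scope and network

The model covers the central carbon metabolism of a proliferating
suspension cell line over a 48 h labelling experiment with
[1,2-¹³C₂]-glucose at 50% enrichment: glycolysis/gluconeogenesis, the
oxidative and non-oxidative pentose phosphate pathway (PPP), the TCA cycle
with anaplerosis, lactate secretion, and the biosynthetic drains to RNA
ribose and lipids.  Reactions that do not rearrange the carbon skeleton
are lumped; pools connected by skeleton-preserving isomerases are merged:

* `f6p` — the hexose-6-phosphate pool (g6p ≡ f6p via phosphoglucose
  isomerase);
* `p5p` — the pentose-phosphate pool (r5p ≡ xu5p ≡ ru5p, fast
  equilibrium);
* `oaa` — the four-carbon pool (oaa ≡ mal ≡ fum);
* `lac`, `rib` — accumulating product pools: lactate secreted into the
  medium and ribose incorporated into RNA.  Their isotopomer content
  integrates the whole labelling window, which is what GC/MS of spent
  medium and of RNA hydrolysate measures.

Medium glucose is clamped (10 mM, labelled `110000` with probability 0.5).
The lumped citrate → malate leg releases the two oxaloacetate-derived
carboxyl carbons as CO₂ and passes through the symmetric
succinate/fumarate intermediate, applied as a 50:50 orientation scramble
of the product skeleton.  Released CO₂ is discarded and carboxylation
(pyruvate carboxylase) fixes unlabelled CO₂; a labelled CO₂ pool is a
known omission.  Glutamate-derived anaplerosis enters as a constant
unlabelled citrate input (`cit_in`), and carbohydrate stores (glycogen
turnover) exchange unlabelled hexose phosphate with the `f6p` pool
(`glyc_in`/`glyc_out`); both are fitted.  The dilution of RNA ribose by
pre-existing unlabelled ribonucleotides is a separate measurement-level
parameter.

## Kinetic layer

dc/dt = N·v(c, p).  Simple reactions are irreversible Michaelis–Menten
with fixed Km (0.5 mM; 0.1 mM for hexokinase so uptake is
glucose-saturated) and a free Vmax; citrate synthase is bi-substrate
(product of saturations).  Triose-phosphate isomerase is a fast
near-equilibrium pair with fixed rate constants.  The hexokinase flux is
pinned to the measured glucose uptake; the lactate-release flux is softly
constrained to the measured value (2% relative sd penalty).  The default
free-parameter set has 29 entries: 18 Vmax/input rates, one aldolase
elementary constant, six transketolase and four transaldolase constants.
Bounds are [10⁻⁹, 10³] in the units of each parameter — the published flux
profiles span below 10⁻⁶ mM/min, so the conventional 10⁻⁶ lower bound
would clip them.

Steady state is found by a Newton solve from the reference concentrations,
accepted only at a strictly positive and locally stable fixed point
(finite-difference Jacobian eigenvalues ≤ 0), with a fallback stiff-BDF
relaxation over growing horizons until max|N·v| ≤ 10⁻⁶·max|v|.
Divergence (a pool above 10⁵ mM) or non-convergence is reported as a
failed state, which the fitting layer scores with a large finite penalty
(10⁹) rather than an exception.

Reference concentrations for parameter inversion are order-of-magnitude
physiological pool sizes (hexose phosphates 0.1 mM, trioses 0.02–0.05 mM,
PPP intermediates 0.005–0.02 mM, citrate 0.2 mM).  Pool sizes control the
labelling time constants (τ ≈ C/v); with these values every intracellular
pool equilibrates well inside the 48 h window, as in the experiment.

## Calibrated default parameters

Defaults are inverted from the published fitted flux profile of each
condition at the reference concentrations: Vmax = v·(Km + c*)/c* for
Michaelis reactions, and, for the ping-pong enzymes, channel constants
from the directional-flux matrix (row sums = channel entry fluxes, column
sums = exit fluxes, enzyme split evenly between its two states).  The
published transketolase/transaldolase values obey the rank-1 structure
u_ij = a_i·b_j/Σb of a shared covalent intermediate to four digits, which
justifies this inversion.  Printed rounding leaves ~1% node imbalances;
the kinetic model absorbs them by relaxing to a nearby exact steady state.
Aldolase constants are a fixed shape (moderate half-exchange, u_e ≈ 0.3
u_f) scaled to the net glycolytic flux; the store-exchange default is a
quarter of the glucose uptake.

## Isotope-exchange decomposition

Label redistribution depends on more than net rates.  Every reversible
reaction contributes its two directions separately; enzymes that split or
transfer skeleton fragments additionally exchange half-molecules.  The
decomposition is computed analytically from the quasi-steady-state
enzyme-intermediate distribution by first-passage probabilities:

* **aldolase** (3-step mechanism): whole-cycle u_f, u_r and the fbp ↔ g3p
  half-exchange (binding, g3p release and re-binding, unbinding as fbp
  without completing step 3);
* **transketolase** (two-state ping-pong, glycolaldehyde adduct, three
  donor channels): entry channel i paired with exit channel j gives
  u_ij = a_i·b_j/Σb — six directional cycle fluxes (i ≠ j) and the
  x5p ↔ g3p, f6p ↔ e4p, s7p ↔ r5p half-exchanges (i = j);
* **transaldolase**: same with two channels (dihydroxyacetone adduct).

u_f − u_r equals the kinetic net rate identically.  The test suite
validates all three against stochastic single-enzyme simulations that
classify every sojourn of marked molecules.

## Isotopomer layer

Positional isotopomers are encoded as binary integers (leftmost bit =
carbon 1).  Each decomposed flux becomes a label event: unimolecular
events map each substrate pattern through the reaction's carbon map at
rate u·x_i/C; bimolecular condensations pair substrate pools at rates
proportional to the product of mole fractions; half-exchanges swap the
declared fragment with the partner pool.  Events are compiled once per
steady state into index arrays, giving a ~460-state ODE system whose
right-hand side and analytic Jacobian are a few dozen vectorised
operations.

Numerics: mole fractions are computed with the *current* pool sum rather
than the fixed kinetic total.  At steady state the two are identical, but
normalising by the fixed total makes the conservation manifold
exponentially repelling under round-off (production scales with the
product of pool-sum errors), whereas the current-sum form is neutrally
stable.  The transient is integrated with BDF (rtol 10⁻⁶–10⁻⁸) from the
fully unlabelled state over 2880 min.  After integration the per-pool
isotopomer sums are compared with the kinetic totals (relative tolerance
10⁻⁴; accumulating pools against flux × time) and any disagreement flags
the solution as inaccurate instead of passing silently.

Observables: lactate MID over carbons 1–3 of the accumulated medium pool;
ribose MID over carbons 1–5 of the accumulated RNA pool, renormalised over
the reported m0–m4 range and mixed with the unlabelled pre-existing
fraction d ("dilution").  Natural ¹³C abundance is assumed corrected in
the data.  Medium lactate is assumed absent at t = 0 (no lactate dilution
parameter); serum-derived lactate would bias m0 slightly high.

## Fitting

χ² = Σ((fᵉ−fᵗ)/σᵉ)², with published sd values floored at 10⁻⁴.  The
dilution is profiled in closed form at every evaluation (the observed MID
is affine in d), so the stochastic search never carries it.  The global
stage is simulated annealing (geometric cooling, multiplicative log-space
perturbations) alternated with cyclic coordinate descent, archiving each
local minimum; the archive seeds a genetic algorithm (uniform crossover,
log-scale mutation, elitist χ²-ranked selection).  A damped
least-squares polish (finite-difference sensitivities on the sd-weighted
residual vector, log-parameter space) is available as a final local
refinement — it is deterministic and cannot leave the basin the
stochastic stages selected.  Confidence intervals are profile-threshold
intervals: the spread of each flux over all sampled parameter sets with
χ² ≤ χ²_min + Δ, Δ from the χ² distribution (3.84 at 95%); if too few
samples qualify, extra points are drawn around the best fit with
shrinking spread.  All stochastic stages are reproducible from a single
seed.

## Synthetic data and what the tests show

The generator runs the identical forward pipeline at known ground-truth
parameters and perturbs each fraction with truncated Gaussian noise of
the magnitudes reported in the measured tables (lactate sd 0.001–0.003,
ribose sd 0.001–0.011), renormalising afterwards; replicates are averaged
as assays are.  It emulates assay noise only — no natural-abundance
envelope, no drift, no fragment cross-contamination — so recovery results
bound estimator behaviour under ideal measurement conditions.

Problem sizes of the end-to-end studies: the recovery study uses 20
replicate datasets with two displaced capacities (pyruvate dehydrogenase
and citrate synthase) fitted by the least-squares refinement, with 95%
interval coverage checked for both fluxes; the control refit frees all
29 parameters.
Under control-like conditions the citrate-synthase flux is only weakly
identified by the data (the χ² profile is nearly flat within ±20% of the
truth), which the intervals report honestly as width; pdh is strongly
identified through the lactate-balance constraint and the m1 signal.

## Known limitations

* No compartmentation (cytosol/mitochondria lumped), no labelled CO₂
  pool, no glutamate-pool labelling (anaplerotic input is unlabelled).
* Exact published rate laws were not available; the Michaelis/elementary
  reconstruction is behaviourally equivalent at steady state but the
  fitted parameter values themselves are not comparable — only fluxes
  are.
* The model is over-parameterised relative to the 9 measured fractions,
  so a successful refit constrains flux *combinations*, not every flux
  individually; conclusions should be drawn from the confidence
  intervals, not point estimates.
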