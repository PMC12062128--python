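# Methods

## The reduced core network

The model is a deliberately small (82 metabolites, 83 reactions in the
default build) stoichiometric network of *R. toruloides* central carbon
metabolism across four compartments (extracellular, cytosol,
mitochondrion, peroxisome). It is not a genome-scale reconstruction and
carries no gene–protein–reaction annotations; its purpose is to make the
cofactor economics of EG oxidation analyzable with transparent, fully
balanced stoichiometry.

Contents and the reasoning behind them:

- **Glycolysis** to pyruvate with standard BiGG-style charged-species
  formulas; phosphoglycerate mutase and enolase are lumped into one
  reversible step, and the non-oxidative pentose phosphate pathway is
  lumped to `2 xu5p + r5p -> 2 f6p + g3p`. Lumping linear segments does
  not change any flux ratio the analysis reports.
- **Oxidative PPP** (G6PDH, lactonase, 6PG dehydrogenase) is the only
  NADPH source besides the EG pathway and arabitol side reactions, so
  the NADPH balance is sharp.
- **Xylose assimilation** via NADPH-dependent xylose reductase,
  NAD-reducing xylitol dehydrogenase and xylulokinase — the cofactor
  imbalance motif — plus reversible D-arabitol 2-/4-dehydrogenases
  (NAD / NADP) and a D-ribulokinase. On xylose these side reactions
  form a NADPH↔NADH interconversion loop; on glucose the loop is
  unreachable (xylulose cannot be formed), which is why the cofactor
  routing prediction is sharper on glucose.
- **TCA cycle** in the mitochondrion; succinate dehydrogenase is lumped
  with FADH₂ oxidation (no ATP credit), NADH respiration is lumped to a
  single oxidative-phosphorylation reaction with P/O = 1.5, a typical
  yeast value. A lumped shuttle moves cytosolic NADH into the matrix.
- **Glyoxylate shunt**: peroxisomal isocitrate lyase with glyoxylate
  export to the cytosol; cytosolic (NADPH) and mitochondrial (NADH)
  glyoxylate reductases, both reversible by default; a peroxisomal
  glycolate oxidase (lumped with catalase). A `close_ga_oxidation`
  switch restricts the reductases to the glyoxylate → glycolate
  direction and closes the oxidase, reflecting the observed 100 % molar
  GA yield. Glycine for biomass is made from glyoxylate via
  mitochondrial alanine–glyoxylate aminotransferase, which keeps a
  baseline glyoxylate-shunt flux in every growing condition — the same
  qualitative behavior the flux predictions show.
- **EG pathway**: extracellular EG, cytosolic transport, and a two-step
  oxidation EG → glycolaldehyde → glycolate. Both steps exist in NAD
  and NADP flavors (selectable at build time); the oxidative direction
  is irreversible, and a separate reductive glycolaldehyde reductase
  (the physiological direction of the GRE2 homolog) is present but
  bounded to zero by default. The net chain hands exactly two electron
  pairs to NAD(P)⁺ per EG.
- **Optional routes**: a D-xylulose-1P aldolase route
  (xylulose → DHAP + glycolaldehyde), off by default, provides the
  hypothesized xylose-derived GA source; a glyoxylate exchange, off by
  default, lets excess shunt flux leave the cell.
- **Biomass** is a per-gram drain built from a generic yeast elemental
  composition CH₁.₈O₀.₅N₀.₂ (24.63 g per Cmol; the organism's own
  composition is not established, and the value is configurable).
  Carbon enters as 0.05 g6p + 0.1 glycine + 0.1 glutamate per Cmol
  (1.0 C, 0.2 N exactly); growth demands 1.5 mol ATP and 0.4 mol NADPH
  per Cmol by default (≈61 and ≈16 mmol per gram), both overridable.
  The NADPH demand is the lipid-synthesis sink that makes the cofactor
  routing question non-degenerate. Non-growth maintenance is
  1 mmol ATP gCDW⁻¹ h⁻¹.

Every internal reaction balances C, H, O and N to 10⁻⁹ (P and S balance
too, by construction); exchanges and the biomass drain are exempt, and
biomass is instead checked to drain exactly 1000/24.63 mmol carbon per
gram. Since the network has no phosphate source, the biomass reaction
returns the g6p phosphate as Pi, keeping the ATP/ADP/Pi pool catalytic.

Models serialize to a JSON document plus a TSV reaction table; numbers
are written as shortest-round-trip decimal strings so write → read is
bit-for-bit identity.

## Flux analysis

All linear programs are `scipy.optimize.linprog` (HiGHS) with solver
tolerance 10⁻⁹; feasibility assertions use 10⁻⁶. Measured specific
rates (mmol gCDW⁻¹ h⁻¹, uptake negative) become two-sided constraints
(lower = upper = value) on the named exchanges.

- **pFBA** is two-stage: maximize growth, then fix growth at the
  optimum within 10⁻⁹ relative and minimize Σ|v| after splitting every
  reversible reaction into two irreversible halves. The split is
  internal and never serialized.
- **FVA** and **sampling** constrain growth to ≥ `growth_fraction`
  (default 0.9) of the pFBA optimum. The published phrase "10 %
  variability from the predicted growth rate" is read as this one-sided
  ≥ 90 % floor — the two-sided ±10 % reading is implementable by
  passing a constraint on the biomass reaction, but the floor keeps the
  polytope convex and matches the phrase.
- The **sampler** is a seeded coordinate hit-and-run walk in the null
  space of S (every point satisfies S·v = 0 by construction), thinning
  10, warm-started from the mean of the FVA vertex solutions (feasible
  by convexity). Summaries report per-reaction median, sd, min and max;
  2000 iterations is the default sample count. Identical seeds give
  identical summaries.
- **Normalization** divides fluxes by |uptake| of a chosen substrate
  exchange; **route fractions** are ratios of summed flux magnitudes.

The cofactor-routing result deserves one note: with both EG
dehydrogenase flavors open and glucose as substrate, stage-1 FBA itself
already forces the NADP route, because EG-derived NADPH displaces
oxidative-PPP flux and its CO₂ loss, raising the attainable growth.
Were the biomass reaction NADPH-free, the two routes would tie and the
split would be solver-arbitrary; the NADPH demand is what breaks it.

## Physiology calculus

- Growth rates are least-squares slopes of ln(OD) vs time; the
  reported SE and r² come from the same regression. Points below twice
  the inoculum OD can be excluded.
- Phase detection: nitrogen limitation starts at the first sample with
  ammonium < 0.1 mM, or — from the %DO trace — at the local minimum of
  a 3-point moving average followed by a sustained rise (oxygen uptake
  peaks at the end of exponential growth). Runs without a transition
  yield a single-phase annotation with a warning.
- Specific rates regress the analyte amount (mmol/L) against the
  trapezoidal biomass-time integral ∫X dt, which is robust to noise and
  exact for growth-linked kinetics; consumption is negative.
- Yields are reported mol/mol, Cmol/Cmol and g/g, interconverted
  through element counts and molar masses computed from formulas
  (EG 62.07, GA 76.05 g/mol; glucose and xylose both 0.400 g C per g).
  The regression yield (slope of cumulative GA on cumulative EG
  consumed, free intercept) tolerates small non-monotone dips in the
  predictor as measurement noise and rejects only gross reversals
  (> 25 % of the range).
- Carbon closure in the end-to-end summary is total carbon out
  (biomass + CO₂ + GA) over total carbon in (sugars + EG consumed);
  with the published Cmol yield tables, the dedicated
  `carbon_balance` sum reproduces the printed closures (0.928 control,
  0.931 with EG) exactly. The RQ computed from the EG-condition mean
  gas yields (30.63/22.57) prints as 1.36; the control-row means give
  1.28 where the published table prints 1.29 — a per-replicate
  averaging artifact (means of ratios vs ratio of means), reported
  as computed, never corrected.
- C/N ratios are molar; this convention reproduces the published 80 and
  8.8 recipes exactly. The 40 g/L-glucose bioreactor recipe
  (2.02 g/L ammonium sulfate) back-computes to ≈43.6 molar against a
  nominal "C/N 40"; the calculator reports computed values.
- Off-gas CO₂/O₂ columns are interval-average evolution rates
  (mmol L⁻¹ h⁻¹ over the preceding sampling interval, as an off-gas
  analyzer reports); summing rate × Δt reconstructs cumulative gas
  exactly, which is how the summary integrates them.

## The synthetic fermenter

The generator emulates the study conditions, not a mechanistic culture:

- Two phases: exponential growth at `mu_exp` (default 0.34 h⁻¹) until
  ammonium is exhausted, then nitrogen-limited growth at `mu_nlim`
  (0.084 h⁻¹) while sugar remains. Glucose is consumed before xylose;
  sugar uptake is growth-linked through `y_xs` (0.42 g/g). Biomass
  formed after nitrogen depletion carries no nitrogen (lipid-like
  storage carbon); for simplicity a single biomass carbon fraction
  (0.488, from CH₁.₈O₀.₅N₀.₂) is used in both phases, a deliberate
  phenomenological shortcut.
- EG is oxidized at `q_eg` (0.15 mmol gCDW⁻¹ h⁻¹, a repository choice
  scaled to reproduce ≈1.7–2 g/L GA over an Nlim phase; the study does
  not print q_EG) whenever the gate allows: `glucose_nlim_only`
  represses EG oxidation while *both* glucose and nitrogen are
  available (so it starts at nitrogen depletion, or at glucose
  depletion in nitrogen-excess media); `xylose_coconsume` and `none`
  impose no repression. EG contributes zero carbon to biomass.
- GA appears at `y_ga_eg` ≤ 1 mol/mol from EG (default 1.0; the
  carbon shortfall of sub-unit yields leaves as CO₂), plus
  `extra_ga_factor` mol GA per mol EG drawn from xylose carbon when
  xylose is present under nitrogen limitation — the generator's stand-in
  for the xylulose-1P route, and the only way apparent yields exceed
  100 %.
- CO₂ is the closing entry of an explicit carbon ledger (sugar C used
  for growth − biomass C, plus unconverted EG carbon); O₂ = CO₂/RQ
  (default 1.36). %DO is a phenomenological proxy, affine-decreasing in
  the oxygen uptake rate and clipped to [0, 100]; only the location of
  its minimum (the phase transition) is meaningful.
- Integration is event-exact: within a regime, biomass follows the
  closed-form exponential and all pools are linear in ΔX or in the
  biomass-time integral; regime switches are located by solving those
  closed forms. Noise-free output therefore returns every configured
  parameter to machine precision and conserves carbon to < 10⁻⁶
  (the test suite asserts ~10⁻¹⁶), so estimator failures are estimator
  bugs, not integration error.
- Noise is applied only at sampling times: multiplicative lognormal on
  OD, additive Gaussian (clipped at zero) on concentrations; a seed is
  mandatory whenever noise is on.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: pH drops from GA accumulation
and their growth effects, lag phases, gradual (Monod-type) rate
transitions, variable biomass composition during lipid accumulation,
evaporation, or replicate-to-replicate variability. Estimator recovery
on synthetic data validates the calculus, not the biology.

The fixture suite writes the four desk-scale shake-flask regimes
(glucose C/N 80, glucose C/N 8.8, xylose C/N 80, glucose+xylose C/N 80;
10–20 g/L sugars, each ± 150 mM EG) with light measurement noise,
deterministically per seed.

## Problem sizes and tolerances

The test suite runs pFBA/FVA/sampling on the 83-reaction core model
(FVA ≈ 160 LPs, < 1 s; the reproducibility check samples 2000 points
twice, ≈ 10 s), Monte-Carlo batteries use 100 seeds, and synthetic runs
use 1–4 h sampling over 36–144 h horizons. Noise-free recovery is
asserted at 1 % relative; noisy recovery at 3 standard errors with
≥ 95/100 coverage; LP feasibility at 10⁻⁶; serialization and carbon
conservation at machine precision. cobrapy (GLPK) serves as an
independent cross-check of FBA optima and pFBA total flux on the same
network — it is never the implementation.

## Known limitations

- The biomass composition, ATP/NADPH demands and P/O ratio are generic
  yeast values; absolute growth predictions inherit them. Route
  fractions and normalized fluxes are much less sensitive.
- The arabitol loop gives the model a free NADPH↔NADH shuttle on
  xylose, so the NADP-route fraction there depends on parsimony rather
  than feasibility; on glucose the prediction is structural.
- The reduced network cannot reproduce sampling statistics of a
  genome-scale model (its solution space is far smaller); sampled
  medians are reported for the reactions the reduced network contains.
- `detect_phases` assumes a single exponential→Nlim transition;
  diauxic %DO signatures yield only the first change-point.
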