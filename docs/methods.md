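# Methods

This note documents the models implemented in `basaltbiome`, the defaults
they ship with, and the choices made where the design was genuinely open.

## Water chemistry and units

Concentrations arrive in ppm and are treated as mg/L throughout (dilute
solutions; density ≈ 1 kg/L), so ppm / molar mass = mmol/L ≈ mmol/kg.
Missing measurements ("n.d.") propagate as nulls: any derived quantity
whose input is missing is itself null, never imputed. Below-quantification
entries ("< 0.1") are likewise treated as missing — the reference table's
own summary row omits that column. Summary quartiles use linear
interpolation (type 7); since the source tables do not state their
convention, published footer statistics are treated as ±1-last-digit
consistency checks rather than bit-exact oracles.

Piper coordinates convert ppm to meq/L via molar mass and charge. Total
dissolved CO₂ is converted to bicarbonate equivalents at the measured
~20 °C pH using the first carbonate dissociation only (pK₁ = 6.38 at
20 °C); carbonate ion is folded into the bicarbonate equivalent. Iron is
reported without oxidation state and is excluded from charge arithmetic.

## Reduced speciation model

The species set is deliberately small: free major ions (Na⁺, K⁺, Ca²⁺,
Mg²⁺, Al³⁺, Cl⁻, F⁻, SO₄²⁻), the carbonate system (H₂CO₃*/HCO₃⁻/CO₃²⁻),
sulfide (H₂S/HS⁻), silicic acid (SiO₂(aq)/H₃SiO₄⁻), and water. Activity
coefficients follow the Davies equation with a temperature-dependent A
parameter; the model is valid to I ≈ 0.5 mol/kg, which covers all bundled
wells including the saline coastal ones. The ionic strength entering the
Davies expression is capped at 1 mol/kg so that bracket evaluations at
extreme pH during root-finding remain finite and monotone.

Given totals and a temperature, the pH is found by bisection on [0, 14]
(cap 200 iterations) to a charge residual below 10⁻¹² eq/kg, with the
ionic strength solved by fixed-point iteration inside each evaluation.
log K(T) values for all reactions ship as an editable YAML grid over
20–115 °C with linear interpolation; the defaults carry
literature-magnitude values and drive the full-speciation mode only.

**Electrical balance.** Following standard practice for field analyses,
the calculated 20 °C pH is reconciled with the measured one by varying one
concentration among {Na⁺, Cl⁻, SO₄²⁻, total CO₂} within ±20 % of its
measured value; among candidates achieving |ΔpH| ≤ 0.2 the smallest
|log multiplier| wins, and if none succeeds the best effort is returned
with a flag. Some wells in the reference table carry a genuine anion
excess larger than the ±20 % envelope can absorb under this reduced
species set (a richer database with ion pairs and hydroxo-complexes
closes more of the gap); they remain flagged.

**In-situ pH.** The wellhead-temperature speciation anchors to the
measured pH rather than to perfect electroneutrality: the residual charge
imbalance of the (adjusted) totals is evaluated at the measured ~20 °C pH
and carried to the wellhead temperature as an inert counter-ion. The
in-situ pH then reflects the temperature shift of the equilibrium
constants (K_w, carbonate, silicic acid) rather than analytical closure
error. For a balanced analysis this coincides with the free
electroneutrality solution. On the bundled wells this reproduces the
published in-situ pH to ~0.1–0.3 units and the published redox potentials
to 0.01–0.06 V across all 22 wells.

**Aluminium.** a_Al³⁺ is taken as the free-ion activity of total Al; no
hydroxo-complexation is modelled. At the alkaline pH of these waters that
overstates free Al³⁺, which affects the basaltic-glass saturation index
only — glass SI/ΔG from full speciation is therefore property-tested
(sign, ordering, robustness), never compared bit-exactly.

## Thermodynamics and kinetics

ΔG = R·T·SI·ln10 with T the wellhead temperature in K (no downhole
correction). The affinity factor is simple TST with Temkin coefficient 1:
f(ΔG) = 1 − exp(ΔG/RT), f = 1 where ΔG is undetermined (dissolution
assumed far from equilibrium), and f clamped to 0 with a "supersaturated"
flag where ΔG > 0 (precipitation is out of scope).

Rate law: r = k · a_H⁺^{n_H} · exp(−E_a/RT) · f(ΔG).

- **Forsterite** (alkaline mechanism, valid pH > 5.6, 0–150 °C): the
  published form log₁₀ r = 4.07 − 0.26 pH − 3464/T is stored exactly as
  log₁₀ k = 4.07, n_H = 0.26 and an Arrhenius temperature
  A_T = E_a/(R ln10) = 3464 K. The rounded activation energy
  (66 kJ mol⁻¹) is *not* used: it shifts rates by ~12 % relative to the
  exact A_T form, which reproduces the reference table within 2 %.
- **Basaltic glass**: k = 3.57 × 10⁻⁵ mol m⁻² s⁻¹, n_H = −0.39,
  E_a = 41 kJ mol⁻¹.

Redox potential assumes the sulfate–sulfide couple controls oxygen
fugacity: SO₄²⁻ + 10H⁺ + 8e⁻ → H₂S(aq) + 4H₂O (reduction direction,
referenced to SHE), E_H = (R·T·ln10 / 8F)(log K − log₁₀ Q) with
Q = a_H₂S/(a_SO₄ · a_H⁺¹⁰). The typeset source formula is ambiguous about
the sign of the activity term; this reconstruction reproduces the
reported reducing values (−0.3 to −0.5 V) and is adopted. The YAML log K
grid must match this convention. Full speciation uses speciated (free)
activities for the couple.

Two input modes keep exactness and modelling separate: **mode A** consumes
published per-well ΔG/pH_T/E_H directly (pure arithmetic, used by every
bit-exact check), **mode B** derives them from speciation (property-tested).

## Community statistics

All statistics operate on explicit matrices and are written out in full:

- **Rarefaction** draws without replacement (multivariate hypergeometric)
  to exact depth; shallower samples are dropped, then empty ASV columns.
  The subsampling RNG is numpy's seeded Generator; cross-ecosystem
  bit-reproducibility with other tools' rarefaction is a non-goal — the
  contract is statistical equivalence.
- **Unweighted UniFrac** = unshared branch length / total observed branch
  length, over branches with at least one present leaf below them in
  either sample. The root edge is excluded (shared by every profile).
- **PCoA**: Gower double-centering B = −½·J·D²·J, symmetric
  eigendecomposition, coordinates = eigenvectors × √eigenvalue for
  positive eigenvalues; negative eigenvalues are reported but unused;
  proportions explained are relative to the positive-eigenvalue sum.
- **Ward clustering** uses the Lance–Williams recurrence on squared
  distances (the ward.D2 dialect; the alternative ward.D dialect can be
  obtained by pre-squaring), deterministic lowest-index tie-break, and
  returns a scipy-style linkage matrix.
- **PERMANOVA** partitions tr(G) by the hat matrix of the design
  (continuous or categorical; intercept added): SS_model = tr(HGH),
  R² = SS_model/SS_total, pseudo-F with (rank−1, n−rank) df, and
  p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) under row permutations of the
  predictors. Multi-term models use sequential (Type I) sums of squares
  and permute raw observations. For a single continuous predictor the
  trace reduces to a quadratic form in the centered predictor, which the
  implementation exploits.
- **Spearman** is the Pearson correlation of average ranks with a
  t-approximation p (n−2 df) — matching the magnitude regime of typical
  reported p-values, not an exact permutation test. Missing data are
  handled pairwise-complete, with per-pair n reported; pairs with fewer
  than 3 complete observations are null.
- **ANOVA** is the single-predictor OLS F-test with (1, n−2) df.

Independent cross-checks in the test suite: scikit-bio for UniFrac and
the PERMANOVA pseudo-F (agreement to 10⁻⁸ on random fixtures), scipy for
Ward linkage heights/partitions and Spearman with ties.

## Synthetic scenario generator

The generator emulates the study conditions, not the study data: wells
uniform over 30–110 °C and pH 7–11; major ions drawn lognormally with
chloride closing the charge balance to within ~5 %; bedrock age drawn
log-linearly decreasing in temperature (0.01–15 Myr) with noise; a random
bifurcating tree from sequential random joins with exponential branch
lengths; sequencing depths log-uniform over 6,000–330,000 reads (the span
of typical MiSeq well samples); and all-or-nothing amplification dropout
above 89 °C with probability 0.8 (modelling failed PCR, not per-ASV
loss).

Each taxon has a Gaussian niche on the log scale of expected abundance in
temperature (optima uniform over 20–90 °C, widths 8–18 °C) and pH (optima
6.5–11.5, widths 0.8–2). Thermal optima are cooler-skewed relative to the
well range, so taxa tolerant of the hottest waters are rare — together
with dropout this yields the qualitative structure of the field system:
temperature-ordered beta diversity and richness declining with
temperature. A single `niche_strength` multiplier scales the Gaussian
penalty; 0 is the exact null (no environmental structure), 1 the default.
Counts are multinomial at the drawn depth.

What passing tests on this generator do and do not show: they demonstrate
that the statistical machinery detects, calibrates and ranks a known
environmental effect of realistic magnitude; they do not validate the
niche model as a description of real communities, nor cover compositional
features the generator omits (taxonomic covariance beyond the shared
tree, per-ASV amplification bias, chimeras, replicate structure).

Problem sizes used by the simulation-based tests — 40 wells × 150 taxa
with 100 replicate scenarios for power, 20 replicates × 5 effect levels
for recovery, 500 small null datasets for type-I calibration — were
chosen to give stable Monte-Carlo estimates (binomial s.e. ≤ 1 %) while
keeping the default suite quick to run.

## Numerical choices and limitations

- Bisection tolerance 10⁻¹² eq/kg on the charge residual; ionic-strength
  fixed point to 10⁻¹⁴; balance optimizer uses Brent's method on the
  multiplier.
- Reactivity summary statistics are computed over determined wells only;
  sd uses the n−1 denominator.
- Ties in Ward merging break on the lowest index pair; rank ties average.
- The reduced speciation database has no ion pairs, no Fe redox, no
  pressure corrections and no gas-phase equilibria; full-speciation
  outputs are therefore semi-quantitative (directions, orderings and
  ~0.1–0.3 pH-unit accuracy on the bundled wells) and all exact claims go
  through mode A.
- The bundled chemistry table carries no per-well bedrock ages (they come
  from a separate supplementary compilation), so age-related correlations
  are exercised on synthetic ground truth only.
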