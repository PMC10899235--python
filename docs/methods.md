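# Methods

## Scope and model

`mutcycle` implements the quantitative analysis pipeline used to probe
allosteric coupling between the agonist-binding extracellular domain (ECD)
and the channel-gating transmembrane domain (TMD) of the muscle-type
*Torpedo* nicotinic acetylcholine receptor (nAChR), a pentameric
ligand-gated ion channel (pLGIC). Four stages, each usable independently:
dose–response fitting, mutant-cycle coupling, group statistics, and
pore-axis geometry, plus a synthetic-data module that provides seeded
inputs with known ground truth for all of them.

## Dose–response fitting

Each oocyte recording (peak current vs agonist concentration) is fit with
the variable-slope Hill model

    I(c) = Imax · c^h / (c^h + EC50^h)

by unweighted nonlinear least squares in linear response space
(`scipy.optimize.least_squares`). Parameters are `(log EC50, log h, Imax)`:
the log parameterisation keeps both positivity constraints implicit and
conditions the problem on wide concentration grids.

* **Bounds.** h ∈ (0.2, 10); EC50 within the measured concentration
  bracket × [10⁻², 10²]; Imax > 0. The bounds prevent boundary pathologies
  on flat or saturating curves without constraining realistic fits.
* **Initialisation.** EC50₀ = geometric mean of the concentration pair
  bracketing half-maximal response (falling back to the geometric mean of
  the grid when no crossing exists), h₀ = 1.5, Imax₀ = max current.
* **Tolerances.** `xtol = 1e-10` (relative step), `ftol = 1e-12`. On
  noiseless Hill data the fitter is an exact interpolator
  (rss < 1e-12 · Imax²); the test suite also cross-checks a noisy fit
  against a dense brute-force grid search over all three parameters.
* **Aggregation.** Per-construct summaries are the mean ± sample SD
  (n−1 denominator) of the per-oocyte EC50 and Hill estimates over
  converged fits, with n the converged-fit count — i.e. each oocyte is one
  experiment, matching standard TEVC practice. Non-functional constructs
  carry a status code instead of numbers: NR (no agonist response),
  NE (no surface expression), NF (expressed but non-functional).
* **Fold change.** The EC50 ratio mutant/WT, reported as magnitude ≥ 1
  with a direction: `loss` when EC50 increased, `gain` when it decreased
  (reciprocal taken), `none` when the ratio rounds to 1.00 at the 3
  significant figures used for display. Full precision is kept internally.

## Mutant-cycle coupling

For k perturbations with single-mutant EC50s `e_1 … e_k`, wild type `e_wt`
and combined construct `e_comb`, the interaction factor is

    Ω = e_wt^(k−1) · e_comb / ∏ e_i

which at k = 2 is the classical double-mutant-cycle expression
`e_wt·e_12/(e_1·e_2)`. Ω = 1 when the combined EC50 equals the
independence prediction `e_wt · ∏(e_i/e_wt)`; the coupling energy is

    ΔΔG = RT ln Ω,  RT = 2.4776 kJ/mol (R = 8.314 J mol⁻¹ K⁻¹, T = 298 K).

Because whole-cell EC50 is a composite of binding and gating equilibria,
ΔΔG ranks couplings; it is not the free-energy change of a single named
equilibrium.

Design choices that were genuinely open:

* **Generalised numerator.** The `e_wt^(k−1)` power is the unique
  extension that (a) reduces to the pairwise formula, (b) keeps Ω
  dimensionless and invariant to a common rescaling of all EC50s, and
  (c) reproduces the published triple- and quadruple-mutant Ω values.
* **Paired complementary-subunit mutations** (the same position mutated in
  both the γ and δ subunits) are decomposed into their two single-subunit
  members: the published independence predictions for such cycles equal
  the product over individual perturbations, not the two-way product using
  the γ+δ double as one unit.
* **Error propagation.** The SD of ΔΔG is reconstructed (the propagation
  used for the published ± values is not stated) as relative EC50 SDs in
  quadrature, scaled by |ΔΔG|, with the WT term entering k−1 times:

      SD(ΔΔG) = |ΔΔG| · sqrt( (k−1)(s_wt/e_wt)² + Σ (s_i/e_i)² + (s_comb/e_comb)² )

  This model reproduces the published ± values to the printed last digit
  on the large majority of rows (verified by brute force before the build;
  the exceptions are rows where the published table itself reflects
  unrounded internal means). It is exactly zero at Ω = 1, which matches
  the published 0.00 ± 0.00 row but is a property of the chosen model
  (first-order propagation through `RT ln Ω` would instead give
  `RT·sqrt(Σ rel²)` independent of Ω; the |ΔΔG|-scaled form is the one
  consistent with the published columns).
* **Printed vs unrounded mode.** `build_cycle_table(..., mode="printed")`
  rounds input means/SDs to 3 significant figures before computing,
  mimicking arithmetic from a published table; `"unrounded"` (default)
  uses the summaries as given. A handful of published rows differ in the
  last digit from printed-mean arithmetic; the reproduction tests carry
  correspondingly looser bounds on exactly those rows.

## Group statistics

One-way fixed-effects ANOVA works from replicates or from (mean, SD, n)
summary triples; between/within sums of squares reconstruct exactly from
summaries, so summary-based and replicate-based results coincide when the
replicates realise the same triples.

Dunnett's many-to-one test compares every construct against the control
using the ANOVA pooled variance. Adjusted p-values come from the null
distribution of max_i |T_i| where the comparison statistics share the
control mean and the pooled variance estimate: with λ_i = √(n_i/(n_i+n_0)),
T_i = (λ_i Z_0 + √(1−λ_i²) Z_i)/√(χ²_df/df) — correlation ½ between
comparisons in a balanced design, plug-in correlations otherwise. The
max-|t| distribution is sampled by seeded Monte Carlo (default 2×10⁵
draws) rather than read from printed tables; accuracy is verified in the
test suite against both `scipy.stats.dunnett` and a brute-force simulation
of raw datasets. The adjusted p is clamped from below by the unadjusted
two-sided t p-value (the analytic bound that Monte-Carlo noise could
otherwise violate), and a single comparison uses the exact t distribution.

Tests default to raw EC50 values to mirror common practice in TEVC work;
passing log-EC50 values is supported and statistically preferable given
the roughly lognormal inter-oocyte spread.

The printed DF/F values of the source tables are not reproduction targets:
the exact group membership of each published ANOVA is not recoverable.

## Structure geometry

* **Pore axis.** Anchor = centroid, direction = principal
  (largest-variance) eigenvector of a CA selection, by default all CA
  atoms; pass the pore-lining M2-segment CAs for full-receptor models
  whose chains contain more than the pore region. On an exactly
  C5-symmetric structure whose axial spread exceeds its radial spread the
  principal axis is the symmetry axis exactly. The sign convention
  (largest-magnitude component positive) is arbitrary; every measurement
  built on the axis is sign-independent.
* **Residue aggregation.** Pore-proximal/distal calls default to the
  side-chain heavy-atom centroid (CB outward; CA fallback for glycine),
  because the claims concern side-chain positions; `CA` and named-atom
  modes exist for sensitivity checks.
* **Tie band.** ε = 0.3 Å: radial differences below this are
  `indeterminate`, since ~3 Å cryo-EM coordinates do not support finer
  claims. Verdicts: proximal ⟺ r_query < r_ref − ε; distal ⟺
  r_query > r_ref + ε.
* **Hydrogen bonds** are measured as donor-heavy-atom to
  acceptor-heavy-atom (N···O) distances with no angle criterion.
* **Pore collapse** is the cross-pore CA–CA distance between the same
  residue (by convention the α-subunit V255 position, deposited numbering)
  in two chains; it applies to any single coordinate set.
* **I/O.** PDB and mmCIF through gemmi; first model only; altloc blank/'A'
  kept. PDB coordinates carry 3 decimals, so write/read round trips are
  exact to 10⁻³ Å.

## Synthetic data

The generator emulates the study conditions of a TEVC mutagenesis screen:

* concentration grid: 8 half-log-style points spanning EC50/30 … 30·EC50
  (the published work does not print its grid; this is a standard design
  that brackets the sigmoid well);
* n = 8 oocytes per construct (the stated minimum replicate target);
* inter-oocyte EC50 variability: lognormal with median at the true EC50
  and CV 19 % — the wild-type summary 9.40 ± 1.82 µM implies ~19 % CV, and
  EC50 spread is the quantity the aggregation consumes, so Hill slope and
  Imax are held fixed within a panel;
* measurement noise: multiplicative Gaussian on peak current, CV 7 %
  (unstated in the source; chosen so that n = 8 averaging is meaningful),
  clipped at zero current;
* NR constructs produce all-zero traces.

All randomness flows from a single integer seed through
`numpy.random.SeedSequence`, with per-construct spawned streams keyed by
sorted label so panels are bit-reproducible and independent of construct
ordering.

What the generator does **not** emulate: desensitisation, voltage
dependence, channel block at high agonist, series-resistance artifacts,
day/batch effects, or correlated Hill-slope variability. Passing tests
therefore demonstrate correctness of the estimators under the stated
noise model, not robustness to every artifact of real recordings.

Synthetic pentamers are exact C5 rings: every atom of a ring (CA plus a
pseudo side-chain CB at the same radius) sits at its specified radius and
height, so radial distances, chord lengths and the symmetry axis all have
closed-form ground truth. They carry no real side-chain geometry.

## Problem sizes used in the checks

The parameter-recovery check runs 200 seeded 8-oocyte panels at the
wild-type regime (≈1600 Hill fits); the Dunnett oracle uses 4×10⁵
analytic null draws against 4×10⁴ simulated raw datasets; the type-I-rate
check uses 2000 simulated null panels against a precomputed critical
value; the generalized-Ω identity is checked on 1000 random EC50
quadruples. These sizes give Monte-Carlo error comfortably below the
asserted tolerances.

## Known limitations

* ΔΔG values inherit every caveat of EC50-based cycles: they are
  composites over the activation mechanism, not state-specific energies.
* The error-propagation model is a reconstruction; it matches the
  published ± values but remains an inference about how they were
  computed.
* The pore-axis estimator assumes the selected CA set is elongated along
  the pore; a single flat ring of atoms has its principal axis in-plane
  and must be measured against an explicitly constructed axis instead.
* Dunnett adjusted p-values below ~1/n_draws are reported at the
  unadjusted-p clamp; raise `n_draws` when very small adjusted p-values
  matter.
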