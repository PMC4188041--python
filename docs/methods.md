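# Methods

## Energy triage

The classifier consumes precomputed free-energy changes (ΔΔG, kcal/mol;
positive = destabilising) from an external structure-based force field.
Two magnitude thresholds define significance tiers: 0.8 kcal/mol (one
standard deviation of the force-field prediction error, ~95% confidence)
and 1.6 kcal/mol (two SDs, ~99%). Both comparisons are strict (`>`), so a
value exactly at a cut-off falls into the lower tier.

Tiering uses the **absolute value** of ΔΔG. Disease-relevant interface
changes are not always destabilising in sign — loss of binding to an
inhibitor is recorded as a positive ΔΔG on that interface, while a
strongly stabilising change can lock an autoinhibited conformation — so
magnitude, not sign, carries the significance.

Class assignment follows the dominant term: among all terms (folding ΔΔG
plus interface terms) whose magnitude exceeds 0.8 kcal/mol, the largest
|ΔΔG| decides the class via its kind (intra-domain interface → 1a,
inhibitory segment → 1b, inter-protein interface → 2, folding → 3). Exact
magnitude ties are broken by the fixed precedence fold > intra_domain >
inhibitory_segment > inter_protein; no published rule exists for this
corner, the precedence simply makes the map deterministic, and the full
term list remains available on the record. Below threshold, buried
positions go to `core_subthreshold` and surface/unknown positions to
class 5 (neutral). Literature evidence overrides energies: experimentally
demonstrated localisation changes force class 4, and catalytic-site
evidence forces the class-1a activity bucket with
`driving_term="catalysis"`; flag-driven assignments carry tier `na`
because no energy term is their basis. Records without structural
coverage are `not_modelled`.

`partition_summary` reports the interaction-vs-folding split of
energy-driven assignments over two denominators (the highly significant
set and the full significant set), because summaries of this kind are
ambiguous about the intended denominator; both are computed rather than
forcing either reading.

## Sequence triage

Shannon entropy of an alignment column is computed in bits over the 20
amino acids, with gaps excluded from the frequencies rather than treated
as a 21st symbol — the classifier measures conservation of the residue
alphabet, and indel structure is not part of the score. The logarithm
base only rescales both the scores and the cohort-mean threshold, so
verdicts are base-invariant (asserted as a property test).

Substitution diverseness is the BLOSUM62 log-odds score by default;
any matrix in NCBI text format can be substituted. Both classifiers are
thresholded at the arithmetic mean of the disease cohort (strict `<`:
equalling the mean does not meet the criterion), and the combination rule
is deliberately simple — two criteria met → *likely*, one → *maybe*,
none → *unlikely* — and isolated behind one function
(`combined_verdict`) so it can be replaced without touching anything
else. Buried positions with sub-threshold energies bypass the rule as
`core_subthreshold`. The fit/predict form of this procedure (learn cohort
means, emit verdicts) is exposed as the scikit-learn estimator
`SequenceTriage`.

## The Ras-cycle model

Eight species (RasD, RasT, RasD·GEF, RasT·GAP, RasT·EFF, free GEF, GAP,
EFF) and seven mass-action channels: reversible GEF binding to RasD
followed by catalysed GDP release; reversible GAP binding to RasT
followed by catalysed hydrolysis; the two intrinsic conversions; and
reversible effector binding to RasT. Assumptions:

- Nucleotide pools are not modelled; free GTP/GDP is assumed saturating,
  so exchange and hydrolysis are first-order in the Ras species (as ATP
  is handled in kinase models).
- No wild-type allele is co-simulated; a variant's rate set replaces the
  wild-type's entirely.
- Abundances are held at wild-type values for all variants; only rate
  constants change.
- State is deterministic molecule counts: the readout is the mean
  steady-state abundance, and copy-number noise is out of scope.

State is in molecules within a reaction volume V (default 10⁻¹⁴ L);
bimolecular on-rates in M⁻¹s⁻¹ are converted to per-molecule rates by
1/(N_A·V), so halving the volume doubles the per-molecule rate.

"Equilibrium" readouts mean the **steady state of the driven cycle** —
the GTPase cycle consumes GTP and does not satisfy detailed balance. The
solver integrates the rate equations (LSODA, rtol 10⁻¹⁰) over
geometrically growing windows until max|dy/dt| < 10⁻⁹ molecules/s, then
polishes with a Powell-hybrid root-finder on the conservation-reduced
four-variable system (RasD, RasD·GEF, RasT·GAP, RasT·EFF; the other four
species follow from the Ras/GEF/GAP/EFF totals). The polish enforces the
conservation laws exactly and takes the residual to machine level; if it
fails or strays negative, the integrated endpoint is reported with its
residual and `converged` set accordingly. Steady-state invariance to the
initial GDP/GTP split of Ras is verified rather than assumed.

In the limit with no deactivation (k_GAP = 0, intrinsic hydrolysis 0)
**and no GAP protein** (GAP_total = 0), all Ras ends GTP-loaded and
RasT·EFF solves the one-site binding quadratic
C² − (Ras_tot + EFF_tot + K_D)·C + Ras_tot·EFF_tot = 0 (K_D in
molecules). GAP_total must be zero for the closed form to be exact
because reversible GAP *binding* sequesters RasT even without catalysis;
this is the regime used for the closed-form solver check.

### Parameters

Default wild-type values ship in
`src/rastriage/data/ras_wt_params.yaml`, clearly marked as
representative placeholders to be replaced by measured values. They are
order-of-magnitude realistic for the mammalian Ras module:

| parameter | default | rationale |
|---|---|---|
| volume | 10⁻¹⁴ L | small-compartment convention of the emulated setup |
| Ras_total | 6000 (≈1 µM) | total H/K/N-Ras |
| GEF_total | 120 (≈20 nM) | SOS1 |
| GAP_total | 300 (≈50 nM) | RASA1 |
| EFF_total | 1200 (≈0.2 µM) | RAF1 + BRAF |
| k_GEF | 3.9 s⁻¹ | GEF-catalysed exchange turnover |
| k_GAP | 19 s⁻¹ | GAP-catalysed hydrolysis turnover |
| k_exch_intr | 10⁻⁴ s⁻¹ | intrinsic nucleotide release |
| k_hydr_intr | 2×10⁻⁴ s⁻¹ | intrinsic hydrolysis |
| kon_GEF/GAP | 10⁷ M⁻¹s⁻¹ | diffusion-limited association |
| koff_GEF/GAP | 0.3 / 1.0 s⁻¹ | solution off-rates decreased 10-fold, representing membrane co-localisation of the enzymes with Ras |
| kon_EFF, koff_EFF | 4.5×10⁷ M⁻¹s⁻¹, 5.4 s⁻¹ | Ras–RBD binding, K_D ≈ 120 nM |

Mutants are parameterised by dimensionless fold changes of the five
measured quantities. Fold changes multiply the **catalytic/intrinsic
steps only**, not the enzyme binding steps: observed k_obs ratios from
exchange/hydrolysis assays report on turnover, and whether binding steps
should co-scale is not determinable from k_obs alone, so catalytic-only
is implemented (and isolated in `apply_fold_changes`). The effector K_D
fold change acts on the off-rate with kon fixed, since interface mutants'
binding losses are dominated by faster dissociation; this, too, sits
behind the same single function.

## Statistics

The germline-vs-somatic comparison is a two-sided two-sample t-test
implemented from its closed form: Welch's unequal-variance statistic
with Welch–Satterthwaite degrees of freedom by default (group variances
are not assumed equal across disease cohorts), the pooled-variance
variant behind `pooled=True`. Group means are reported alongside p so
the direction of the effect is explicit. Degenerate zero-variance inputs
return t = 0, p = 1 for identical groups. Which ΔΔG enters the
comparison per mutation is configurable; the dominant (max-|ΔΔG|) term
is the default, matching the triage logic.

The rate–energy correlation is Pearson's r of ΔΔG against
log₁₀(fold change): energies are additive while rate ratios are
multiplicative, so the log is the natural common scale. The raw-scale
coefficient is reported alongside.

Closed-form power of the two-sample test (noncentral t with
ncp = d·√(n/2)) backs the power-recovery check of the synthetic
generator.

## Synthetic data

The generator emulates the curated study inputs with their assumed
statistical structure, as pure functions of (seed, config):

- **Catalogue**: default origin counts 295 germline-only / 603
  somatic-only / 58 dual, the disjoint-count convention (it is the one
  consistent with a 956-mutation total); keys are unique by
  construction so the file round-trips to exactly these counts.
- **Energies**: per-origin normal ΔΔG distributions (defaults: germline
  mean 1.0, somatic mean 2.0, SD 1.5 kcal/mol — overlapping, with the
  somatic mean higher, the emulated effect direction); 65% structural
  coverage; 82% surface; a class mix whose interaction:folding ratio
  among significant classes is ≈65:35; ~3% literature-flagged. The
  drawn ΔΔG lands on the term kind of the drawn class, with
  sub-threshold noise elsewhere.
- **MSAs**: per-column residue distributions from the
  point-mass/uniform mixture family solved (Brent) to hit an exact
  target entropy, so empirical column entropies converge to the profile
  as depth grows; the first sequence is the ungapped dominant-residue
  target.
- **Fold changes**: a GAP-insensitive oncogenic-like reference
  (GAP fold 0.001, intrinsic hydrolysis 0.2), pure GAP-loss variants,
  and partly compensatory variants sharing the same GAP loss plus a
  moderate GEF loss (0.4/0.6) — chosen so the compensatory mechanism is
  present by construction: reduced deactivation dominates, and the added
  GEF loss pulls the readout back toward wild type.

What the generator does **not** emulate: real per-gene mutation
hotspots, structural contact maps, phylogenetic correlation between
alignment rows (residues are drawn i.i.d. per column), or non-normal
ΔΔG tails. Passing tests therefore demonstrate correctness of the
pipeline's logic and numerics under the assumed statistical structure,
not performance on real curated catalogues.

## Numerical choices

- Steady-state tolerance 10⁻⁹ molecules/s; acceptance-level invariance
  checks at 10⁻⁶ relative.
- Relative differences are measured as |a−b|/max(|a|,|b|,1), so
  near-zero abundances are compared absolutely.
- Interval membership in variant comparisons uses the closed interval
  with a 10⁻⁹ relative slack for solver round-off at the endpoints.
- Energy-table I/O writes floats at full precision (`%.17g`) so files
  round-trip exactly.
- Problem sizes in the test-suite and acceptance checks (10,000
  classifier records, 100 random kinetic parameter sets, a 27-point
  ordering grid, 500 power replicates) were chosen as the smallest sizes
  at which the corresponding statistical checks are sharp.

## Known limitations

- The force field itself is out of scope: ΔΔG values are inputs, and the
  package inherits their error model only through the 0.8/1.6 kcal/mol
  tier conventions.
- The classifier resolves one dominant mechanism per mutation; genuinely
  composite effects are visible only through the retained term list.
- The sequence-triage combination rule is a deliberate simplification;
  cohort-mean thresholds make verdicts depend on cohort composition.
- The kinetic model has no MEK/ERK cascade, no membrane recruitment
  dynamics and no stochasticity; conclusions are about relative
  steady-state effector engagement, not signalling dynamics.
- Default kinetic parameters are representative, not fitted; absolute
  RasT·EFF values move with them, though the variant orderings tested
  are robust across the parameter grids exercised.
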