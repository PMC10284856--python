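# Methods

This note documents the models implemented in `foldtrap`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Refolding kinetics (`foldtrap.kinetics`)

**Model.** Refolding assays report percent refolded versus time; after
`p_nn = (100 − %refolded)/100` the decay of the non-native population is
modelled as two parallel folding pathways with no interconversion:

    P_NN(t) = a0·exp(−k1·t) + a1·exp(−k2·t),   a0 + a1 ≡ 1.

`a0`, `a1` are the initial fast- and slow-folding (misfolded)
populations; `k1 ≥ k2 ≥ 0` their folding rates.  The sum-to-one
constraint is enforced by substitution (`a1 = 1 − a0`), never penalized.

**Fitting.** Rates are optimized as log10 values with box bounds
[−30, 2] so that extremely slow folders (time constants of 10¹⁶ minutes
and beyond) are representable without underflow.  A bounded trust-region
least-squares solve is started from a small grid: `k1` from the first
e-fold crossing time of the curve, `k2` from `duration⁻¹·10⁻ᵐ`,
m = 0…6; the best start by SSE wins.  If the optimizer returns
`k2 ≈ k1` the amplitude split is unidentifiable (the model degenerates
to one exponential) and the fit is collapsed to `a0 = 1` with `k2`
flagged `unidentifiable`.

**Measurability.** When `k2·t` stays near zero over the whole course,
first-order Taylor expansion shows the slow term is a plateau plus a
linear drift of slope `a1·k2`; a tenth of a slope change over the
experiment is taken as the resolvable limit, so
`k2_min = 1/(10·duration)` — a 100-minute course resolves decay times up
to 1000 minutes.  Fits below the limit are flagged `lower-bound-only`
and should be read as order-of-magnitude statements; the plateau `a1`
remains identifiable in this regime (zeroth-order Taylor form), which
the recovery tests exercise directly.

**Slow-rate bounds.** Published error bars rarely come with a
propagation recipe, so bounds on `k2` are obtained by refitting the
model to the data envelopes `p_nn ± σ` (reported errors, else a flat 1 %
in probability units) and taking the extreme `k2` of the two envelope
fits.  This envelope-refit construction is an interpretation — it brackets
the systematic effect of a uniform offset, not the full sampling
distribution.

**Residual randomness.** The Wald–Wolfowitz runs test is applied to
residual signs, one-sided toward *too few* runs: clustered residuals are
the signature of a structurally wrong (e.g. single-exponential) model,
while alternation is consistent with noise.  Verdict `non-random` at
p < 0.05.

**Unit conversions.** `time_constant_order` maps `k2` to
`10^round(log10(1/k2))` minutes (half rounded away from zero).  The
package reports its own conversions only; 10¹⁶ minutes ≈ 1.9·10¹⁰ years.

**Limitations.** With evenly spaced sampling and durations much longer
than `1/k1`, few points sample the fast phase, so `k1` recovery degrades
even where `a1` stays accurate; the acceptance script reports both
errors separately.

## GroEL/GroES ATP cycle (`foldtrap.groel`)

**Reaction scheme.** A single GroEL ring binds a bundle of 7 ATP
(treated as one species), captures an unfolded client, is capped by
GroES, hydrolyses the ATP, and releases the client partitioned into
folded/misfolded/unfolded states with per-cycle probabilities `φ_F`,
`φ_M`, `1 − φ_F − φ_M`.  A bulk channel (`k6`) folds clients
spontaneously with its own coefficients, and a futile basal cycle
(`k7` hydrolysis without client, `k8` ADP release) consumes ATP.  The
basal cycle is implemented as `G·7ATP → G·7ADP → G`, the form consistent
with the rate definitions and with exact conservation of total GroEL;
with this form, total client, total GroEL and total GroES are conserved
identically (verified numerically to ≤10⁻⁶ relative across random
parameterizations) and free ATP is nonincreasing.

Client conservation holds exactly only when the bulk pair satisfies
`φ_F^bulk + φ_M^bulk = 1`: the bulk channel drains U at rate `k6` but
re-deposits only the φ-weighted fractions.  Tests therefore draw bulk
pairs summing to one; incomplete bulk partitioning models an unobserved
loss channel and is allowed but breaks the client total.

**Numerics.** LSODA with rtol 10⁻⁸, atol 10⁻¹⁰ µM (both exposed);
negative excursions within tolerance are clipped.

**ATP accounting.** Free ATP is stored as bundles; reported consumption
multiplies by 7 (`bundle7`, default) or not (`literal`) — the convention
is a config flag because downstream µM-level claims depend on it.

**Partition-coefficient fit.** For each experiment, `φ_F` is scanned on
the literal grid 0.001…1.001 step 0.001 (the odd endpoint is kept for
fidelity; it is always removed by the feasibility rule), `φ_M` is tied
to the experimental plateau through
`φ_M = P_eq/(1 − P_eq)·φ_F` with `P_eq` the non-native probability at
the final time point (an option averages the last two), candidates with
`φ_F + φ_M > 1` are discarded, and each survivor is integrated and
scored against the data: maximal Pearson r², ties broken by total
absolute error.  On model-generated curves the grid fit recovers the
planted `φ_F` to grid resolution (±0.001), which is the recovery check
the acceptance script performs.  Simulated curves are compared as
`P_NN^sim(t) = 1 − [F](t)/[U]₀`.

**Units.** Bimolecular rates are µM⁻¹·min⁻¹, unimolecular min⁻¹; the
config requires explicit values and the module never guesses units.

## Binding analysis (`foldtrap.binding`)

**Bound classification.** Frames with at least `threshold` intermolecular
contacts are bound; `P_complex` is the bound-frame fraction.  Thresholds
are recordable inputs; when unspecified, a two-means split of the contact
histogram supplies a default.  On well-separated two-state data the
resulting `K_D` is insensitive (<5 %) to the threshold across the
inter-mode gap.

**Dissociation constant.** With one chaperone and one client in the
simulation volume, `P_chap = P_client = 1 − P_complex` and

    K_D = ((1 − p)²/p) · (1/V[Å³]) · 1/(6.022·10²³ · 10⁻²⁷)   mol/L.

Default volumes are spheres of radius 160 Å (GroEL geometry) or 200 Å
(DnaK/HtpG), both overridable.  Half occupancy in the 160 Å sphere gives
≈ 48 µM.  Trajectories with occupancy exactly 0 or 1 carry no finite
`K_D` and are reported censored, never extrapolated.  Replicate sets get
a t-based 95 % CI and optional log2 ratios to a reference state.

**Odds ratios.** `OR = (P_X,on/P_X,off)/(P_F,on/P_F,off)` compares how
much switching the attractive chaperone interaction on changes binding
for conformation X versus the folded reference.  With replicate-level
probabilities, a two-tailed one-sample Student t-test on the replicate
log odds ratios against zero supplies the p-value (replicates paired by
index; an interpretation, since the source only names the test family).

**Permutation test on K_D groups.** Two-tailed, difference of group
means, exact enumeration of label reassignments when feasible (ties
count as exceedances, so identical groups give p = 1), otherwise random
shuffles.  Type-I error at nominal 0.05 is calibrated in-suite.

## Coarse-grained energy (`foldtrap.energy`)

A static evaluator (no dynamics) for the six-term Cα potential: harmonic
bonds; a four-fold cosine torsion series; a double-well angle term
blended by a log-sum-exp with sharpness γ (defaults kα = 106.4, θα =
1.60 rad, εα = 4.3, kβ = 26.3, θβ = 2.27 rad, γ = 0.1, all overridable);
Debye–Hückel electrostatics with l_D = 10 Å, ε_r = 78.5 and charges +e
for Lys/Arg, −e for Glu/Asp, 0 otherwise; and 12-10-6 contact terms
`ε·(13(σ/r)¹² − 18(σ/r)¹⁰ + 4(σ/r)⁶)` for native (per-pair ε, σ from a
parameter table) and non-native pairs (ε = 0.000132 kcal/mol).

Two facts about the 12-10-6 form worth recording: its minimum sits
exactly at `r = σ` with depth −ε (the 13/−18/4 coefficients are chosen
for that), and it carries a small desolvation barrier near `r ≈ 1.45 σ`.
Under the convention that σ is the native Cα distance divided by 2^(1/6),
the modelled minimum therefore sits slightly inside the
crystallographic contact distance; the evaluator takes σ from its input
table and does not reinterpret it.  Nonbonded exclusion (default:
sequence separation < 4) is configurable because it is inherited from
the parameterization lineage, not derivable.

## Entanglement topology (`foldtrap.topology`)

**Native contacts and Q.** Contacts are Cα pairs within 8 Å and ≥4
residues apart (both defaults configurable); an optional
secondary-structure mask restricts pairs to masked-in residues (masks
are caller-supplied; no assigner is embedded).  A contact is formed in a
frame when its distance is ≤1.2× the native distance.  `Q_mode` is the
per-window mode of Q over bins of width `1/N_contacts` (stride one
frame, ties toward higher Q); a trajectory is long-lived misfolded iff
no window mode reaches the native-ensemble reference `⟨Q_mode^NS⟩`.

**Linking numbers.** For a native contact (i, j), the backbone loop
i…j is closed by a straight virtual segment and compared against the
N- and C-terminal tails, skipping the 5 residues adjacent to each loop
terminus (a convention to suppress spurious near-loop contributions;
configurable).  The Gauss double integral is discretized over segment
pairs by the midpoint rule

    g = 1/(4π) Σᵢ Σⱼ (Rᵢ − Rⱼ)·(dRᵢ × dRⱼ)/|Rᵢ − Rⱼ|³,

accurate for chains discretized at Cα spacing (test fixtures are
validated against an independent dense-quadrature oracle; agreement
before rounding is well inside 0.05).  Partial (per-tail) and total
linking numbers are rounded half-away-from-zero before any comparison.

**G metric.** Over the N native contacts, G counts those formed in the
current structure whose rounded total linking number differs from the
native structure's, divided by N.  G ∈ [0, 1], is invariant under rigid
motions, equals 0 for the native self-comparison and 1/N when exactly
one formed contact changes linking state.

**Crossings, change types, clustering.** Crossing residues are localized
as the tail segments carrying the dominant per-segment Gauss
contribution (one per unit of linking) — an approximation to piercing
tests on triangulated minimal surfaces, adequate for well-separated
crossings.  For a loss of entanglement the native structure supplies the
crossings; for a gain, the current one.  Per-tail change types are the
categorical {none, gain, loss, switch} derived from rounded partials
(the finer taxonomy of the lineage codes is collapsed onto this
interpretation).  Degenerate changes are merged when they agree on all
six discrete parameters (crossing counts, rounded partials and change
types per tail) *and* all crossing residues lie within ±5 residues;
each cluster is represented by its minimal-loop member (ties: smaller
loop start).

**SASA.** Shrake–Rupley accessibility with golden-spiral sampling
(default 960 points/bead, <1 % error against the single-sphere closed
form), per-residue radii supplied by the caller, probe 1.4 Å.  ΔSASA
between two structures is the per-residue difference; for cut-site
comparisons the mean over the cut site ±5 window is used by default
(cut-site-only is available).

## LiP-MS consistency (`foldtrap.lipms`)

**Statistics.** For entanglement e and significant peptide l, `O[e,l] = 1`
iff the Jaccard index between the residues within ±5 of l's PK cut site
and the residues within 8 Å of e's crossing residues is positive;
`S[e,l] = 1` iff additionally the sign of the simulated exposure change
of the cut-site region equals the sign of the peptide's log2
refolded/native ratio (a zero on either side never agrees — the sign
function's zero case is undefined in the source and resolved
conservatively).  Per-timepoint means `⟨O⟩_t`, `⟨S⟩_t` are the test
statistics; `S ≤ O` elementwise by construction.

**Null model.** Candidate half-tryptic peptides are enumerated from the
sequence (PK cut paired with the nearest up/downstream trypsin site);
each carries an intrinsic cut propensity
`P_intrinsic(AA) = P_observed(AA)/P_proteome(AA)` (zero-frequency types
excluded with a warning) and a length/internal-trypsin-site probability.
`sample_random_cutsites` implements the literal two-uniform rejection
sampler (propensities scaled by their maximum to form acceptance
probabilities, accepted draws accumulating into a unique cut-site set).
Inside the permutation loop the mathematically equivalent form is used:
keeping first-seen sites from with-replacement draws is weighted
sampling without replacement with per-site aggregated weights, which
Gumbel-top-k implements exactly and vectorizes.

**Permutation rule and its behaviour.** For each permutation, random cut
sites are redrawn per timepoint (a flag reuses one set across
timepoints), matching the observed number of unique sites per timepoint;
random sites inherit the observed peptides' ratio signs (the source
leaves the sign pairing unstated).  A draw is "more consistent" when it
strictly exceeds both observed statistics at two or more timepoints, one
of them the longest; p is the fraction of such draws, with no continuity
correction, read at p < 0.05.

This rule is the probability of a conjunction event, not a rank
statistic, and that has a measurable consequence: under a fully
exchangeable null (observed cut sites drawn from the same theoretical
distribution as the permutation draws), the per-timepoint exceedance
probabilities behave like products of uniforms, so p concentrates near
zero and the rejection rate at nominal 0.05 is far above 0.05 (the test
suite and acceptance script measure ≈0.5).  The rule is therefore a
consistency *score* with excellent sensitivity — planted-signal datasets
are flagged at p < 0.05 essentially always — but its p-values are not
calibrated type-I error rates and should not be reported as such.  The
implementation keeps the rule as defined; the calibration expectation is
asserted (and fails honestly) in the acceptance suite.

## Synthetic data (`foldtrap.synthetic`)

The generators define the study conditions for all tests:

- **Time courses** — exact forward model plus i.i.d. Gaussian noise
  (default sd 0.01 in probability units, mirroring the 1 % fallback
  uncertainty convention), clipped to [0, 1] after noise; durations
  default to 150 min (the meta-analysis range 30–600 min is sampled in
  the recovery checks).
- **Contact trajectories** — two-state Markov chains with the requested
  stationary bound probability and geometric bound dwells; contact
  counts are Poisson around state means (60 bound / 3 unbound by
  default).  The Poisson choice is a stand-in: the source only exhibits
  two-state behaviour, never a count distribution.
- **Toy links** — a planar bead circle threaded (or not) by a straight
  perpendicular chain through its centroid, joined by a below-plane
  spacer; the simplest geometry with a provable |link| = 1, with the
  thread orientation set to carry the requested chirality.  Outputs are
  validated against the independent dense-quadrature Gauss oracle, not
  against the production code.
- **LiP-MS tables** — random sequences, per-timepoint unique cut sites
  drawn by residue-type propensity, half-tryptic spans to the nearest
  trypsin site, planted abundance-ratio signs within ±5 of effect
  sites; plus a complete consistency scenario (extended chain,
  entanglement records, exposure-change profile, cut-site model) for
  null-calibration and power studies.

All generators take explicit seeds and are bit-reproducible; none of
them emulate MD integration, ribosome synthesis, thermal denaturation,
autocorrelated experimental noise, or peptide-level missingness of real
LiP-MS data — so passing tests demonstrate correctness of the analysis
machinery under the stated models, not robustness to those real-data
features.

## Problem sizes

The default verification runs use 100 synthetic fits for amplitude
recovery, 50 random parameterizations for conservation checks, 20 rate
sets for φ recovery, 2·10⁵-frame trajectories for K_D equivalence, and
200–1000 datasets × 1000 permutations for the LiP-MS calibration and
power measurements — sizes chosen so the whole suite completes in
minutes on one CPU while keeping Monte-Carlo error well inside the
asserted tolerances.
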