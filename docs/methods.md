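# Methods

This note documents the models, conventions and numerical choices behind
`geomine`, in the order the pipeline runs them.

## Scope and data model

The package covers the *computational* stages of an integrative
genomic-mining and enzyme-engineering workflow for ketoacid decarboxylases:
it consumes protein sequences plus externally computed scores (TM-scores
from structural superposition, protein–ligand interface energies in
Rosetta-energy-unit-like scales from docking/design simulations), and
published kinetic and fermentation measurements.  It does not run homology
search, structure modelling, docking, multiple sequence alignment programs,
or any wet-lab step; those products are typed inputs
(`SequenceRecord`, `GeoCandidate`, `DockingScoreTable`, kinetics and titer
tables).

## Pairwise identity and clustering

Identity between two sequences is computed from one optimal global alignment
under BLOSUM62 with gap open 11 and gap extension 1 (Biopython
`PairwiseAligner`), as the count of identical aligned residue pairs divided
by the length of the shorter sequence.  This is the convention of greedy
deduplication tools (CD-HIT defines identity against the shorter sequence),
which is the semantics the dedup stage needs.  `X` never counts as a match.
The alignment is computed on the lexicographically ordered pair, so the
function is exactly symmetric even when alignments are co-optimal.

Deduplication is incremental greedy clustering: records are visited in
length-descending order (ties by id), and each record joins the first
existing representative whose identity is **at or above** the threshold,
else founds a new cluster.  The threshold comparison is inclusive (≥),
matching the invoked tool family's convention; the default deduplication
threshold is 0.90 and the diversity-selection stage reuses the same
procedure at 0.40.

A caveat worth knowing: with the shorter-length denominator, a perfect
substring scores identity 1.0 against its supersequence.  For the
equal-length simulated families this case cannot arise.

The pairwise-identity histogram uses 5-percentage-point bins over [0, 1];
the mode is reported as the midpoint of the most populated bin, ties broken
toward the lower bin.  Note that under this alignment convention two
*unrelated* 200-residue protein sequences already score ≈ 0.19 identity
(gaps let spurious matches accumulate); a deeply diverged single-fold
family therefore shows a mode in the 0.20–0.25 bin largely because measured
identity saturates at the twilight-zone floor.

## Filters

Candidates are kept iff TM-score is **strictly** greater than the cutoff
(default 0.5, the usual same-fold criterion) and, when the taxonomy filter
is on, the candidate is not labelled `Eukaryota` (eukaryotic sequences are
poor candidates for soluble expression in *E. coli*).  The filter returns an
explicit rejection log; kept ∪ rejected is always a partition of the input.

## Docking-score reduction and candidate selection

Each candidate's docking table (one row per simulated model: total protein
energy, protein–ligand interface energy) is reduced in two stages: the 100
rows of lowest total energy are retained — ties at the boundary broken by
model index, ascending, a convention this package fixes because the
upstream protocol does not — and the minimum interface energy within that
subset is the candidate's score.  With `n_keep` ≥ table size this equals the
unconditional minimum.

Selection takes `k_energy` = 5 candidates of lowest interface energy (ties
by id), then greedily clusters the remainder at 40% identity; each cluster
contributes its lowest-energy member as representative, and the five
lowest-energy representatives are the diversity picks.  Reading "the
filtered list" as the clustered survivors, with each cluster represented by
its best member, is this package's interpretation; only the stated
40%-filter-then-lowest-energy rule is implemented, with no manual curation
stage.

Bar heights for tree annotation are the linear map
h = (E_max − E)/(E_max − E_min), so the lowest energy gets height 1 and the
highest 0.  An all-equal input maps to all 1.0 (the "relative to the
lowest" reading, avoiding 0/0); heights are invariant to adding a constant
to all energies.

Designed mutations are reverted to the native residue unless they improve
the interface energy by **strictly more than** 2.0 energy units
(improvement = −Δ interface energy).

## Phylogenetics

Distances are d = 1 − identity with no multiple-substitution correction:
the tree is a visual grouping device over a diverse family, not an
evolutionary-rate estimate, and any monotone transform yields the same
grouping structure.  Trees are built with Saitou–Nei neighbor joining;
negative branch-length estimates are clamped to zero with the deficit
transferred to the sister branch, preserving the joined pair's summed
length.  The pair to join is the first minimum of the Q-matrix in row-major
order, making the output deterministic for tied inputs.  For additive
matrices NJ recovers the generating topology and path lengths exactly
(tested via Robinson–Foulds distance 0 against the generating trees, and
against scikit-bio's independent NJ implementation).

Rooting splits the reference leaf's pendant edge at its midpoint, so total
tree length and all leaf-to-leaf path lengths are unchanged.  Newick export
uses 6-decimal fixed-precision branch lengths and no internal node labels;
per-leaf bar heights go to a sidecar TSV (leaves without an annotation get
height 0).

## Library design

A design profile is the per-position set of residues observed across the
(deduplicated) design sequences, minus the native residue.  The library is
every single substitution plus, for every pair of design positions whose
sequence-index difference is at most the pairing window (default 5,
"within five residues" read literally on positions), every cross-product
double substitution.  Triples are never generated, even when three
positions are mutually within the window.  Variants are deduplicated and
sorted by (first position, first residue, second position, second residue).

Coverage is the **expected per-variant inclusion probability** under uniform
sampling with replacement: 1 − (1 − 1/N)^n, which equals the expected
covered fraction of the library, approaching 1 − e⁻³ ≈ 95.0% at n = 3N.
This per-variant reading is deliberate and documented prominently: the
probability that *every* variant is present at n = 3N tends to 0 for large
N, so "pick 3N colonies for ~95%" is only coherent as expected coverage.

The activity screen passes a variant when its activity is at least 1.25×
wild type on any tested substrate ("25% higher" read as inclusive ≥).

## Kinetics

Initial-velocity curves (≥ 5 substrate points, concentrations in mM,
velocities in M/s, enzyme concentration in M) are fitted by nonlinear least
squares to v = k_cat·E₀·S/(K_M + S), or with the + S²/K_i denominator term
for substrate inhibition.  Numerics: the fit is performed on the turnover
rate v/E₀ (s⁻¹ scale) so the optimizer's relative termination criteria are
well-conditioned — fitting raw molar velocities (~10⁻⁵ M/s) can terminate
at the starting point; initial guesses are V_max⁰ = max observed v,
K_M⁰ = the first S where v ≥ V_max⁰/2, K_i⁰ = max S; parameters are bounded
non-negative; tolerances 10⁻¹². Non-convergence is returned as a flagged
result with NaN parameters, never silently.  Standard errors come from the
covariance at the optimum; the substrate-inhibition fit reports a
least-squares AIC difference against the plain fit.  Noiseless synthetic
curves are recovered to ≈ machine precision, and the nested-model limit
(K_i → ∞) reproduces the plain fit.

Catalytic efficiency is k_cat/K_M in M⁻¹s⁻¹ (K_M converted mM → M), with a
delta-method standard error including the k_cat–K_M covariance.  Values
below the 0.2 M⁻¹s⁻¹ detection limit are left-censored.  Reported values
are rounded to 2 significant figures; exact values are retained internally.

Censored statistics: censored efficiencies participate in medians **by
rank only**, below every detected value, so the result is invariant to the
placeholder magnitude.  An even-count median whose central value is
censored is itself censored.  Fold ratios with a censored denominator are
reported as lower bounds evaluated at the detection limit.  This rank-based
censoring is required to reproduce the published mined-versus-naive median
comparison (≈ 74–75-fold); simply excluding the censored enzyme gives
≈ 7.6-fold, an order of magnitude off.

The specificity factor is SF = ½[log₁₀(eff_C8/eff_C5) +
log₁₀(eff_C8/eff_C3)] — a reconstruction consistent with its description as
a comparison of log-scaled C8 efficiency against C5 and C3; multiplying the
C8 efficiency by 10 raises SF by exactly 1.  Specificity improvement
between two enzymes is the ratio of their C8/C5 (or any stated pair)
efficiency ratios.

### Consistency of the published constants

For published rows the bundled table keeps the printed decimal *strings*.
Each printed number is treated as an interval of half a unit in its last
significant digit (trailing integer zeros non-significant: 32,000 → ±500).
A printed efficiency is accepted as consistent when the interval of
k_cat/K_M computed from the printed k_cat and K_M intervals overlaps the
printed efficiency's interval.  This matters: several published
efficiencies were evidently computed from unrounded fit parameters, so an
exact 2-significant-figure re-derivation from the rounded constants fails
(e.g. k_cat 7 s⁻¹ / K_M 0.21 mM gives 33,333, printed 32,000), while every
complete row passes the printed-precision interval test.

## Product profiles

An alcohol counts as quantified only when **all** replicates are at or
above the limit of quantitation (default 5 mg/l).  All percentages and the
longer-chain fraction use the total over the strain's quantified alcohols
as denominator — the only convention that reproduces the published per-
alcohol shares (hexanol 47%, heptanol 50%).  Percentages are rounded to
integers, half away from zero; exact fractions are kept alongside.
"Longer-chain" means chain length ≥ 5 by default.  Profile comparisons
report per-alcohol folds; a below-LOQ denominator yields a lower bound at
the LOQ, never a division error.  Note the published longer-chain subtotal
for the discovered-enzyme strain (522 mg/l) is the sum of its three major
longer-chain products (pentanol + hexanol + heptanol); the ≥ C5 sum
including the 10 mg/l octanol is 532 mg/l, and the >95% longer-chain yield
(96.6%) only holds with octanol included.  The summary exposes per-alcohol
titers so both readings are available.

## Synthetic data

The generators define the study conditions for all pipeline tests; every
generator is a pure function of a spec plus one integer seed (one
`numpy.random.default_rng` stream per generator) and returns ground truth
sufficient for recovery tests.

* **Families** evolve i.i.d. sites along a binary guide tree (balanced, or
  random sequential pair-joining with exponential height increments
  normalized to the tree depth).  Per branch, each site draws a
  Poisson(rate × length) number of substitution events, each replacing the
  residue uniformly among the other 19.  Defaults: 120 sequences of length
  200, root-to-leaf depth 1.0, rate 1.0 — placing most pairs past the
  twilight zone so the identity mode sits near 20%; clade fraction 0.15
  (the subtree closest in size to that fraction is the planted functional
  clade); 10% of leaves labelled eukaryotic so the taxonomy filter has work
  to do.
* **Scores**: additive Gaussian energies around a clade mean (−12) and a
  background mean (−2), noise SD 1; TM-scores uniform in [0.55, 0.95].
  Matching the one-s.d. style of the published tables, energies and titers
  use additive noise and velocities multiplicative noise.
* **Kinetics**: the default grid spans 0.005–10 mM (the assayed range) with
  10 points; 5% multiplicative Gaussian velocity noise; enzyme 1 µM.
* **Designs**: at each design position a design draws uniformly from the
  allowed alphabet plus the native residue.
* **Titers**: replicate draws (default 3) with additive Gaussian noise,
  clipped at zero, flagged against the LOQ.

What the generators do **not** emulate: real substitution processes (no
rate heterogeneity, no indels — simulated sequences stay equal-length, so
alignment gaps only arise spuriously), real Rosetta energy magnitudes
(ordering only), correlated assay errors, or fermentation dynamics.
Passing tests therefore demonstrate the pipeline's logic and statistical
machinery, not performance on real mined families.

## Problem sizes

Analysis scripts use an 80-sequence family of length 200 (the identity
matrix is the O(n²)-alignment bottleneck; 80 sequences keep a full run
under a minute), 50 designs over 10 positions, 200–500 replicate fits, and
Monte-Carlo cross-checks of a few hundred trials.  These sizes are the
package's defaults for demonstration; all operations accept larger inputs.

## Known limitations

* Identity is alignment-based but uncorrected; trees built from it
  compress large distances (saturation), which is acceptable for grouping
  but not for divergence-time reasoning.
* The greedy clustering is order-dependent by construction (that is the
  tool semantics being mirrored), so cluster *membership* can differ from
  other tools at borderline identities even when representatives agree.
* The substrate-inhibition fit reports a least-squares AIC comparison, not
  an F-test; with ≤ 10 points both are indicative rather than decisive.
* Censored efficiencies are handled rank-wise only; no parametric
  likelihood for left-censored values is attempted.
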