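# Methods

## Model

A distance-dependent pairwise statistical potential assigns a model the
score

S = Σ<sub>pairs (i,j)</sub> u<sub>i,j</sub>(r<sub>ij</sub>)

over all heavy-atom pairs whose residues are at least 4 positions apart
in the chain and whose distance is strictly below 15.0 Å. The per-bin
term u compares the pair-type-specific distance frequency
f<sub>i,j</sub><sup>OBS</sup>(r), estimated from native structures, with a
type-indistinct reference f<sup>REF</sup>(r). Four terms are implemented
(PMF, TIG, MCK1, MCK2; see README for the formulas). All four vanish
when f<sup>OBS</sup> = f<sup>REF</sup> > 0, are negative where a distance
is over-represented for that pair type, and positive where it is
under-represented. Lower totals mean more native-like; scores are
dimensionless and not length-normalized, since ranking happens within
one target where chain length cancels.

Undefined cases take a fixed default of +10: f<sup>REF</sup> = 0 for every
formalism, and additionally f<sup>OBS</sup> = 0 for PMF (log of zero).
MCK1 and MCK2 are defined at f<sup>OBS</sup> = 0 (values +2 and +1) and
only their 0/0 case defaults. TIG at f<sup>OBS</sup> = 0 equals exactly
+1, which separates "this pair type was never seen at this distance"
(+1) from "no atoms at all were ever seen at this distance" (+10).

## Training pipeline

1. **Parsing.** One chain per entry; heavy atoms of the 20 standard
   residues only; first MODEL block; alternate locations resolved to the
   highest-occupancy conformer (ties → first encountered); residues
   renumbered 0..n−1 in order of appearance so numbering gaps and
   insertion codes cannot inflate sequence separation. Nonstandard
   residues (e.g. MSE) are dropped with a warning — the type alphabet
   must stay closed.
2. **Pair collection.** Every unordered pair with |Δindex| ≥ 4
   (min_separation, exposed as a parameter) and d < 15.0 Å (strict, so
   the last bin [14.5, 15.0) is well defined), grouped by the
   canonicalized (residue, atom) × (residue, atom) key.
3. **Frequency estimation.** Per pair type, a Gaussian KDE with Scott's
   rule-of-thumb bandwidth h = 1.06·min(sd, IQR/1.349)·n^(−1/5),
   computed per pair type (each sample gets its own bandwidth). Bin
   frequencies are the kernel's exact mass inside each 0.5 Å bin
   (difference of normal CDFs at the bin edges), renormalized over
   [0, 15): smoothing mass that leaks past the cutoff is discarded by
   the renormalization. Bin-integration rather than center-point
   evaluation was chosen because it converges exactly to the histogram
   as h → 0 and matches analytic bin masses on known distributions —
   both used as test oracles. A degenerate (zero-spread) sample puts
   frequency 1 in its single bin; fewer than 2 observations mark the
   pair "insufficient" (all-zero vector, excluded from the reference and
   from scoring; min_count, default 2, is configurable).
4. **Frequency floor.** Bin masses below 1e-9 are zeroed and the vector
   renormalized. Kernel tails at many bandwidths' distance from any
   observation carry masses like 1e-45; treating those as genuine
   support would let ratio-based terms amplify pure floating-point
   noise. A mass below the floor is "numerically unobserved", which is
   exactly the regime the +1/+10 plateau rules are for. No pseudo-counts
   are added anywhere.
5. **Reference state.** The count-weighted arithmetic mean of the
   sufficient per-pair vectors — the unique weighting for which the
   reference equals the pooled, type-indistinct distribution. It is kept
   exactly as that mean (no floor applied afterwards) so the convexity
   and exactness invariants hold bit-for-bit.

The trained table round-trips through a TSV file bit-exactly (floats
written with shortest-round-trip repr).

## Scoring

Scoring reuses the training pair filters (selection and min_separation
default to the table's metadata; explicit mismatches warn). Pairs whose
type is absent from the potential contribute 0 and are counted as
skipped: absence is a training-coverage gap, not evidence about
nativeness. Score ties between two models count as incorrect in the
pairwise benchmark (conservative).

## Benchmark statistics

* **Pairwise accuracy.** Within each target, all unordered model pairs
  with true-quality difference ≥ 0.1; a pair is correct when the lower
  score belongs to the higher-quality model; accuracies are pooled over
  targets (100·correct/total). Categories (near-native ≥ 0.8, good
  ≥ 0.6, medium ≥ 0.4, poor < 0.4; boundaries belong to the upper
  category) are assigned to a pair via its higher-quality member by
  default — requiring both members in-category would leave near-native
  rows a sliver, since pairs must differ by ≥ 0.1. The assignment rule
  is a config option (higher | lower | both).
* **Average predicted rank.** Models ranked ascending by score within a
  target (ties → average ranks); category members' ranks averaged per
  target, then over targets having that category.
* **Correlation.** Per-target Pearson r between score and quality,
  unweighted mean over targets; zero-variance targets are skipped with a
  warning. Good scorers give negative r.
* **Method comparison.** Two-sided Wilcoxon signed-rank on paired
  per-target accuracy percentages, zero differences dropped; all-zero →
  p = 1. Per-target accuracies (rather than pooled binary outcomes) were
  chosen as the test unit so targets, the independent sampling units,
  are what is paired.

## Synthetic data

The generator emulates the features of real single-domain chains that a
distance potential actually consumes, and nothing more:

* **Natives.** Cα traces with 3.8 ± 0.05 Å virtual bonds; self-avoiding
  (no non-bonded pair < 3.5 Å); "mixed" folds use a centroid-biased
  self-avoiding walk giving compact globules (R<sub>g</sub> ≈ 2.5·n^0.4),
  plus ideal α-helix and plain random-walk fold types. Default lengths
  80–250 residues. An optional pseudo-CB (1.53 Å, pointing away from the
  chain) exercises multi-atom typing.
* **Residue assignment.** Identities are drawn from a Swiss-Prot-like
  composition *tilted by burial*: the draw probability is multiplied by
  exp(−1.5·hydropathy·z), z the standardized distance from the centroid
  (Kyte–Doolittle hydropathies scaled to [−1, 1]). This couples residue
  type to geometry — hydrophobic core, polar surface — which is the
  signal a knowledge-based potential learns. Without it every pair type
  would share one distance distribution, f<sup>OBS</sup> ≡ f<sup>REF</sup>,
  and all scores would be indistinguishable from noise by construction.
* **Decoys.** I.i.d. Gaussian coordinate noise of chosen sigma; graded
  sigmas (0.5–12 Å by default) span the quality scale from near-native
  to poor. Clashes at high sigma are kept: they are the non-native
  signal the short-range plateaus penalize.
* **Toy quality.** Optimal least-squares (Kabsch) superposition of Cα
  sets, then q = (1/L) Σ 1/(1 + (d_i/d0)²) with
  d0 = max(1.24·(L−15)^(1/3) − 1.8, 0.5); the d0 floor avoids degenerate
  short-chain behaviour. This assumes equal length and fixed residue
  correspondence — it is not the published TM-score algorithm (no
  alignment search or iterative seed extension).

What passing on synthetic data does **not** show: real side-chain
packing, secondary-structure-specific geometry, sequence-dependent
backbone conformations, or realistic decoy generation (fragment-based
decoys differ from Gaussian noise). Synthetic results validate the
machinery and its statistical behaviour, not absolute accuracy levels on
experimental decoy sets.

## Numerical choices and problem sizes

* Bins are half-open [k·0.5, (k+1)·0.5); the cutoff comparison is
  strict (<) so every distance maps to exactly one bin.
* kT = 1 is hard-coded in the PMF term; the constant only rescales
  scores and cannot change rankings.
* Whole-structure sums use float64 accumulation over vectorized per-pair
  groups; the test oracle compares against `math.fsum` of a double-loop
  enumeration at 1e-9 relative tolerance.
* The acceptance script uses 100 targets × 50 decoys at 60–120 residues
  for the random-scorer baseline (≈105,000 qualifying pairs); the
  end-to-end recovery test trains on 50 natives of 80–250 residues and
  evaluates 10 held-out targets × 30 heavy-noise decoys. These sizes
  give stable statistics (random-scorer accuracy varies by ≈ ±0.2
  percentage points across seeds) at interactive runtimes.

## Known limitations

* PDB input only (wwPDB v3.3 ATOM records); no mmCIF, no structure
  repair, no NMR multi-model averaging, no symmetry expansion.
* No radius-of-gyration or molecular-volume reference-state corrections;
  the reference is the plain pooled mean, which carries the training
  set's size bias.
* Scott's bandwidth depends on n, so enlarging the corpus legitimately
  sharpens the estimated frequencies; trained tables are comparable only
  at a fixed corpus.
* Sparse pair types (fewer than min_count observations) are silently
  neutral at scoring time rather than informative.
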