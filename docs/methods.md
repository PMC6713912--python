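# Methods

## Model overview

hairpin3d treats miRNA precursor recognition as two-class learning on a
compact structural descriptor. Every candidate hairpin passes through
four stages: secondary-structure prediction, case-coding of pairing
state, embedding as a 3D lattice curve, and reduction to a fixed
36-component vector that the classifiers consume.

## Folding

The built-in engine is a Nussinov-style maximum-base-pairing dynamic
program, not a thermodynamic model. It maximizes the number of allowed
pairs (A–U, G–C, G–U and their mirror images by default) over all
non-crossing pairings, subject to a minimum of `min_loop` unpaired bases
inside every hairpin loop. Defaults and conventions:

* `min_loop = 3` nt — the physical hairpin-loop minimum that
  thermodynamic folders also enforce.
* Lonely (isolated) base pairs are allowed.
* Traceback tie-breaking is deterministic: among co-optimal structures
  the algorithm prefers leaving the rightmost base of the current
  interval unpaired, then pairing it with the smallest admissible
  partner index. Identical input and configuration therefore always
  yield the identical structure.
* A sequence shorter than `min_loop + 2` cannot close a loop and
  returns the all-dots structure with score 0 (not an error).
* The score is the pair count (`score_kind="pair_count"`).

An external thermodynamic folder can be substituted through a small
adapter contract: the command receives FASTA on standard input and must
emit RNAfold-style output (header, sequence, `structure (energy)`); its
minimum free energy in kcal/mol becomes the score
(`score_kind="energy"`). The descriptor and classifier layers are
agnostic to which engine produced the structure. Keeping a self-contained
default folder means the package has no hard external dependency and
every structural computation is exactly reproducible and testable
against brute-force enumeration.

## Case-coding convention

In the characteristic sequence, unpaired (dot) positions keep their
uppercase base letter and paired (bracket) positions become lowercase.
This pairing of dot→uppercase, bracket→lowercase is pinned in one
module-level constant (`UPPERCASE_IS_UNPAIRED`), so the opposite
convention is a one-line switch. The dot-bracket states are retained
alongside the letters: the case alone cannot distinguish the 5' from
the 3' side of a stem, and the descriptor uses that distinction.

## The 3D curve

Each base maps to a corner of {−1, +1}³ with one chemical dichotomy per
axis — purine/pyrimidine on x, amino/keto on y, strong/weak H-bonding on
z — so A = (+1,+1,−1), C = (−1,+1,+1), G = (+1,−1,+1), U = (−1,−1,−1),
and the four vectors sum to zero. A paired base takes the negated
vector of its unpaired form: pairing flips all three chemical axes,
placing bonded and non-bonded occurrences of the same base at antipodal
corners. The curve is the cumulative sum of these steps from the
origin; every step has per-axis increment ±1 (length √3), and the
endpoint equals the sum of all letter vectors. One useful consequence:
in a perfect stem the 3' arm's lowercase complement of a 5' base
contributes exactly the 5' base's unpaired vector (complementary bases
have negated vectors, and pairing negates again), so a clean hairpin's
curve walks out along the 5' arm and back along the 3' arm.

## The 36-component descriptor

Curve points are partitioned into 12 classes — base (A, C, G, U, in that
order) × pairing state ('.', '(', ')', in that order) — and each class k
with n_k points at positions S_k contributes the occupancy-weighted
geometric center

    D_k = (1/n²) · Σ_{i∈S_k} P_i = (n_k/n) · (center_k / n),

three coordinates per class, 36 values total, each bounded in [−1, +1]
(the absolute row sum of any coordinate is at most n(n+1)/2). Absent
classes contribute exactly (0, 0, 0).

Two normalization choices were genuinely open, and we settled them as
follows. Dividing the class center by n makes descriptors comparable
across hairpins of different lengths. Weighting by the class occupancy
n_k/n keeps the base-and-pairing-state *composition* of the hairpin in
the descriptor; a pure per-class center discards how much of the
molecule is paired, which we measured to be the single strongest signal
separating real-precursor geometry from shuffled decoys (a
centers-only variant plateaued near 0.76 random-forest accuracy on the
default synthetic corpus, versus ≈0.84–0.89 with occupancy weighting).
The descriptor deliberately retains positional information: permuting
bases within one class moves that class's center, so the curve injects
order information rather than reducing to a composition histogram.

The column order (A,C,G,U × dot,open,close × x,y,z) is frozen and
written into every feature-table header, making the files
self-describing.

## Classification protocol

* **Balanced sampling.** Each repetition draws n = min(|pos|, |neg|)
  rows from each class without replacement, removing class imbalance
  before learning.
* **Split.** 70% learning / 30% testing, stratified by class; the
  training share per class is rounded half-up, the remainder tests.
* **Learners.** Decision tree (single Gini-impurity recursive
  partition), Gaussian naive Bayes (per-class per-feature Gaussians,
  class priors from training frequencies, variance floor 1e−9 to avoid
  degenerate likelihoods), and random forest (100 bootstrap-aggregated
  trees, ⌈√36⌉ = 6 features considered per split). These are standard
  fits and are delegated to scikit-learn estimators behind the module
  surface.
* **Monte Carlo cross-validation.** The default protocol repeats the
  sample/split/train/evaluate cycle 1000 times. Per classifier, the
  model with the highest held-out accuracy is retained (ties resolve to
  the earliest repetition). Per-repetition seeds derive from the run
  seed as `SeedSequence([seed, r]) mod 2^31`, so any single repetition
  is reproducible in isolation.
* **Metrics.** accuracy, sensitivity (= recall), specificity,
  precision, and F-measure from the held-out confusion counts, with the
  miRNA class positive. A ratio with a zero denominator is reported as
  0 and flagged. A prediction score of exactly 0.5 is labeled miRNA.

Persisted models carry a format-version tag and the classifier kind, so
cross-version loads fail explicitly.

## Synthetic corpus generator

The generator emulates the two corpus shapes the method needs: positives
are stem–loop sequences (stem 18–30 bp, loop 4–12 nt, both uniform; 50%
GC) whose 3' arm is the reverse complement of the 5' arm with a 10%
per-position mismatch rate and a 5% per-position single-base bulge
rate — values chosen once as a realistic imperfection level for animal
precursor stems. Negatives default to dinucleotide-preserving shuffles
of freshly drawn hairpins (an Altschul–Erickson Eulerian-walk shuffle),
which keep mono- and dinucleotide composition — the honest analogue of
genomic pseudohairpins, which are composition-realistic rather than
random. An i.i.d. `random_matched` mode is kept as an easier baseline.

What the generator does *not* emulate: real precursors' sequence motifs
for the processing enzymes, conserved loop structures, multi-branch
folds, genomic context, and the composition biases of any particular
species. Passing tests on this corpus therefore demonstrate that the
pipeline's machinery is correct and that the descriptor separates
structured from composition-matched unstructured hairpins; they do not
certify performance on real miRBase/MirGeneDB-scale data.

## Numerical and degenerate-input choices

* Feature tables are TSV with a mandated 38-column header (id, label,
  36 descriptor names), printed at 17 significant digits; round trips
  are lossless past 12 significant digits.
* T is silently mapped to U and case is folded on input (database
  corpora mix DNA/RNA conventions); ambiguity codes (N, R, Y, ...) are
  rejected with the record id and offset, since the descriptor is
  undefined for unknown bases.
* An empty prediction input produces an empty (header-only) output and
  success, not an error.
* Vienna output writes the parenthesized score suffix only for energy
  scores, so re-reading never mislabels a pair count as an energy.

## Problem sizes

The shipped verification runs use a 200 + 200 synthetic corpus with 10
cross-validation repetitions, brute-force folding oracles at sequence
length ≤ 12, and 100–1000-sequence property sweeps — sizes at which the
exhaustive oracles are exact and the full suite runs in seconds while
exercising every stage at realistic hairpin lengths (40–75 nt).

## Known limitations

* The built-in folder maximizes pair count, not thermodynamic
  stability; it over-pairs flexible sequences relative to an MFE
  folder. The external adapter exists for users who need MFE
  structures.
* The descriptor construction (cube-corner mapping, negation on
  pairing, occupancy-weighted centers) is this package's own
  definition; other 36-dimensional decompositions of the same curve are
  possible.
* Only single non-crossing structures are supported — no pseudoknots,
  suboptimal ensembles, or partition functions.
* No ROC/AUC, probability calibration, or feature selection.
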