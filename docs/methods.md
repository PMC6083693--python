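# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `ligopharm` in the way a maintainer or reviewer would want
them stated. Nothing here claims an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Feature perception

Features are perceived by SMARTS substructure matching against configurable
dictionaries (`FeatureDefs`), with one point per match at the centroid of
the matched atoms. The shipped defaults follow the Catalyst-style
conventions that most common-feature implementations descend from:

| type | definition | point placement |
| --- | --- | --- |
| D | any O–H or N–H | heavy atom |
| A | neutral N/O lone-pair bearers; amide/sulfonamide N, anilines and pyrrole-type N–H excluded | heavy atom |
| PI | formal +1 centres; primary aliphatic amines; amidine/guanidine N | heavy atom / match centroid |
| H | connected groups of saturated carbons with no N/O/P/S neighbour; heavy halogens | group centroid |
| R | 5-/6-membered aromatic rings | ring centroid |

Same-type points closer than 0.5 Å are merged (single linkage, replaced by
their centroid). The merge radius exists to keep redundant points from
inflating the clique search; 0.5 Å is well below any tolerance radius in
use, so merging cannot change mapping outcomes.

Direction vectors for donors/acceptors are *not* modeled: mapping and fit
are purely distance-based. This matches the screening semantics implemented
here but means features with wrong approach geometry can still map.

Commercial feature dictionaries are proprietary, so feature *counts* on any
given molecule may differ from those of other software; the dictionaries are
user-replaceable (`FeatureDefs.from_file`) for tuning.

## Conformer ensembles

Ensembles are produced by ETKDGv3 distance-geometry embedding with
duplicate pruning (RMSD < 0.5 Å) followed by MMFF94 relaxation (UFF where
MMFF is unparameterized). Energies are stored relative to the ensemble
minimum; conformers above the energy window are discarded. Defaults — at
most 300 conformers inside a 20 kcal/mol window — follow standard
"best-quality" conformer-generation practice for pharmacophore work. The
window is applied to *relative* energy, the usual convention. Embedding is
seeded and single-threaded, so fixed seeds give bitwise-identical ensembles.

## Correspondence search

Feature correspondences between a reference feature set and another
molecule's feature set are enumerated as maximal cliques in the standard
correspondence (association) graph: nodes are same-type feature pairs,
edges connect pairs whose intra-molecular distances agree within
`dist_tol`. Maximal cliques are exactly the maximal one-to-one,
type-consistent, distance-compatible pairings; the test suite verifies this
equivalence against an independent exhaustive enumeration on several
hundred random instances. `dist_tol` equals the tolerance radius (1.6 Å
default): a single spatial scale governs both pairwise compatibility and
per-feature mapping.

Clique enumeration is exponential in the worst case; feature sets here are
small (≲15 points after merging), where it is inexpensive. Hypothesis
generation iterates over all conformers of all molecules, so cost grows
with (molecules × conformers)²; the shipped tests and benchmarks use small
ensembles, and large real-world runs should cap `max_conformers`
accordingly.

## Hypothesis generation and ranking

Every training molecule acts in turn as reference (the "principal = 2"
convention: the reference must map fully). Candidate hypotheses are subsets
of reference features drawn from the maximal cliques against each other
molecule (plus pairwise intersections of those clique footprints, capped at
200 candidates per reference conformer). A candidate survives only if every
training molecule covers it within `max_omit_feat` omissions *and* actually
maps onto the built hypothesis under the full mapping criterion below.
Hypothesis feature positions are the consensus (mean) of the matched points
of all contributing molecules after Kabsch superposition onto the
reference. Tolerances and weights of generated features are uniform
(`tolerance_radius`, weight 1): the data contain no basis for per-feature
values, and uniformity keeps max_fit interpretable as the feature count.

Ranking uses

    rank(H) = max(0, Σ_m (best_fit(m, H) − ω·omitted(m, H))) + λ·|features(H)|

with λ = 1 (size bonus) and ω = 2 (omission penalty). The penalty is the
deliberate design choice here: a matched feature can earn at most
weight 1 + λ share, so with ω = 2 a feature omitted by even a minority of
molecules costs more than it contributes. Without the penalty, hypotheses
decorated with reference-specific distractor features (matched by one
molecule, omitted by the rest under the omission budget) systematically
outrank the genuinely common arrangement — measured on planted benchmarks,
recovery drops from 50/50 to 39/50. Ranks are on this package's own scale
and not comparable to any commercial rank value.

Pooled hypotheses are deduplicated (same composition and same sorted
pairwise-distance multiset within `dist_tol`) and the top 10 returned,
sorted by rank descending, composition, then creation order — fully
deterministic.

## Mapping and fit

A molecule maps onto a hypothesis if some correspondence, after Kabsch
superposition of the matched molecule features onto the hypothesis centres,
places every matched feature within its tolerance sphere, leaving at most
`max_omit` hypothesis features unmatched. Out-of-sphere pairs are dropped
one at a time (worst excess first, with re-alignment) until the mapping is
valid or the omission budget is exhausted. The fit is

    fit = Σ_matched w·(1 − (d/t)²)

— the Catalyst-lineage quadratic falloff, clipped at zero. Max fit is Σw.
Degenerate correspondences of one or two points are aligned by the same SVD
machinery (one point: displacement 0; two points: half the length
mismatch). Screening uses `max_omit = 0` (database hits must map every
feature); generation uses `max_omit = 1` by default.

Empty hypotheses are rejected everywhere (every molecule would vacuously
map with fit 0); featureless molecules simply produce no mapping.

## Validation statistics

From a labeled decoy screen, with D molecules, A actives, Ht hits and Ha
active hits (DecoyCounts enforces the realizability constraints
Ha ≤ min(A, Ht), Ht ≤ D, A ≤ D and Ht − Ha ≤ D − A — a screen cannot return
more inactive hits than there are inactives):

    yield% = 100·Ha/Ht    ratio% = 100·Ha/A    EF = Ha·D/(Ht·A)
    FN = A − Ha           FP = Ht − Ha
    GH = [Ha·(3A + Ht)/(4·Ht·A)]·[1 − (Ht − Ha)/(D − A)]

On the realizable grid GH ∈ [0, 1] with GH = 1 iff Ha = Ht = A (brute-forced
over every valid contingency with D ≤ 50 in the test suite). Degenerate
inputs (Ht = 0, A = 0 or D = A) mark the affected metrics as undefined with
a logged warning instead of raising. A GH in [0.6, 0.8] is annotated
"very good model" in the report, as is conventional.

Display rounding: percentages and EF round to one decimal; **GH is
truncated (floored) to two decimals**. Truncation is a deliberate,
conservative display convention — the displayed GH never overstates the
score (e.g. a raw GH of 0.7950 displays as 0.79, not 0.80). Raw
full-precision values are always retained in the report and in the JSON
output.

## Synthetic benchmarks

Synthetic molecules are *feature clouds* — typed 3D points carried directly
on the `Molecule` — which isolates the geometric algorithms from perception
chemistry. What they emulate: a training set sharing a rigid common feature
arrangement up to isotropic Gaussian jitter and rigid motion, plus
irrelevant decoration (distractor features); a decoy database of actives
and inactives; imperfect retrieval with prescribed false-negative/positive
counts. What they do not emulate: conformational flexibility coupled to
feature positions, perception ambiguity, property-matched decoys
(DUD-E-style), or activity cliffs — so green benchmarks demonstrate the
correctness of the machinery, not screening performance on real chemistry.
A second fixture path in the tests runs real SMILES through perception and
hypothesis generation to cover the chemical route.

Defaults (`BenchmarkSpec`): composition `RHDDDAA` (one ring, one
hydrophobe, three donors, two acceptors — the arrangement a diarylurea-like
antagonist series shares), 8 training clouds, 30 actives + 970 inactives,
jitter σ = 0.2 Å (an eighth of the tolerance radius — feature scatter well
inside the sphere), 2 distractors per cloud, 10 Å placement box, 1.6 Å
tolerance.

Identifiability margins: template features are ≥ 2 Å apart overall and
same-type features ≥ 4.5 Å apart; distractors are kept ≥ 2.5 tolerance
radii from every planted point (the sampling shell widens adaptively if the
clearance makes the default box infeasible). These margins guarantee that
when `corrupt_benchmark` displaces one feature of an active far beyond
tolerance (100 Å), no jittered same-type feature (≥ 4.5 − 1.6 ≈ 2.9 Å of
slack against a 0.2 Å jitter) and no distractor (≥ 2.4 Å of slack) can
stand in for it — the corrupted active cannot map at `max_omit = 0` under
any seed. Inactives are constructed without *any* feature of one randomly
chosen template type, so they can never match the full template; corrupted
false positives receive the full template arrangement and always map.
Consequently a corrupted benchmark reproduces its contingency counts
(e.g. 30/970 with 6 FN + 6 FP → D, A, Ht, Ha = 1000, 30, 30, 24) exactly
for every seed; this is a property of the generator's construction, not a
statistical outcome.

## Determinism and numerical choices

All randomness flows through `numpy.random.default_rng` seeded from
user-supplied seeds; embedding uses the seeded single-threaded ETKDG path.
Ties are broken lexicographically everywhere (correspondences by size then
pair order, hits by fit then id, hypotheses by rank, composition, creation
order), so every public operation is deterministic for fixed inputs and
seeds. Kabsch superposition uses SVD with the standard reflection guard;
rank-deficient point sets (1–2 points, collinear) fall back to the least-
squares optimum the SVD provides. Distance comparisons use inclusive
tolerances (`<= dist_tol`, `d <= t`).

## Problem sizes used by the shipped tests

The test suite and acceptance script were sized for a single CPU: the
decoy screen runs the full 1000-molecule database; planted-recovery spans
50 seeded benchmarks of 4 training clouds; the clique-search oracle
comparison covers 200 random instances of up to 6 features per cloud; the
GH brute force covers every realizable contingency with D ≤ 50 (312k
tuples, vectorized). Real chemical fixtures use small ensembles
(≤ 10 conformers) of simple molecules.

## Known limitations

* Feature directionality (donor/acceptor vectors, ring normals) is not
  modeled; projected points and excluded volumes are likewise out of scope.
* Rank and fit values are on package-local scales; only orderings are
  meaningful, and neither reproduces the values printed by commercial
  packages.
* Hypothesis generation is exhaustive over conformer pairs; very flexible
  molecules with hundreds of conformers each will be slow.
* SMILES/SDF ingestion keeps the largest fragment of multi-fragment
  records and does not enumerate protonation states or tautomers; feature
  perception sees the input protonation state only.
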