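# Methods

This note documents the models and procedures implemented in
`foldrank`, the choices made where the design was genuinely open, and
what the synthetic benchmarks do and do not establish.

## Structure comparison

**Correspondence and normalisation.** All scoring is CA-only, with
residue correspondence by author residue-number intersection; scoring
models against references of a different sequence is out of scope.
TM-score is normalised by the length of the *reference* (first
argument), so a truncated model is penalised for the residues it
misses. GDT-TS fractions use the same denominator. The pairwise
similarity matrix symmetrises the two scoring directions by their
mean. Published TM-score/GDT implementations differ in small details
of their searches; rather than chase agreement with any one binary,
the implementation is bounded against a brute-force oracle (below).

**Search.** Both scores maximise over rigid superpositions. The search
is deterministic (no random restarts; scores are bit-reproducible):

1. *Seeds*: Kabsch superpositions of contiguous windows of lengths
   {3, 5, 7, L/2, L} slid along the chain (stride ≈ L/20). For chains
   of ≤ 20 residues every window length is seeded — the cost is
   negligible and short-chain score landscapes are rugged.
2. *Mask refinement*: from each seed, alternate between selecting
   residue pairs closer than max(d0, 3 Å) (the cutoff grows by 0.5 Å
   until at least three pairs survive) and re-superposing on the
   selection, until the selection stabilises (≤ 20 iterations).
3. *Reweighted ascent (IRLS)*: re-superposing with weights
   1/(1+(d/d0)²)² — the derivative of the per-residue TM term —
   climbs directly toward superpositions with many residues near d0.
   This complements step 2, which struggles when d0 (floored at 0.5 Å
   for short chains) sits far below the selection cutoff.

The score is the maximum over *every* superposition visited. For
GDT-TS the same frames are counted against each distance cutoff, plus
per-cutoff mask refinements (select within t, re-superpose), a
loose-to-tight cascade across cutoffs, and — because a frame
maximising "residues within t" is generally *not* a least-squares fit
of its inliers — a rank-trimmed Chebyshev-style growth that enlarges
the fitted subset one nearest residue at a time while reweighting
toward the subset's farthest members. For chains of ≤ 20 residues both
scores additionally sweep an exhaustive frame stack (all contiguous
windows, all residue triples, and a 30°-spaced rotation grid with
residue-anchored translations), and for ≤ 12 residues GDT-TS tests
every residue subset for joint superimposability with an annealed
minimax (Chebyshev) fit — the inlier set of a counting optimum is
jointly superimposable by definition, so exhaustive subset
feasibility makes the tiny-chain search effectively exact. Subsets
whose reweighted fit stalls just above a cutoff (the iteration's one
failure mode sits at feasibility boundaries) get a smooth-max
Nelder-Mead polish. A production call on a CASP-sized domain never
pays for any of this.

**Oracle bound.** An independently written brute-force search
(scipy-based superposition, exhaustive windows, triples and subsets, a
dense rotation grid with residue-pair-anchored translations, batched
reweighted refinement, Nelder-Mead polish) lives in the test
harness. On 200 random toys of 8–12 residues with coordinate noise of
0.3–3 Å and random hinges, the library's TM-score and GDT-TS agree
with the oracle to within 0.02 (on the development sample both scores
agree exactly).

**Pairwise matrices.** For pools where every model shares one residue
set and the parameters request only the global seed window
(`FAST_POOL_PARAMS`), the identical three-phase algorithm runs
vectorised over all pairs simultaneously, with converged pairs
dropping out of the working set; equality with the per-pair loop is
property-tested. A 200-model pool takes a few seconds. The global
seed is adequate for same-fold decoy pools; pools mixing unrelated
folds should use the full seed search.

## MSA engineering

**Template-hit filtering.** Hits with e-value > 1, aligned length
≤ 40 residues, or coverage ≤ 0.5 are insignificant and removed.
`coverage` is taken as supplied by the hit-table producer (aligned
length over template length); which length the 0.5 cutoff refers to
is ambiguous in the protocol this follows, so the field is used as
given.

**Segmentation.** Maximal continuous hit-covered regions become
domains; unaligned gaps longer than 40 residues become their own
domain; shorter internal gaps are split at their midpoint (the left
flank takes ⌊gap/2⌋), and short leading/trailing gaps are absorbed
into the terminal domains. Midpoint splitting is our concretisation —
the >40 rule defines only the long-gap case — chosen to preserve
exact coverage without inventing sub-domains. If a disorder track is
given, a boundary falling strictly inside a disordered run of ≥ 5
residues moves to the run's midpoint (disordered linkers, not ordered
cores, are where cut points belong); moves that would reorder
boundaries are discarded. Segmentation engines themselves
(sequence- or structure-based domain parsers) are not implemented;
their outputs enter as hit tables or explicit interval lists.

**Pairing, padding, assembly.** Rows are paired across domain MSAs by
range-stripped identifier (`ID/23-180` → `ID`), first occurrence per
MSA, concatenated in domain order; everything unpaired is gap-padded
into full-length coordinates. A domain-based MSA stacks query →
full-length rows → paired rows → padded unpaired rows and drops exact
duplicates (same identifier *and* residue string; the protocol is
silent on deduplication). Insertion states of domain alignments are
dropped at assembly; only match columns carry through.

**Profile augmentation.** The masked-language-model augmentation step
(two synthetic sequences from confident single-residue substitutions)
is reproduced with a pluggable predictor whose default is the
alignment's own column profile: synthetic row k takes the k-th most
frequent non-query residue in each column when its frequency among
aligned residues exceeds 0.3, else the query residue. This is an
explicit stand-in interface — a transformer scorer can be plugged in
— and the default documents exactly what it is.

## Consensus ranking and selection

**Normalisation.** Scores of unlike scales (plDDT 0–100, ranking
scores 0–1) are min-max normalised per column over the models where
the column is present before any averaging; a switch allows raw
averaging. A constant column contributes 0.5 to every model. Models
missing every requested score rank last rather than erroring, so
partially scored pools stay usable. All ties break lexicographically
on model id, making every selection deterministic.

**Clustering.** K-means runs on the rows of (1 − similarity): a
model's dissimilarity profile against the whole pool is its feature
vector (the feature representation is our choice; coordinates would
require a shared frame). k = min(5, number of distinct profiles),
with 5 matching the CASP submission count; fixed seed, 10 restarts.
Each cluster is represented by its best model under the configured
primary score (default `gate`, falling back to global plDDT).

**Strategies.** The five CASP16 submission strategies are implemented
as quoted in their descriptions; two points needed interpretation.
The `multicom` strategy lists five secondary criteria for four
remaining slots; the implementation cycles through the criteria in
order, taking the next-best unused model per criterion. Manual
adjustment steps are modelled as an explicit user-supplied override
list applied last — never a heuristic. The AlphaFold3-inclusion rule
replaces the final slot with the best-ranked AlphaFold3 model when
none was selected and the pool contains one.

**Rescue property.** The two-conformation experiment (below) checks
the mechanism the clustering strategy exists for: consensus scores
(PSS) rank the dominant conformation first by construction, so when
the dominant conformation is wrong, only per-cluster representation
keeps the rare correct fold in the top five. The experiment runs the
clustering strategy without the AlphaFold3 slot rule, which is
orthogonal to the mechanism (generator tags in the synthetic pools
are independent of conformation).

## Fragment assembly

Fragments must arrive sorted, contiguous, and overlapping by at least
`min_overlap` residues (default 20; stability needs ≥ 3, 20 adds
robustness against locally distorted overlap geometry). The first
fragment fixes the frame; each next fragment is Kabsch-superposed onto
the growing assembly over the shared residues, and the per-junction
overlap RMSD is reported. Overlap coordinates come from the earlier
fragment by default — deterministic, no chimeric geometry — with a
midpoint-blend mode as an option.

## The Z-score evaluation protocol

Per domain, predictor scores are standardised (population standard
deviation by default; sample selectable — the protocol does not state
which), entries with z < −2 are dropped as outliers, and *all* present
entries are re-standardised against the survivors' mean and standard
deviation, so dropped predictors also receive a pass-2 score. Exactly
one removal pass is performed. Degenerate cases: zero deviation gives
all-zero z; fewer than two survivors leaves the pass-1 scores; fewer
than two present scores leaves the domain undefined with a warning.

For accumulation, configured alternative-conformation domain pairs
are averaged on raw z *before* clipping (a predictor absent from one
member inherits the other's value; a clip-then-average mode exists
for sensitivity analysis), and each unique domain then contributes
max(0, z), with absences contributing 0. The pair list is always
explicit configuration input, never inferred from domain names.

One property of the protocol is worth knowing: the accumulation is
*not* strictly monotone in a predictor's own scores. The −2 exclusion
is a discontinuity — raising one score inflates the first-pass
standard deviation, which can lift a previously excluded low outlier
back above the cutoff; the reinstated outlier widens the survivor
spread and deflates every recalculated Z, including that of the
predictor whose score improved. A property test verifies the sharp
statement: violations of monotonicity are rare (on the order of 0.2%
of randomised tables) and occur only when a domain's exclusion set
changes; away from that boundary, raising a score never lowers the
predictor's positive-sum total.

The paired comparison test is the one-sided Wilcoxon signed-rank test
(zero differences dropped; exact null up to n = 25 untied
differences; sign-permutation enumeration up to n = 16 when magnitudes
tie; normal approximation with tie correction beyond), computed via
scipy and cross-checked in the tests against an explicit 2^n
enumeration oracle.

## Synthetic data: what it emulates, and what it does not

Reference chains are ideal α-helices (1.5 Å rise, 100° twist, radius
tuned for 3.8 Å CA-CA spacing) or self-avoiding 3.8 Å random walks
(non-consecutive CAs ≥ 4 Å apart). Decoy pools draw a conformation
per model (alternative conformations hinge the chain at its midpoint
by a configured angle — simple, controllable cluster separation), add
isotropic Gaussian coordinate noise, and land in a random rigid
frame. Simulated global plDDT is an affine transform of true TM plus
Gaussian noise calibrated to a target correlation ρ (default 0.8),
which lets tests reproduce the qualitative finding that
confidence-based ranking fails when a wrong conformation dominates
the pool. Every pool ships a truth table (conformation, noise level,
true TM/GDT, plDDT, generator tag), making downstream selection tests
self-validating.

These fixtures are CA traces with isotropic noise: no side chains, no
secondary-structure-dependent error, no correlated domain motions, no
alignment-depth-dependent model quality. Passing tests therefore
demonstrate the *algorithms* (scoring, clustering, selection logic,
protocol arithmetic) under controlled conditions, not predictive
performance on real proteins.

Hit-table generation shrinks each planted domain's hit by a
10-residue margin at internal boundaries so that midpoint splitting
of the short unaligned gaps recovers the planted boundaries — exactly
at zero jitter, within the jitter bound otherwise — and emits decoy
hits that each violate one significance filter.

## Study conditions of the acceptance experiments

- Z-score protocol: the 4-score worked example {0.9, 0.8, 0.7, 0.2}
  against hand arithmetic (tolerance 1e−9); accumulation monotonicity
  over 1,000 randomised predictor×domain tables.
- Scoring: 200 random toys, 8–12 residues, noise σ ∈ [0.3, 3] Å, 40%
  hinged; TM and GDT-TS within 0.02 of the brute-force oracle;
  exactly 1.0 on identity and rigid-transform pairs.  (Toy length is
  capped at 12 so the exhaustive subset stage that makes both searches
  near-exact stays cheap; 2^n subsets are enumerated per toy.)
- Selection: 100 replicates of a 200-model, 30-residue pool, 90%
  hinged (wrong) / 10% reference (correct) conformation, σ = 0.8 Å;
  the clustering strategy must include ≥ 1 minority-cluster model in
  ≥ 95% of replicates while the consensus top-1 is majority-cluster
  in ≥ 95%.
- MSA round trips: 300 random planted segmentations (1–4 domains of
  65–185 residues) recovered exactly from zero-jitter hit tables;
  pairing counts match a set-intersection oracle over 1,000
  randomised identifier sets.

Problem sizes were chosen so the full suite and the acceptance script
each run in minutes on one CPU. The pool-similarity preset used in
the selection experiment relaxes the TM convergence tolerance to
1e−4 and caps refinement at 12 iterations (same-fold pools converge
quickly; the ranking is insensitive to the last digit of the
similarity).

## Known limitations

- Scoring assumes a shared residue numbering; no sequence-alignment
  correspondence, no GDT-HA, no lDDT, no side-chain metrics.
- The GDT-TS search is near-exhaustive only for short chains; for
  long chains it is a heuristic like every practical GDT
  implementation, and small deviations from other implementations are
  expected.
- Alignment pairing is identifier-based only (no taxonomy-aware
  pairing); segmentation quality is bounded by the hit table it is
  given.
- The published-number reproduction of the CASP16 summary statistics
  requires the publicly deposited per-domain tables, which must be
  supplied locally; without them that check reports failure by design.
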