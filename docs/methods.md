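# Methods

## Model and assumptions

The package implements neighbourhood-based protein function prediction on a
protein–protein interaction network (PPIN). Its central assumption is the
guilt-by-association principle: interacting proteins tend to share function
and subcellular location, and the signal is strongest among *essential*
(highly connected) proteins joined by *reliable* (neighbourhood-sharing)
edges. The pipeline therefore prunes the network before predicting, and
predicts only for the pruned network's members.

A second, independent signal comes from sequence: proteins in the same
functional module tend to have correlated physicochemical profiles, so a
scalar PCP score (mean of selected z-scored descriptors) is used as the
distance in which candidate neighbourhood clusters compete.

## Network weighting and thresholds

* **Node weight** (default `degree_over_mean`): NW(v) = deg(v) / mean
  degree. Unit mean by construction; `raw_degree` is available. The
  weighting literature behind the original method leaves the exact formula
  unspecified, so the package declares its own degree-normalised default —
  its scale (thresholds slightly above 1) matches the node thresholds the
  original study reports (~1.07).
* **Edge weight** (default `jaccard_cn`):
  EW(u,v) = |N(u) ∩ N(v)| / |(N(u) ∪ N(v)) \ {u,v}|, zero when the
  denominator vanishes; `common_neighbor_count` is available. The Jaccard
  normalisation keeps EW in [0,1] and again matches the reported edge
  thresholds' magnitude (~0.11).
* **Thresholds**: Th_k = α + k·σ·(1 − 1/(1+σ²)), k = 1/2/3 for
  low/medium/high, with α the mean and σ the *population* standard
  deviation of the weight values (the thresholds are descriptive statistics
  of the full distribution, so n-weighting rather than n−1 is the natural
  reading). With σ = 0 all levels collapse to the mean; because pruning
  removes only *strictly smaller* weights, a constant-weight (regular)
  network is left intact rather than deleted wholesale.

Refinement is two-stage: node pruning first (giving G′), then edge weights
and edge thresholds are **recomputed on each level's G′** before edge
pruning (giving G″). Proteins isolated by edge pruning are retained — they
can still be cluster singletons. A consequence of per-sub-network edge
tables is that while the surviving *protein* sets provably nest
(high ⊆ medium ⊆ low; node thresholds are monotone in k), the surviving
*edge* sets need not: an edge can clear the medium sub-network's recomputed
threshold yet fail the low one. The tests assert the guaranteed nesting.

## Clustering and prediction

Clustering is deterministic seed expansion: the unassigned protein of
maximal node weight (ties: lexicographically smallest identifier) absorbs
its unassigned level-1 neighbours whose seed-edge weight meets the level's
edge threshold; members are recorded in descending edge-weight-to-seed
order. Only direct neighbours of the seed are absorbed — no transitive
growth — and assigned proteins are removed from the candidate pool but
their edges are not masked for later seeds.

Prediction for a test protein works on the node-pruned graph G′ (not the
edge-pruned G″): each level-1 neighbour seeds a candidate cluster holding
that neighbour plus its own immediate neighbours above the edge threshold,
with the test protein excluded. The candidate cluster whose mean PCP score
is nearest the test protein's wins (ties: larger seed-edge weight to the
test protein, then smaller seed identifier), and its full label union
transfers — no per-label ranking or cutoff, which is why the method runs
recall-heavy. Cluster means include unannotated members that have
sequences. A protein with no level-1 cluster is reported `unpredictable`,
distinct from a predicted-but-empty label set. During batch runs every test
protein's own annotation is masked while it is being predicted, so no label
leaks back through itself.

## Physicochemical descriptors

Ten candidates per sequence (Biopython/ProtParam conventions): aromaticity,
GRAVY (Kyte–Doolittle), instability index (Guruprasad), isoelectric point,
D+E and K+R counts (histidine excluded, per ProtParam), molar extinction
coefficient at 280 nm (oxidised-cystine variant by default), Ikai's
aliphatic index, absorbance (extinction / average molecular weight) and
pI / molecular weight. pI is found by Brent root-finding of the Bjellqvist
net-charge curve on [0, 14] to 1e-6 pH; the net charge at the returned pI
is below 1e-3 in magnitude.

Descriptors are z-scored over the analysis's protein set (population σ,
constant columns map to 0) before selection and scoring — without scaling,
the aliphatic index (~100) would drown GRAVY (~±2) in any mean. A raw-scale
path is deliberately not offered for the PCP score.

One numerical caveat, stated because the tests encode it: pI is *not*
exactly length-scale invariant. The side-chain charge balance is scale-free,
but the two chain termini are counted once per sequence, so doubling a
sequence halves their relative weight; for realistic 150+-residue sequences
the induced shift is ≲0.2 pH, and successive doublings shift pI less and
less. Composition descriptors (aromaticity, GRAVY, aliphatic index) are
exactly invariant.

## Feature selection

Four seeded, single-threaded importance rankers — XGBoost, random forest,
extra trees (100 trees each) and RFE over logistic regression — each
nominate their top five descriptors; descriptors nominated by ≥2 rankers
(`min_hits`, default 2) are selected. Trained on (z-scored descriptors →
primary annotation label); the original study does not state its training
target, and the primary functional label is the natural default. The
reference nomination matrix from the original yeast analysis ships as a
fixture (`REFERENCE_TOP5_RANKINGS`, selecting six descriptors); it is used
as a fallback when a dataset offers fewer than two annotation classes, and
by the acceptance script's worked-example arithmetic. Classifier
hyperparameters are minimal fixed settings — the binding requirement is
determinism, not tuning.

## Localization

Majority vote over the known locations (nucleus / cytoplasm / interface)
of the test protein's level-1 neighbours only; no multi-level fallback.
Ties break by the larger summed edge weight from the tied side's voters to
the test protein, then by the fixed order nucleus > cytoplasm > interface
(the tie rule is an implementation decision; votes rarely tie at realistic
degrees). No known neighbour ⇒ the vote fails, reported distinctly.
Accuracy per category is matched / (matched + unmatched + failed) — failures
count against accuracy, matching the arithmetic of the original study's
published tallies (e.g. 112 of 162 nuclear test proteins ⇒ 69.1%).

## Evaluation

Per-protein TP = |pred ∩ true|, FP = |pred \ true|, FN = |true \ pred|.
Micro-averaging (pool counts, then P/R/F) is the default; macro is
available. Degenerate conventions: P = 0 when nothing is predicted, R = 0
when there are no true labels, F = 0 when P + R = 0. Unpredictable proteins
are excluded from the counts and tallied separately.

## Synthetic data

The generator emulates a bench-scale annotated interactome. Defaults — the
conditions every recovery test runs under — are 5 planted clusters × 40
proteins, within-cluster edge probability 0.3 versus 0.01 between, 5%
label-noise resampling, secondary labels shared between adjacent clusters
(rate 0.3) to exercise multi-label scoring, sequences of 200–400 residues,
and a 0.15 composition tilt: each cluster multiplies a uniform background
by exp(±shift) over the four descriptor-relevant residue groups (D/E, K/R,
F/W/Y, A/V/I/L; 16 distinct sign patterns). Locations are drawn per cluster
(weights 0.4/0.4/0.2 for nucleus/cytoplasm/interface), members deviate with
probability 0.1 and become `unknown` with probability 0.05. Everything
derives from one `numpy` generator seed, so outputs are byte-identical
across runs.

What the generator does *not* model — scale-free degree distributions,
sequence motifs, hierarchical functional catalogues, annotation
incompleteness correlated with degree — bounds what passing tests show:
they demonstrate that the pipeline recovers planted modular structure and
composition signal under idealised conditions, not that it attains any
particular accuracy on a real interactome.

## Problem sizes and runtime choices

Property tests run on ≤20-node random graphs (200 of them for the
partition invariants) and the complete ≤6-node graph enumeration for the
edge-weight oracle. Recovery tests and the acceptance script use the
generator defaults (200 proteins) over 10 replicate seeds — at this size a
full pipeline run takes about two seconds, and the recovery margins
(planted-label recall ≈ 0.8 against the 0.2 chance level; localization
accuracy ≈ 0.94 against 1/3) are far from their acceptance floors, so
replicate-to-replicate noise is immaterial.

## Known limitations

* The node/edge weight formulas are this package's declared defaults; the
  original method cites external work without reproducing the formulas, so
  exact numeric agreement with the original study's thresholds cannot be
  checked without its exact data and formulas.
* Interaction-*type* prediction (e.g. "Two hybrid" vs "Synthetic lethal")
  is out of scope; no method for it is defined.
* Localization truth arrives as a local table; there is no annotation
  service access.
* Hierarchical (catalogue-aware) scoring is not implemented; labels are
  compared as flat sets.
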