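# Methods

## Binding-residue definition

A protein residue is RNA-binding when the minimum Euclidean distance
between any of its atoms and any atom of the bound RNA is **strictly less
than 5.0 Å**; ties at exactly 5.0 Å are non-binding.  All atoms present in
the structure participate in the distance test (hydrogens included when
present); waters and heteroatoms are excluded from both molecules.  Labels
use the ±1 convention (+1 binding).  Parsing collapses alternate locations
to the highest-occupancy conformer and skips non-standard residues with a
warning; residues that lose all atoms are dropped, residues missing only
side-chain atoms are kept and their features degrade gracefully.

## Geometry

* **Euclidean neighbour graph** — residues r, n are neighbours when their
  minimum *heavy-atom* (non-hydrogen) distance is ≤ 10 Å (inclusive).
* **Voronoi adjacency** — space is tessellated around individual atoms;
  two residues are adjacent when any atoms of the two share a Voronoi
  facet.  Because surface cells are unbounded, the tessellation is computed
  after adding a shell of 256 evenly spaced dummy points on a sphere of
  radius (structure radius + 15 Å); facets involving dummy points are
  discarded.  The shell bounds every real cell, which also makes the
  adjacency exactly the Delaunay edge set of the augmented point cloud
  restricted to real atoms — the property the test suite verifies against
  an independently computed Delaunay triangulation.  Duplicate coordinates
  are jittered by 10⁻⁶ Å with a fixed seed; collinear/coplanar point sets
  raise a degeneracy error.
* **Delaunay tetrahedra** — computed over one representative point per
  residue (Cα, falling back to the heavy-atom centroid).  Fewer than four
  residues gives an empty tessellation.
* **Contact counts** — NC_a(r) is the number of atom–atom pairs between r
  and other residues within a configurable cutoff (default 5.0 Å) divided
  by r's atom count; NC_r(r) counts distinct contacting residues, likewise
  normalised.
* **Side-chain centre** — unweighted centroid of side-chain heavy atoms;
  glycine and side-chain-less residues fall back to Cα.

## Site features (63) and neighbourhood blocks

Fixed column order: physicochemical (10), pKa (2), PSSM (20),
conservation (1), ASA/RSA (2), secondary structure (3), interaction
propensity (4), disorder (6), contacts (2), pair potential (1),
topographical index (1), LSE/ΔLSE (2), four-body potential (1), side-chain
energy (6), Voronoi contacts (2).  Group sizes sum to 63; the full vector
is 63 site + 63 Euclidean-neighbourhood + 63 Voronoi-neighbourhood = 189.
Both neighbourhood blocks sum the *neighbour's* site value per feature
(an empty neighbourhood contributes zeros), so a residue's context enters
additively and permutation-equivariantly.

Notable definitions and approximations:

* **Interaction propensity.** Binding events are distinct (protein residue,
  contacted RNA nucleotide) pairs under the < 5 Å rule.  Per protein–RNA
  pair, the joint frequency is normalised over observed events, triplet
  frequencies over the protein's interior (unpadded) sequence triplets, and
  nucleotide frequencies over the RNA.  Zero-frequency terms contribute 0.
  Residue triplets are the (i−1, i, i+1) window; chain termini pad with
  'X' and padded triplets look up as 0.  IP uses log₂.  Because the
  statistic is a plain sum over complexes, duplicating the training set
  doubles every entry; per-pair contributions are scale invariant.
* **Pair potential.** PP_i = |Σ_j P(aa_i, aa_j)| over residues with
  sequence separation ≥ 4 and side-chain-centre distance ≤ 7 Å.  The
  packaged 210-pair table is a *synthetic* hydrophobicity-product stand-in
  (favourable for hydrophobic pairs); any published contact-potential table
  with the same keying can be supplied through `PipelineConfig`.
* **Four-body potential.** Per Delaunay tetrahedron, log(f/p) of its
  order-free amino-acid composition: f observed over training tetrahedra,
  p multinomial in background amino-acid frequencies with the 4!/∏mₖ!
  multiplicity correction.  Natural log by default (configurable base);
  unseen compositions score 0, an observed composition with p = 0 is a
  model inconsistency and raises.  A residue's score sums over the
  tetrahedra containing it.
* **Topographical index.** Euclidean-neighbour count of the residue
  divided by the training-set mean count for its amino-acid type (global
  mean for unseen types).
* **Local structural entropy.** Shannon entropy (bits) of the mean 8-state
  secondary-structure propensity over 5-residue sequence windows, averaged
  over the up-to-4 windows covering the residue (clamped at termini).  The
  propensity table is a constructed approximation from helix/sheet
  propensities.  ΔLSE is 0 in prediction mode (no mutant sequence).
* **External providers.** PSSM rows (PSI-BLAST ASCII format), conservation,
  disorder (6 values), DSSP secondary structure and accessibility, and
  side-chain energy terms are file-backed, keyed per residue, with
  documented fallbacks: BLOSUM62 row, 0, zeros, all-coil, sphere-sampling
  ASA, zeros.  Missing individual rows use the provider's fallback, never
  silent NaN; fallback usage is counted and reported.  The internal ASA is
  Shrake–Rupley sphere sampling: 960 points per atom, probe 1.4 Å,
  per-element van der Waals radii.  DSSP classes map G/H/I → helix,
  B/E → sheet, T/S/blank → coil.

## Feature selection

Continuous features are z-scored and discretised into 3 bins at ±1 sd
(standard mRMR practice).  Mutual information is the discrete log₂ sum with
zero-probability cells contributing 0.  Ranking is greedy MID: first
argmax I(f; y), then argmax [I(f; y) − mean_{s∈selected} I(f; s)], ties to
the lower column index.  IFS cross-validates nested prefixes (stride
configurable) and returns the smallest prefix maximising AUC + MCC.  CV
folds are stratified by label at residue level with a fixed seed;
protein-grouped folds are available via `CVProtocol.groups`.

## Classifier

Gradient tree boosting on ±1 labels with logistic loss
L = log(1 + exp(−2yΘ)): Θ₀ = ½ log(p₊/p₋); per stage a depth-limited
regression tree (scikit-learn's tree inducer) is fitted to the negative
gradients r = 2y/(1 + e^{2yΘ}) and each leaf value is replaced by the
one-step Newton minimiser γ = Σr / Σ|r|(2 − |r|); the update applies
shrinkage ν.  Scores are σ(2Θ); the default decision threshold is 0.5.
Defaults: M = 500 stages, ν = 0.1, depth 3, subsample 1.0 — standard
boosting settings at this data scale; all configurable.  Training deviance
is non-increasing by construction and recorded per stage.  Models serialise
with a schema version and reload with bit-identical predictions.
Undersampling keeps all minority samples and draws the majority uniformly
without replacement to a 1:1 ratio; during cross-validation it is applied
only to the training portion of each fold, so test folds keep the natural
imbalance (no leakage).  Already-balanced data is returned unchanged.

## Evaluation

SN, SP, precision, ACC, F and MCC from the confusion counts; any metric
with a zero denominator reports 0 and is flagged rather than raising, so
degenerate folds aggregate cleanly.  ROC is a threshold sweep over the
unique scores; the trapezoid AUC equals the Mann–Whitney pair statistic
with ties counted 0.5 (property-tested).  Fold summaries are mean ± sample
standard deviation.

## Synthetic data

The generator emulates the study conditions of curated protein–RNA
interface sets: a protein chain as a persistent self-avoiding walk (3.8 Å
Cα steps, ≥ 4 Å separation of non-adjacent residues, restart on dead ends),
1–5 heavy side-chain atoms per residue at 1.5 Å steps, and an RNA chain of
single-atom nucleotides — sufficient because no in-scope feature reads RNA
internal geometry.  Anchor nucleotides are placed 3.5–4.5 Å from randomly
chosen residues, pointing outward; surplus nucleotides are placed ~10 Å
outside the protein.  The number of anchors is adjusted over bounded
retries until the realised binding fraction (by the real labelling rule)
is within ±5 percentage points of the target, default 14.5% — the positive
rate of curated interface data sets.  Feature datasets run the real
extraction pipeline; the planted signal shifts the named site features
(default: ASA, RSA, PP and the IP block) of binding residues by
`signal_strength` column standard deviations *before* neighbourhood
aggregation, so it propagates into the ED/VD blocks realistically.

What passing synthetic tests do **not** show: real interfaces have
correlated evolutionary signal (PSSM, conservation), real secondary
structure and real side-chain packing; here those channels are fallback
constants, the planted signal is additive and axis-aligned, and amino-acid
composition is independent of binding.  Synthetic performance therefore
validates the machinery, not biological accuracy.

## Problem sizes and determinism

The acceptance benchmark uses 10 complexes × 200 residues (~2000 residues,
~15–18% positives), signal strength 2 sd, 10-fold CV with 200 boosting
stages — sizes chosen so the whole suite and the acceptance script each run
in about a minute on one CPU while keeping fold statistics stable.  Every
stochastic component (generator, undersampling, fold assignment, tree
seeds, jitter) derives from explicit seeds; fixed-seed runs are
byte-reproducible end to end, including the extracted feature TSV.

## Known limitations

* Structure-bound: proteins without a solved (or modelled) 3D structure
  cannot be scored.
* The pair-potential and LSE propensity tables are synthetic/constructed
  stand-ins; absolute values of those two features are not comparable to
  published potentials (the contracts — neighbourhood rules, absolute-sum,
  entropy windows — are exact and tested).
* Tetrahedron types are not distinguished in the four-body statistic
  (single-type model; the frequency model is a pluggable hook).
* The Voronoi dummy-shell treatment of surface cells is one defensible
  choice among several; adjacency near the surface depends mildly on the
  shell radius.
* mRMR intentionally demotes redundant copies of informative features, so
  planted-signal recovery into a top quartile saturates below 100% when the
  planted set contains near-duplicates (e.g. ASA and RSA).
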