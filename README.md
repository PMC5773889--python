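# rnabind

Structure-based prediction of protein–RNA binding residues.

RNA-binding proteins steer translation, post-transcriptional modification
and gene regulation, and they do it through specific interface residues.
Given the 3D structure of a protein–RNA complex, `rnabind` labels each
protein residue as RNA-binding or not (a residue is *binding* when at least
one of its atoms lies strictly within 5.0 Å of any RNA atom), describes
every residue with a large structural feature vector, and learns a
classifier that predicts binding residues from structure alone.  It is
aimed at structural bioinformaticians who want a transparent, fully
scriptable re-implementation of this kind of interface predictor, with
every stage testable offline.

## Method

For each protein residue *r* the pipeline computes **63 site features**:
ten physicochemical constants, side-chain pKa values, the 20-column
PSI-BLAST PSSM row, an evolutionary conservation score, absolute and
relative solvent accessibility (RSA = ASA / maxASA), a 3-state secondary
structure one-hot, four interaction propensities, six disorder scores,
atom/residue contact densities, a residue-pair contact potential, a
topographical index, local structural entropy, a four-body Delaunay
pseudo-potential, six side-chain energy terms and two Voronoi contact
counts.

Two **structural-neighbourhood blocks** aggregate context: for feature *i*,

* `EN_i(r) = Σ_n F_i(n)` over Euclidean neighbours *n* — residues whose
  minimum heavy-atom distance to *r* is ≤ 10 Å, and
* `VD_i(r) = Σ_n P_i(n)` over Voronoi neighbours — residues sharing at
  least one atom-level Voronoi facet with *r* (the tessellation is bounded
  by a dummy-point shell so surface cells are finite),

giving 63 × 3 = **189 features** per residue.  The **interaction
propensity** of residue triplet *t* with nucleotide *n* is a log-odds
statistic over training complexes,

    IP(t, n) = Σ_(P,R) f_(P,R)(t, n) · log2[ f_(P,R)(t, n) / (f_P(t) · f_R(n)) ],

with 20³ × 4 = 32,000 addressable cells.  Features are ranked by **mRMR**
(mutual-information relevance minus mean redundancy) and a prefix of the
ranking is chosen by **incremental feature selection** maximising
cross-validated AUC + MCC.  Classification uses **gradient tree boosting**
on ±1 labels with logistic loss `L(y, Θ) = log(1 + exp(−2yΘ))`: half
log-odds initialisation, per-stage regression trees fitted to the negative
gradients with one-step Newton leaf values, shrinkage ν, and scores
σ(2Θ) ∈ (0, 1).  Class imbalance (~1:6) is handled by 1:1 random
undersampling applied strictly inside each training fold.

Outputs of external tools (PSI-BLAST, DSSP, conservation/disorder
predictors) are read from files when available; every provider has a
documented fallback (BLOSUM62 rows, internal sphere-sampling accessibility,
all-coil, zeros) so the pipeline runs with no external binaries.

## Worked example

```sh
python examples/04_train_and_evaluate.py
```

prints

```
750 residues, 18.8% binding
 ACC: 0.999 +/- 0.004
  SN: 1.000 +/- 0.000
  SP: 0.998 +/- 0.005
 MCC: 0.996 +/- 0.013
 AUC: 1.000 +/- 0.000
label-shuffled null AUC: 0.451 (chance = 0.5)
```

Five synthetic complexes (750 residues, 18.8% binding under the < 5 Å rule)
are pushed through the real 189-feature pipeline with a 2-standard-deviation
signal planted on the accessibility, pair-potential and interaction-
propensity features of binding residues.  Ten-fold cross-validation of the
undersampled boosting classifier recovers the planted signal essentially
perfectly (AUC 1.0, MCC 0.996), while shuffling the labels drops AUC to
chance — the pipeline finds exactly the signal that is there and nothing
else.  The other examples walk through labelling (`01`), feature extraction
(`02`) and mRMR/IFS feature selection (`03`).

The same stages are available as a CLI:

```sh
rnabind synth --n-complexes 2 --seed 3 --out-dir work/
rnabind extract work/*.pdb --out work/features.tsv
rnabind train --features work/features.tsv --model work/model.joblib
rnabind predict --model work/model.joblib --features work/features.tsv --out work/scores.tsv
rnabind eval --scores work/scores.tsv --out work/metrics.json
```

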