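# Methods

## Problem and model

The positive class is the NAD-interacting residue (NIR): a residue whose
side chain directly contacts a bound NAD molecule in a complex
structure. The classifier never sees structure at prediction time; it
sees only the sequence window centred on the residue, on the premise that
the local sequence context (for classical NAD binders, the Rossmann
fingerprint with consensus GXGXXG and its enriched Gly/Tyr/Thr/His/Ser
neighbourhood) carries most of the signal.

The decision rule is a soft-margin kernel SVM over fixed-length window
features. Nothing in the contract depends on a particular solver; libsvm
(via scikit-learn) is used, with the positive-class cost factor j mapped
to `class_weight={1: j}`.

## Contact labeling

The original NIR annotation came from a ligand–protein contact server
whose surface-complementarity criterion is not reproducible from its
description. A heavy-atom distance cutoff stands in:

* residue i is labeled 1 iff any of its side-chain heavy atoms lies
  within `cutoff` (default **4.5 Å**, a standard heavy-atom contact
  distance) of any NAD atom;
* side chain = all heavy atoms except the backbone set {N, CA, C, O};
  for glycine the CA is additionally treated as the side-chain atom —
  otherwise Gly could never be an NIR, contradicting its observed
  enrichment at NAD sites;
* first model only; Biopython's selected altloc conformer; hydrogens
  ignored; multiple NAD copies contribute the union of their contacts;
  nonstandard residues map to `X` and are never labeled positive.

The cutoff is monotone: labels at a smaller cutoff are a subset of labels
at a larger one, which the tests exploit.

Redundancy reduction is greedy longest-first clustering (CD-HIT-like,
ties broken by id): a chain joins the first representative whose global
alignment identity with it exceeds the threshold (default 0.40). Identity
is identities / shorter length from a Needleman–Wunsch alignment with
match +1, mismatch −1, gap open −10, extend −0.5; the strict gap
penalties keep random-sequence identity near the ungapped expectation
(~5% for uniform 100-mers). Externally computed cluster files can be
imported instead.

## Window features

* Window length W is odd, 3–21 in the published sweeps; terminal padding
  is (W−1)/2 `X` per side (8 for W=17). A stated "(L−1)/2" padding count
  in the source description is inconsistent with its own W=17 example and
  is read as (W−1)/2.
* Binary mode: 21-symbol one-hot per position, symbol order
  A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V,X — the PSSM column order plus
  `X` last, so both encodings share one ordering.
* PSSM mode: the first (log-odds) score block of a PSI-BLAST
  `-out_ascii_pssm` file, one 20-vector per window position. Whether and
  how the original work scaled these scores is unstated; the default here
  is the logistic s(x) = 1/(1+e^(−x)) into [0, 1] (common in this method
  family), with `identity` and `div100` available as config. Padding
  positions are all-zero rows and are not passed through the scaler, so a
  padding row (0) is distinguishable from a real zero score (0.5).

## Training and evaluation

* Equal-mode balancing keeps all positives and a uniform seeded sample of
  negatives of the same size, drawn once per run (not per fold) and
  intersected with each fold's training chains; real mode keeps the
  natural imbalance. If negatives are fewer than positives, balancing
  degrades to real mode with a warning.
* Thresholding: predict positive iff score ≥ threshold (the tie counts as
  positive; the source description never states tie handling).
* Cross-validation: seeded shuffle of chain ids, round-robin assignment
  to k=5 folds (sizes differ by ≤1). Folds are chain-level, so no window
  of one protein ever appears on both sides of a split. The final report
  is the unweighted mean of per-fold metrics (matching "averaging the
  performance of the five sets"), not a pooled tally.
* MCC with a zero denominator factor is defined as 0 and flagged in the
  report. ROC is a native sweep over distinct scores with trapezoidal
  AUC; ties are grouped.
* Protein-level calling: fraction of predicted NIRs over length, binder
  iff fraction ≥ 0.10 (boundary inclusive — "10 or more residues of 100"),
  with the residue threshold raised to 0.3 in this mode.

## Synthetic world

`SimConfig` defaults state the world once: 50 chains (recovery
experiments use 150 explicitly), lengths uniform on 60–80, uniform
background over the 20 amino acids, one planted `GxGxxG` motif per chain
with wildcard positions drawn from the enriched alphabet {G,Y,T,H,S},
labels = motif span ± 1 flanking residue (the smallest non-trivial flank
consistent with the "motif plus enriched flanks" label rule), optional
per-residue label-flip noise.

Pseudo-profiles give labeled positions a conserved signature (self-score
= strength + noise, off-scores = −strength + noise, integer noise in
[−2, 2]; default strength 9) and unlabeled positions pure noise. When
label noise is applied, profiles are generated from the noisy labels: the
profile is a conservation-signal carrier, so profile mode retains
near-perfect information while the noise caps what the one-hot model can
reach — reproducing the published profile > sequence ordering as a trend,
not its absolute numbers.

Toy complexes are deterministic line geometry: CA atoms at 3.8 Å spacing,
one CB pseudo-atom per residue (including toy glycines), and one NAD
heteroatom per labeled residue. Labeled residues' CB extends 14 Å off the
backbone line and the NAD atom sits 3 Å beyond it; this is the only
arrangement on a 3.8 Å line in which every NAD atom is simultaneously
3.0 Å from its target side chain and ≥ 15 Å (actually ≥ 15.9 Å) from
every unlabeled side-chain atom, so contact labeling recovers the planted
labels exactly for any cutoff in (3.0, 15.0) Å. Placement is verified at
generation time and raises if the separation fails.

What a green recovery test establishes: the pipeline finds a planted,
strongly localized sequence signal through every stage (structure →
labels → windows → SVM → CV → protein call). What it does not establish:
performance on real structures — there is no fold geometry, no homology,
no compositional bias beyond the planted one, and the published
PDB-scale numbers (74.13%/MCC 0.47 binary at W=17; 87.25%/MCC 0.75
profile at W=19; 72% protein-level accuracy) depend on external datasets
and profile databases that are out of scope here.

## Numerical and design choices

* Degenerate inputs: empty evaluation → error; single-class training →
  error; structure without ligand atoms → all-zero labels + warning;
  empty chain list → empty outputs.
* `ResidueSVC` accepts any two label values (sklearn estimator-check
  conformance) but the pipeline uses 0/1 throughout.
* Whether the published models were trained on the equal or the real
  dataset is unstated; both modes are exposed, with equal as the default
  for training (it is the variant a balanced-MCC selection implies).
* Kernel specs are accepted both as long names and as the short-letter
  lines of the published parameter tables (`t 2 g 0.1 j 1 c 10`).
* All randomness flows from explicit integer seeds (numpy default_rng);
  CLI runs record their resolved configuration as JSON next to outputs.

## Known limitations

* The distance-cutoff contact criterion is a declared approximation of
  the original surface-complementarity annotation, not a claim of
  equivalence.
* Greedy identity clustering approximates CD-HIT; cluster membership can
  differ from CD-HIT's on borderline pairs.
* Profile generation (PSI-BLAST against nr, 3 iterations, e-value 0.001)
  is consumed as files, never executed; the pseudo-profile generator is a
  statistical stand-in, not an evolutionary simulation.
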