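# nadbinder

Sequence-based prediction of NAD-interacting residues (NIRs) in proteins.

Nicotinamide adenine dinucleotide (NAD) is one of the most widely used
organic cofactors; annotating which proteins bind it — and through which
residues — usually requires a solved complex structure. `nadbinder`
implements the classic sequence-only alternative: a kernel SVM classifies
every residue from a sliding window of its sequence neighbourhood, using
either a one-hot encoding of the window or an evolutionary profile
(PSI-BLAST PSSM), and whole chains are called NAD binders when enough of
their residues are predicted to interact.

## The method

For a chain of length L, each residue i is represented by the odd-length
window of W residues centred on it; termini are padded with (W−1)/2 dummy
`X` residues, so every chain yields exactly L windows. Two feature
encodings are supported:

* **binary** — each window position is a 21-dimensional one-hot block
  (20 amino acids + `X`), giving a 21·W vector;
* **pssm** — each window position contributes the 20 position-specific
  log-odds scores of the chain's profile, squashed into [0, 1] by a
  logistic; padding positions contribute zero rows (20·W vector).

A soft-margin SVM (linear / polynomial / rbf / sigmoid kernel, cost C,
positive-class cost factor j — the historical `t/d/g/j/c` notation is
parsed directly) is trained on all interacting residues plus an equally
sized seeded sample of non-interacting ones, and scored residues are
called interacting when the margin score reaches a threshold. Evaluation
is five-fold cross-validation with folds assigned at chain level, reporting

    Sn = TP/(TP+FN)·100   Sp = TN/(TN+FP)·100   Acc = (TP+TN)/N·100
    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

plus ROC/AUC from a native threshold sweep. A chain is called an NAD
binder when the fraction of predicted interacting residues reaches 10% of
its length at a residue-score threshold of 0.3 (a 100-residue query with
10+ predicted NIRs is a binder call).

Training labels can be derived from protein–NAD complex structures:
residue i is interacting when any of its side-chain heavy atoms lies
within a cutoff (default 4.5 Å) of any NAD atom (for glycine the CA
counts as the side chain). Datasets are made non-redundant by greedy
longest-first clustering at 40% pairwise identity.

## Worked example

```python
import nadbinder as nb

# a synthetic world: 150 chains, each carrying one GxGxxG-style motif
cfg = nb.SimConfig(n_chains=150, seed=1)
chains, labels, _ = nb.simulate_chains(cfg)

res = nb.cross_validate(chains, labels, "t 2 g 0.1 j 1 c 10",
                        nb.WindowConfig(17), "binary", seed=1)
m = res.mean
print(f"Sn {m.Sn:.1f}  Sp {m.Sp:.1f}  Acc {m.Acc:.1f}  MCC {m.MCC:.3f}")
```

prints

```
Sn 100.0  Sp 97.6  Acc 97.9  MCC 0.906
```

i.e. five-fold cross-validated sensitivity 100% (every planted motif
residue recovered), specificity 97.6% (a few background residues
mis-called), and Matthews correlation 0.906. On this synthetic world the
signal is a planted local motif, so performance is far above what is
reachable on real structural data.

The same pipeline is available from the shell:

```
nadbinder simulate --out fixtures --n-chains 50 --seed 1
nadbinder build-dataset --pdb-dir fixtures/pdb --out dataset
nadbinder cv dataset/dataset.labeled.fasta --out cv -W 17
nadbinder train dataset/dataset.labeled.fasta --out model.joblib -W 17
nadbinder predict query.fasta --model model.joblib --out pred --threshold 0.3
```

`predict` writes a per-residue score table, a marked FASTA (interacting
residues upper-cased with a parallel `*` line) and a protein-level binder
call table.

## Scikit-learn interface

`SlidingWindowEncoder` (chains → per-residue feature rows) and
`ResidueSVC` (a binary classifier with `fit` / `predict` /
`decision_function`, passing `sklearn.utils.estimator_checks`) compose
with sklearn model selection; the module-level functions (`train`,
`cross_validate`, `sweep_windows`, ...) are thin wrappers over them.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline from scratch: it simulates the synthetic
world, verifies that contact labeling recovers the planted contacts from
toy PDB complexes, cross-validates the one-hot and profile models
(including the profile-beats-sequence comparison under 10% label noise
and a label-permutation null), makes protein-level binder calls, prints a
summary and writes the JSON report to `--out`.
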