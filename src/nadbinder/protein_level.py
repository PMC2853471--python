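"""Protein-level aggregation and compositional analysis.

A whole chain is called an NAD binder when the fraction of its residues
predicted to interact reaches a cutoff (default 10% of the length, with
the residue decision threshold raised to 0.3 in this mode): a 100-residue
query with 10 or more predicted interacting residues is called a binder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structures import AMINO_ACIDS, ProteinChain, ResidueLabelSet

__all__ = [
    "ProteinCall",
    "nir_fraction",
    "classify_protein",
    "call_protein",
    "composition",
]

#: Residue decision-score threshold recommended for binder calling.
BINDER_SCORE_THRESHOLD = 0.3
#: Fraction of predicted interacting residues at which a chain is called a binder.
BINDER_FRACTION_CUTOFF = 0.10


@dataclass(frozen=True)
class ProteinCall:
    chain_id: str
    predicted_fraction: float
    is_binder: bool
    score_threshold: float
    fraction_cutoff: float


def nir_fraction(predictions) -> float:
    """Predicted-positive count over chain length, i.e. (TP + FP) / L."""
    pred = np.asarray(predictions).astype(int)
    if pred.size == 0:
        raise ValueError("empty prediction vector")
    return float(pred.sum() / pred.size)


def classify_protein(fraction: float, cutoff: float = BINDER_FRACTION_CUTOFF) -> bool:
    """Binder iff fraction >= cutoff (boundary inclusive)."""
    if not 0 < cutoff <= 1:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    return bool(fraction >= cutoff)


def call_protein(
    chain_id: str,
    predictions,
    cutoff: float = BINDER_FRACTION_CUTOFF,
    score_threshold: float = BINDER_SCORE_THRESHOLD,
) -> ProteinCall:
    frac = nir_fraction(predictions)
    return ProteinCall(chain_id, frac, classify_protein(frac, cutoff), score_threshold, cutoff)


def composition(
    chains: list[ProteinChain], labels: list[ResidueLabelSet]
) -> pd.DataFrame:
    """Percentage amino-acid composition of the interacting (NIR) vs
    non-interacting residue sets; 'X' residues excluded from both. Each
    column sums to 100."""
    counts = {"NIR": dict.fromkeys(AMINO_ACIDS, 0), "non-NIR": dict.fromkeys(AMINO_ACIDS, 0)}
    for chain, lab in zip(chains, labels, strict=True):
        if len(chain) != len(lab):
            raise ValueError(f"labels for chain {chain.id!r} not aligned")
        for aa, v in zip(chain.sequence, lab.labels):
            if aa == "X":
                continue
            counts["NIR" if v else "non-NIR"][aa] += 1
    table = pd.DataFrame(counts, index=list(AMINO_ACIDS))
    totals = table.sum(axis=0)
    if (totals == 0).any():
        empty = totals[totals == 0].index.tolist()
        raise ValueError(f"empty residue class(es): {empty}")
    return 100.0 * table / totals
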