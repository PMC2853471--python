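"""Sliding-window feature encoding of residues.

Each residue is classified from an odd-length window centred on it. Two
encodings are supported:

* binary — each window position is a 21-dimensional one-hot block
  (20 amino acids + the terminal dummy 'X'), giving a 21*W vector;
* pssm — each window position contributes the 20 log-odds scores of a
  position-specific scoring matrix, squashed into [0, 1] by a logistic,
  giving a 20*W vector. Window positions that fall into the terminal 'X'
  padding contribute all-zero rows (zero both pre- and post-scaling, so
  padding is distinguishable from a real zero score, which scales to 0.5).

Termini are handled by appending (W-1)/2 dummy 'X' residues on each side,
so every chain yields exactly L windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .structures import ALPHABET, AMINO_ACIDS, ProteinChain, ResidueLabelSet

__all__ = [
    "WindowConfig",
    "WindowPattern",
    "PSSMProfile",
    "PSSMFormatError",
    "pad_sequence",
    "make_windows",
    "encode_binary",
    "decode_binary",
    "parse_pssm_ascii",
    "write_pssm_ascii",
    "encode_pssm",
    "build_feature_matrix",
    "SlidingWindowEncoder",
]

_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Scalers mapping raw integer log-odds scores into a bounded range.
PSSM_SCALERS = {
    "logistic": lambda x: 1.0 / (1.0 + np.exp(-x)),
    "identity": lambda x: np.asarray(x, dtype=float),
    "div100": lambda x: np.asarray(x, dtype=float) / 100.0,
}


class PSSMFormatError(ValueError):
    """Raised for malformed or misaligned ASCII profile files."""


@dataclass(frozen=True)
class WindowConfig:
    """Odd window length W; pad = (W-1)/2 dummy residues per terminus."""

    W: int = 17

    def __post_init__(self):
        if self.W < 3 or self.W % 2 == 0:
            raise ValueError(f"window length must be an odd integer >= 3, got {self.W}")

    @property
    def pad(self) -> int:
        return (self.W - 1) // 2


@dataclass(frozen=True)
class WindowPattern:
    """A W-residue pattern centred on residue ``center_index`` (0-based,
    unpadded coordinates); ``label`` is the centre residue's class."""

    center_index: int
    residues: str
    label: int | None = None


@dataclass(frozen=True)
class PSSMProfile:
    """L x 20 integer log-odds matrix aligned to a chain.

    Column order A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V (the first score
    block of a PSI-BLAST ``-out_ascii_pssm`` file).
    """

    chain_id: str
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[1] != 20:
            raise ValueError(f"profile matrix must be L x 20, got shape {m.shape}")
        object.__setattr__(self, "matrix", m.astype(int))

    def __len__(self) -> int:
        return self.matrix.shape[0]


def pad_sequence(chain: ProteinChain | str, cfg: WindowConfig) -> str:
    """Append (W-1)/2 'X' at both termini (8 per side for W=17)."""
    seq = chain.sequence if isinstance(chain, ProteinChain) else chain
    return "X" * cfg.pad + seq + "X" * cfg.pad


def make_windows(
    chain: ProteinChain | str,
    cfg: WindowConfig,
    labels: ResidueLabelSet | None = None,
) -> list[WindowPattern]:
    """All L overlapping windows of a chain; window i is centred on residue i."""
    seq = chain.sequence if isinstance(chain, ProteinChain) else chain
    padded = pad_sequence(seq, cfg)
    lab = labels.labels if labels is not None else None
    if lab is not None and len(lab) != len(seq):
        raise ValueError("labels not aligned to chain")
    return [
        WindowPattern(i, padded[i : i + cfg.W], None if lab is None else lab[i])
        for i in range(len(seq))
    ]


def encode_binary(pattern: WindowPattern | str) -> np.ndarray:
    """One-hot encode a window: W blocks of 21, exactly one 1 per block."""
    residues = pattern.residues if isinstance(pattern, WindowPattern) else pattern
    out = np.zeros(21 * len(residues))
    for i, aa in enumerate(residues):
        try:
            out[21 * i + _AA_INDEX[aa]] = 1.0
        except KeyError:
            raise ValueError(f"illegal residue character {aa!r} in window") from None
    return out


def decode_binary(vector: np.ndarray) -> str:
    """Inverse of :func:`encode_binary` (injectivity check)."""
    blocks = np.asarray(vector).reshape(-1, 21)
    return "".join(ALPHABET[int(b.argmax())] for b in blocks)


# -- ASCII PSSM I/O ---------------------------------------------------------

def parse_pssm_ascii(text: str, chain: ProteinChain | None = None) -> PSSMProfile:
    """Parse the PSI-BLAST ``-out_ascii_pssm`` layout (first score block).

    Rows look like ``  12 G   -1  0 ... `` — index, residue letter, 20
    log-odds integers (followed by percentages we ignore). When ``chain``
    is given, the residue column must match its sequence.
    """
    rows: list[list[int]] = []
    letters: list[str] = []
    chain_id = chain.id if chain is not None else "pssm"
    for lineno, raw in enumerate(text.splitlines(), 1):
        fields = raw.split()
        if len(fields) < 22:
            continue
        if not fields[0].isdigit():
            continue
        if len(fields[1]) != 1 or fields[1] not in ALPHABET:
            continue
        try:
            scores = [int(v) for v in fields[2:22]]
        except ValueError:
            raise PSSMFormatError(f"line {lineno}: malformed score row") from None
        letters.append(fields[1])
        rows.append(scores)
    if not rows:
        raise PSSMFormatError("no profile rows found")
    if chain is not None:
        if len(rows) != len(chain):
            raise PSSMFormatError(
                f"profile has {len(rows)} rows but chain {chain.id!r} "
                f"has {len(chain)} residues"
            )
        if "".join(letters) != chain.sequence:
            raise PSSMFormatError(
                f"profile residue column disagrees with chain {chain.id!r} sequence"
            )
    return PSSMProfile(chain_id, np.array(rows, dtype=int))


def write_pssm_ascii(profile: PSSMProfile, sequence: str) -> str:
    """Emit a profile in the ASCII layout :func:`parse_pssm_ascii` reads."""
    if len(sequence) != len(profile):
        raise ValueError("sequence not aligned to profile")
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "  ".join(AMINO_ACIDS) + "   " + "  ".join(AMINO_ACIDS),
    ]
    for i, (aa, row) in enumerate(zip(sequence, profile.matrix), 1):
        scores = " ".join(f"{int(v):3d}" for v in row)
        percentages = " ".join(f"{0:3d}" for _ in row)
        lines.append(f"{i:5d} {aa} {scores} {percentages}  0.00 0.00")
    lines.append("")
    return "\n".join(lines)


def encode_pssm(
    profile: PSSMProfile,
    center_index: int,
    cfg: WindowConfig,
    scaler: str = "logistic",
) -> np.ndarray:
    """Encode the window centred at ``center_index`` from a profile.

    Rows beyond the termini (the 'X' padding) are all-zero and are not
    passed through the scaler.
    """
    L = len(profile)
    if not 0 <= center_index < L:
        raise IndexError(f"center index {center_index} outside chain of length {L}")
    scale = PSSM_SCALERS[scaler]
    out = np.zeros((cfg.W, 20))
    for k in range(cfg.W):
        j = center_index - cfg.pad + k
        if 0 <= j < L:
            out[k] = scale(profile.matrix[j].astype(float))
    return out.ravel()


# -- dataset assembly -------------------------------------------------------

def _binary_rows(seq: str, cfg: WindowConfig) -> np.ndarray:
    idx = np.array([_AA_INDEX[aa] for aa in pad_sequence(seq, cfg)])
    onehot = np.eye(21)[idx]
    windows = np.lib.stride_tricks.sliding_window_view(onehot, (cfg.W, 21))
    return windows.reshape(len(seq), cfg.W * 21)


def _pssm_rows(profile: PSSMProfile, cfg: WindowConfig, scaler: str) -> np.ndarray:
    scaled = PSSM_SCALERS[scaler](profile.matrix.astype(float))
    padded = np.vstack(
        [np.zeros((cfg.pad, 20)), scaled, np.zeros((cfg.pad, 20))]
    )
    windows = np.lib.stride_tricks.sliding_window_view(padded, (cfg.W, 20))
    return windows.reshape(len(profile), cfg.W * 20)


def build_feature_matrix(
    chains: list[ProteinChain],
    labels: list[ResidueLabelSet] | None,
    mode: str,
    cfg: WindowConfig,
    profiles: dict[str, PSSMProfile] | None = None,
    scaler: str = "logistic",
) -> tuple[np.ndarray, np.ndarray | None, pd.DataFrame]:
    """Stack per-residue window features for a whole dataset.

    Returns ``(X, y, index)`` where ``index`` is a provenance frame with
    one (chain_id, residue_index) row per feature row, used downstream for
    chain-level fold assignment and protein-level aggregation. ``y`` is
    None when ``labels`` is None.
    """
    if mode not in ("binary", "pssm"):
        raise ValueError(f"mode must be 'binary' or 'pssm', got {mode!r}")
    blocks, ys, idx_chain, idx_res = [], [], [], []
    label_by_id = {l.chain_id: l for l in labels} if labels is not None else None
    for chain in chains:
        if mode == "binary":
            rows = _binary_rows(chain.sequence, cfg)
        else:
            if profiles is None or chain.id not in profiles:
                raise KeyError(f"pssm mode: no profile supplied for chain {chain.id!r}")
            profile = profiles[chain.id]
            if len(profile) != len(chain):
                raise ValueError(f"profile for chain {chain.id!r} not aligned")
            rows = _pssm_rows(profile, cfg, scaler)
        blocks.append(rows)
        idx_chain.extend([chain.id] * len(chain))
        idx_res.extend(range(len(chain)))
        if label_by_id is not None:
            lab = label_by_id[chain.id]
            if len(lab) != len(chain):
                raise ValueError(f"labels for chain {chain.id!r} not aligned")
            ys.append(lab.as_array())
    X = np.vstack(blocks) if blocks else np.empty((0, 0))
    y = np.concatenate(ys).astype(int) if label_by_id is not None and ys else None
    index = pd.DataFrame({"chain_id": idx_chain, "residue_index": idx_res})
    return X, y, index


class SlidingWindowEncoder(TransformerMixin, BaseEstimator):
    """Stateless transformer from chains to per-residue window features.

    Parameters
    ----------
    window : odd int, default 17
        Window length W. The value 17 is where single-sequence (binary)
        models peak; profile models peak near 19.
    mode : {'binary', 'pssm'}
    scaler : {'logistic', 'identity', 'div100'}
        How raw profile scores are squashed (pssm mode only).

    Notes
    -----
    ``transform`` maps n chains to sum(L_i) feature rows; use the index
    returned by :func:`build_feature_matrix` when row provenance matters.
    """

    def __init__(self, window: int = 17, mode: str = "binary", scaler: str = "logistic"):
        self.window = window
        self.mode = mode
        self.scaler = scaler

    def fit(self, X, y=None):
        WindowConfig(self.window)  # validate
        if self.mode not in ("binary", "pssm"):
            raise ValueError(f"mode must be 'binary' or 'pssm', got {self.mode!r}")
        self.n_features_out_ = (21 if self.mode == "binary" else 20) * self.window
        return self

    def transform(self, X, profiles: dict[str, PSSMProfile] | None = None):
        """X: list of ProteinChain (or plain strings in binary mode)."""
        if not hasattr(self, "n_features_out_"):
            self.fit(X)
        chains = [
            c if isinstance(c, ProteinChain) else ProteinChain(f"seq{i}", c)
            for i, c in enumerate(X)
        ]
        mat, _, _ = build_feature_matrix(
            chains, None, self.mode, WindowConfig(self.window), profiles, self.scaler
        )
        return mat
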