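"""Structure-derived labeling of ligand-contacting residues.

Residues whose side chain lies close to a bound NAD molecule in a
protein--NAD complex are the positive class of the whole method. The
original annotation came from a surface-complementarity contact server;
here a heavy-atom distance cutoff (default 4.5 A) stands in for it, which
is monotone in the cutoff and therefore testable.

Also provides CD-HIT-style greedy redundancy reduction and the labeled
FASTA dialect (a '.'/'*' line parallel to the sequence) used to ship
training data.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from Bio.PDB.Polypeptide import protein_letters_3to1

__all__ = [
    "AtomRecord",
    "ComplexStructure",
    "ProteinChain",
    "ResidueLabelSet",
    "PDBFormatError",
    "LabeledFastaError",
    "parse_pdb_complex",
    "label_contacts",
    "pairwise_identity",
    "reduce_redundancy",
    "load_cluster_representatives",
    "parse_labeled_fasta",
    "write_labeled_fasta",
    "write_manifest",
]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
#: 21-letter alphabet: the 20 amino acids plus the dummy/unknown symbol.
ALPHABET = AMINO_ACIDS + "X"

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


class PDBFormatError(ValueError):
    """Raised for unparseable or empty coordinate input."""


class LabeledFastaError(ValueError):
    """Raised for malformed labeled-FASTA records."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom from an ATOM/HETATM record (author numbering)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    coord: tuple[float, float, float]
    is_hetero: bool


@dataclass(frozen=True)
class ProteinChain:
    """A chain identifier plus its one-letter sequence over the 21-letter alphabet."""

    id: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"chain {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"chain {self.id!r}: illegal characters {sorted(bad)!r}; "
                f"alphabet is {ALPHABET!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ResidueLabelSet:
    """Per-residue binary labels (1 = ligand-interacting) aligned to a chain."""

    chain_id: str
    labels: tuple[int, ...]

    def __post_init__(self):
        if any(v not in (0, 1) for v in self.labels):
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.labels)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=np.int8)


@dataclass
class _Residue:
    number: int
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def one_letter(self) -> str:
        return protein_letters_3to1.get(self.name, "X")


@dataclass
class ComplexStructure:
    """Flattened first-model view of a protein--ligand complex."""

    atoms: list[AtomRecord]
    ligand_code: str = "NAD"
    _residues_by_chain: dict[str, list[_Residue]] = field(default_factory=dict)

    @property
    def ligand_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_hetero and a.residue_name == self.ligand_code]

    @property
    def chain_ids(self) -> list[str]:
        return list(self._residues_by_chain)

    def chain_sequence(self, chain_id: str) -> ProteinChain:
        residues = self._chain(chain_id)
        return ProteinChain(chain_id, "".join(r.one_letter for r in residues))

    def _chain(self, chain_id: str) -> list[_Residue]:
        try:
            return self._residues_by_chain[chain_id]
        except KeyError:
            raise KeyError(
                f"chain {chain_id!r} not in structure (have {self.chain_ids})"
            ) from None


def parse_pdb_complex(text: str, ligand_code: str = "NAD") -> ComplexStructure:
    """Parse PDB-format text into a :class:`ComplexStructure`.

    Only the first model is used; for alternate locations the conformer
    Biopython selects (highest occupancy) is kept. Hydrogens are dropped:
    the contact criterion is defined on heavy atoms.

    Raises
    ------
    PDBFormatError
        If no ATOM records are present, or a coordinate field cannot be
        parsed (the message names the offending line).
    """
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure("complex", io.StringIO(text))
    except PDBConstructionException as exc:
        raise PDBFormatError(str(exc)) from exc
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise PDBFormatError("no ATOM records found") from None

    atoms: list[AtomRecord] = []
    residues_by_chain: dict[str, list[_Residue]] = {}
    n_standard = 0
    for chain in model:
        for residue in chain:
            hetfield, resseq, _icode = residue.id
            is_hetero = hetfield.strip() != ""
            rec_atoms = []
            for atom in residue.get_atoms():
                if atom.element == "H":
                    continue
                x, y, z = atom.get_coord()
                rec_atoms.append(
                    AtomRecord(
                        chain_id=chain.id,
                        residue_number=int(resseq),
                        residue_name=residue.get_resname().strip(),
                        atom_name=atom.get_name(),
                        coord=(float(x), float(y), float(z)),
                        is_hetero=is_hetero,
                    )
                )
            atoms.extend(rec_atoms)
            if not is_hetero and rec_atoms:
                n_standard += 1
                residues_by_chain.setdefault(chain.id, []).append(
                    _Residue(int(resseq), residue.get_resname().strip(), rec_atoms)
                )
    if n_standard == 0:
        raise PDBFormatError("no ATOM records found")
    return ComplexStructure(atoms, ligand_code, residues_by_chain)


def _side_chain_atoms(residue: _Residue) -> list[AtomRecord]:
    side = [a for a in residue.atoms if a.atom_name not in BACKBONE_ATOMS]
    # Glycine has no side-chain heavy atom in real structures; treating its
    # CA as the side chain keeps Gly eligible as an interacting residue.
    if residue.name == "GLY":
        side.extend(a for a in residue.atoms if a.atom_name == "CA")
    return side


def label_contacts(
    structure: ComplexStructure, chain_id: str, cutoff: float = 4.5
) -> ResidueLabelSet:
    """Label residue i positive iff a side-chain heavy atom is within
    ``cutoff`` angstroms of any ligand atom.

    Nonstandard residues (mapped to 'X') are never labeled positive.
    A structure without ligand atoms yields all-zero labels and a warning.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    residues = structure._chain(chain_id)
    ligand = structure.ligand_atoms
    if not ligand:
        warnings.warn(
            f"no {structure.ligand_code!r} ligand atoms in structure; all labels 0",
            stacklevel=2,
        )
        return ResidueLabelSet(chain_id, tuple([0] * len(residues)))
    ligand_xyz = np.array([a.coord for a in ligand])
    labels = []
    for res in residues:
        side = _side_chain_atoms(res)
        if not side or res.one_letter == "X":
            labels.append(0)
            continue
        xyz = np.array([a.coord for a in side])
        d2 = ((xyz[:, None, :] - ligand_xyz[None, :, :]) ** 2).sum(axis=2)
        labels.append(int(d2.min() <= cutoff * cutoff))
    return ResidueLabelSet(chain_id, tuple(labels))


# -- redundancy reduction ---------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="global")
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Fraction of identical aligned positions over the shorter sequence,
    from a global alignment with strict gap penalties."""
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(a, b)[0]
    return aln.counts().identities / min(len(a), len(b))


def reduce_redundancy(
    chains: list[ProteinChain], identity_threshold: float = 0.40
) -> list[ProteinChain]:
    """Greedy longest-first clustering; returns cluster representatives.

    A chain joins the first existing representative whose pairwise identity
    with it exceeds ``identity_threshold``; otherwise it founds a new
    cluster. Deterministic: chains are processed longest first, ties broken
    by id.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError(f"identity threshold must be in (0, 1], got {identity_threshold}")
    aligner = _make_aligner()
    ordered = sorted(chains, key=lambda c: (-len(c), c.id))
    reps: list[ProteinChain] = []
    for chain in ordered:
        for rep in reps:
            if pairwise_identity(chain.sequence, rep.sequence, aligner) > identity_threshold:
                break
        else:
            reps.append(chain)
    return reps


def load_cluster_representatives(
    text: str, chains: list[ProteinChain]
) -> list[ProteinChain]:
    """Import externally produced clustering (e.g. CD-HIT): one line per
    cluster, whitespace-separated chain ids, first id = representative."""
    by_id = {c.id: c for c in chains}
    reps = []
    for line in text.splitlines():
        fields = line.split()
        if not fields:
            continue
        rep_id = fields[0]
        if rep_id not in by_id:
            raise KeyError(f"cluster representative {rep_id!r} not among input chains")
        reps.append(by_id[rep_id])
    return reps


# -- labeled FASTA dialect --------------------------------------------------

def parse_labeled_fasta(text: str) -> tuple[list[ProteinChain], list[ResidueLabelSet]]:
    """Parse the labeled dialect: header, sequence line(s), then one label
    line of '.'/'*' of equal length ('*' = interacting)."""
    chains: list[ProteinChain] = []
    labels: list[ResidueLabelSet] = []
    record_lines: list[str] = []
    header: str | None = None

    def flush():
        if header is None:
            return
        name = header[1:].split()[0] if len(header) > 1 else header[1:]
        if not record_lines:
            raise LabeledFastaError(f"record {name!r}: no sequence or label line")
        label_line = record_lines[-1]
        if not label_line or set(label_line) - {".", "*"}:
            raise LabeledFastaError(f"record {name!r}: missing '.'/'*' label line")
        seq = "".join(record_lines[:-1])
        if not seq:
            raise LabeledFastaError(f"record {name!r}: missing sequence line")
        if len(label_line) != len(seq):
            raise LabeledFastaError(
                f"record {name!r}: label length {len(label_line)} != "
                f"sequence length {len(seq)}"
            )
        chains.append(ProteinChain(name, seq))
        labels.append(
            ResidueLabelSet(name, tuple(1 if c == "*" else 0 for c in label_line))
        )

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line
            record_lines = []
        else:
            if header is None:
                raise LabeledFastaError("sequence data before first header")
            record_lines.append(line)
    flush()
    return chains, labels


def write_labeled_fasta(
    chains: list[ProteinChain], labels: list[ResidueLabelSet]
) -> str:
    """Inverse of :func:`parse_labeled_fasta` (write-then-parse is identity)."""
    out = []
    for chain, lab in zip(chains, labels, strict=True):
        if len(chain) != len(lab):
            raise LabeledFastaError(
                f"record {chain.id!r}: label length {len(lab)} != sequence length {len(chain)}"
            )
        marks = "".join("*" if v else "." for v in lab.labels)
        out.append(f">{chain.id}\n{chain.sequence}\n{marks}\n")
    return "".join(out)


def write_manifest(chains: list[ProteinChain], labels: list[ResidueLabelSet]) -> str:
    """TSV dataset manifest: chain_id, length, n_positive."""
    lines = ["chain_id\tlength\tn_positive"]
    for chain, lab in zip(chains, labels, strict=True):
        lines.append(f"{chain.id}\t{len(chain)}\t{int(sum(lab.labels))}")
    return "\n".join(lines) + "\n"
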