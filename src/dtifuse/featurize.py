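"""Featurization of raw inputs into the four modality representations.

A drug is viewed through two lenses: its SMILES string tokenized
character-by-character, and its molecular graph with per-atom and
per-bond feature vectors.  A protein is likewise viewed twice: its
residue sequence tokenized per residue, and its k-mer sequence obtained
by sliding a length-k window one residue at a time (k defaults to 2
downstream).  Token streams are integer vectors padded with id 0 to a
fixed length, carried together with a validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .alphabets import residue_alphabet, smiles_alphabet, SmilesAlphabet

RDLogger.DisableLog("rdApp.*")

# Number of chemical properties encoded per atom / per bond (the feature
# vectors below are concatenations of encodings of exactly these many
# properties).
ATOM_PROPERTY_COUNT = 8
BOND_PROPERTY_COUNT = 4

# Default length caps per modality.
DEFAULT_L_SMILES = 150
DEFAULT_L_PROTEIN = 1000


def default_kmer_cap(k: int, protein_cap: int = DEFAULT_L_PROTEIN) -> int:
    """Length cap for the k-mer stream of a protein capped at ``protein_cap``."""
    return protein_cap - k + 1


class InvalidInputError(ValueError):
    """Raised when an input string violates a featurizer precondition."""


class SmilesParseError(InvalidInputError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


@dataclass
class TokenVector:
    """Padded integer token ids plus validity mask for one modality."""

    ids: np.ndarray          # (L_max,) int64; 0 = padding
    mask: np.ndarray         # (L_max,) bool
    true_length: int

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph with directed-edge structure.

    Every chemical bond contributes two directed edges (v->w and w->v);
    ``rev_edge[e]`` is the index of the edge opposite to edge ``e``.
    """

    n_atoms: int
    atom_features: np.ndarray     # (n_atoms, f_atom)
    edge_src: np.ndarray          # (n_edges,) source atom of each directed edge
    edge_dst: np.ndarray          # (n_edges,) target atom
    bond_features: np.ndarray     # (n_edges, f_bond)
    rev_edge: np.ndarray          # (n_edges,) involution

    @property
    def n_edges(self) -> int:
        return len(self.edge_src)

    @property
    def directed_edges(self) -> list[tuple[int, int]]:
        return list(zip(self.edge_src.tolist(), self.edge_dst.tolist()))


def _pad_ids(ids: list[int], L_max: int) -> TokenVector:
    ids = ids[:L_max]
    n = len(ids)
    out = np.zeros(L_max, dtype=np.int64)
    out[:n] = ids
    mask = np.zeros(L_max, dtype=bool)
    mask[:n] = True
    return TokenVector(out, mask, n)


def encode_protein_sequence(seq: str, L_max: int = DEFAULT_L_PROTEIN) -> TokenVector:
    """Encode a residue sequence into integer ids in [1, 22], zero-padded.

    Residues outside the 22-symbol alphabet map to the fallback symbol
    ``X``.  Sequences longer than ``L_max`` keep their prefix.
    """
    if not seq:
        raise InvalidInputError("empty protein sequence")
    if L_max < 1:
        raise InvalidInputError("L_max must be >= 1")
    alpha = residue_alphabet()
    return _pad_ids([alpha.encode_char(c) for c in seq], L_max)


def kmer_vocab_size(k: int) -> int:
    """Vocabulary size 22**k of the k-mer token stream (padding excluded)."""
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    return 22 ** k


def kmer_token_id(kmer: str) -> int:
    """Positional base-22 id of a k-mer: contiguous ids in [1, 22**k]."""
    alpha = residue_alphabet()
    tid = 0
    for c in kmer:
        tid = tid * 22 + (alpha.encode_char(c) - 1)
    return tid + 1


def make_kmer_tokens(seq: str, k: int, L_max: int | None = None,
                     allow_large_k: bool = False) -> TokenVector:
    """Slide a length-k window one residue at a time and encode each k-mer.

    A sequence of length N yields N-k+1 tokens before truncation/padding.
    ``k`` must be in {1, 2, 3} unless ``allow_large_k`` is set: at k = 4
    the vocabulary grows to 22**4 = 234 256 entries, which the default
    configuration rejects.
    """
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    if k > 3 and not allow_large_k:
        raise InvalidInputError(
            f"k={k} rejected by default configuration (vocabulary 22**{k})")
    if len(seq) < k:
        raise InvalidInputError(f"sequence length {len(seq)} < k={k}")
    if L_max is None:
        L_max = default_kmer_cap(k)
    ids = [kmer_token_id(seq[i:i + k]) for i in range(len(seq) - k + 1)]
    return _pad_ids(ids, L_max)


def tokenize_smiles(smiles: str, L_max: int = DEFAULT_L_SMILES,
                    alphabet: SmilesAlphabet | None = None) -> TokenVector:
    """Per-character SMILES token ids in [1, 64], zero-padded to ``L_max``."""
    if not smiles:
        raise InvalidInputError("empty SMILES string")
    alpha = alphabet if alphabet is not None else smiles_alphabet()
    return _pad_ids([alpha.encode_char(c) for c in smiles], L_max)


# --- molecular graph featurization -------------------------------------

_ATOMIC_NUMS = [5, 6, 7, 8, 9, 14, 15, 16, 17, 35, 53]  # B C N O F Si P S Cl Br I
_DEGREES = [0, 1, 2, 3, 4, 5]
_CHARGES = [-2, -1, 0, 1, 2]
_CHIRALITY = [
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
    Chem.ChiralType.CHI_OTHER,
]
_NUM_HS = [0, 1, 2, 3, 4]
_HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]
_BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]
_STEREO = [
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOANY,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
]


def _one_hot(value, choices, with_other: bool = True) -> list[float]:
    vec = [1.0 if value == c else 0.0 for c in choices]
    if with_other:
        vec.append(0.0 if any(vec) else 1.0)
    return vec


def atom_feature_vector(atom: Chem.Atom) -> np.ndarray:
    """Concatenated encodings of the 8 atomic properties.

    atomic number, degree, formal charge, chirality, attached hydrogens,
    hybridization, aromaticity, atomic mass (scaled by 0.01).
    """
    feats = (
        _one_hot(atom.GetAtomicNum(), _ATOMIC_NUMS)
        + _one_hot(atom.GetTotalDegree(), _DEGREES, with_other=False)
        + _one_hot(atom.GetFormalCharge(), _CHARGES, with_other=False)
        + _one_hot(atom.GetChiralTag(), _CHIRALITY, with_other=False)
        + _one_hot(atom.GetTotalNumHs(), _NUM_HS, with_other=False)
        + _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + [atom.GetMass() * 0.01]
    )
    return np.asarray(feats, dtype=np.float64)


def bond_feature_vector(bond: Chem.Bond) -> np.ndarray:
    """Concatenated encodings of the 4 bond properties.

    bond type, bond position (ring membership), conjugation, stereochemistry.
    """
    feats = (
        _one_hot(bond.GetBondType(), _BOND_TYPES, with_other=False)
        + [1.0 if bond.IsInRing() else 0.0]
        + [1.0 if bond.GetIsConjugated() else 0.0]
        + _one_hot(bond.GetStereo(), _STEREO, with_other=False)
    )
    return np.asarray(feats, dtype=np.float64)


ATOM_FEATURE_DIM = 12 + 6 + 5 + 4 + 5 + 6 + 1 + 1   # 40
BOND_FEATURE_DIM = 4 + 1 + 1 + 6                    # 12


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom :class:`MolecularGraph`."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    n = mol.GetNumAtoms()
    atom_feats = np.zeros((n, ATOM_FEATURE_DIM), dtype=np.float64)
    for atom in mol.GetAtoms():
        atom_feats[atom.GetIdx()] = atom_feature_vector(atom)
    src, dst, bfeats = [], [], []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = bond_feature_vector(bond)
        src.extend((u, v))
        dst.extend((v, u))
        bfeats.extend((f, f))
    n_e = len(src)
    rev = np.arange(n_e, dtype=np.int64)
    rev[0::2] += 1
    rev[1::2] -= 1
    return MolecularGraph(
        n_atoms=n,
        atom_features=atom_feats,
        edge_src=np.asarray(src, dtype=np.int64),
        edge_dst=np.asarray(dst, dtype=np.int64),
        bond_features=(np.asarray(bfeats, dtype=np.float64)
                       if n_e else np.zeros((0, BOND_FEATURE_DIM))),
        rev_edge=rev,
    )


@dataclass
class FeaturizedPair:
    """All four modality inputs for one (drug, protein) record."""

    smiles_tokens: TokenVector
    graph: MolecularGraph
    seq_tokens: TokenVector
    mer_tokens: TokenVector


def featurize_pair(smiles: str, sequence: str, k: int = 2,
                   L_smiles: int = DEFAULT_L_SMILES,
                   L_protein: int = DEFAULT_L_PROTEIN) -> FeaturizedPair:
    """Featurize one interaction record through all four modalities."""
    return FeaturizedPair(
        smiles_tokens=tokenize_smiles(smiles, L_smiles),
        graph=smiles_to_graph(smiles),
        seq_tokens=encode_protein_sequence(sequence, L_protein),
        mer_tokens=make_kmer_tokens(sequence, k, default_kmer_cap(k, L_protein)),
    )
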