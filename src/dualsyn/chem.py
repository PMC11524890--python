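"""Drug featurization: SMILES to molecular graphs and Morgan fingerprints.

Each drug is represented two ways, feeding the two views of the model:

* a molecular graph over heavy atoms, one 78-dimensional feature row per
  atom (graph view);
* a radius-6 Morgan fingerprint bit vector (fingerprint view).

The 78-dim atom feature layout follows the convention popularized by
graph-based drug-response models: a 44-symbol one-hot (with an
out-of-vocabulary slot), degree one-hot over 0–10, total-hydrogen-count
one-hot over 0–10, implicit-valence one-hot over 0–10, and a single
aromaticity flag. Rows are left as raw one-hot indicators (no
normalization). Hydrogens are implicit: graphs contain heavy atoms only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

ATOM_SYMBOLS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb",
]  # 43 named symbols + 1 out-of-vocabulary slot = 44

N_ATOM_FEATURES = 78
_DEGREE_RANGE = list(range(11))
_HS_RANGE = list(range(11))
_VALENCE_RANGE = list(range(11))

DEFAULT_FP_BITS = 1024
DEFAULT_FP_RADIUS = 6


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom graph of one drug.

    ``edges`` stores each chemical bond once as a sorted (i, j) index
    pair; the graph is undirected by convention.
    """

    node_features: np.ndarray          # (n_atoms, 78)
    edges: frozenset[tuple[int, int]]  # unordered heavy-atom index pairs
    smiles: str = ""

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    def __post_init__(self):
        n = self.node_features.shape[0]
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop ({i},{j}) in molecular graph")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i},{j}) references invalid atom index")


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise SmilesParseError(f"SMILES has no heavy atoms: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def _one_hot(value, choices, out, offset, allow_unknown):
    try:
        idx = choices.index(value)
    except ValueError:
        if allow_unknown:
            idx = len(choices)  # OOV slot (symbol block) -- last position
        else:
            return  # out-of-range: leave the block all-zero
    out[offset + idx] = 1.0


def atom_features(atom: Chem.Atom) -> np.ndarray:
    """78-dim feature row for one heavy atom (see module docstring)."""
    x = np.zeros(N_ATOM_FEATURES)
    _one_hot(atom.GetSymbol(), ATOM_SYMBOLS, x, 0, allow_unknown=True)
    _one_hot(atom.GetDegree(), _DEGREE_RANGE, x, 44, allow_unknown=False)
    _one_hot(atom.GetTotalNumHs(), _HS_RANGE, x, 55, allow_unknown=False)
    _one_hot(atom.GetImplicitValence(), _VALENCE_RANGE, x, 66, allow_unknown=False)
    x[77] = 1.0 if atom.GetIsAromatic() else 0.0
    return x


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES into a heavy-atom molecular graph.

    Nodes are heavy atoms in RDKit atom order; edges are chemical bonds.

    Raises
    ------
    SmilesParseError
        If the SMILES does not parse or has no heavy atoms.
    """
    mol = _mol_from_smiles(smiles)
    feats = np.vstack([atom_features(a) for a in mol.GetAtoms()])
    edges = frozenset(
        tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx())))
        for b in mol.GetBonds()
    )
    return MolecularGraph(node_features=feats, edges=edges, smiles=smiles)


def smiles_to_fingerprint(smiles: str, n_bits: int = DEFAULT_FP_BITS,
                          radius: int = DEFAULT_FP_RADIUS) -> np.ndarray:
    """Morgan fingerprint as a 0/1 float vector of length ``n_bits``.

    Radius defaults to 6 (the model's convention); identical molecules
    produce identical bits regardless of SMILES atom ordering.
    """
    if n_bits < 64:
        raise ValueError("n_bits must be at least 64")
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits)
    for bit in fp.GetOnBits():
        arr[bit] = 1.0
    return arr


@dataclass
class DrugLibrary:
    """Drug name -> SMILES table with cached featurizations."""

    smiles: dict[str, str]
    fp_bits: int = DEFAULT_FP_BITS
    fp_radius: int = DEFAULT_FP_RADIUS
    _graphs: dict[str, MolecularGraph] = field(default_factory=dict, repr=False)
    _fps: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def graph(self, name: str) -> MolecularGraph:
        if name not in self._graphs:
            self._graphs[name] = smiles_to_graph(self.smiles[name])
        return self._graphs[name]

    def fingerprint(self, name: str) -> np.ndarray:
        if name not in self._fps:
            self._fps[name] = smiles_to_fingerprint(
                self.smiles[name], self.fp_bits, self.fp_radius
            )
        return self._fps[name]

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DrugLibrary":
        import pandas as pd

        df = pd.read_csv(path)
        if not {"drug_name", "smiles"}.issubset(df.columns):
            raise ValueError("drug table must have columns drug_name,smiles")
        return cls(smiles=dict(zip(df["drug_name"], df["smiles"])), **kwargs)
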