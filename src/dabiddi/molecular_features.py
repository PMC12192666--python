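"""SMILES parsing and DrugBank-style molecular descriptors.

Drugs are represented as molecular graphs: heavy atoms are nodes (hydrogens
implicit) and chemical bonds are edges.  Parsing and aromaticity perception
are delegated to RDKit; molecular weight is computed from an in-code table
of standard atomic masses (IUPAC 2021, three decimals) so that the reported
value is an auditable sum over the parsed graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Lipinski

RDLogger.DisableLog("rdApp.*")  # rdkit prints parse errors; we raise instead

# Standard atomic masses, IUPAC 2021, rounded to 3 decimals.  Elements
# outside this table fall back to RDKit's periodic table.
ATOMIC_MASS = {
    "H": 1.008, "B": 10.811, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "Mg": 24.305, "Si": 28.085, "P": 30.974,
    "S": 32.060, "Cl": 35.450, "K": 39.098, "Ca": 40.078, "Br": 79.904,
    "I": 126.904,
}

# One-hot element vocabulary for node feature matrices; the final slot is
# reserved for any element not listed.
ELEMENT_VOCAB = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P"]
N_ATOM_FEATURES = len(ELEMENT_VOCAB) + 1 + 3  # one-hot + other + deg/arom/charge


class SmilesParseError(ValueError):
    """Raised for syntactically invalid SMILES, with the offending position."""

    def __init__(self, smiles: str, position: int):
        self.smiles = smiles
        self.position = position
        super().__init__(
            f"invalid SMILES {smiles!r}: parse failure at or after "
            f"position {position} ({smiles[position:position + 8]!r})"
        )


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom graph of one molecule.

    atoms: ordered (element, aromatic flag, formal charge, implicit-H count),
    in SMILES input order.  bonds: (i, j, order) with order in {1, 2, 3,
    1.5 for aromatic}.
    """

    atoms: tuple
    bonds: tuple
    id: str = ""
    smiles: str = field(default="", compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_atoms, self.n_atoms))
        for i, j, _ in self.bonds:
            a[i, j] = a[j, i] = 1.0
        return a


@dataclass(frozen=True)
class DescriptorSet:
    mol_weight: float
    heavy_atom_count: int
    bond_count: int
    hbd: int
    hba: int


_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}


def _locate_parse_error(smiles: str) -> int:
    """Best-effort index of the first token at which parsing breaks."""
    for i in range(1, len(smiles) + 1):
        frag = Chem.MolFromSmiles(smiles[:i], sanitize=False)
        if frag is None:
            return i - 1
    return 0


def parse_smiles(smiles: str, mol_id: str = "") -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Atom order follows the SMILES input order; aromaticity follows RDKit's
    default perception.  Raises :class:`SmilesParseError` naming the
    offending token position for invalid input.
    """
    if not smiles:
        raise SmilesParseError(smiles, 0)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, _locate_parse_error(smiles))
    atoms = tuple(
        (a.GetSymbol(), a.GetIsAromatic(), a.GetFormalCharge(), a.GetTotalNumHs())
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_ORDER[b.GetBondType()])
        for b in mol.GetBonds()
    )
    return MolecularGraph(atoms=atoms, bonds=bonds, id=mol_id, smiles=smiles)


def _mass(symbol: str) -> float:
    if symbol in ATOMIC_MASS:
        return ATOMIC_MASS[symbol]
    return Chem.GetPeriodicTable().GetAtomicWeight(symbol)


def descriptors(g: MolecularGraph) -> DescriptorSet:
    """DrugBank-style descriptors for a parsed molecule.

    Molecular weight sums standard atomic masses over heavy atoms plus
    1.008 per hydrogen (implicit H counts from parsing) and is reported to
    two decimals, e.g. aspirin -> 180.16 g/mol.
    """
    weight = sum(_mass(sym) + ATOMIC_MASS["H"] * nh for sym, _, _, nh in g.atoms)
    # donor/acceptor counts use Lipinski definitions via rdkit
    mol = Chem.MolFromSmiles(g.smiles) if g.smiles else None
    hbd = Lipinski.NumHDonors(mol) if mol is not None else 0
    hba = Lipinski.NumHAcceptors(mol) if mol is not None else 0
    return DescriptorSet(
        mol_weight=round(weight, 2),
        heavy_atom_count=g.n_atoms,
        bond_count=g.n_bonds,
        hbd=hbd,
        hba=hba,
    )


def atom_features(g: MolecularGraph) -> np.ndarray:
    """Node feature matrix: one row per heavy atom.

    Layout: one-hot element over ``ELEMENT_VOCAB`` (+1 reserved slot for
    unknown elements), then degree, aromatic flag, formal charge.
    """
    n = g.n_atoms
    deg = np.zeros(n)
    for i, j, _ in g.bonds:
        deg[i] += 1
        deg[j] += 1
    X = np.zeros((n, N_ATOM_FEATURES))
    for idx, (sym, aromatic, charge, _) in enumerate(g.atoms):
        slot = ELEMENT_VOCAB.index(sym) if sym in ELEMENT_VOCAB else len(ELEMENT_VOCAB)
        X[idx, slot] = 1.0
        X[idx, len(ELEMENT_VOCAB) + 1] = deg[idx]
        X[idx, len(ELEMENT_VOCAB) + 2] = 1.0 if aromatic else 0.0
        X[idx, len(ELEMENT_VOCAB) + 3] = charge
    return X


def descriptor_table(molecules) -> pd.DataFrame:
    """Descriptor CSV layout ``id,mol_weight,heavy_atoms,bonds,hbd,hba``."""
    rows = []
    for mol_id, smiles in molecules:
        d = descriptors(parse_smiles(smiles, mol_id))
        rows.append(
            {
                "id": mol_id,
                "mol_weight": d.mol_weight,
                "heavy_atoms": d.heavy_atom_count,
                "bonds": d.bond_count,
                "hbd": d.hbd,
                "hba": d.hba,
            }
        )
    return pd.DataFrame(rows)


def read_smiles_file(path) -> list:
    """Read a file of ``id<TAB>smiles`` (or bare SMILES) lines."""
    out = []
    with open(path) as fh:
        for k, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                out.append((f"mol{k}", parts[0]))
            else:
                out.append((parts[0], parts[1]))
    return out
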