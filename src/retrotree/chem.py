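"""Thin RDKit helpers shared across the package.

Everything here operates on plain SMILES/InChI text or ``rdkit.Chem.Mol``
objects; no state is kept besides small caches.
"""
from __future__ import annotations

from functools import lru_cache

from rdkit import Chem, RDLogger

# InChI generation and aromatic-fragment sanitization are chatty on stderr;
# silence the RDKit C++ logger the way most downstream toolkits do.
RDLogger.DisableLog("rdApp.*")


class MoleculeError(ValueError):
    """Raised when a SMILES cannot be parsed or an InChI cannot be made."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def demap(mol: Chem.Mol) -> Chem.Mol:
    """Copy of *mol* with all atom-map numbers cleared."""
    out = Chem.Mol(mol)
    for atom in out.GetAtoms():
        atom.SetAtomMapNum(0)
    return out


def inchi_for_mol(mol: Chem.Mol) -> str:
    text = Chem.MolToInchi(demap(mol))
    if not text:
        raise MoleculeError(f"InChI generation failed for {Chem.MolToSmiles(mol)!r}")
    return text


@lru_cache(maxsize=100_000)
def inchi(smiles: str) -> str:
    return inchi_for_mol(mol_from_smiles(smiles))


@lru_cache(maxsize=100_000)
def inchikey(smiles: str) -> str:
    key = Chem.MolToInchiKey(demap(mol_from_smiles(smiles)))
    if not key:
        raise MoleculeError(f"InChIKey generation failed for {smiles!r}")
    return key


def largest_fragment(smiles: str) -> str:
    """Strip salts/counter-ions by keeping the fragment with most heavy atoms."""
    mol = mol_from_smiles(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    best = max(frags, key=lambda m: (m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))
    return Chem.MolToSmiles(best)
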