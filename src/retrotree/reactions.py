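"""Reaction-record parsing, curation, hashing, and deduplication.

Input records are single-step reaction SMILES of the Daylight form
``reactants>agents>products``.  Agents are folded into the reactant list on
parse (only species that contribute mapped atoms matter downstream), after
which a record is curated: it must have at least one reactant, exactly one
product, and the reactant set must not be InChI-equivalent to the product
set.  Curated reactions are identified by an order- and mapping-invariant
hash: atom maps are removed, each side is converted to standard InChIs,
sorted, concatenated reactants-then-products, and digested with SHA-256.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem

from .chem import MoleculeError, inchi_for_mol

REASON_OK = "ok"
REASON_MULTI_PRODUCT = "multi_product"
REASON_INCOMPLETE = "incomplete"
REASON_EQUAL = "reactants_equal_products"
REASON_UNPARSEABLE = "unparseable"

VALID_REASONS = frozenset(
    {REASON_OK, REASON_MULTI_PRODUCT, REASON_INCOMPLETE, REASON_EQUAL, REASON_UNPARSEABLE}
)


class ReactionParseError(ValueError):
    """Raised when a reaction SMILES cannot be turned into a MappedReaction."""


@dataclass(frozen=True)
class RawReactionRecord:
    """One line of a reaction file: SMILES plus optional id and class label."""

    reaction_smiles: str
    record_id: str = ""
    class_label: str | None = None


@dataclass(frozen=True)
class CurationVerdict:
    accepted: bool
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in VALID_REASONS:
            raise ValueError(f"unknown curation reason {self.reason!r}")
        if self.accepted != (self.reason == REASON_OK):
            raise ValueError("verdict accepted flag inconsistent with reason")


class MappedReaction:
    """A parsed single-step reaction with atom-map annotations retained.

    Agents have already been merged into ``reactants``; after curation there
    is at least one reactant and exactly one product.
    """

    __slots__ = ("reactants", "products", "record_id", "class_label")

    def __init__(
        self,
        reactants: Sequence[Chem.Mol],
        products: Sequence[Chem.Mol],
        record_id: str = "",
        class_label: str | None = None,
    ) -> None:
        self.reactants = list(reactants)
        self.products = list(products)
        self.record_id = record_id
        self.class_label = class_label

    def reaction_smiles(self) -> str:
        left = ".".join(Chem.MolToSmiles(m) for m in self.reactants)
        right = ".".join(Chem.MolToSmiles(m) for m in self.products)
        return f"{left}>>{right}"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"MappedReaction({self.reaction_smiles()!r}, id={self.record_id!r})"


def _parse_side(text: str, what: str) -> list[Chem.Mol]:
    mols = []
    for species in filter(None, text.split(".")):
        mol = Chem.MolFromSmiles(species)
        if mol is None:
            raise ReactionParseError(f"unparseable {what} SMILES: {species!r}")
        mols.append(mol)
    return mols


def _check_unique_maps(mols: Sequence[Chem.Mol], side: str) -> None:
    seen: set[int] = set()
    for mol in mols:
        for atom in mol.GetAtoms():
            num = atom.GetAtomMapNum()
            if num == 0:
                continue
            if num in seen:
                raise ReactionParseError(f"duplicate atom map {num} on {side} side")
            seen.add(num)


def parse_reaction(
    text: str, record_id: str = "", class_label: str | None = None
) -> MappedReaction:
    """Parse ``reactants>agents>products`` text, merging agents into reactants.

    Raises :class:`ReactionParseError` for empty input, more than two ``>``
    separators (multi-step records), unparseable species, or atom-map indices
    repeated within one side.
    """
    if not text or not text.strip():
        raise ReactionParseError("empty reaction record")
    parts = text.strip().split(">")
    if len(parts) != 3:
        raise ReactionParseError(
            f"expected reactants>agents>products with exactly two '>' separators, "
            f"got {len(parts)} part(s)"
        )
    reactants = _parse_side(parts[0], "reactant") + _parse_side(parts[1], "agent")
    products = _parse_side(parts[2], "product")
    _check_unique_maps(reactants, "reactant")
    _check_unique_maps(products, "product")
    return MappedReaction(reactants, products, record_id, class_label)


def curate(rxn: MappedReaction) -> CurationVerdict:
    """Accept only complete, single-product, non-identity reactions.

    Identity is judged on de-mapped standard InChIs with order-invariant
    (sorted) comparison of the two sides.
    """
    if not rxn.reactants or not rxn.products:
        return CurationVerdict(False, REASON_INCOMPLETE)
    if len(rxn.products) > 1:
        return CurationVerdict(False, REASON_MULTI_PRODUCT)
    try:
        left = sorted(inchi_for_mol(m) for m in rxn.reactants)
        right = sorted(inchi_for_mol(m) for m in rxn.products)
    except MoleculeError:
        return CurationVerdict(False, REASON_UNPARSEABLE)
    if left == right:
        return CurationVerdict(False, REASON_EQUAL)
    return CurationVerdict(True, REASON_OK)


def reaction_hash(rxn: MappedReaction) -> str:
    """Order- and atom-map-invariant SHA-256 digest of a reaction.

    Each side is reduced to its de-mapped per-species standard InChIs in
    lexicographic order, the sides are concatenated reactants-then-products,
    and the result digested.  Two curated reactions hash identically iff
    their de-mapped reactant and product sets are identical.
    """
    left = ".".join(sorted(inchi_for_mol(m) for m in rxn.reactants))
    right = ".".join(sorted(inchi_for_mol(m) for m in rxn.products))
    return hashlib.sha256(f"{left}>>{right}".encode()).hexdigest()


def deduplicate(records: Iterable[MappedReaction]) -> list[MappedReaction]:
    """Keep the first occurrence per reaction hash, preserving input order."""
    seen: set[str] = set()
    kept: list[MappedReaction] = []
    for rxn in records:
        digest = reaction_hash(rxn)
        if digest not in seen:
            seen.add(digest)
            kept.append(rxn)
    return kept


# ---------------------------------------------------------------------------
# file dialect: UTF-8, one record per line, smiles[TAB]id[TAB]class,
# blank lines and '#' comments skipped
# ---------------------------------------------------------------------------

def read_reaction_file(path: str | Path) -> list[RawReactionRecord]:
    records = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        records.append(
            RawReactionRecord(
                reaction_smiles=fields[0],
                record_id=fields[1] if len(fields) > 1 else "",
                class_label=fields[2] if len(fields) > 2 else None,
            )
        )
    return records


def curate_records(
    records: Iterable[RawReactionRecord],
) -> tuple[list[MappedReaction], pd.DataFrame]:
    """Parse and curate raw records.

    Returns the accepted :class:`MappedReaction` objects (not yet
    deduplicated) and a verdict table with one row per input record:
    hash (empty for rejects), reaction_smiles, record_id, class_label,
    verdict.
    """
    kept: list[MappedReaction] = []
    rows = []
    for rec in records:
        digest = ""
        try:
            rxn = parse_reaction(rec.reaction_smiles, rec.record_id, rec.class_label)
            verdict = curate(rxn)
        except ReactionParseError:
            verdict = CurationVerdict(False, REASON_UNPARSEABLE)
        else:
            if verdict.accepted:
                digest = reaction_hash(rxn)
                kept.append(rxn)
        rows.append(
            {
                "hash": digest,
                "reaction_smiles": rec.reaction_smiles,
                "record_id": rec.record_id,
                "class_label": rec.class_label or "",
                "verdict": verdict.reason,
            }
        )
    return kept, pd.DataFrame(rows)


def write_curated_table(
    table: pd.DataFrame, path: str | Path, rejected_path: str | Path | None = None
) -> None:
    table.to_csv(path, sep="\t", index=False)
    if rejected_path is not None:
        table[table["verdict"] != REASON_OK].to_csv(rejected_path, sep="\t", index=False)
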