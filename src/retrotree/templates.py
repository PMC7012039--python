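"""Retro-template extraction, validation, application, and libraries.

A retro template is a SMIRKS rewrite ``product_pattern >> reactant_patterns``
extracted from an atom-mapped, curated reaction.  The product-side pattern
covers the reaction center (atoms whose bonding environment, H count, charge
or stereo flag changes between the two sides), every atom within ``radius``
bonds of it, and - regardless of radius - all atoms of any functional or
protecting group from the group library whose substructure match overlaps
that neighborhood.  The reactant side covers the corresponding mapped atoms
plus any leaving atoms attached to them; reactant species contributing no
product atoms (agents, spectators) are dropped.

Applying a template to a query compound runs the SMIRKS in the retro
direction with RDKit: each distinct substructure match yields a candidate
precursor set, invalid outcomes are dropped, and outcomes identical as
de-mapped InChI multisets are merged.  Validation applies a template back to
the product of its own source reaction and categorizes the result:
``precise`` (only the source reactants are regenerated), ``selective``
(source reactants among other outcomes), ``unselective`` (outcomes exist
but never the source reactants), ``failed`` (no outcome).
"""
from __future__ import annotations

import ast
import hashlib
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import MoleculeError, demap, inchi, mol_from_smiles
from .reactions import MappedReaction

CATEGORY_PRECISE = "precise"
CATEGORY_SELECTIVE = "selective"
CATEGORY_UNSELECTIVE = "unselective"
CATEGORY_FAILED = "failed"

DEFAULT_RADIUS = 1
DEFAULT_MATCH_CAP = 100


class TemplateExtractionError(RuntimeError):
    """Raised when no valid template can be extracted from a reaction."""


class TemplateApplicationError(RuntimeError):
    """Raised for malformed templates at application time."""


# ---------------------------------------------------------------------------
# group library
# ---------------------------------------------------------------------------

class GroupLibrary:
    """Named SMARTS patterns for functional and protecting groups.

    The default library ships with the package (~75 groups commonly used in
    organic synthesis: Boc, Cbz, Fmoc, acyl, benzyl, trityl, silyl ethers,
    esters, carbamates, sulfonyls plus plain functional groups).  Variable
    alkyl-chain variants are represented by a core pattern only.
    """

    def __init__(self, entries: Sequence[tuple[str, str]], source_path: str = "") -> None:
        names = [name for name, _ in entries]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        self.entries: list[tuple[str, str]] = list(entries)
        self.source_path = source_path
        self._patterns: list[tuple[str, Chem.Mol]] = []
        for name, smarts in entries:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"invalid SMARTS for group {name!r}: {smarts!r}")
            self._patterns.append((name, patt))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self._patterns)

    @classmethod
    def from_file(cls, path: str | Path) -> "GroupLibrary":
        entries = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, smarts = line.split("\t")
            entries.append((name, smarts))
        return cls(entries, source_path=str(path))

    @classmethod
    def default(cls) -> "GroupLibrary":
        ref = resources.files("retrotree").joinpath("data/protecting_groups.smarts")
        with resources.as_file(ref) as path:
            return cls.from_file(path)


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

def _canonical_map_smirks(smirks: str) -> str:
    """Renumber atom maps by first occurrence so numbering is irrelevant."""
    mapping: dict[str, int] = {}

    def sub(match: re.Match) -> str:
        old = match.group(1)
        mapping.setdefault(old, len(mapping) + 1)
        return f":{mapping[old]}]"

    return re.sub(r":(\d+)\]", sub, smirks)


def hash_smirks(smirks: str) -> str:
    """Deterministic digest of a SMIRKS, invariant to atom-map renumbering."""
    return hashlib.sha256(_canonical_map_smirks(smirks).encode()).hexdigest()


@dataclass(frozen=True)
class RetroTemplate:
    """A retro-direction SMIRKS transform with its provenance metadata."""

    smirks: str
    radius: int
    group_atoms_included: tuple[str, ...] = ()
    count: int = 1
    category: str | None = None

    @property
    def template_hash(self) -> str:
        return hash_smirks(self.smirks)


@dataclass(frozen=True)
class PrecursorSet:
    """One outcome of applying a retro template: a set of precursor SMILES."""

    molecules: tuple[str, ...]
    source_template_hash: str

    def inchi_key_tuple(self) -> tuple[str, ...]:
        return tuple(sorted(inchi(s) for s in self.molecules))


# ---------------------------------------------------------------------------
# reaction center
# ---------------------------------------------------------------------------

def _atom_env(atom: Chem.Atom) -> tuple:
    """Mapping-relative bonding environment used for the center diff."""
    neighbors = []
    n_unmapped = 0
    for bond in atom.GetBonds():
        other = bond.GetOtherAtom(atom)
        num = other.GetAtomMapNum()
        if num:
            neighbors.append((num, int(bond.GetBondType())))
        else:
            n_unmapped += 1
    chiral = atom.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED
    return (
        atom.GetFormalCharge(),
        atom.GetTotalNumHs(),
        chiral,
        tuple(sorted(neighbors)),
        n_unmapped,
    )


def find_reaction_center(rxn: MappedReaction) -> frozenset[int]:
    """Product atom-map indices whose environment changes across the reaction.

    An atom belongs to the center when its formal charge, total H count,
    stereo flag, or the multiset of (mapped-neighbor, bond order) pairs
    differs between the reactant and product sides.  Raises
    :class:`TemplateExtractionError` for unmapped product atoms, map indices
    missing from the reactant side, or an empty center.
    """
    if len(rxn.products) != 1:
        raise TemplateExtractionError("template extraction requires exactly one product")
    product = rxn.products[0]
    reactant_atoms: dict[int, Chem.Atom] = {}
    for mol in rxn.reactants:
        for atom in mol.GetAtoms():
            if atom.GetAtomMapNum():
                reactant_atoms[atom.GetAtomMapNum()] = atom

    center: set[int] = set()
    for atom in product.GetAtoms():
        num = atom.GetAtomMapNum()
        if num == 0:
            raise TemplateExtractionError("product contains unmapped atoms")
        partner = reactant_atoms.get(num)
        if partner is None:
            raise TemplateExtractionError(
                f"product atom map {num} has no reactant counterpart"
            )
        if _atom_env(atom) != _atom_env(partner):
            center.add(num)
    if not center:
        raise TemplateExtractionError("empty reaction center: nothing changes")
    return frozenset(center)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

_AROMATIC_LOWER = {"B", "C", "N", "O", "P", "S"}


def _element(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    if atom.GetIsAromatic() and sym in _AROMATIC_LOWER:
        return sym.lower()
    return sym


def _query_symbol(atom: Chem.Atom, map_num: int) -> str:
    """SMARTS query atom: element/aromaticity, H count, charge, map."""
    return f"[{_element(atom)};H{atom.GetTotalNumHs()};{atom.GetFormalCharge():+d}:{map_num}]"


def _product_symbol(atom: Chem.Atom, map_num: int | None) -> str:
    """SMILES-style atom for the generated (reactant) side of the SMIRKS."""
    h = atom.GetTotalNumHs()
    charge = atom.GetFormalCharge()
    text = _element(atom)
    if h:
        text += "H" if h == 1 else f"H{h}"
    if charge:
        sign = "+" if charge > 0 else "-"
        text += sign if abs(charge) == 1 else f"{sign}{abs(charge)}"
    if map_num is not None:
        return f"[{text}:{map_num}]"
    return f"[{text}]"


def _fragment_output_order(mol: Chem.Mol, atom_ids: Sequence[int]) -> list[int]:
    Chem.MolFragmentToSmiles(mol, atomsToUse=list(atom_ids), canonical=True)
    return list(ast.literal_eval(mol.GetProp("_smilesAtomOutputOrder")))


def _fragment_smiles(
    mol: Chem.Mol, atom_ids: Sequence[int], symbols: Sequence[str]
) -> str:
    return Chem.MolFragmentToSmiles(
        mol,
        atomsToUse=list(atom_ids),
        atomSymbols=list(symbols),
        canonical=True,
        allBondsExplicit=True,
    )


def extract_template(
    rxn: MappedReaction,
    radius: int = DEFAULT_RADIUS,
    groups: GroupLibrary | None = None,
) -> RetroTemplate:
    """Extract the retro template of a curated, atom-mapped reaction.

    ``radius`` counts bonds beyond the reaction center included in the
    pattern; group-library matches overlapping that neighborhood are pulled
    in completely regardless of radius.  Atom maps in the emitted SMIRKS are
    canonically renumbered so identical chemistry yields identical text.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    center_maps = find_reaction_center(rxn)
    product = rxn.products[0]

    idx_by_map = {a.GetAtomMapNum(): a.GetIdx() for a in product.GetAtoms()}
    selected = {idx_by_map[m] for m in center_maps}
    frontier = set(selected)
    for _ in range(radius):
        nxt = set()
        for idx in frontier:
            for nbr in product.GetAtomWithIdx(idx).GetNeighbors():
                if nbr.GetIdx() not in selected:
                    nxt.add(nbr.GetIdx())
        selected |= nxt
        frontier = nxt

    group_names: list[str] = []
    if groups is not None:
        neighborhood = frozenset(selected)
        for name, pattern in groups:
            hit = False
            for match in product.GetSubstructMatches(pattern):
                if neighborhood & set(match):
                    selected |= set(match)
                    hit = True
            if hit:
                group_names.append(name)

    # canonical template map numbers from the fragment's canonical output order
    product_clean = demap(product)
    try:
        order = _fragment_output_order(product_clean, sorted(selected))
    except Exception as exc:  # pragma: no cover - defensive
        raise TemplateExtractionError(f"product pattern construction failed: {exc}")
    new_map_by_idx = {idx: pos + 1 for pos, idx in enumerate(order)}
    new_map_by_orig = {
        product.GetAtomWithIdx(idx).GetAtomMapNum(): new_map_by_idx[idx]
        for idx in selected
    }

    symbols = [a.GetSymbol() for a in product.GetAtoms()]
    for idx in selected:
        symbols[idx] = _query_symbol(product.GetAtomWithIdx(idx), new_map_by_idx[idx])
    left = _fragment_smiles(product_clean, sorted(selected), symbols)

    product_maps = set(idx_by_map)
    right_parts: list[str] = []
    for reactant in rxn.reactants:
        keep = {
            a.GetIdx()
            for a in reactant.GetAtoms()
            if a.GetAtomMapNum() in new_map_by_orig
        }
        if not keep:
            continue  # spectator/agent: contributes no selected product atom
        # pull in leaving atoms (absent from the product side) attached to kept atoms
        grew = True
        while grew:
            grew = False
            for idx in list(keep):
                for nbr in reactant.GetAtomWithIdx(idx).GetNeighbors():
                    if nbr.GetIdx() in keep:
                        continue
                    if nbr.GetAtomMapNum() not in product_maps:
                        keep.add(nbr.GetIdx())
                        grew = True
        r_clean = demap(reactant)
        r_symbols = [a.GetSymbol() for a in reactant.GetAtoms()]
        for idx in keep:
            atom = reactant.GetAtomWithIdx(idx)
            r_symbols[idx] = _product_symbol(
                atom, new_map_by_orig.get(atom.GetAtomMapNum())
            )
        try:
            right_parts.append(_fragment_smiles(r_clean, sorted(keep), r_symbols))
        except Exception as exc:  # pragma: no cover - defensive
            raise TemplateExtractionError(f"reactant pattern construction failed: {exc}")

    if not right_parts:
        raise TemplateExtractionError("no reactant contributes mapped product atoms")
    smirks = f"{left}>>{'.'.join(sorted(right_parts))}"
    try:
        rxn_obj = AllChem.ReactionFromSmarts(smirks)
        if rxn_obj is None:
            raise ValueError("ReactionFromSmarts returned None")
    except Exception as exc:
        raise TemplateExtractionError(f"invalid SMIRKS {smirks!r}: {exc}")
    return RetroTemplate(
        smirks=smirks, radius=radius, group_atoms_included=tuple(group_names)
    )


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _compiled_reaction(smirks: str):
    rxn = AllChem.ReactionFromSmarts(smirks)
    if rxn is None:
        raise TemplateApplicationError(f"malformed template SMIRKS: {smirks!r}")
    return rxn


def apply_template(
    tpl: RetroTemplate,
    product_smiles: str,
    max_matches: int = DEFAULT_MATCH_CAP,
) -> list[PrecursorSet]:
    """Apply a retro template to a compound.

    Returns one :class:`PrecursorSet` per distinct outcome (outcomes with the
    same de-mapped InChI multiset are merged; outcomes containing invalid
    precursors are dropped); empty list when the product pattern does not
    match.  ``max_matches`` caps substructure-match explosion on degenerate
    symmetric inputs.
    """
    mol = mol_from_smiles(product_smiles)
    reaction = _compiled_reaction(tpl.smirks)
    try:
        outcomes = reaction.RunReactants((mol,), maxProducts=max_matches)
    except Exception:
        return []
    results: list[PrecursorSet] = []
    seen: set[tuple[str, ...]] = set()
    for frags in outcomes:
        smiles_list: list[str] = []
        key_list: list[str] = []
        ok = True
        for frag in frags:
            try:
                for atom in frag.GetAtoms():
                    atom.SetAtomMapNum(0)
                Chem.SanitizeMol(frag)
                smi = Chem.MolToSmiles(frag)
                reparsed = Chem.MolFromSmiles(smi)
                if reparsed is None:
                    raise ValueError("round trip failed")
                smi = Chem.MolToSmiles(reparsed)
                key_list.append(inchi(smi))
                smiles_list.append(smi)
            except (Exception,):
                ok = False
                break
        if not ok or not smiles_list:
            continue
        key = tuple(sorted(key_list))
        if key in seen:
            continue
        seen.add(key)
        results.append(
            PrecursorSet(tuple(sorted(smiles_list)), tpl.template_hash)
        )
    return results


def validate_template(
    tpl: RetroTemplate, source: MappedReaction, max_matches: int = DEFAULT_MATCH_CAP
) -> str:
    """Categorize a template by re-applying it to its own source product."""
    product_smiles = Chem.MolToSmiles(demap(source.products[0]))
    try:
        outcomes = apply_template(tpl, product_smiles, max_matches=max_matches)
    except (TemplateApplicationError, MoleculeError):
        return CATEGORY_FAILED
    if not outcomes:
        return CATEGORY_FAILED
    product_maps = {
        a.GetAtomMapNum() for a in source.products[0].GetAtoms() if a.GetAtomMapNum()
    }
    contributing = [
        m
        for m in source.reactants
        if any(a.GetAtomMapNum() in product_maps for a in m.GetAtoms())
    ]
    source_key = tuple(
        sorted(inchi(Chem.MolToSmiles(demap(m))) for m in contributing)
    )
    outcome_keys = {o.inchi_key_tuple() for o in outcomes}
    if outcome_keys == {source_key}:
        return CATEGORY_PRECISE
    if source_key in outcome_keys:
        return CATEGORY_SELECTIVE
    return CATEGORY_UNSELECTIVE


# ---------------------------------------------------------------------------
# libraries
# ---------------------------------------------------------------------------

@dataclass
class TemplateLibrary:
    """Occurrence-filtered unique templates with contiguous integer labels.

    Templates are ordered by descending occurrence count, ties broken by
    ascending template hash, so label indices are reproducible across runs.
    """

    templates: list[RetroTemplate] = field(default_factory=list)

    def __post_init__(self) -> None:
        hashes = [t.template_hash for t in self.templates]
        if len(set(hashes)) != len(hashes):
            raise ValueError("duplicate template hashes in library")
        self.label_index: dict[str, int] = {h: i for i, h in enumerate(hashes)}

    def __len__(self) -> int:
        return len(self.templates)

    @property
    def hashes(self) -> list[str]:
        return [t.template_hash for t in self.templates]

    def label_of(self, template_hash: str) -> int:
        return self.label_index[template_hash]

    def template_of(self, label: int) -> RetroTemplate:
        return self.templates[label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": range(len(self.templates)),
                "template_hash": [t.template_hash for t in self.templates],
                "smirks": [t.smirks for t in self.templates],
                "count": [t.count for t in self.templates],
                "category": [t.category or "" for t in self.templates],
                "radius": [t.radius for t in self.templates],
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "TemplateLibrary":
        frame = pd.read_csv(path, sep="\t", keep_default_na=False)
        templates = [
            RetroTemplate(
                smirks=row.smirks,
                radius=int(row.radius),
                count=int(row.count),
                category=row.category or None,
            )
            for row in frame.itertuples()
        ]
        return cls(templates)


def build_library(
    records: Sequence[tuple[str, RetroTemplate]], min_count: int = 1
) -> TemplateLibrary:
    """Accumulate per-template occurrence counts and filter by ``min_count``.

    ``records`` pairs each (deduplicated) reaction hash with its extracted
    template.  Raises ``ValueError`` when nothing survives the cut-off.
    """
    counts: Counter[str] = Counter()
    representative: dict[str, RetroTemplate] = {}
    for _, tpl in records:
        digest = tpl.template_hash
        counts[digest] += 1
        representative.setdefault(digest, tpl)
    kept = [
        (digest, count) for digest, count in counts.items() if count >= min_count
    ]
    if not kept:
        raise ValueError(f"no template occurs at least {min_count} times")
    kept.sort(key=lambda item: (-item[1], item[0]))
    templates = [
        replace(representative[digest], count=count) for digest, count in kept
    ]
    return TemplateLibrary(templates)


def library_overlap(libraries: dict[str, TemplateLibrary]) -> pd.DataFrame:
    """Exclusive-region counts/percentages for every non-empty name subset.

    Mirrors a Venn decomposition: each row is the set of libraries a template
    hash occurs in and nothing else; percentages are of the union and sum
    to 100.
    """
    if len(libraries) < 2:
        raise ValueError("need at least two libraries")
    sets = {name: set(lib.hashes) for name, lib in libraries.items()}
    union = set().union(*sets.values())
    names = sorted(sets)
    rows = []
    for size in range(1, len(names) + 1):
        for subset in combinations(names, size):
            inside = set.intersection(*(sets[n] for n in subset))
            for other in names:
                if other not in subset:
                    inside -= sets[other]
            rows.append(
                {
                    "region": "&".join(subset),
                    "count": len(inside),
                    "percent": 100.0 * len(inside) / len(union) if union else 0.0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# corpus-level pipeline
# ---------------------------------------------------------------------------

def extract_templates(
    reactions: Iterable[MappedReaction],
    radius: int = DEFAULT_RADIUS,
    groups: GroupLibrary | None = None,
    validate: bool = True,
) -> tuple[list[tuple[str, RetroTemplate, MappedReaction]], Counter]:
    """Extract (and optionally validate) templates for a reaction corpus.

    Returns successfully extracted ``(reaction_hash, template, reaction)``
    triples plus a counter over validation categories (extraction failures
    are counted under ``failed``); reactions whose extraction fails are
    discarded, mirroring corpus curation practice.
    """
    from .reactions import reaction_hash

    extracted = []
    categories: Counter[str] = Counter()
    for rxn in reactions:
        try:
            tpl = extract_template(rxn, radius=radius, groups=groups)
        except TemplateExtractionError:
            categories[CATEGORY_FAILED] += 1
            continue
        if validate:
            category = validate_template(tpl, rxn)
            tpl = replace(tpl, category=category)
            categories[category] += 1
        extracted.append((reaction_hash(rxn), tpl, rxn))
    return extracted, categories
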