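"""Self-contained toy reaction worlds for exercising the whole pipeline.

A world is built from parametrized template families — simple bond-forming
couplings (esterification, amide coupling, O/N/S-alkylation with halide
leaving groups, sulfonamide and sulfonate formation, acyl-chloride
acylations, carbamate formation, biaryl coupling, Boc deprotection) —
instantiated over homologous series of building blocks.  Atom maps are
written by the generating transform itself, so every record is a correctly
mapped single-product reaction.  Within one family all blocks share the
attachment-shell environment (a primary CH2), so a radius-1 template is
unique per family and planted multiplicities are exact; at radius >= 2 the
blocks' outer shells split each family into more specific templates.

Block pools are partitioned between families that would otherwise produce
identical products (acid vs acid-chloride acylation, Br/Cl/I alkylation),
keeping the product -> template-class mapping unambiguous for policy
training.  Worlds also plant multi-step routes: a bi- or tri-functional
core is elaborated step by step with mono-functional blocks, and the stock
is the set of all blocks and cores, so every planted route terminates in
stock.
"""
from __future__ import annotations

import json
import random
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from rdkit import Chem

from .chem import canonical_smiles, demap, mol_from_smiles
from .reactions import (
    RawReactionRecord,
    curate,
    deduplicate,
    parse_reaction,
    reaction_hash,
)


class WorldGenerationError(ValueError):
    """Raised for infeasible generator parameter combinations."""


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

# substituents R for R-CH2-X blocks; index pools below slice this list.
# long unbranched homologs are avoided: beyond ~6 CH2 units their folded
# binary ECFP4 fingerprints coincide, which would blur the class labels
_RSET = [
    "C", "CC", "CCC", "CCCC", "CC(C)(C)C", "CC(C)(C)CC",
    "CC(C)C", "CCC(C)C", "CC(C)CC", "C1CCCCC1", "C1CCCC1", "c1ccccc1",
]
_ARSET = ["C", "CC", "CCC", "CCCC", "OC", "CC(C)C", "F", "C(F)(F)F", "OCC", "CCCCC"]

BLOCKS: dict[str, list[str]] = {
    "acid": [r + "CC(=O)O" for r in _RSET],
    "alcohol": [r + "CO" for r in _RSET],
    "amine": [r + "CN" for r in _RSET],
    "bromide": [r + "CBr" for r in _RSET],
    "chloride": [r + "CCl" for r in _RSET],
    "iodide": [r + "CI" for r in _RSET],
    "thiol": [r + "CS" for r in _RSET],
    "acid_chloride": [r + "CC(=O)Cl" for r in _RSET],
    "sulfonyl_chloride": [r + "CS(=O)(=O)Cl" for r in _RSET],
    "chloroformate": [r + "COC(=O)Cl" for r in _RSET],
    "aryl_bromide": [f"Brc1ccc({a})cc1" for a in _ARSET],
    "boronic_acid": [f"OB(O)c1ccc({a})cc1" for a in _ARSET],
}

_ANCHORS: dict[str, tuple[str, int, tuple[int, ...]]] = {
    # role -> (SMARTS, anchor position in match, leaving positions in match)
    "acid": ("[CX3](=[OX1])[OX2H1]", 0, (2,)),
    "alcohol": ("[CX4][OX2H1]", 1, ()),
    "amine": ("[CX4][NX3H2]", 1, ()),
    "thiol": ("[CX4][SX2H1]", 1, ()),
    "bromide": ("[CX4][Br]", 0, (1,)),
    "chloride": ("[CX4][Cl]", 0, (1,)),
    "iodide": ("[CX4][I]", 0, (1,)),
    "acid_chloride": ("[CX3](=[OX1])[Cl]", 0, (2,)),
    "sulfonyl_chloride": ("[SX4](=[OX1])(=[OX1])[Cl]", 0, (3,)),
    "chloroformate": ("[OX2][CX3](=[OX1])[Cl]", 1, (3,)),
    "aryl_bromide": ("[c][Br]", 0, (1,)),
    "boronic_acid": ("[c][BX3]([OX2H1])[OX2H1]", 0, (1, 2, 3)),
}

_LO = tuple(range(6))
_HI = tuple(range(6, 12))
_ALL = tuple(range(12))
_AR = tuple(range(10))
# alkylation electrophiles must share the attachment shell (R-CH2- with an
# R whose first atom is itself a CH2), otherwise one family would split into
# several radius-1 templates; nucleophile pools avoid those indices so that
# the symmetric R-CH2-X-CH2-R' products never collide across Br/Cl/I families
_NU = (0, 7, 8, 9, 10, 11)


@dataclass(frozen=True)
class CouplingFamily:
    name: str
    role_a: str
    pool_a: tuple[int, ...]
    role_b: str
    pool_b: tuple[int, ...]
    special: str | None = None  # "boc" marks the deprotection family

    def block_pairs(self) -> list[tuple[str, str]]:
        if self.special == "boc":
            return [(BLOCKS[self.role_b][i], "") for i in self.pool_b]
        return [
            (BLOCKS[self.role_a][i], BLOCKS[self.role_b][j])
            for i in self.pool_a
            for j in self.pool_b
        ]


FAMILIES: list[CouplingFamily] = [
    CouplingFamily("esterification", "acid", _LO, "alcohol", _ALL),
    CouplingFamily("amide_coupling", "acid", _LO, "amine", _ALL),
    CouplingFamily("thioether_br", "thiol", _NU, "bromide", (1, 2, 3)),
    CouplingFamily("williamson_br", "alcohol", _NU, "bromide", (1, 2)),
    CouplingFamily("amine_alkylation_br", "amine", _NU, "bromide", (1, 2)),
    CouplingFamily("sulfonamide", "sulfonyl_chloride", _ALL, "amine", _ALL),
    CouplingFamily("acyl_chloride_ester", "acid_chloride", _HI, "alcohol", _ALL),
    CouplingFamily("acyl_chloride_amide", "acid_chloride", _HI, "amine", _ALL),
    CouplingFamily("carbamate", "chloroformate", _ALL, "amine", _ALL),
    CouplingFamily("williamson_cl", "alcohol", _NU, "chloride", (3, 4)),
    CouplingFamily("amine_alkylation_cl", "amine", _NU, "chloride", (3, 4)),
    CouplingFamily("suzuki_biaryl", "aryl_bromide", _AR, "boronic_acid", _AR),
    CouplingFamily("williamson_i", "alcohol", _NU, "iodide", (5, 6)),
    CouplingFamily("amine_alkylation_i", "amine", _NU, "iodide", (5, 6)),
    CouplingFamily("thioether_cl", "thiol", _NU, "chloride", (4, 5, 6)),
    CouplingFamily("sulfonate_ester", "sulfonyl_chloride", _ALL, "alcohol", _ALL),
    CouplingFamily("boc_deprotection", "amine", (), "amine", _ALL, special="boc"),
]

FAMILY_NAMES = [f.name for f in FAMILIES]

_CORE2 = "NCCCO"          # amino-alcohol: ester then amide
_CORE3 = "NCC(CO)CS"      # amine + alcohol + thiol: three sequential steps


def _mapped(smiles: str, start: int) -> Chem.Mol:
    mol = mol_from_smiles(smiles)
    for i, atom in enumerate(mol.GetAtoms()):
        atom.SetAtomMapNum(start + i)
    return mol


def _first_match(mol: Chem.Mol, smarts: str) -> tuple[int, ...]:
    match = mol.GetSubstructMatch(Chem.MolFromSmarts(smarts))
    if not match:
        raise WorldGenerationError(
            f"{Chem.MolToSmiles(mol)!r} does not match anchor {smarts!r}"
        )
    return match


def couple(family: CouplingFamily, smiles_a: str, smiles_b: str) -> tuple[str, str]:
    """Build one mapped forward reaction of a family.

    Returns ``(reaction_smiles, product_smiles)``; the reaction SMILES
    carries a complete atom mapping written by the transform itself
    (leaving-group atoms keep reactant-only map numbers).
    """
    if family.special == "boc":
        return _boc_deprotection(smiles_a)
    mol_a = _mapped(smiles_a, 1)
    mol_b = _mapped(smiles_b, mol_a.GetNumAtoms() + 1)
    smarts_a, anchor_a, leave_a = _ANCHORS[family.role_a]
    smarts_b, anchor_b, leave_b = _ANCHORS[family.role_b]
    match_a = _first_match(mol_a, smarts_a)
    match_b = _first_match(mol_b, smarts_b)
    offset = mol_a.GetNumAtoms()
    editable = Chem.RWMol(Chem.CombineMols(mol_a, mol_b))
    editable.AddBond(
        match_a[anchor_a], match_b[anchor_b] + offset, Chem.BondType.SINGLE
    )
    doomed = [match_a[i] for i in leave_a] + [match_b[i] + offset for i in leave_b]
    for idx in sorted(doomed, reverse=True):
        editable.RemoveAtom(idx)
    product = editable.GetMol()
    Chem.SanitizeMol(product)
    reaction = (
        f"{Chem.MolToSmiles(mol_a)}.{Chem.MolToSmiles(mol_b)}"
        f">>{Chem.MolToSmiles(product)}"
    )
    return reaction, Chem.MolToSmiles(demap(product))


def _boc_deprotection(amine_smiles: str) -> tuple[str, str]:
    amine = _mapped(amine_smiles, 1)
    boc = _mapped("CC(C)(C)OC(Cl)=O", amine.GetNumAtoms() + 1)
    match_n = _first_match(amine, "[CX4][NX3H2]")
    match_c = _first_match(boc, "[OX2][CX3](=[OX1])[Cl]")
    offset = amine.GetNumAtoms()
    editable = Chem.RWMol(Chem.CombineMols(amine, boc))
    editable.AddBond(match_n[1], match_c[1] + offset, Chem.BondType.SINGLE)
    editable.RemoveAtom(match_c[3] + offset)
    protected = editable.GetMol()
    Chem.SanitizeMol(protected)
    reaction = f"{Chem.MolToSmiles(protected)}>>{Chem.MolToSmiles(amine)}"
    return reaction, canonical_smiles(amine_smiles)


# ---------------------------------------------------------------------------
# worlds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RouteStep:
    product: str
    family: str
    precursors: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "product": self.product,
            "family": self.family,
            "precursors": list(self.precursors),
        }


@dataclass(frozen=True)
class PlantedRoute:
    target: str
    steps: tuple[RouteStep, ...]  # retro order: target first
    depth: int

    @property
    def leaves(self) -> set[str]:
        produced = {step.product for step in self.steps}
        used = {p for step in self.steps for p in step.precursors}
        return used - produced

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "depth": self.depth,
            "steps": [s.to_dict() for s in self.steps],
        }


@dataclass
class ToyWorld:
    reactions: list[RawReactionRecord]
    family_names: list[str]
    template_multiplicities: dict[str, int]
    targets: list[str]
    routes: list[PlantedRoute]
    stock: list[str]
    seed: int
    corruption: dict[str, int] = field(default_factory=dict)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        lines = [
            f"{r.reaction_smiles}\t{r.record_id}\t{r.class_label or ''}"
            for r in self.reactions
        ]
        (directory / "reactions.smi").write_text("\n".join(lines) + "\n")
        (directory / "stock.smi").write_text("\n".join(self.stock) + "\n")
        (directory / "targets.smi").write_text("\n".join(self.targets) + "\n")
        (directory / "routes.json").write_text(
            json.dumps([r.to_dict() for r in self.routes], indent=2)
        )


def _route_program(
    depth: int, rng: random.Random, families: Sequence[CouplingFamily]
) -> PlantedRoute:
    by_name = {f.name: f for f in families}

    def pick(role: str, pool: tuple[int, ...]) -> str:
        return BLOCKS[role][rng.choice(pool)]

    if depth == 1:
        candidates = [f for f in families if f.special is None]
        fam = rng.choice(candidates)
        a, b = rng.choice(fam.block_pairs())
        _, product = couple(fam, a, b)
        steps = (RouteStep(product, fam.name, (canonical_smiles(a), canonical_smiles(b))),)
        return PlantedRoute(product, steps, 1)

    if depth == 2:
        ester, amide = by_name["esterification"], by_name["amide_coupling"]
        acid1 = pick("acid", ester.pool_a)
        acid2 = pick("acid", amide.pool_a)
        _, m1 = couple(ester, acid1, _CORE2)
        _, target = couple(amide, acid2, m1)
        steps = (
            RouteStep(target, "amide_coupling", (canonical_smiles(acid2), m1)),
            RouteStep(m1, "esterification", (canonical_smiles(acid1), canonical_smiles(_CORE2))),
        )
        return PlantedRoute(target, steps, 2)

    if depth == 3:
        thio = by_name["thioether_br"]
        ester, amide = by_name["esterification"], by_name["amide_coupling"]
        bromide = pick("bromide", thio.pool_b)
        acid1 = pick("acid", ester.pool_a)
        acid2 = pick("acid", amide.pool_a)
        _, m1 = couple(thio, _CORE3, bromide)
        _, m2 = couple(ester, acid1, m1)
        _, target = couple(amide, acid2, m2)
        steps = (
            RouteStep(target, "amide_coupling", (canonical_smiles(acid2), m2)),
            RouteStep(m2, "esterification", (canonical_smiles(acid1), m1)),
            RouteStep(m1, "thioether_br", (canonical_smiles(_CORE3), canonical_smiles(bromide))),
        )
        return PlantedRoute(target, steps, 3)

    raise WorldGenerationError(f"unsupported route depth {depth}")


def _default_multiplicities(n_reactions: int, families: Sequence[CouplingFamily]) -> list[int]:
    weights = [0.75**i for i in range(len(families))]
    total = sum(weights)
    counts = [max(1, round(n_reactions * w / total)) for w in weights]
    # trim overshoot from the largest families, respect per-family capacity
    caps = [len(f.block_pairs()) for f in families]
    counts = [min(c, cap) for c, cap in zip(counts, caps)]
    while sum(counts) > n_reactions:
        i = counts.index(max(counts))
        counts[i] -= 1
    return counts


def generate_world(
    n_reactions: int = 200,
    n_families: int = 8,
    max_depth: int = 2,
    seed: int = 7,
    n_targets: int = 8,
    multiplicities: Sequence[int] | None = None,
) -> ToyWorld:
    """Generate a deterministic toy reaction world.

    ``multiplicities`` plants an exact per-family reaction count (after
    deduplication); by default counts follow a descending profile summing
    to roughly ``n_reactions``.  Routes of depth 1..``max_depth`` are
    planted for ``n_targets`` targets, and their step reactions join the
    corpus.  Regeneration with the same arguments is bitwise identical.
    """
    if n_families < 2 or n_families > len(FAMILIES):
        raise WorldGenerationError(
            f"n_families must be in [2, {len(FAMILIES)}], got {n_families}"
        )
    if max_depth < 1 or max_depth > 3:
        raise WorldGenerationError("max_depth must be in [1, 3]")
    if max_depth >= 3 and n_families < 3:
        raise WorldGenerationError("depth-3 routes need at least 3 families")
    rng = random.Random(seed)
    families = FAMILIES[:n_families]

    if multiplicities is None:
        counts = _default_multiplicities(n_reactions, families)
    else:
        if len(multiplicities) != n_families:
            raise WorldGenerationError("need one multiplicity per family")
        counts = list(multiplicities)

    records: list[RawReactionRecord] = []
    index = 0
    for fam, want in zip(families, counts):
        pairs = fam.block_pairs()
        if want > len(pairs):
            raise WorldGenerationError(
                f"family {fam.name} supports at most {len(pairs)} distinct "
                f"reactions, requested {want}"
            )
        rng.shuffle(pairs)
        for a, b in pairs[:want]:
            reaction, _ = couple(fam, a, b)
            records.append(RawReactionRecord(reaction, f"R{index:05d}", fam.name))
            index += 1

    routes: list[PlantedRoute] = []
    seen_targets: set[str] = set()
    attempts = 0
    while len(routes) < n_targets and attempts < n_targets * 20:
        attempts += 1
        depth = (len(routes) % max_depth) + 1
        route = _route_program(depth, rng, families)
        if route.target in seen_targets:
            continue
        seen_targets.add(route.target)
        routes.append(route)
        for k, step in enumerate(reversed(route.steps)):  # forward order
            fam = next(f for f in families if f.name == step.family)
            a, b = step.precursors if fam.special != "boc" else (step.precursors[0], "")
            # couple() expects (role_a, role_b) order as stored in the step
            reaction, _ = couple(fam, a, b)
            records.append(
                RawReactionRecord(reaction, f"T{len(routes) - 1:03d}_{k}", fam.name)
            )
    if len(routes) < n_targets:
        raise WorldGenerationError("could not plant the requested number of routes")

    # ground-truth multiplicities = surviving class counts after curation+dedup
    mapped = []
    for rec in records:
        rxn = parse_reaction(rec.reaction_smiles, rec.record_id, rec.class_label)
        assert curate(rxn).accepted, f"generator produced uncuratable {rec}"
        mapped.append(rxn)
    unique = deduplicate(mapped)
    multiplicity = Counter(r.class_label for r in unique)

    stock_smiles = {canonical_smiles(s) for blocks in BLOCKS.values() for s in blocks}
    stock_smiles |= {canonical_smiles(_CORE2), canonical_smiles(_CORE3)}
    return ToyWorld(
        reactions=records,
        family_names=[f.name for f in families],
        template_multiplicities=dict(multiplicity),
        targets=[r.target for r in routes],
        routes=routes,
        stock=sorted(stock_smiles),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------

_CORRUPT_MODES = ("duplicate", "identity", "multi_product", "bad_maps")


def _permuted_duplicate(rec: RawReactionRecord, rng: random.Random) -> str:
    rxn = parse_reaction(rec.reaction_smiles)
    mols = list(rxn.reactants)
    rng.shuffle(mols)
    old_maps = sorted(
        {a.GetAtomMapNum() for m in mols + rxn.products for a in m.GetAtoms() if a.GetAtomMapNum()}
    )
    new_maps = old_maps[:]
    rng.shuffle(new_maps)
    remap = dict(zip(old_maps, new_maps))
    out_mols = []
    for mol in mols + rxn.products:
        copy = Chem.Mol(mol)
        for atom in copy.GetAtoms():
            if atom.GetAtomMapNum():
                atom.SetAtomMapNum(remap[atom.GetAtomMapNum()])
        out_mols.append(copy)
    left = ".".join(Chem.MolToSmiles(m) for m in out_mols[: len(mols)])
    right = ".".join(Chem.MolToSmiles(m) for m in out_mols[len(mols) :])
    return f"{left}>>{right}"


def _scrambled_maps(rec: RawReactionRecord, rng: random.Random) -> str:
    rxn = parse_reaction(rec.reaction_smiles)
    product = Chem.Mol(rxn.products[0])
    maps = [a.GetAtomMapNum() for a in product.GetAtoms()]
    shuffled = maps[:]
    while shuffled == maps:
        rng.shuffle(shuffled)
    for atom, num in zip(product.GetAtoms(), shuffled):
        atom.SetAtomMapNum(num)
    left = ".".join(Chem.MolToSmiles(m) for m in rxn.reactants)
    return f"{left}>>{Chem.MolToSmiles(product)}"


def corrupt_world(
    world: ToyWorld,
    fraction: float,
    modes: Sequence[str] = ("duplicate", "identity", "multi_product"),
    seed: int = 0,
) -> ToyWorld:
    """Copy of *world* with curation/deduplication noise injected.

    ``fraction`` of the record count (rounded) is injected, split evenly
    across the requested modes; exact per-mode counts are recorded in
    ``corruption`` so tests can assert that curation and deduplication
    remove exactly the planted noise.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    for mode in modes:
        if mode not in _CORRUPT_MODES:
            raise ValueError(f"unknown corruption mode {mode!r}")
    rng = random.Random(seed)
    records = list(world.reactions)
    total = round(fraction * len(records))
    share = {mode: total // len(modes) for mode in modes}
    for mode in list(modes)[: total % len(modes)]:
        share[mode] += 1

    injected: list[RawReactionRecord] = []
    for mode in modes:
        for i in range(share[mode]):
            base = rng.choice(records)
            if mode == "duplicate":
                smiles = _permuted_duplicate(base, rng)
                label = "corrupt_duplicate"
            elif mode == "identity":
                block = rng.choice(world.stock)
                mol = _mapped(block, 1)
                text = Chem.MolToSmiles(mol)
                smiles = f"{text}>>{text}"
                label = "corrupt_identity"
            elif mode == "multi_product":
                extra = rng.choice(world.stock)
                smiles = base.reaction_smiles + "." + extra
                label = "corrupt_multi_product"
            else:  # bad_maps
                smiles = _scrambled_maps(base, rng)
                label = "corrupt_bad_maps"
            injected.append(
                RawReactionRecord(smiles, f"X_{mode}_{i:04d}", label)
            )

    return ToyWorld(
        reactions=records + injected,
        family_names=list(world.family_names),
        template_multiplicities=dict(world.template_multiplicities),
        targets=list(world.targets),
        routes=list(world.routes),
        stock=list(world.stock),
        seed=world.seed,
        corruption=dict(share),
    )
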