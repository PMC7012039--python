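"""Purchasable-compound ("stock") sets keyed by standard InChIKey.

The search terminates a retrosynthetic branch when every molecule of a
state is found in stock; membership is a hashed-set test on the full
27-character standard InChIKey.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

from .chem import MoleculeError, inchikey

logger = logging.getLogger(__name__)

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


def is_inchikey(text: str) -> bool:
    return bool(_INCHIKEY_RE.match(text.strip()))


class StockSet:
    """A deduplicated set of purchasable compounds, keyed by InChIKey."""

    def __init__(self, keys: Iterable[str] = (), name: str = "stock") -> None:
        self.keys: set[str] = set(keys)
        self.name = name

    @property
    def size(self) -> int:
        return len(self.keys)

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, smiles_or_key: str) -> bool:
        return self.contains(smiles_or_key)

    def contains(self, smiles_or_key: str) -> bool:
        """Membership by full InChIKey equality; SMILES input is converted."""
        if is_inchikey(smiles_or_key):
            return smiles_or_key.strip() in self.keys
        return inchikey(smiles_or_key) in self.keys

    @classmethod
    def from_smiles(cls, smiles: Iterable[str], name: str = "stock") -> "StockSet":
        keys = set()
        for smi in smiles:
            try:
                keys.add(inchikey(smi))
            except MoleculeError:
                logger.warning("skipping unparseable stock entry %r", smi)
        return cls(keys, name=name)

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(sorted(self.keys)) + "\n", encoding="utf-8")


def load_stock(path: str | Path, format: str = "smiles", name: str | None = None) -> StockSet:
    """Load a stock file (one SMILES or InChIKey per line).

    Unparseable rows are logged and skipped; duplicates collapse.  Raises
    ``ValueError`` if nothing valid remains.
    """
    if format not in ("smiles", "inchikey"):
        raise ValueError(f"unknown stock format {format!r}")
    rows = [
        line.strip()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    ]
    name = name or Path(path).stem
    if format == "inchikey":
        keys = set()
        for row in rows:
            if is_inchikey(row):
                keys.add(row)
            else:
                logger.warning("skipping malformed InChIKey %r", row)
        stock = StockSet(keys, name=name)
    else:
        stock = StockSet.from_smiles(rows, name=name)
    if not stock.keys:
        raise ValueError(f"stock file {path} yielded no valid compounds")
    return stock


def merge_stocks(stocks: Sequence[StockSet], name: str = "merged") -> StockSet:
    """Set union of one or more stocks."""
    if not stocks:
        raise ValueError("need at least one stock")
    keys: set[str] = set()
    for stock in stocks:
        keys |= stock.keys
    return StockSet(keys, name=name)
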