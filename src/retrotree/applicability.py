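"""Top-N template applicability — the task-specific policy assessment.

Test-set accuracy rewards reproducing the one recorded template per
product, but route finding needs many applicable disconnections.  This
module counts, per query compound, how many of the N highest-ranked
templates actually produce at least one valid precursor set when applied
in the retro direction.  "Successfully applied" means a subgraph match
exists and every generated precursor is valid SMILES; chemical feasibility
is deliberately not checked.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import MoleculeError, largest_fragment
from .policy import PolicyModel, predict_templates
from .templates import (
    DEFAULT_MATCH_CAP,
    TemplateLibrary,
    apply_template,
)

logger = logging.getLogger(__name__)


@dataclass
class ApplicabilityReport:
    per_compound: list[tuple[str, int, tuple[str, ...]]]  # (smiles, n_applicable, hashes)
    top_n: int

    @property
    def mean_applicable(self) -> float:
        if not self.per_compound:
            return 0.0
        return float(np.mean([n for _, n, _ in self.per_compound]))

    @property
    def mean_fraction(self) -> float:
        return self.mean_applicable / self.top_n if self.top_n else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "smiles": [s for s, _, _ in self.per_compound],
                "n_applicable": [n for _, n, _ in self.per_compound],
                "applied_hashes": [";".join(h) for _, _, h in self.per_compound],
            }
        )

    def summary(self) -> dict:
        return {
            "n_compounds": len(self.per_compound),
            "top_n": self.top_n,
            "mean_applicable": self.mean_applicable,
            "mean_fraction": self.mean_fraction,
        }

    def save(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.summary(), indent=2))


def template_applies(
    library: TemplateLibrary, template_hash: str, smiles: str, max_matches: int = DEFAULT_MATCH_CAP
) -> bool:
    tpl = library.template_of(library.label_of(template_hash))
    return bool(apply_template(tpl, smiles, max_matches=max_matches))


def assess_applicability(
    model: PolicyModel,
    library: TemplateLibrary,
    compounds: Sequence[str],
    top_n: int = 50,
    max_matches: int = DEFAULT_MATCH_CAP,
) -> ApplicabilityReport:
    """Count applicable templates among the top-N policy predictions.

    A template counts once per compound regardless of how many sites it
    matches.  Unparseable compounds are skipped with a log entry.
    """
    per_compound = []
    for smiles in compounds:
        try:
            ranked = predict_templates(model, library, smiles, top_n=top_n)
        except MoleculeError:
            logger.warning("skipping unparseable compound %r", smiles)
            continue
        applied = tuple(
            digest
            for _, digest, _ in ranked
            if template_applies(library, digest, smiles, max_matches)
        )
        per_compound.append((smiles, len(applied), applied))
    return ApplicabilityReport(per_compound=per_compound, top_n=top_n)


def exhaustive_applicability(
    library: TemplateLibrary,
    compounds: Sequence[str],
    max_matches: int = DEFAULT_MATCH_CAP,
) -> dict[str, set[str]]:
    """Brute force: every library template applied to every compound.

    Returns the set of applicable template hashes per compound; used both
    as the assessment baseline (equivalent to N = library size) and as the
    independent oracle for :func:`assess_applicability`.
    """
    out: dict[str, set[str]] = {}
    for smiles in compounds:
        out[smiles] = {
            tpl.template_hash
            for tpl in library.templates
            if apply_template(tpl, smiles, max_matches=max_matches)
        }
    return out


def prepare_assessment_set(
    smiles_list: Sequence[str], n: int, seed: int = 1
) -> list[str]:
    """Salt-strip (largest fragment) then draw a seeded random subset."""
    cleaned = []
    for smiles in smiles_list:
        try:
            cleaned.append(largest_fragment(smiles))
        except MoleculeError:
            logger.warning("dropping unparseable assessment entry %r", smiles)
    if n > len(cleaned):
        raise ValueError(f"requested {n} compounds but only {len(cleaned)} usable")
    order = np.random.RandomState(seed).permutation(len(cleaned))
    return [cleaned[i] for i in order[:n]]
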