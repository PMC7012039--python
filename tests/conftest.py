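"""Shared fixtures: toy reaction worlds and trained policies.

The heavyweight artifacts (a ~20-class policy-training world and a
route-planted search world) are session-scoped so the suite builds each
exactly once.
"""
from __future__ import annotations

import pytest

from retrotree import fixtures as fx
from retrotree import policy as pol
from retrotree import reactions as rx
from retrotree import templates as tpl
from retrotree.stock import StockSet


@pytest.fixture(scope="session")
def group_library() -> tpl.GroupLibrary:
    return tpl.GroupLibrary.default()


def _prepare(world, radius=1, groups=None, validate=True):
    kept, table = rx.curate_records(world.reactions)
    unique = rx.deduplicate(kept)
    extracted, categories = tpl.extract_templates(
        unique, radius=radius, groups=groups, validate=validate
    )
    library = tpl.build_library([(h, t) for h, t, _ in extracted], min_count=1)
    return {
        "world": world,
        "curated": kept,
        "table": table,
        "unique": unique,
        "extracted": extracted,
        "categories": categories,
        "library": library,
    }


@pytest.fixture(scope="session")
def policy_world():
    """500-reaction world spanning every template family (~20 classes)."""
    world = fx.generate_world(
        n_reactions=500, n_families=17, max_depth=1, seed=101, n_targets=0
    )
    return _prepare(world)


@pytest.fixture(scope="session")
def policy_splits(policy_world):
    X, y, products = pol.dataset_from_reactions(
        policy_world["extracted"], policy_world["library"]
    )
    train, valid, test = pol.split_dataset(X, y, seed=42)
    return {"X": X, "y": y, "products": products,
            "train": train, "valid": valid, "test": test}


@pytest.fixture(scope="session")
def policy_model(policy_world, policy_splits):
    config = pol.TrainConfig(epochs=60, seed=0)
    return pol.train_policy(
        policy_splits["train"],
        policy_splits["valid"],
        config,
        label_hashes=policy_world["library"].hashes,
    )


@pytest.fixture(scope="session")
def search_world():
    """Route-planted world: 50 targets of depth 1-3 with matching stock."""
    world = fx.generate_world(
        n_reactions=150, n_families=6, max_depth=3, seed=23, n_targets=50
    )
    prepared = _prepare(world)
    prepared["stock"] = StockSet.from_smiles(world.stock)
    return prepared


@pytest.fixture(scope="session")
def search_policy(search_world):
    X, y, _ = pol.dataset_from_reactions(
        search_world["extracted"], search_world["library"]
    )
    train, valid, _ = pol.split_dataset(X, y, seed=42)
    config = pol.TrainConfig(epochs=40, seed=1)
    return pol.train_policy(
        train, valid, config, label_hashes=search_world["library"].hashes
    )
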