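"""Monte-Carlo tree search over retrosynthetic disconnections (1N-MCTS).

One policy network serves both expansion and rollout.  A node's state is
the list of molecules still to be made plus the number of retro transforms
each has undergone from the root target.  Actions (molecule + template) are
stored at the parent with per-action Q (sum of rewards, initialized 0.5)
and N (visit count, initialized 1: expansion counts as a first visit);
child nodes are instantiated lazily by applying the template when first
visited, and an action whose template produces no outcome is marked dead
with Q = -10^6 so it is never selected again.

Selection descends by the upper confidence bound

    UCB(a) = Q(a)/N(a) + C * sqrt(ln N_parent / N(a))

with C = 1.4 by default and uniform random tie-breaking; policy priors are
stored but not used during selection.  Rollout picks uniformly among live
actions until the state is solved (all molecules in stock), the transform
cap is reached, or no action remains; rollout expansions stay in the tree
for reuse.  The terminal reward

    r = w_stock * N_in_stock/N + (1 - w_stock) * (1 - depth/max_transforms)

(w_stock = 0.95, depth = the maximum per-molecule transform count) grows
with the fraction of the state already purchasable and shrinks with route
depth; it is backpropagated along the traversed path (Q += r, N += 1).
"""
from __future__ import annotations

import math
import random
import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .chem import inchikey
from .policy import PolicyModel
from .stock import StockSet
from .templates import RetroTemplate, TemplateLibrary, apply_template

DEAD_Q = -1.0e6


@dataclass(frozen=True)
class SearchConfig:
    C: float = 1.4
    max_transforms: int = 7
    expansion_top_n: int = 50
    expansion_cum_prob: float = 0.995
    iteration_limit: int = 1000
    time_limit: float = 120.0
    early_stop_on_solved: bool = True
    seed: int = 0
    max_matches: int = 100
    reward_stock_weight: float = 0.95

    def __post_init__(self) -> None:
        if self.C < 0:
            raise ValueError("exploration constant C must be >= 0")
        if self.iteration_limit <= 0 or self.time_limit <= 0:
            raise ValueError("search limits must be positive")


@dataclass(frozen=True)
class Molecule:
    smiles: str
    inchikey: str

    @classmethod
    def from_smiles(cls, smiles: str) -> "Molecule":
        return cls(smiles=smiles, inchikey=inchikey(smiles))


class SearchState:
    """Molecules still to be made plus per-molecule retro-step counts."""

    __slots__ = ("molecules", "transforms", "in_stock")

    def __init__(
        self,
        molecules: Sequence[Molecule],
        transforms: Sequence[int],
        stock: StockSet,
    ) -> None:
        self.molecules = tuple(molecules)
        self.transforms = tuple(transforms)
        self.in_stock = tuple(m.inchikey in stock.keys for m in self.molecules)

    @property
    def is_solved(self) -> bool:
        return all(self.in_stock)

    @property
    def depth(self) -> int:
        return max(self.transforms)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SearchState({[m.smiles for m in self.molecules]}, t={self.transforms})"


@dataclass(frozen=True)
class Action:
    molecule_index: int
    label: int
    template: RetroTemplate
    prior: float


class SearchNode:
    __slots__ = (
        "state", "parent", "parent_action", "actions", "Q", "N", "dead",
        "children", "expanded", "terminal", "visits", "step", "node_id",
    )

    def __init__(
        self,
        state: SearchState,
        parent: "SearchNode | None" = None,
        parent_action: int | None = None,
        step: tuple | None = None,
        node_id: int = 0,
    ) -> None:
        self.state = state
        self.parent = parent
        self.parent_action = parent_action
        self.actions: list[Action] = []
        self.Q: list[float] = []
        self.N: list[int] = []
        self.dead: list[bool] = []
        self.children: dict[int, SearchNode] = {}
        self.expanded = False
        self.terminal = False
        self.visits = 1
        self.step = step  # (product_smiles, template_hash, smirks, precursors)
        self.node_id = node_id

    def live_actions(self) -> list[int]:
        return [i for i in range(len(self.actions)) if not self.dead[i]]


def ucb_score(q: float, n: int, n_parent: int, c: float) -> float:
    """Upper confidence bound of one action (UCT form)."""
    return q / n + c * math.sqrt(math.log(n_parent) / n)


def reward(state: SearchState, config: SearchConfig) -> float:
    """Terminal-state value in [0, 1]; maximal when everything is in stock
    at zero depth, increasing in the stock fraction, decreasing in depth."""
    w = config.reward_stock_weight
    frac = sum(state.in_stock) / len(state.molecules)
    depth_term = 1.0 - min(state.depth, config.max_transforms) / config.max_transforms
    return w * frac + (1.0 - w) * depth_term


def expansion_cutoff(
    sorted_probs: Sequence[float], top_n: int = 50, cum_prob: float = 0.995
) -> int:
    """Number of ranked templates kept: the smallest prefix reaching the
    cumulative-probability cutoff, capped at ``top_n``."""
    cumulative = np.cumsum(np.asarray(sorted_probs, dtype=np.float64))
    reach = int(np.searchsorted(cumulative, cum_prob - 1e-12)) + 1
    return min(reach, top_n, len(cumulative))


@dataclass
class Route:
    """A linearized retrosynthetic route from the target to its leaves."""

    target: str
    steps: list[dict]
    solved: bool
    depth: int
    score: float

    def leaf_molecules(self) -> list[str]:
        produced = {s["product"] for s in self.steps}
        return sorted(
            {p for s in self.steps for p in s["precursors"]} - produced
        )

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "solved": self.solved,
            "depth": self.depth,
            "score": self.score,
            "steps": self.steps,
        }

    def key(self) -> tuple:
        return tuple(
            (s["product"], s["template_hash"], tuple(s["precursors"]))
            for s in self.steps
        )


class MctsSearch:
    """One search instance binding policy, library, stock, and config."""

    def __init__(
        self,
        policy: PolicyModel,
        library: TemplateLibrary,
        stock: StockSet,
        config: SearchConfig | None = None,
        trace: list | None = None,
    ) -> None:
        self.policy = policy
        self.library = library
        self.stock = stock
        self.config = config or SearchConfig()
        self.rng = random.Random(self.config.seed)
        self.trace = trace
        self._ranked_cache: dict[str, list[tuple[int, float]]] = {}
        self._next_id = 0
        self.nodes_created = 0

    # -- policy-driven expansion ------------------------------------------

    def _ranked_templates(self, smiles: str) -> list[tuple[int, float]]:
        cached = self._ranked_cache.get(smiles)
        if cached is None:
            probs = self.policy.predict_smiles(smiles)
            labels = np.arange(len(probs))
            order = np.lexsort((labels, -probs))
            keep = expansion_cutoff(
                probs[order],
                top_n=self.config.expansion_top_n,
                cum_prob=self.config.expansion_cum_prob,
            )
            cached = [(int(i), float(probs[i])) for i in order[:keep]]
            self._ranked_cache[smiles] = cached
        return cached

    def _new_node(self, *args, **kwargs) -> SearchNode:
        node = SearchNode(*args, **kwargs, node_id=self._next_id)
        self._next_id += 1
        self.nodes_created += 1
        return node

    def expand(self, node: SearchNode) -> None:
        """Create the action list of a node (policy ranking per molecule)."""
        if node.expanded or node.terminal:
            return
        if node.state.is_solved:
            node.terminal = True
            return
        for mol_index, molecule in enumerate(node.state.molecules):
            if node.state.transforms[mol_index] >= self.config.max_transforms:
                continue
            for label, prior in self._ranked_templates(molecule.smiles):
                node.actions.append(
                    Action(
                        molecule_index=mol_index,
                        label=label,
                        template=self.library.template_of(label),
                        prior=prior,
                    )
                )
        node.Q = [0.5] * len(node.actions)
        node.N = [1] * len(node.actions)
        node.dead = [False] * len(node.actions)
        node.expanded = True
        if not node.actions:
            node.terminal = True
        if self.trace is not None:
            self.trace.append(("expand", node.node_id, len(node.actions)))

    def instantiate_child(self, node: SearchNode, action_index: int) -> SearchNode | None:
        """Apply an action's template; dead-mark on failure (Q = -10^6)."""
        if action_index in node.children:
            return node.children[action_index]
        action = node.actions[action_index]
        molecule = node.state.molecules[action.molecule_index]
        outcomes = apply_template(
            action.template, molecule.smiles, max_matches=self.config.max_matches
        )
        if not outcomes:
            node.dead[action_index] = True
            node.Q[action_index] = DEAD_Q
            if self.trace is not None:
                self.trace.append(("dead", node.node_id, action_index))
            return None
        outcome = min(outcomes, key=lambda o: o.molecules)
        molecules = list(node.state.molecules)
        transforms = list(node.state.transforms)
        parent_t = transforms.pop(action.molecule_index)
        molecules.pop(action.molecule_index)
        precursors = [Molecule.from_smiles(s) for s in outcome.molecules]
        molecules.extend(precursors)
        transforms.extend([parent_t + 1] * len(precursors))
        child = self._new_node(
            SearchState(molecules, transforms, self.stock),
            parent=node,
            parent_action=action_index,
            step=(
                molecule.smiles,
                action.template.template_hash,
                action.template.smirks,
                tuple(outcome.molecules),
            ),
        )
        node.children[action_index] = child
        return child

    # -- selection / rollout / backprop -----------------------------------

    def _argmax_ucb(self, node: SearchNode) -> int | None:
        live = node.live_actions()
        if not live:
            node.terminal = True
            return None
        scores = {
            i: ucb_score(node.Q[i], node.N[i], node.visits, self.config.C)
            for i in live
        }
        best = max(scores.values())
        winners = [i for i in live if scores[i] == best]
        choice = winners[0] if len(winners) == 1 else self.rng.choice(winners)
        if self.trace is not None:
            self.trace.append(
                (
                    "select",
                    node.node_id,
                    tuple(node.Q),
                    tuple(node.N),
                    node.visits,
                    dict(scores),
                    choice,
                )
            )
        return choice

    def select_leaf(self, root: SearchNode) -> tuple[SearchNode, list[tuple[SearchNode, int]]]:
        """UCB descent from the root to an unexpanded or terminal node."""
        node = root
        path: list[tuple[SearchNode, int]] = []
        while True:
            if node.terminal or not node.expanded:
                return node, path
            action_index = self._argmax_ucb(node)
            if action_index is None:
                return node, path
            child = self.instantiate_child(node, action_index)
            if child is None:
                continue  # action died; rescore the same node
            path.append((node, action_index))
            if not child.expanded:
                return child, path
            node = child

    def rollout(
        self, node: SearchNode, path: list[tuple[SearchNode, int]]
    ) -> tuple[SearchNode, list[tuple[SearchNode, int]]]:
        """Random-action descent to a terminal state; nodes stay in the tree."""
        while True:
            if not node.expanded:
                self.expand(node)
            if node.terminal:
                return node, path
            live = node.live_actions()
            if not live:
                node.terminal = True
                return node, path
            action_index = self.rng.choice(live)
            child = self.instantiate_child(node, action_index)
            if child is None:
                continue
            if self.trace is not None:
                self.trace.append(("rollout", node.node_id, action_index))
            path.append((node, action_index))
            node = child

    def backpropagate(self, path: list[tuple[SearchNode, int]], value: float) -> None:
        """Q += r, N += 1 along every traversed action; visits bump per node."""
        if not math.isfinite(value):
            raise ValueError("reward must be finite")
        for parent, action_index in path:
            parent.Q[action_index] += value
            parent.N[action_index] += 1
            parent.visits += 1
        if path:
            final = path[-1][0].children[path[-1][1]]
            final.visits += 1
        if self.trace is not None:
            self.trace.append(
                ("backprop", [(p.node_id, a) for p, a in path], value)
            )

    # -- main loop ---------------------------------------------------------

    def run(self, target_smiles: str) -> tuple[SearchNode, list[Route], dict]:
        root_mol = Molecule.from_smiles(target_smiles)
        root = self._new_node(SearchState([root_mol], [0], self.stock))
        started = time.monotonic()
        self.expand(root)
        iterations = 0
        solved_seen = root.state.is_solved
        if not solved_seen:
            for iterations in range(1, self.config.iteration_limit + 1):
                if time.monotonic() - started > self.config.time_limit:
                    break
                node, path = self.select_leaf(root)
                if not node.terminal:
                    self.expand(node)
                node, path = self.rollout(node, path)
                value = reward(node.state, self.config)
                self.backpropagate(path, value)
                if node.state.is_solved:
                    solved_seen = True
                    if self.config.early_stop_on_solved:
                        break
        routes = extract_routes(root, self.config, max_routes=10)
        stats = {
            "iterations": iterations,
            "nodes": self.nodes_created,
            "solved": solved_seen,
            "wall_time": time.monotonic() - started,
        }
        return root, routes, stats


def _iter_nodes(root: SearchNode):
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(node.children.values())


def extract_routes(
    root: SearchNode, config: SearchConfig, max_routes: int = 10
) -> list[Route]:
    """Collect deduplicated routes for terminal/solved states, best first."""
    target = root.state.molecules[0].smiles
    candidates = [
        n for n in _iter_nodes(root) if n.terminal or n.state.is_solved
    ]
    routes: list[Route] = []
    seen: set[tuple] = set()
    for node in candidates:
        steps = []
        walker = node
        while walker.parent is not None:
            product, digest, smirks, precursors = walker.step
            steps.append(
                {
                    "product": product,
                    "template_hash": digest,
                    "smirks": smirks,
                    "precursors": list(precursors),
                }
            )
            walker = walker.parent
        steps.reverse()
        route = Route(
            target=target,
            steps=steps,
            solved=node.state.is_solved,
            depth=node.state.depth,
            score=reward(node.state, config),
        )
        key = route.key()
        if key in seen:
            continue
        seen.add(key)
        routes.append(route)
    routes.sort(key=lambda r: (not r.solved, -r.score, r.depth))
    return routes[:max_routes]


def run_search(
    target_smiles: str,
    policy: PolicyModel,
    library: TemplateLibrary,
    stock: StockSet,
    config: SearchConfig | None = None,
    trace: list | None = None,
) -> tuple[SearchNode, list[Route], dict]:
    """Convenience wrapper: build an :class:`MctsSearch` and run one target."""
    search = MctsSearch(policy, library, stock, config=config, trace=trace)
    return search.run(target_smiles)
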