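"""Synthetic coupled lexicon + trait evolution on a shared tree of descent.

The generator produces everything the analysis pipeline consumes —
wordlists with true cognate classes, a variety -> group (province) map, a
bounded trait per group, and the true tree — so the whole method is
testable without external lexical databases, and so the phylogenetic
confound itself (Galton's problem) can be demonstrated: a trait and a
lexicon that evolve on the *same* tree with no causal link between them
will still produce correlated distance matrices.

Model, in the order it runs:

1. ``simulate_tree`` — pure-birth (Yule) topology with exponential waiting
   times, scaled so every root-to-leaf path has length 1 (ultrametric).
2. ``evolve_lexicon`` — an ancestral vocabulary of random words (one form
   per concept) descends along the tree; per branch of length t each
   symbol substitutes with probability mutation_rate·t and each concept is
   replaced by a brand-new word (opening a new cognate class) with
   probability replacement_rate·t.
3. ``apply_borrowing`` — optional horizontal transfer: varieties sit on a
   ring (a 1-D stand-in for geography, in tree order so neighbours tend to
   be relatives); each (variety, concept) copies form + cognate class from
   a ring neighbour with probability borrowing_rate.  Events are applied
   sequentially and logged.
4. ``evolve_trait`` — Brownian motion from root value 0 with per-unit
   variance ``trait_step_variance``; leaf values pass through the logistic
   function into [0, 1] (think: proportion of land under rice).
5. ``make_dataset`` — composes the above, assigns provinces as the k
   contiguous clades under the k−1 deepest splits, lifts the trait to
   groups by the mean over member varieties, and can write every file the
   readers in :mod:`galtonlex.lexical_io` accept.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit

from .clustering import ClusterTree, Node
from .lexical_io import (
    GroupMap,
    TraitTable,
    Wordlist,
    write_trait_table,
    write_wordlists,
)

logger = logging.getLogger("galtonlex")

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"
_MIN_WORD_LEN = 3
_MAX_WORD_LEN = 7


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the coupled lexicon + trait simulation.

    Rates are per concept (or per symbol) per unit of branch length; the
    tree has total height 1, so a root-to-leaf path accumulates one unit
    and a pair of leaves up to two.
    """

    n_varieties: int = 40
    n_concepts: int = 100
    alphabet_size: int = 10
    mutation_rate: float = 0.3
    replacement_rate: float = 0.25
    borrowing_rate: float = 0.0
    trait_step_variance: float = 1.0
    n_groups: int = 18
    seed: int = 0

    def __post_init__(self):
        if self.n_varieties < 2:
            raise ValueError("n_varieties must be >= 2")
        if self.n_concepts < 1:
            raise ValueError("n_concepts must be >= 1")
        if not 2 <= self.alphabet_size <= len(_ALPHABET):
            raise ValueError(f"alphabet_size must be in [2, {len(_ALPHABET)}]")
        for name in ("mutation_rate", "replacement_rate", "borrowing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.trait_step_variance < 0:
            raise ValueError("trait_step_variance must be >= 0")
        if not 1 <= self.n_groups <= self.n_varieties:
            raise ValueError("n_groups must be in [1, n_varieties]")


@dataclass
class SimulationOutput:
    """Everything one simulated study provides."""

    config: SimulationConfig
    tree: ClusterTree
    wordlists: list[Wordlist]
    group_map: GroupMap
    trait_table: TraitTable
    leaf_traits: dict[str, float]
    borrowing_events: list[dict] = field(default_factory=list)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit all files in the formats the lexical_io readers accept."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "wordlists": outdir / "wordlists.tsv",
            "groups": outdir / "groups.tsv",
            "traits": outdir / "traits.csv",
            "tree": outdir / "true_tree.nwk",
            "events": outdir / "borrowing_events.json",
        }
        write_wordlists(self.wordlists, paths["wordlists"])
        with open(paths["groups"], "w", encoding="utf-8") as fh:
            fh.write("variety\tgroup\n")
            for v, grp in self.group_map.items():
                fh.write(f"{v}\t{grp}\n")
        write_trait_table(self.trait_table, paths["traits"])
        paths["tree"].write_text(self.tree.to_newick() + "\n", encoding="utf-8")
        with open(paths["events"], "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "config": asdict(self.config),
                    "leaf_traits": self.leaf_traits,
                    "borrowing_events": self.borrowing_events,
                },
                fh,
                indent=1,
            )
        return paths


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# 1. Tree scaffold
# ---------------------------------------------------------------------------

def simulate_tree(n: int, seed=0) -> ClusterTree:
    """Random pure-birth rooted binary tree with n leaves, height 1.

    Lineages split at exponential waiting times (rate = number of extant
    lineages); node heights are rescaled so the root sits at height 1 and
    all leaves at 0 (ultrametric).  Leaves are labeled v001, v002, ... in
    tree traversal order.
    """
    if n < 2:
        raise ValueError("need n >= 2 leaves")
    rng = _as_rng(seed)
    root = Node(0.0)
    root.children = [Node(0.0), Node(0.0)]
    split_time = {id(root): 0.0}
    tips = list(root.children)
    t = 0.0
    while len(tips) < n:
        t += rng.exponential(1.0 / len(tips))
        idx = int(rng.integers(len(tips)))
        node = tips.pop(idx)
        node.children = [Node(0.0), Node(0.0)]
        split_time[id(node)] = t
        tips.extend(node.children)
    total = t + rng.exponential(1.0 / n)

    counter = 0
    order = 0

    def finish(node: Node) -> None:
        nonlocal counter, order
        if node.is_leaf:
            counter += 1
            node.label = f"v{counter:03d}"
            node.height = 0.0
        else:
            node.height = (total - split_time[id(node)]) / total
            order += 1
            node.order = order
            for ch in node.children:
                finish(ch)

    finish(root)
    return ClusterTree(root)


# ---------------------------------------------------------------------------
# 2. Lexicon descent
# ---------------------------------------------------------------------------

def _random_word(rng: np.random.Generator, alphabet_size: int) -> str:
    length = int(rng.integers(_MIN_WORD_LEN, _MAX_WORD_LEN + 1))
    return "".join(
        _ALPHABET[int(i)] for i in rng.integers(alphabet_size, size=length)
    )


def _mutate(word: str, p: float, rng: np.random.Generator, alphabet_size: int) -> str:
    out = []
    for ch in word:
        if rng.random() < p:
            # substitute with a different symbol
            k = int(rng.integers(alphabet_size - 1))
            new = _ALPHABET[k if k < _ALPHABET.index(ch) else k + 1]
            out.append(new)
        else:
            out.append(ch)
    return "".join(out)


def evolve_lexicon(
    tree: ClusterTree, config: SimulationConfig, seed=0
) -> list[Wordlist]:
    """Descend an ancestral vocabulary along the tree.

    Each concept starts as one random word in cognate class 0; replacement
    events open globally fresh classes, so two leaf forms share a class
    iff they descend from the same replacement (or the root word) without
    an intervening replacement.  Returns one Wordlist per leaf, in tree
    traversal order, with concepts c001..cNNN.
    """
    rng = _as_rng(seed)
    concepts = [f"c{i + 1:03d}" for i in range(config.n_concepts)]
    root_state = {
        c: (_random_word(rng, config.alphabet_size), f"{c}:0") for c in concepts
    }
    class_counter = {c: 0 for c in concepts}
    wordlists: list[Wordlist] = []

    def walk(node: Node, state: dict[str, tuple[str, str]]) -> None:
        if node.is_leaf:
            entries = {c: [(w, k)] for c, (w, k) in state.items()}
            wordlists.append(Wordlist(node.label, entries))
            return
        for child in node.children:
            t = node.height - child.height
            child_state = {}
            p_rep = min(1.0, config.replacement_rate * t)
            p_mut = min(1.0, config.mutation_rate * t)
            for c in concepts:
                word, klass = state[c]
                if rng.random() < p_rep:
                    class_counter[c] += 1
                    child_state[c] = (
                        _random_word(rng, config.alphabet_size),
                        f"{c}:{class_counter[c]}",
                    )
                else:
                    child_state[c] = (
                        _mutate(word, p_mut, rng, config.alphabet_size),
                        klass,
                    )
            walk(child, child_state)

    walk(tree.root, root_state)
    return wordlists


# ---------------------------------------------------------------------------
# 3. Horizontal borrowing
# ---------------------------------------------------------------------------

def apply_borrowing(
    wordlists: list[Wordlist], config: SimulationConfig, seed=0
) -> tuple[list[Wordlist], list[dict]]:
    """Copy forms between ring-adjacent varieties with prob. borrowing_rate.

    The ring is the order of ``wordlists``.  Events are drawn and applied
    sequentially (variety by variety, concept by concept), so a borrowed
    word can itself be passed on within the same sweep; every event is
    logged with donor, recipient, concept and both forms.
    """
    rng = _as_rng(seed)
    n = len(wordlists)
    state = {
        w.variety_id: {c: list(w.entries[c]) for c in w.entries} for w in wordlists
    }
    order = [w.variety_id for w in wordlists]
    events: list[dict] = []
    if config.borrowing_rate > 0 and n > 1:
        for i, vid in enumerate(order):
            for concept in sorted(state[vid]):
                if rng.random() >= config.borrowing_rate:
                    continue
                side = 1 if rng.random() < 0.5 else -1
                donor = order[(i + side) % n]
                if donor == vid or concept not in state[donor]:
                    continue
                old = state[vid][concept]
                state[vid][concept] = list(state[donor][concept])
                events.append(
                    {
                        "recipient": vid,
                        "donor": donor,
                        "concept": concept,
                        "old": [list(p) for p in old],
                        "new": [list(p) for p in state[vid][concept]],
                    }
                )
    out = [Wordlist(vid, state[vid]) for vid in order]
    return out, events


# ---------------------------------------------------------------------------
# 4. Trait descent
# ---------------------------------------------------------------------------

def evolve_trait(
    tree: ClusterTree, config: SimulationConfig, seed=0
) -> dict[str, float]:
    """Brownian motion on the tree, logistic-squashed at the leaves.

    Root liability is 0; each branch adds N(0, trait_step_variance · t).
    Returns leaf label -> trait in [0, 1] (logistic of the leaf liability).
    """
    rng = _as_rng(seed)
    traits: dict[str, float] = {}

    def walk(node: Node, x: float) -> None:
        if node.is_leaf:
            traits[node.label] = float(expit(x))
            return
        for child in node.children:
            t = node.height - child.height
            step = rng.normal(0.0, np.sqrt(config.trait_step_variance * t))
            walk(child, x + step)

    walk(tree.root, 0.0)
    return traits


# ---------------------------------------------------------------------------
# 5. Composition
# ---------------------------------------------------------------------------

def assign_groups(tree: ClusterTree, n_groups: int) -> GroupMap:
    """Provinces as the contiguous clades under the n_groups−1 deepest splits."""
    clades = tree.cut(n_groups)
    # deterministic group numbering: clades ordered by tree traversal
    position = {lab: i for i, lab in enumerate(tree.leaf_labels)}
    clades = sorted(clades, key=lambda s: min(position[lab] for lab in s))
    mapping: GroupMap = {}
    for g, clade in enumerate(clades, start=1):
        for lab in clade:
            mapping[lab] = f"p{g:02d}"
    return {lab: mapping[lab] for lab in tree.leaf_labels}


def make_dataset(config: SimulationConfig) -> SimulationOutput:
    """Run the full generator; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    tree_seed, lex_seed, borrow_seed, trait_seed = (
        int(s) for s in rng.integers(2**31, size=4)
    )
    tree = simulate_tree(config.n_varieties, tree_seed)
    wordlists = evolve_lexicon(tree, config, lex_seed)
    events: list[dict] = []
    if config.borrowing_rate > 0:
        wordlists, events = apply_borrowing(wordlists, config, borrow_seed)
    leaf_traits = evolve_trait(tree, config, trait_seed)
    group_map = assign_groups(tree, config.n_groups)
    by_group: dict[str, list[float]] = {}
    for leaf, grp in group_map.items():
        by_group.setdefault(grp, []).append(leaf_traits[leaf])
    trait_table = TraitTable({g: float(np.mean(v)) for g, v in by_group.items()})
    return SimulationOutput(
        config=config,
        tree=tree,
        wordlists=wordlists,
        group_map=group_map,
        trait_table=trait_table,
        leaf_traits=leaf_traits,
        borrowing_events=events,
    )
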