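"""Synthetic data: Yule trees, Mk trait simulation with recorded change
histories, and a preset two-clade scenario shaped like a small symbiont
phenotype dataset (two major ingroup clades plus a distant outgroup, five
states with one dominant state, heterogeneous transition rates)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .mklik import QMatrix, RootPrior
from .mlfit import PAIRS, RateModel, ZERO
from .treeio import (DEFAULT_ALPHABET, Node, PhyloTree, TraitData,
                     write_newick, write_trait_table)


def simulate_yule_tree(n_tips: int, birth_rate: float, seed: int = 0,
                       prefix: str = "t", rng=None) -> PhyloTree:
    """Pure-birth tree with exactly *n_tips* leaves, ultrametric.

    Construction: start from the root split (2 lineages); while j lineages
    are extant wait Exp(j*birth_rate) and split one uniformly; after the
    n-th lineage appears add a final Exp(n*birth_rate) stretch.  Expected
    height is therefore sum_{j=2..n} 1/(j*birth_rate).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed) if rng is None else rng
    root = Node()
    tips = [root.add_child(Node(length=0.0)), root.add_child(Node(length=0.0))]
    j = 2
    while True:
        wait = rng.exponential(1.0 / (j * birth_rate))
        for tip in tips:
            tip.length += wait
        if j == n_tips:
            break
        victim = tips[int(rng.integers(j))]
        a = victim.add_child(Node(length=0.0))
        b = victim.add_child(Node(length=0.0))
        tips.remove(victim)
        tips.extend([a, b])
        j += 1
    for order, tip in enumerate(tips, start=1):
        tip.name = f"{prefix}{order}"
    return PhyloTree(root)


def yule_expected_height(n_tips: int, birth_rate: float) -> float:
    return sum(1.0 / (j * birth_rate) for j in range(2, n_tips + 1))


def rescale_tree(tree: PhyloTree, factor: float) -> PhyloTree:
    out = tree.copy()
    for node in out.postorder():
        if node.length is not None:
            node.length *= factor
    return out


@dataclass
class ChangeEvent:
    leaf_below: str          # a leaf under the branch; locates the edge
    time: float              # time from the branch's parent end
    from_state: int
    to_state: int


@dataclass
class TraitHistory:
    root_state: int
    events: list[ChangeEvent] = field(default_factory=list)
    #: realized state at every node, keyed by id(node) (in-memory only)
    node_states: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def state_at(self, node) -> int:
        return self.node_states[id(node)]


def count_realized_transitions(history: TraitHistory) -> int:
    """Total number of recorded change events (>= the parsimony minimum)."""
    return history.n_events


def simulate_trait(tree: PhyloTree, Q: QMatrix, pi: RootPrior, seed: int = 0,
                   alphabet=DEFAULT_ALPHABET, rng=None) -> tuple[TraitData, TraitHistory]:
    """Gillespie simulation of the CTMC down the tree; returns tip states
    and the full per-branch change history."""
    rng = np.random.default_rng(seed) if rng is None else rng
    k = Q.k
    exit_rates = -np.diag(Q.q)
    jump = Q.q.copy()
    np.fill_diagonal(jump, 0.0)
    root_state = int(rng.choice(k, p=pi.pi))
    history = TraitHistory(root_state=root_state)
    history.node_states[id(tree.root)] = root_state
    states: dict[str, int] = {}

    def a_leaf_below(node: Node) -> str:
        while not node.is_leaf:
            node = node.children[0]
        return node.name

    def walk(node: Node, state: int) -> None:
        for child in node.children:
            s = state
            t = 0.0
            length = child.effective_length()
            while True:
                rate = exit_rates[s]
                if rate <= 0.0:
                    break
                t += rng.exponential(1.0 / rate)
                if t >= length:
                    break
                new_s = int(rng.choice(k, p=jump[s] / rate))
                history.events.append(
                    ChangeEvent(a_leaf_below(child), t, s, new_s)
                )
                s = new_s
            history.node_states[id(child)] = s
            if child.is_leaf:
                states[child.name] = s
            else:
                walk(child, s)

    walk(tree.root, root_state)
    return TraitData(states, alphabet), history


# ---------------------------------------------------------------------------
# Preset scenario
# ---------------------------------------------------------------------------


def two_class_rate_model(slow: float = 0.3, fast: float = 3.0) -> tuple[RateModel, np.ndarray]:
    """Default heterogeneous-rate truth: a slow class (all transitions out
    of the dominant state plus returns into it from FI/PI), a fast class
    (PI->MK, MK->O, O->CI, MK->CI), everything else zero."""
    alphabet = DEFAULT_ALPHABET
    idx = {s: i for i, s in enumerate(alphabet)}

    def p(a, b):
        return (idx[a], idx[b])

    fast_pairs = {p("PI", "MK"), p("MK", "O"), p("O", "CI"), p("MK", "CI")}
    slow_pairs = {p("CI", "FI"), p("CI", "MK"), p("CI", "O"), p("CI", "PI"),
                  p("FI", "CI"), p("PI", "CI")}
    assignment = {}
    for pair in PAIRS:
        if pair in fast_pairs:
            assignment[pair] = "C2"
        elif pair in slow_pairs:
            assignment[pair] = "C1"
        else:
            assignment[pair] = ZERO
    model = RateModel(assignment, scheme="true-2class")
    return model, np.array([slow, fast])


@dataclass
class SimScenario:
    tree: PhyloTree
    traits: TraitData
    tags: dict[str, set]
    true_model: RateModel
    true_rates: np.ndarray
    root_prior: RootPrior
    history: TraitHistory
    seed: int
    variant: str
    #: realized true state at each tagged clade's MRCA
    true_tag_states: dict[str, int] = field(default_factory=dict)

    def emit(self, outdir) -> dict[str, str]:
        """Write Newick + trait TSV + truth JSON; returns the paths."""
        import os

        paths = {
            "tree": os.path.join(outdir, "tree.nwk"),
            "traits": os.path.join(outdir, "traits.tsv"),
            "truth": os.path.join(outdir, "truth.json"),
        }
        with open(paths["tree"], "wt", encoding="utf-8") as fh:
            fh.write(write_newick(self.tree) + "\n")
        write_trait_table(self.traits, paths["traits"])
        truth = {
            "variant": self.variant,
            "seed": self.seed,
            "true_pair_rates": dict(zip(
                [f"{DEFAULT_ALPHABET[i]}->{DEFAULT_ALPHABET[j]}" for i, j in PAIRS],
                self.true_model.pair_rates(self.true_rates).tolist(),
            )),
            "root_prior": self.root_prior.pi.tolist(),
            "root_state": int(self.history.root_state),
            "n_true_changes": self.history.n_events,
            "tags": {k: sorted(v) for k, v in self.tags.items()},
            "true_tag_states": {k: int(v) for k, v in self.true_tag_states.items()},
        }
        with open(paths["truth"], "wt", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
        return paths


#: dominant-state-skewed root prior used by the preset scenario
SCENARIO_ROOT_PRIOR = np.array([0.6, 0.1, 0.1, 0.1, 0.1])


def wolbachia_like_scenario(variant: str = "small", seed: int = 0,
                            slow: float = 0.3, fast: float = 3.0,
                            birth_rate: float = 1.0) -> SimScenario:
    """Two-clade ingroup (tags "A" and "B") plus one distant outgroup.

    ``small`` gives 53 ingroup tips, ``large`` 71 (plus the outgroup).
    The ingroup is rescaled to height 1; the outgroup hangs off the root
    on a stem twice the ingroup height.  Traits evolve under the default
    two-class rate model with a dominant-state-skewed root prior.
    """
    sizes = {"small": 53, "large": 71}
    if variant not in sizes:
        raise ValueError(f"variant must be one of {sorted(sizes)}")
    n = sizes[variant]
    rng = np.random.default_rng(seed)
    n_a = n // 2 + n % 2
    n_b = n - n_a

    sub_a = simulate_yule_tree(n_a, birth_rate, prefix="A", rng=rng)
    sub_b = simulate_yule_tree(n_b, birth_rate, prefix="B", rng=rng)
    # normalize each clade to height 0.8, joined 0.2 below the ingroup root
    for sub in (sub_a, sub_b):
        height = max(sub.depths().values())
        factor = 0.8 / height
        for node in sub.postorder():
            if node.length is not None:
                node.length *= factor

    ingroup = Node()
    sub_a.root.length = 0.2
    sub_b.root.length = 0.2
    ingroup.children = [sub_a.root, sub_b.root]
    sub_a.root.parent = ingroup
    sub_b.root.parent = ingroup

    root = Node()
    ingroup.length = 1.0     # ingroup sits far from the root
    root.add_child(ingroup)
    ingroup.parent = root
    root.add_child(Node(name="OUT", length=2.0))  # stem 2x ingroup height

    tree = PhyloTree(root)
    true_model, true_rates = two_class_rate_model(slow, fast)
    root_prior = RootPrior(SCENARIO_ROOT_PRIOR)
    traits, history = simulate_trait(
        tree, true_model.q_matrix(true_rates), root_prior, rng=rng
    )
    tags = {
        "A": {l for l in tree.leaf_names() if l.startswith("A")},
        "B": {l for l in tree.leaf_names() if l.startswith("B")},
    }
    tags["AB"] = tags["A"] | tags["B"]
    from .treeio import mrca

    tag_states = {t: history.state_at(mrca(tree, taxa)) for t, taxa in tags.items()}
    return SimScenario(tree, traits, tags, true_model, true_rates,
                       root_prior, history, seed, variant,
                       true_tag_states=tag_states)
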