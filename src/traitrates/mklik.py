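"""Continuous-time Markov (Mk-type) likelihood engine for discrete traits.

The public entry points (:func:`log_likelihood`, :func:`node_marginals`)
rebuild the pruning cache on every call; repeated evaluation over the same
(tree, traits) — as in optimisation or MCMC — should construct a
:class:`PruningEngine` once and reuse it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm as _scipy_expm

from .treeio import Node, PhyloTree, TraitData

NEG_INF = float("-inf")

#: eigendecomposition is used when cond(V) stays below this
_EIG_COND_MAX = 1e8
#: transition-probability entries more negative than this are an error
_NEG_TOL = -1e-12


class LikelihoodError(ValueError):
    pass


@dataclass
class QMatrix:
    """Instantaneous rate matrix: off-diagonals >= 0, rows sum to zero."""

    q: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 2 or q.shape[0] != q.shape[1]:
            raise LikelihoodError("Q must be square")
        off = q - np.diag(np.diag(q))
        if np.any(off < 0):
            raise LikelihoodError("off-diagonal rates must be nonnegative")
        if np.max(np.abs(q.sum(axis=1))) > 1e-10:
            raise LikelihoodError("rows of Q must sum to zero")
        self.q = q

    @property
    def k(self) -> int:
        return self.q.shape[0]

    @classmethod
    def from_off_diagonal(cls, rates: np.ndarray) -> "QMatrix":
        """Build Q from a (k,k) array of off-diagonal rates (diagonal ignored)."""
        rates = np.asarray(rates, dtype=float)
        q = rates.copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return cls(q)

    @classmethod
    def equal_rates(cls, k: int, rate: float) -> "QMatrix":
        return cls.from_off_diagonal(np.full((k, k), rate))

    def stationary_distribution(self) -> np.ndarray:
        """Left null vector of Q, normalised; fails for reducible chains
        only in the sense that one of possibly many stationary vectors is
        returned."""
        w, v = np.linalg.eig(self.q.T)
        i = int(np.argmin(np.abs(w)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass
class RootPrior:
    """Probability vector over states used to weight the root."""

    pi: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if np.any(pi < 0):
            raise LikelihoodError("root prior entries must be nonnegative")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise LikelihoodError("root prior must sum to 1")
        self.pi = pi

    @classmethod
    def uniform(cls, k: int) -> "RootPrior":
        return cls(np.full(k, 1.0 / k))

    @classmethod
    def stationary(cls, Q: QMatrix) -> "RootPrior":
        return cls(Q.stationary_distribution())


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------


def _eig_factors(q: np.ndarray):
    """(eigvals, V, Vinv) if Q is safely diagonalizable, else None."""
    try:
        w, v = np.linalg.eig(q)
        if np.linalg.cond(v) > _EIG_COND_MAX:
            return None
        vinv = np.linalg.inv(v)
    except np.linalg.LinAlgError:
        return None
    return w, v, vinv


def _clamp(p: np.ndarray) -> np.ndarray:
    if p.min() < _NEG_TOL:
        raise LikelihoodError(
            f"transition probability {p.min():.3e} below tolerance; Q ill-conditioned"
        )
    return np.clip(p, 0.0, 1.0)


def transition_matrices(Q: QMatrix, ts: np.ndarray) -> np.ndarray:
    """P(t) = exp(Qt) for a batch of branch lengths; shape (len(ts), k, k)."""
    ts = np.asarray(ts, dtype=float)
    if np.any(ts < 0):
        raise LikelihoodError("branch lengths must be nonnegative")
    fac = _eig_factors(Q.q)
    if fac is not None:
        w, v, vinv = fac
        el = np.exp(np.multiply.outer(ts, w))  # (m, k)
        p = np.einsum("ij,tj,jk->tik", v, el, vinv)
        p = np.real(p)
        if p.min() >= _NEG_TOL and p.max() <= 1.0 - _NEG_TOL:
            return _clamp(p)
        # eigenroute inaccurate (stiff or near-defective Q): fall through
    # scaling-and-squaring handles defective / ill-conditioned Q
    p = np.stack([_scipy_expm(Q.q * t) for t in ts])
    return _clamp(p)


def transition_probabilities(Q: QMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for a single branch length."""
    if t < 0:
        raise LikelihoodError("branch length must be nonnegative")
    return transition_matrices(Q, np.array([t]))[0]


def series_expm(q: np.ndarray, t: float, terms: int = 60) -> np.ndarray:
    """Truncated power series for exp(Qt); independent oracle for tests."""
    k = q.shape[0]
    acc = np.eye(k)
    term = np.eye(k)
    for m in range(1, terms + 1):
        term = term @ (q * t) / m
        acc = acc + term
    return acc


# ---------------------------------------------------------------------------
# Pruning engine
# ---------------------------------------------------------------------------


class PruningEngine:
    """Flattened post-order representation of (tree, traits) for fast
    repeated likelihood evaluation.

    Tip states may include ``-1`` meaning "missing" (all-ones partial);
    the standard pipeline never produces those.
    """

    def __init__(self, tree: PhyloTree, traits: TraitData | None = None,
                 k: int | None = None):
        self.tree = tree
        if traits is not None:
            traits.check_tree(tree)
            k = traits.k
        if k is None:
            raise LikelihoodError("either traits or k must be given")
        self.k = k

        nodes = list(tree.postorder())
        self.nodes = nodes
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.children = [
            [self.index[id(c)] for c in n.children] for n in nodes
        ]
        lengths = np.array(
            [n.effective_length() if n.parent is not None else 0.0 for n in nodes]
        )
        # group identical branch lengths so exp(Qt) is computed once per value
        self.unique_lengths, self.length_idx = np.unique(lengths, return_inverse=True)
        self.leaf_order = [i for i, n in enumerate(nodes) if n.is_leaf]
        self.leaf_names = [nodes[i].name for i in self.leaf_order]

        # level structure: internal nodes grouped by height so the pruning
        # pass is a handful of batched operations instead of per-node ones
        heights = np.zeros(self.n_nodes, dtype=int)
        for i in range(self.n_nodes):
            if self.children[i]:
                heights[i] = 1 + max(heights[c] for c in self.children[i])
        self._node_level = heights
        self._levels = []
        for h in range(1, heights.max() + 1):
            nodes_h = np.flatnonzero(heights == h)
            echild = np.array([c for i in nodes_h for c in self.children[i]], dtype=int)
            eparent = np.array([i for i in nodes_h for _ in self.children[i]], dtype=int)
            self._levels.append((nodes_h, echild, eparent, self.length_idx[echild]))

        self.tip_state = np.full(self.n_nodes, -2, dtype=int)
        self._template = np.ones((self.n_nodes, self.k))
        if traits is not None:
            self.set_tip_states([traits.states[name] for name in self.leaf_names])

    def set_tip_states(self, states) -> None:
        """Assign tip state indices following ``self.leaf_names`` order."""
        states = list(states)
        if len(states) != len(self.leaf_order):
            raise LikelihoodError("tip state vector has wrong length")
        for i, s in zip(self.leaf_order, states):
            self.tip_state[i] = s
            self._template[i] = 0.0
            if s == -1:  # missing observation: all-ones partial
                self._template[i] = 1.0
            else:
                self._template[i, s] = 1.0

    def log_likelihood(
        self,
        Q: QMatrix,
        pi: RootPrior,
        clamp_node: int | Node | None = None,
        clamp_state: int | None = None,
    ) -> float:
        """Pruning log-likelihood; −inf when the data have probability 0.

        ``clamp_node``/``clamp_state`` restrict one node to one state,
        which is how node marginals are computed.
        """
        if Q.k != self.k or len(pi.pi) != self.k:
            raise LikelihoodError("Q / prior dimension does not match alphabet")
        if np.any(self.tip_state[self.leaf_order] == -2):
            raise LikelihoodError("tip states not set")
        if isinstance(clamp_node, Node):
            clamp_node = self.index[id(clamp_node)]
        pmats = transition_matrices(Q, self.unique_lengths)
        partials = self._template.copy()
        if clamp_node is not None and not self.children[clamp_node]:
            mask = np.zeros(self.k)
            mask[clamp_state] = 1.0
            partials[clamp_node] *= mask
        log_scale = 0.0
        for nodes_h, echild, eparent, elen in self._levels:
            contrib = np.einsum("eij,ej->ei", pmats[elen], partials[echild])
            np.multiply.at(partials, eparent, contrib)
            if clamp_node is not None and self.children[clamp_node] \
                    and self._node_level[clamp_node] == self._node_level[nodes_h[0]]:
                mask = np.zeros(self.k)
                mask[clamp_state] = 1.0
                partials[clamp_node] *= mask
            m = partials[nodes_h].max(axis=1)
            if m.min() <= 0.0:
                return NEG_INF
            partials[nodes_h] /= m[:, None]
            log_scale += float(np.log(m).sum())
        lik = float(pi.pi @ partials[self.n_nodes - 1])
        if lik <= 0.0:
            return NEG_INF
        return math.log(lik) + log_scale

    def node_marginals(self, Q: QMatrix, pi: RootPrior, node: int | Node) -> np.ndarray:
        """Marginal posterior state probabilities at *node*.

        Computed as renormalised clamped likelihoods, which is exact and
        handles polytomies and zero branches with no special cases.
        """
        if isinstance(node, Node):
            node = self.index[id(node)]
        logs = np.array(
            [self.log_likelihood(Q, pi, clamp_node=node, clamp_state=s)
             for s in range(self.k)]
        )
        top = logs.max()
        if top == NEG_INF:
            raise LikelihoodError("data have probability 0 under (Q, pi); marginal undefined")
        w = np.exp(logs - top)
        return w / w.sum()


# ---------------------------------------------------------------------------
# Public one-shot wrappers and the brute-force oracle
# ---------------------------------------------------------------------------


def log_likelihood(tree: PhyloTree, traits: TraitData, Q: QMatrix, pi: RootPrior) -> float:
    return PruningEngine(tree, traits).log_likelihood(Q, pi)


def node_marginals(tree: PhyloTree, traits: TraitData, Q: QMatrix, pi: RootPrior,
                   node: Node) -> np.ndarray:
    return PruningEngine(tree, traits).node_marginals(Q, pi, node)


def brute_force_log_likelihood(tree: PhyloTree, traits: TraitData, Q: QMatrix,
                               pi: RootPrior, max_internal: int = 8) -> float:
    """Exact enumeration over internal-node state assignments (test oracle)."""
    traits.check_tree(tree)
    k = traits.k
    internal = tree.internal_nodes()
    m = len(internal)
    if m > max_internal:
        raise LikelihoodError(f"too many internal nodes for enumeration ({m} > {max_internal})")
    pos = {id(n): i for i, n in enumerate(internal)}

    nodes = [n for n in tree.postorder() if n.parent is not None]
    plen = np.array([n.effective_length() for n in nodes])
    pmats = {t: transition_probabilities(Q, t) for t in set(plen)}

    def state_of(node: Node, assign) -> int:
        if node.is_leaf:
            return traits.states[node.name]
        return assign[pos[id(node)]]

    total = 0.0
    root = tree.root
    for assign in itertools.product(range(k), repeat=m):
        prob = pi.pi[state_of(root, assign)]
        for node in nodes:
            prob *= pmats[node.effective_length()][
                state_of(node.parent, assign), state_of(node, assign)
            ]
            if prob == 0.0:
                break
        total += prob
    return math.log(total) if total > 0.0 else NEG_INF


def brute_force_node_marginals(tree: PhyloTree, traits: TraitData, Q: QMatrix,
                               pi: RootPrior, node: Node) -> np.ndarray:
    """Enumeration-based marginal at one node (test oracle).

    For a leaf this returns the point mass on its observed state.
    """
    k = traits.k
    if node.is_leaf:
        out = np.zeros(k)
        out[traits.states[node.name]] = 1.0
        return out
    internal = tree.internal_nodes()
    pos = {id(n): i for i, n in enumerate(internal)}
    nodes = [n for n in tree.postorder() if n.parent is not None]
    pmats = {n.effective_length(): transition_probabilities(Q, n.effective_length())
             for n in nodes}
    weights = np.zeros(k)
    root = tree.root

    def state_of(n: Node, assign) -> int:
        return traits.states[n.name] if n.is_leaf else assign[pos[id(n)]]

    for assign in itertools.product(range(k), repeat=len(internal)):
        prob = pi.pi[state_of(root, assign)]
        for n in nodes:
            prob *= pmats[n.effective_length()][state_of(n.parent, assign), state_of(n, assign)]
        weights[assign[pos[id(node)]]] += prob
    total = weights.sum()
    if total <= 0.0:
        raise LikelihoodError("data have probability 0; marginal undefined")
    return weights / total
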