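"""Reversible-jump MCMC over rate-class models.

The sampler walks over models that assign each of the 20 ordered state
pairs either to a zero class or to one of an unlabeled set of shared
free-rate classes, with an exponential prior on each class rate and a
uniform prior over model structures.  Moves: within-class rate updates
(random-walk and prior redraw), single-pair reassignment (including class
birth/death), class split/merge, and switching among supplied trees.
All dimension-changing proposals draw fresh rates from the prior, so the
Metropolis-Hastings-Green ratios reduce to likelihood and counting terms.

Bayes factors are computed as posterior-vs-prior visit odds against a
matched prior-only run (the induced model prior is characterized
empirically, not in closed form).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from . import treeio
from .mklik import NEG_INF, PruningEngine, QMatrix, RootPrior
from .mlfit import N_PAIRS, PAIRS, PAIR_LABELS
from .treeio import PhyloTree, TraitData

#: Kass & Raftery verbal scale for natural-log Bayes factors
_KR_LABELS = (
    (5.0, "decisive"),
    (3.0, "strong"),
    (1.0, "positive"),
    (0.0, "weak"),
)


class MCMCError(ValueError):
    pass


@dataclass
class PriorSpec:
    """Exponential prior on class rates, mean ``mu``."""

    mu: float

    def __post_init__(self):
        if self.mu <= 0:
            raise MCMCError("prior mean must be positive")

    def log_density(self, r: float) -> float:
        return -math.log(self.mu) - r / self.mu

    def sample(self, rng) -> float:
        return float(rng.exponential(self.mu))


DEFAULT_PRIOR_MEANS = (1.0, 10.0, 100.0, 500.0)

#: default move-mixture weights
DEFAULT_MOVE_WEIGHTS = {
    "rate_update": 0.55,
    "prior_redraw": 0.05,
    "reassign": 0.15,
    "split": 0.10,
    "merge": 0.10,
    "tree_switch": 0.05,
}

RATE_PROPOSAL_SD = 0.3


class RJState:
    """Current sampler state: pair assignment, class rates, tree index."""

    __slots__ = ("assign", "rates", "tree_idx", "lnl", "_next_id")

    def __init__(self, assign: np.ndarray, rates: dict[int, float], tree_idx: int = 0):
        self.assign = assign          # (20,) ints; 0 = ZERO, else class id
        self.rates = rates            # class id -> rate
        self.tree_idx = tree_idx
        self.lnl = 0.0
        self._next_id = max(rates, default=0) + 1

    def new_class_id(self) -> int:
        cid = self._next_id
        self._next_id += 1
        return cid

    @property
    def k(self) -> int:
        return len(self.rates)

    def pair_rates(self) -> np.ndarray:
        return np.array([self.rates.get(a, 0.0) for a in self.assign])

    def q_matrix(self) -> QMatrix:
        off = np.zeros((5, 5))
        r = self.pair_rates()
        for idx, (i, j) in enumerate(PAIRS):
            off[i, j] = r[idx]
        return QMatrix.from_off_diagonal(off)

    def signature(self) -> str:
        """Canonical model string: classes relabeled by first appearance,
        ZERO written as '0', pairs in canonical order."""
        relabel: dict[int, str] = {}
        out = []
        for a in self.assign:
            if a == 0:
                out.append("0")
            else:
                if a not in relabel:
                    relabel[a] = f"C{len(relabel) + 1}"
                out.append(relabel[a])
        return ",".join(out)

    def class_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for a in self.assign:
            if a != 0:
                sizes[a] = sizes.get(a, 0) + 1
        return sizes


def _initial_state(rng, prior: PriorSpec) -> RJState:
    """Start from the one-class model with a prior-drawn rate."""
    assign = np.ones(N_PAIRS, dtype=int)
    return RJState(assign, {1: prior.sample(rng)})


def _n_targets(state: RJState, pair_idx: int) -> int:
    """Number of reassignment targets for one pair in a state: other
    classes, ZERO (if not already there), and NEW (unless the pair is the
    sole member of its class, where NEW would be a disguised rate redraw)."""
    cur = int(state.assign[pair_idx])
    sizes = state.class_sizes()
    n = len(sizes) - (1 if cur != 0 else 0)   # other existing classes
    if cur != 0:
        n += 1                                 # ZERO
    if cur == 0 or sizes[cur] >= 2:
        n += 1                                 # NEW
    return n


@dataclass
class ChainTrace:
    """Sampled MCMC output plus run metadata."""

    iterations: np.ndarray          # (n,)
    signatures: list[str]           # (n,)
    k: np.ndarray                   # (n,)
    pair_rates: np.ndarray          # (n, 20) realized rates, zeros included
    lnl: np.ndarray                 # (n,)
    tree_index: np.ndarray          # (n,)
    meta: dict

    @property
    def n_samples(self) -> int:
        return len(self.signatures)

    def burn_slice(self, burn_frac: float | None = None) -> slice:
        frac = self.meta.get("burn_in_frac", 0.1) if burn_frac is None else burn_frac
        return slice(int(self.n_samples * frac), self.n_samples)

    def post_burn(self, burn_frac: float | None = None) -> "ChainTrace":
        s = self.burn_slice(burn_frac)
        return ChainTrace(
            iterations=self.iterations[s],
            signatures=self.signatures[s],
            k=self.k[s],
            pair_rates=self.pair_rates[s],
            lnl=self.lnl[s],
            tree_index=self.tree_index[s],
            meta={**self.meta, "burn_in_frac": 0.0},
        )

    # -- persistence (TSV + JSON sidecar) ---------------------------------

    def to_tsv(self, path, meta_path=None) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            cols = ["iteration", "signature", "k"] + list(PAIR_LABELS) + ["lnL", "tree_index"]
            fh.write("\t".join(cols) + "\n")
            for i in range(self.n_samples):
                rates = "\t".join(repr(float(r)) for r in self.pair_rates[i])
                fh.write(
                    f"{int(self.iterations[i])}\t{self.signatures[i]}\t{int(self.k[i])}"
                    f"\t{rates}\t{float(self.lnl[i])!r}\t{int(self.tree_index[i])}\n"
                )
        if meta_path is not None:
            with open(meta_path, "wt", encoding="utf-8") as fh:
                json.dump(self.meta, fh, indent=2, sort_keys=True)

    @classmethod
    def from_tsv(cls, path, meta_path=None) -> "ChainTrace":
        meta = {}
        if meta_path is not None:
            with open(meta_path, "rt", encoding="utf-8") as fh:
                meta = json.load(fh)
        iterations, signatures, ks, rates, lnls, tidx = [], [], [], [], [], []
        with open(path, "rt", encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                f = line.rstrip("\n").split("\t")
                iterations.append(int(f[0]))
                signatures.append(f[1])
                ks.append(int(f[2]))
                rates.append([float(x) for x in f[3:3 + N_PAIRS]])
                lnls.append(float(f[3 + N_PAIRS]))
                tidx.append(int(f[4 + N_PAIRS]))
        return cls(
            iterations=np.array(iterations),
            signatures=signatures,
            k=np.array(ks),
            pair_rates=np.array(rates),
            lnl=np.array(lnls),
            tree_index=np.array(tidx),
            meta=meta,
        )


def run_chain(trees, traits: TraitData, prior: PriorSpec, n_generations: int = 10**6,
              sample_freq: int = 500, seed: int = 0, prior_only: bool = False,
              pi: RootPrior | None = None,
              move_weights: dict | None = None,
              burn_in_frac: float = 0.1) -> ChainTrace:
    """Run one reversible-jump chain and return its sampled trace.

    With ``prior_only`` the likelihood term is constant, so the chain
    samples the induced prior over (model, rates); such runs supply the
    reference distribution for Bayes factors.
    """
    if isinstance(trees, PhyloTree):
        trees = [trees]
    if not trees:
        raise MCMCError("at least one tree is required")
    leafset = set(trees[0].leaf_names())
    for t in trees[1:]:
        if set(t.leaf_names()) != leafset:
            raise MCMCError("all trees must share one leaf set")
    if n_generations < sample_freq:
        raise MCMCError("n_generations must be >= sample_freq")
    pi = pi or RootPrior.uniform(traits.k)
    weights = dict(DEFAULT_MOVE_WEIGHTS)
    if move_weights:
        weights.update(move_weights)
    move_names = sorted(weights)
    probs = np.array([weights[m] for m in move_names], dtype=float)
    probs = probs / probs.sum()
    cum = np.cumsum(probs)
    norm_weights = {m: float(p) for m, p in zip(move_names, probs)}

    engines = None if prior_only else [PruningEngine(t, traits) for t in trees]
    rng = np.random.default_rng(seed)
    state = _initial_state(rng, prior)

    def loglik(st: RJState) -> float:
        if prior_only:
            return 0.0
        return engines[st.tree_idx].log_likelihood(st.q_matrix(), pi)

    state.lnl = loglik(state)

    n_samples = n_generations // sample_freq
    out_it = np.empty(n_samples, dtype=int)
    out_sig: list[str] = []
    out_k = np.empty(n_samples, dtype=int)
    out_rates = np.empty((n_samples, N_PAIRS))
    out_lnl = np.empty(n_samples)
    out_tree = np.empty(n_samples, dtype=int)

    sample_i = 0
    n_trees = len(trees)
    for it in range(1, n_generations + 1):
        move = move_names[int(np.searchsorted(cum, rng.random()))]
        _MOVES[move](state, rng, prior, loglik, n_trees, norm_weights)
        if it % sample_freq == 0 and sample_i < n_samples:
            out_it[sample_i] = it
            out_sig.append(state.signature())
            out_k[sample_i] = state.k
            out_rates[sample_i] = state.pair_rates()
            out_lnl[sample_i] = state.lnl
            out_tree[sample_i] = state.tree_idx
            sample_i += 1

    meta = {
        "n_generations": n_generations,
        "sample_freq": sample_freq,
        "seed": seed,
        "mu": prior.mu,
        "prior_only": prior_only,
        "move_weights": {m: weights[m] for m in move_names},
        "burn_in_frac": burn_in_frac,
        "n_trees": len(trees),
    }
    return ChainTrace(out_it, out_sig, out_k, out_rates, out_lnl, out_tree, meta)


# ---------------------------------------------------------------------------
# Moves.  Each mutates the state in place when accepted.
# ---------------------------------------------------------------------------


def _accept(rng, log_alpha: float) -> bool:
    return log_alpha >= 0 or math.log(rng.random()) < log_alpha


def _move_rate_update(state, rng, prior, loglik, n_trees, weights):
    if not state.rates:
        return
    cid = list(state.rates)[rng.integers(len(state.rates))]
    r = state.rates[cid]
    r_new = r * math.exp(rng.normal(0.0, RATE_PROPOSAL_SD))
    old_lnl = state.lnl
    state.rates[cid] = r_new
    new_lnl = loglik(state)
    # lognormal multiplicative proposal: Hastings ratio r_new / r
    log_alpha = (new_lnl - old_lnl) - (r_new - r) / prior.mu + math.log(r_new / r)
    if new_lnl > NEG_INF and _accept(rng, log_alpha):
        state.lnl = new_lnl
    else:
        state.rates[cid] = r


def _move_prior_redraw(state, rng, prior, loglik, n_trees, weights):
    # independence proposal from the prior: prior terms cancel
    if not state.rates:
        return
    cid = list(state.rates)[rng.integers(len(state.rates))]
    r = state.rates[cid]
    state.rates[cid] = prior.sample(rng)
    new_lnl = loglik(state)
    if new_lnl > NEG_INF and _accept(rng, new_lnl - state.lnl):
        state.lnl = new_lnl
    else:
        state.rates[cid] = r


def _move_reassign(state, rng, prior, loglik, n_trees, weights):
    pair = int(rng.integers(N_PAIRS))
    cur = int(state.assign[pair])
    sizes = state.class_sizes()
    targets: list = [c for c in sorted(sizes) if c != cur]
    if cur != 0:
        targets.append("ZERO")
    if cur == 0 or sizes[cur] >= 2:
        targets.append("NEW")
    if not targets:
        return
    n_fwd = len(targets)
    target = targets[rng.integers(n_fwd)]

    old_lnl = state.lnl
    added_cid = None
    removed = None  # (cid, rate)
    if target == "NEW":
        added_cid = state.new_class_id()
        state.rates[added_cid] = prior.sample(rng)
        state.assign[pair] = added_cid
    elif target == "ZERO":
        state.assign[pair] = 0
    else:
        state.assign[pair] = target
    if cur != 0 and cur not in state.assign:
        removed = (cur, state.rates.pop(cur))

    n_rev = _n_targets(state, pair)
    new_lnl = loglik(state)
    # prior density of born/dead rates cancels against the prior-draw proposal
    log_alpha = (new_lnl - old_lnl) + math.log(n_fwd) - math.log(n_rev)
    if new_lnl > NEG_INF and _accept(rng, log_alpha):
        state.lnl = new_lnl
    else:
        state.assign[pair] = cur
        if added_cid is not None:
            del state.rates[added_cid]
        if removed is not None:
            state.rates[removed[0]] = removed[1]


def _move_split(state, rng, prior, loglik, n_trees, weights):
    sizes = state.class_sizes()
    splittable = sorted(c for c, s in sizes.items() if s >= 2)
    if not splittable:
        return
    n_split = len(splittable)
    cid = splittable[rng.integers(n_split)]
    members = np.flatnonzero(state.assign == cid)
    m = len(members)
    # ordered nonempty bipartition via a random mask in 1..2^m-2;
    # bit set = member moves to the new class (which gets a fresh rate)
    mask = int(rng.integers(1, 2**m - 1))
    moving = [members[b] for b in range(m) if mask >> b & 1]

    old_lnl = state.lnl
    new_cid = state.new_class_id()
    state.rates[new_cid] = prior.sample(rng)
    state.assign[moving] = new_cid
    k_after = state.k
    new_lnl = loglik(state)
    p_merge, p_split = weights["merge"], weights["split"]
    log_alpha = (
        (new_lnl - old_lnl)
        + math.log(p_merge) - math.log(p_split)
        + math.log(n_split) + math.log(2**m - 2)
        - math.log(2.0) - math.log(k_after * (k_after - 1) / 2)
    )
    if new_lnl > NEG_INF and _accept(rng, log_alpha):
        state.lnl = new_lnl
    else:
        state.assign[moving] = cid
        del state.rates[new_cid]


def _move_merge(state, rng, prior, loglik, n_trees, weights):
    cids = sorted(state.rates)
    k = len(cids)
    if k < 2:
        return
    i, j = rng.choice(k, size=2, replace=False)
    keep, die = cids[int(i)], cids[int(j)]
    if rng.random() < 0.5:
        keep, die = die, keep

    old_lnl = state.lnl
    moved = np.flatnonzero(state.assign == die)
    state.assign[moved] = keep
    dead_rate = state.rates.pop(die)
    m = int((state.assign == keep).sum())
    sizes_after = state.class_sizes()
    n_split_after = sum(1 for s in sizes_after.values() if s >= 2)
    new_lnl = loglik(state)
    p_merge, p_split = weights["merge"], weights["split"]
    log_alpha = (
        (new_lnl - old_lnl)
        + math.log(p_split) - math.log(p_merge)
        + math.log(2.0) + math.log(k * (k - 1) / 2)
        - math.log(n_split_after) - math.log(2**m - 2)
    )
    if new_lnl > NEG_INF and _accept(rng, log_alpha):
        state.lnl = new_lnl
    else:
        state.assign[moved] = die
        state.rates[die] = dead_rate


def _move_tree_switch(state, rng, prior, loglik, n_trees, weights):
    if n_trees < 2:
        return
    others = [t for t in range(n_trees) if t != state.tree_idx]
    old_idx, old_lnl = state.tree_idx, state.lnl
    state.tree_idx = others[rng.integers(len(others))]
    new_lnl = loglik(state)
    if new_lnl > NEG_INF and _accept(rng, new_lnl - old_lnl):
        state.lnl = new_lnl
    else:
        state.tree_idx = old_idx


_MOVES = {
    "rate_update": _move_rate_update,
    "prior_redraw": _move_prior_redraw,
    "reassign": _move_reassign,
    "split": _move_split,
    "merge": _move_merge,
    "tree_switch": _move_tree_switch,
}


# ---------------------------------------------------------------------------
# Trace post-processing
# ---------------------------------------------------------------------------


@dataclass
class ModelCounts:
    by_signature: dict[str, int]
    by_k: dict[int, int]
    total: int
    meta: dict


def classify_models(trace: ChainTrace, burn_frac: float | None = None) -> ModelCounts:
    """Visit counts per canonical model signature and per free-parameter count."""
    if trace.n_samples == 0:
        raise MCMCError("empty trace")
    sub = trace.post_burn(burn_frac)
    by_sig: dict[str, int] = {}
    by_k: dict[int, int] = {}
    for sig, k in zip(sub.signatures, sub.k):
        by_sig[sig] = by_sig.get(sig, 0) + 1
        by_k[int(k)] = by_k.get(int(k), 0) + 1
    return ModelCounts(by_sig, by_k, sub.n_samples, trace.meta)


def _kr_label(ln_bf: float) -> str:
    for cut, lab in _KR_LABELS:
        if ln_bf > cut:
            return lab
    return "negative"


@dataclass
class BFRow:
    item: str
    posterior_fraction: float
    prior_fraction: float
    bf: float
    ln_bf: float
    log10_bf: float
    label: str
    undefined: bool = False


@dataclass
class BFTable:
    models: list[BFRow]
    classes: list[BFRow]

    def to_tsv(self, path, which: str = "classes") -> None:
        rows = self.classes if which == "classes" else self.models
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("item\tposterior_fraction\tprior_fraction\tBF\tln_BF\tlog10_BF\tlabel\n")
            for r in rows:
                fh.write(
                    f"{r.item}\t{r.posterior_fraction!r}\t{r.prior_fraction!r}"
                    f"\t{r.bf!r}\t{r.ln_bf!r}\t{r.log10_bf!r}\t{r.label}\n"
                )


def _bf_rows(post: dict, prior: dict, n_post: int, n_prior: int) -> list[BFRow]:
    rows = []
    for item in sorted(set(post) | set(prior), key=str):
        # add-one smoothing on item-vs-rest counts
        p = (post.get(item, 0) + 1) / (n_post + 2)
        q = (prior.get(item, 0) + 1) / (n_prior + 2)
        bf = (p / (1 - p)) / (q / (1 - q))
        ln_bf = math.log(bf)
        rows.append(BFRow(
            item=str(item), posterior_fraction=post.get(item, 0) / n_post,
            prior_fraction=prior.get(item, 0) / n_prior, bf=bf, ln_bf=ln_bf,
            log10_bf=ln_bf / math.log(10.0), label=_kr_label(ln_bf),
            undefined=item not in prior,
        ))
    rows.sort(key=lambda r: -r.ln_bf)
    return rows


def bayes_factors(posterior_counts: ModelCounts, prior_counts: ModelCounts) -> BFTable:
    """Posterior-vs-prior visit-odds Bayes factors per model and per k-class.

    The prior run must be a prior-only chain with the same rate-prior mean
    and move kernel; anything else invalidates the comparison.
    """
    pm, qm = posterior_counts.meta, prior_counts.meta
    if not qm.get("prior_only", False):
        raise MCMCError("prior_counts must come from a prior_only run")
    if pm.get("mu") != qm.get("mu"):
        raise MCMCError("posterior and prior runs used different prior means")
    if pm.get("move_weights") != qm.get("move_weights"):
        raise MCMCError("posterior and prior runs used different move kernels")
    return BFTable(
        models=_bf_rows(posterior_counts.by_signature, prior_counts.by_signature,
                        posterior_counts.total, prior_counts.total),
        classes=_bf_rows(posterior_counts.by_k, prior_counts.by_k,
                         posterior_counts.total, prior_counts.total),
    )


# ---------------------------------------------------------------------------
# Convergence and posterior summaries
# ---------------------------------------------------------------------------


@dataclass
class GewekeResult:
    z: float
    converged: bool
    undefined: bool = False


def _spectral_var(x: np.ndarray, n_batches: int = 20) -> float:
    """Spectral density at zero via batch means: batch_size * var(batch means)."""
    n = len(x)
    batch = max(n // n_batches, 1)
    used = batch * (n // batch)
    means = x[:used].reshape(-1, batch).mean(axis=1)
    if len(means) < 2:
        return float(np.var(x, ddof=1)) if n > 1 else 0.0
    return batch * float(np.var(means, ddof=1))


def geweke_diagnostic(series, frac_first: float = 0.1, frac_last: float = 0.5) -> GewekeResult:
    """Geweke z-score comparing early and late window means, with
    batch-means spectral variance estimates."""
    x = np.asarray(series, dtype=float)
    if len(x) < 100:
        raise MCMCError("series too short for the Geweke diagnostic (need >= 100)")
    if frac_first + frac_last > 1:
        raise MCMCError("windows overlap: frac_first + frac_last must be <= 1")
    a = x[: int(len(x) * frac_first)]
    b = x[len(x) - int(len(x) * frac_last):]
    va, vb = _spectral_var(a), _spectral_var(b)
    if va == 0.0 and vb == 0.0:
        return GewekeResult(z=float("nan"), converged=False, undefined=True)
    z = (a.mean() - b.mean()) / math.sqrt(va / len(a) + vb / len(b))
    return GewekeResult(z=float(z), converged=abs(z) < 1.96)


@dataclass
class AncestralEstimate:
    probabilities: np.ndarray
    mc_error: np.ndarray
    n_used: int
    n_skipped: int


def ancestral_at_mrca(trace: ChainTrace, trees, traits: TraitData, taxa,
                      pi: RootPrior | None = None, thin: int = 1,
                      burn_frac: float | None = None) -> AncestralEstimate:
    """Posterior ancestral-state probabilities at the MRCA of *taxa*,
    averaged over the sampled (model, rates, tree) triples."""
    if isinstance(trees, PhyloTree):
        trees = [trees]
    pi = pi or RootPrior.uniform(traits.k)
    engines = [PruningEngine(t, traits) for t in trees]
    nodes = [engines[i].index[id(treeio.mrca(t, taxa))] for i, t in enumerate(trees)]
    sub = trace.post_burn(burn_frac)
    vecs = []
    skipped = 0
    for s in range(0, sub.n_samples, thin):
        ti = int(sub.tree_index[s])
        off = np.zeros((5, 5))
        for idx, (i, j) in enumerate(PAIRS):
            off[i, j] = sub.pair_rates[s, idx]
        Q = QMatrix.from_off_diagonal(off)
        try:
            vecs.append(engines[ti].node_marginals(Q, pi, nodes[ti]))
        except Exception:
            skipped += 1
    if not vecs:
        raise MCMCError("no usable samples for ancestral estimation")
    arr = np.array(vecs)
    mean = arr.mean(axis=0)
    mc_err = arr.std(axis=0, ddof=1) / math.sqrt(len(arr)) if len(arr) > 1 else np.zeros(traits.k)
    return AncestralEstimate(mean / mean.sum(), mc_err, len(arr), skipped)


@dataclass
class RateMeans:
    means: np.ndarray                  # (20,)
    geweke: list[GewekeResult]

    def converged_flags(self) -> list[bool]:
        return [g.converged or g.undefined for g in self.geweke]


def posterior_rate_means(trace: ChainTrace, burn_frac: float | None = None) -> RateMeans:
    """Per-pair posterior mean of realized rates (zeros included), with a
    Geweke convergence flag per pair."""
    if trace.n_samples == 0:
        raise MCMCError("empty trace")
    sub = trace.post_burn(burn_frac)
    means = sub.pair_rates.mean(axis=0)
    flags = []
    for idx in range(N_PAIRS):
        series = sub.pair_rates[:, idx]
        if len(series) >= 100:
            flags.append(geweke_diagnostic(series))
        else:
            flags.append(GewekeResult(z=float("nan"), converged=False, undefined=True))
    return RateMeans(means, flags)
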