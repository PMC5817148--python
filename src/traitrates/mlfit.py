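"""Maximum-likelihood fitting of transition-rate models.

The model family: equal-rates ("single"), symmetric, all-rates-different
("unconstrained"), and five reduced models obtained from the unconstrained
fit by zeroing small rates and binning the survivors into 1..5 equal-width
rate classes.  The best model is the AIC minimiser, ties going to the model
with fewer parameters.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import treeio
from .mklik import NEG_INF, PruningEngine, QMatrix, RootPrior
from .treeio import DEFAULT_ALPHABET, PhyloTree, TraitData

logger = logging.getLogger(__name__)

ZERO = "ZERO"

#: the 20 ordered state-index pairs, lexicographic by (from, to)
PAIRS: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i, j in itertools.product(range(5), repeat=2) if i != j
)
N_PAIRS = len(PAIRS)


def pair_label(pair: tuple[int, int], alphabet=DEFAULT_ALPHABET) -> str:
    return f"{alphabet[pair[0]]}->{alphabet[pair[1]]}"


PAIR_LABELS: tuple[str, ...] = tuple(pair_label(p) for p in PAIRS)


class ModelError(ValueError):
    pass


@dataclass
class RateModel:
    """Assignment of the 20 ordered state pairs to ZERO or shared rate classes."""

    assignment: dict[tuple[int, int], str]
    scheme: str = "custom"

    def __post_init__(self):
        if set(self.assignment) != set(PAIRS):
            raise ModelError("assignment must cover exactly the 20 ordered pairs")

    @property
    def classes(self) -> list[str]:
        """Non-ZERO class labels ordered by first appearance over PAIRS."""
        seen: list[str] = []
        for p in PAIRS:
            lab = self.assignment[p]
            if lab != ZERO and lab not in seen:
                seen.append(lab)
        return seen

    @property
    def k(self) -> int:
        return len(self.classes)

    def q_matrix(self, class_rates) -> QMatrix:
        rates = dict(zip(self.classes, np.asarray(class_rates, dtype=float)))
        off = np.zeros((5, 5))
        for (i, j), lab in self.assignment.items():
            off[i, j] = 0.0 if lab == ZERO else rates[lab]
        return QMatrix.from_off_diagonal(off)

    def pair_rates(self, class_rates) -> np.ndarray:
        """Realized 20-vector of per-pair rates (ZERO pairs -> 0)."""
        rates = dict(zip(self.classes, np.asarray(class_rates, dtype=float)))
        return np.array(
            [0.0 if self.assignment[p] == ZERO else rates[self.assignment[p]]
             for p in PAIRS]
        )


def build_scheme(name: str) -> RateModel:
    """Construct one of the three unreduced schemes."""
    if name == "single":
        return RateModel({p: "C1" for p in PAIRS}, scheme="single")
    if name == "symmetric":
        assignment = {}
        labels = {}
        for (i, j) in PAIRS:
            key = (min(i, j), max(i, j))
            if key not in labels:
                labels[key] = f"C{len(labels) + 1}"
            assignment[(i, j)] = labels[key]
        return RateModel(assignment, scheme="symmetric")
    if name == "unconstrained":
        return RateModel(
            {p: f"C{n + 1}" for n, p in enumerate(PAIRS)}, scheme="unconstrained"
        )
    raise ModelError(f"unknown scheme {name!r}")


def reduce_model(ard_rates, k: int, threshold: float = 0.1) -> RateModel:
    """Reduced model from unconstrained-fit rates.

    Rates below *threshold* are fixed at zero; survivors are binned into
    *k* equal-width intervals over their range (half-open, last closed;
    boundary values join the upper interval).  Empty intervals are dropped
    so the resulting number of classes equals the occupied bins.
    """
    ard_rates = np.asarray(ard_rates, dtype=float)
    if ard_rates.shape != (N_PAIRS,):
        raise ModelError("ard_rates must be a 20-vector ordered like PAIRS")
    if np.any(ard_rates < 0):
        raise ModelError("rates must be nonnegative")
    if not 1 <= k <= 5:
        raise ModelError("k must be in 1..5")
    surviving = ard_rates >= threshold
    if not surviving.any():
        raise ModelError("no free rates remain after thresholding")
    lo = ard_rates[surviving].min()
    hi = ard_rates[surviving].max()
    if hi == lo:
        if k > 1:
            logger.info("all surviving rates equal; collapsing to one class")
        bins = np.zeros(N_PAIRS, dtype=int)
    else:
        # epsilon nudge: a value exactly on an interior boundary joins the
        # upper interval even when the division is inexact in floats
        t = (ard_rates - lo) / (hi - lo) * k
        bins = np.floor(t + 1e-9).astype(int)
        bins = np.clip(bins, 0, k - 1)  # hi joins the last class
    assignment: dict[tuple[int, int], str] = {}
    relabel: dict[int, str] = {}
    for idx, p in enumerate(PAIRS):
        if not surviving[idx]:
            assignment[p] = ZERO
        else:
            b = int(bins[idx])
            if b not in relabel:
                relabel[b] = f"C{len(relabel) + 1}"
            assignment[p] = relabel[b]
    return RateModel(assignment, scheme=f"reduced-{k}")


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FitOptions:
    bounds: tuple[float, float] = (1e-8, 1e3)
    n_random_starts: int = 5
    parsimony_start: bool = True
    maxfun: int = 3000
    gtol: float = 1e-6
    seed: int = 0


@dataclass
class MLFit:
    model: RateModel
    rates: np.ndarray            # one rate per model class
    lnl: float
    converged: bool
    seed: int
    n_starts: int

    @property
    def n_params(self) -> int:
        return self.model.k

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.lnl

    def q_matrix(self) -> QMatrix:
        return self.model.q_matrix(self.rates)

    def pair_rates(self) -> np.ndarray:
        return self.model.pair_rates(self.rates)

    def to_dict(self) -> dict:
        return {
            "scheme": self.model.scheme,
            "k": self.n_params,
            "lnL": self.lnl,
            "AIC": self.aic,
            "converged": self.converged,
            "rates": {lab: rate for lab, rate in
                      zip(PAIR_LABELS, self.pair_rates())},
        }


def _parsimony_rate(tree: PhyloTree, traits: TraitData) -> float:
    from .parsignal import min_transitions  # local import: avoid cycle

    changes = max(min_transitions(tree, traits), 1)
    total = max(tree.total_length(), 1e-12)
    return changes / total


def fit_model(tree: PhyloTree, traits: TraitData, model: RateModel,
              pi: RootPrior | None = None, opts: FitOptions | None = None,
              engine: PruningEngine | None = None,
              extra_starts: list | None = None) -> MLFit:
    """Maximise the pruning likelihood over the model's class rates.

    Bounded multi-start L-BFGS-B on log rates; deterministic given
    ``opts.seed``.  Non-convergence of every start yields a flagged fit,
    not an exception.
    """
    opts = opts or FitOptions()
    pi = pi or RootPrior.uniform(traits.k)
    engine = engine or PruningEngine(tree, traits)
    k = model.k
    if k == 0:
        raise ModelError("model has no free rate classes")
    lo, hi = math.log(opts.bounds[0]), math.log(opts.bounds[1])

    def objective(logr: np.ndarray) -> float:
        lnl = engine.log_likelihood(model.q_matrix(np.exp(logr)), pi)
        return 1e12 if lnl == NEG_INF else -lnl

    rng = np.random.default_rng(opts.seed)
    starts = []
    for s in extra_starts or []:
        s = np.clip(np.asarray(s, dtype=float), *opts.bounds)
        starts.append(np.log(np.broadcast_to(s, (k,)).copy()))
    if opts.parsimony_start:
        r0 = float(np.clip(_parsimony_rate(tree, traits), *opts.bounds))
        starts.append(np.full(k, math.log(r0)))
        # high-rate start: the no-signal (tip-decorrelating) optimum lives
        # in a corner that random central starts rarely reach
        r_hi = float(np.clip(100.0 * r0, *opts.bounds))
        starts.append(np.full(k, math.log(r_hi)))
    for _ in range(opts.n_random_starts):
        # central sub-range: extreme rates are pathological start points
        starts.append(rng.uniform(math.log(1e-3), math.log(10.0), size=k))

    best = None
    converged = False
    for x0 in starts:
        res = minimize(
            objective, x0, method="L-BFGS-B",
            bounds=[(lo, hi)] * k,
            options={"maxfun": opts.maxfun, "gtol": opts.gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    lnl = -float(best.fun)
    if lnl <= -1e11:
        lnl = NEG_INF
        converged = False
    return MLFit(model=model, rates=np.exp(best.x), lnl=lnl,
                 converged=converged, seed=opts.seed, n_starts=len(starts))


@dataclass
class ModelSelection:
    fits: list[MLFit]
    best_index: int
    skipped: list[str] = field(default_factory=list)

    @property
    def best(self) -> MLFit:
        return self.fits[self.best_index]

    def to_dict(self) -> dict:
        return {
            "models": [f.to_dict() for f in self.fits],
            "best": self.best.model.scheme,
            "skipped": self.skipped,
        }

    def to_json(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_tsv(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("scheme\tk\tlnL\tAIC\tconverged\tbest\n")
            for i, f in enumerate(self.fits):
                fh.write(
                    f"{f.model.scheme}\t{f.n_params}\t{f.lnl!r}\t{f.aic!r}"
                    f"\t{int(f.converged)}\t{int(i == self.best_index)}\n"
                )


def select_best(tree: PhyloTree, traits: TraitData, pi: RootPrior | None = None,
                opts: FitOptions | None = None,
                threshold: float = 0.1,
                ard_start: np.ndarray | None = None) -> ModelSelection:
    """Fit the eight-model family and pick the AIC minimiser.

    Candidates: single, symmetric, unconstrained, then reduced-1..5 built
    from the unconstrained fit's rates.  Reduced candidates for which no
    free rate survives the threshold are skipped with a warning.
    """
    opts = opts or FitOptions()
    pi = pi or RootPrior.uniform(traits.k)
    engine = PruningEngine(tree, traits)
    fits: list[MLFit] = []
    skipped: list[str] = []
    def class_means(model: RateModel, pair_rates: np.ndarray) -> list[float]:
        return [
            float(np.mean([pair_rates[i] for i, p in enumerate(PAIRS)
                           if model.assignment[p] == lab]))
            for lab in model.classes
        ]

    def starts_for(model: RateModel, chain: list) -> list:
        out = list(chain)
        if ard_start is not None:
            # floor near-zero seed rates: the low-bound corner is flat and
            # traps L-BFGS-B
            out.append(class_means(model, np.maximum(ard_start, 1e-3)))
        return out

    single = fit_model(tree, traits, build_scheme("single"), pi, opts, engine,
                       extra_starts=starts_for(build_scheme("single"), []))
    fits.append(single)
    # nested starts: richer models start from the simpler optimum too,
    # which keeps lnL monotone in model complexity up to optimizer tolerance
    for name in ("symmetric", "unconstrained"):
        model = build_scheme(name)
        fits.append(fit_model(tree, traits, model, pi, opts, engine,
                              extra_starts=starts_for(model, [single.rates[0]])))
    ard = fits[2].pair_rates()
    # when a cross-estimate is supplied, reduced structures are built from
    # both rate vectors and the better fit kept: the threshold-and-bin step
    # is path-dependent, and this keeps paired comparisons (star vs. tree)
    # about topology rather than about which ARD basin each side found
    sources = [ard] if ard_start is None else [ard, np.asarray(ard_start, dtype=float)]
    for k in range(1, 6):
        candidates = []
        errors = []
        for src in sources:
            try:
                model = reduce_model(src, k, threshold=threshold)
            except ModelError as exc:
                errors.append(exc)
                continue
            candidates.append(
                fit_model(tree, traits, model, pi, opts, engine,
                          extra_starts=starts_for(model, [class_means(model, src)]))
            )
        if not candidates:
            logger.warning("skipping reduced-%d: %s", k, errors[0])
            skipped.append(f"reduced-{k}: {errors[0]}")
            continue
        best_k = min(candidates, key=lambda f: f.aic)
        best_k.model.scheme = f"reduced-{k}"
        fits.append(best_k)
    best_index = min(
        range(len(fits)), key=lambda i: (fits[i].aic, fits[i].n_params)
    )
    return ModelSelection(fits=fits, best_index=best_index, skipped=skipped)


def ml_ancestral(tree: PhyloTree, traits: TraitData, fit: MLFit, taxa,
                 pi: RootPrior | None = None) -> np.ndarray:
    """Marginal state probabilities at the MRCA of *taxa* under the fitted Q."""
    pi = pi or RootPrior.uniform(traits.k)
    node = treeio.mrca(tree, taxa)
    return PruningEngine(tree, traits).node_marginals(fit.q_matrix(), pi, node)
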