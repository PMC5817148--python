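"""Cross-method synthesis of transition-rate estimates.

Rates from each (method, dataset) combination are min-max standardized to
[0, 1], averaged per transition across combinations, and ranked; agreement
between combinations is measured by Spearman rank correlation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .mlfit import N_PAIRS, PAIR_LABELS

logger = logging.getLogger(__name__)


class SummaryError(ValueError):
    pass


def standardize_rates(rates) -> np.ndarray:
    """Min-max standardization to [0, 1]; a constant vector maps to all
    zeros (keeps zero rates at zero)."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise SummaryError("rates must be nonnegative")
    lo, hi = rates.min(), rates.max()
    if hi == lo:
        logger.info("constant rate vector; standardizing to all zeros")
        return np.zeros_like(rates)
    return (rates - lo) / (hi - lo)


def average_standardized(vectors) -> tuple[np.ndarray, np.ndarray]:
    """Per-transition mean and standard error (sd/sqrt(m), sample sd)
    across m standardized vectors."""
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim != 2:
        raise SummaryError("expected a list of equal-length vectors")
    if arr.shape[0] < 2:
        raise SummaryError("need at least 2 vectors to average")
    mean = arr.mean(axis=0)
    se = arr.std(axis=0, ddof=1) / math.sqrt(arr.shape[0])
    return mean, se


def rank_transitions(mean_vector, labels=PAIR_LABELS) -> list[tuple[str, float]]:
    """Transitions sorted by descending mean (ties: lexicographic label)."""
    mean_vector = np.asarray(mean_vector, dtype=float)
    if len(mean_vector) != len(labels):
        raise SummaryError("mean vector length does not match transition labels")
    order = sorted(range(len(labels)), key=lambda i: (-mean_vector[i], labels[i]))
    return [(labels[i], float(mean_vector[i])) for i in order]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; two-sided p
    from the t approximation.  Returns (nan, nan) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise SummaryError("vectors must have equal length")
    if len(x) < 4:
        raise SummaryError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class RateSummary:
    combo_names: list[str]
    standardized: np.ndarray        # (m, 20)
    mean: np.ndarray                # (20,)
    se: np.ndarray                  # (20,)
    ranking: list[tuple[str, float]]
    correlations: np.ndarray        # (m, m) Spearman rho
    correlation_p: np.ndarray       # (m, m)
    tied: bool = False

    @property
    def top4(self) -> list[str]:
        return [lab for lab, _ in self.ranking[:4]]


def summarize_rates(rate_vectors: dict[str, np.ndarray]) -> RateSummary:
    """Standardize, average, rank and cross-correlate per-combination
    20-vectors of transition-rate estimates."""
    names = list(rate_vectors)
    std = np.array([standardize_rates(rate_vectors[n]) for n in names])
    mean, se = average_standardized(std)
    ranking = rank_transitions(mean)
    m = len(names)
    rho = np.eye(m)
    pmat = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            r, p = spearman(std[i], std[j])
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    tied = len({v for _, v in ranking}) < len(ranking)
    return RateSummary(names, std, mean, se, ranking, rho, pmat, tied)


@dataclass
class Report:
    """Aggregated analysis report (signal, Bayes factors, rate summary,
    ancestral states), serializable as JSON and a set of TSVs."""

    signal: list[dict] = field(default_factory=list)
    bayes_factors_by_k: list[dict] = field(default_factory=list)
    rate_summary: dict | None = None
    ancestral: dict[str, dict] = field(default_factory=dict)
    ml_models: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "signal": self.signal,
            "bayes_factors_by_k": self.bayes_factors_by_k,
            "rate_summary": self.rate_summary,
            "ancestral": self.ancestral,
            "ml_models": self.ml_models,
            "notes": self.notes,
        }

    def to_json(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "Report":
        with open(path, "rt", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            signal=d.get("signal", []),
            bayes_factors_by_k=d.get("bayes_factors_by_k", []),
            rate_summary=d.get("rate_summary"),
            ancestral=d.get("ancestral", {}),
            ml_models=d.get("ml_models", []),
            notes=d.get("notes", []),
        )

    # -- TSV tables --------------------------------------------------------

    def write_tables(self, outdir) -> list[str]:
        import os

        written = []

        def table(name, header, rows):
            path = os.path.join(outdir, name)
            with open(path, "wt", encoding="utf-8") as fh:
                fh.write("\t".join(header) + "\n")
                for row in rows:
                    fh.write("\t".join(str(v) for v in row) + "\n")
            written.append(path)

        if self.signal:
            table(
                "signal_table.tsv",
                ["dataset", "min_transitions", "null_median", "p_value", "delta_aic_star", "best_aic", "best_k"],
                [[s.get(c, "NA") for c in
                  ("dataset", "min_transitions", "null_median", "p_value", "delta_aic_star", "best_aic", "best_k")]
                 for s in self.signal],
            )
        if self.bayes_factors_by_k:
            table(
                "bf_by_k.tsv",
                ["run", "k", "ln_BF", "log10_BF", "posterior_fraction", "prior_fraction", "label"],
                [[b.get(c, "NA") for c in
                  ("run", "k", "ln_BF", "log10_BF", "posterior_fraction", "prior_fraction", "label")]
                 for b in self.bayes_factors_by_k],
            )
        if self.rate_summary is not None:
            rs = self.rate_summary
            table(
                "rate_mean_se.tsv",
                ["transition", "mean", "se", "rank", "top4"],
                [[lab, rs["mean"][i], rs["se"][i],
                  1 + [l for l, _ in rs["ranking"]].index(lab),
                  int(lab in rs["top4"])]
                 for i, lab in enumerate(PAIR_LABELS)],
            )
            names = rs["combo_names"]
            corr_rows = []
            for i, n in enumerate(names):
                corr_rows.append([n] + [rs["correlations"][i][j] for j in range(len(names))])
            table("rate_correlations.tsv", ["combo"] + names, corr_rows)
        if self.ancestral:
            rows = []
            for tag in sorted(self.ancestral):
                d = self.ancestral[tag]
                for method in sorted(d):
                    rows.append([tag, method] + list(d[method]))
            table("ancestral_states.tsv",
                  ["clade", "method"] + [f"P({s})" for s in ("CI", "FI", "MK", "O", "PI")],
                  rows)
        if self.ml_models:
            table(
                "ml_models.tsv",
                ["scheme", "k", "lnL", "AIC", "best"],
                [[m.get(c, "NA") for c in ("scheme", "k", "lnL", "AIC", "best")]
                 for m in self.ml_models],
            )
        return written


def build_report(ml_fits=None, bf_tables=None, signal_reports=None,
                 ancestral_estimates=None, rate_vectors=None) -> Report:
    """Assemble the final report from whichever result families exist;
    missing sections are omitted with a note."""
    report = Report()
    if signal_reports:
        for name, s in signal_reports.items():
            report.signal.append({
                "dataset": name,
                "min_transitions": s.observed_min_transitions,
                "null_median": s.null_median,
                "p_value": s.p_value,
                "delta_aic_star": s.delta_aic_star,
            })
    else:
        report.notes.append("no signal reports supplied")
    if ml_fits:
        for name, sel in ml_fits.items():
            for i, f in enumerate(sel.fits):
                report.ml_models.append({
                    "dataset": name, "scheme": f.model.scheme, "k": f.n_params,
                    "lnL": f.lnl, "AIC": f.aic, "best": int(i == sel.best_index),
                })
            for s in report.signal:
                if s["dataset"] == name:
                    s["best_aic"] = sel.best.aic
                    s["best_k"] = sel.best.n_params
    else:
        report.notes.append("no maximum-likelihood fits supplied")
    if bf_tables:
        for run, table in bf_tables.items():
            for row in table.classes:
                report.bayes_factors_by_k.append({
                    "run": run, "k": row.item, "ln_BF": row.ln_bf,
                    "log10_BF": row.log10_bf,
                    "posterior_fraction": row.posterior_fraction,
                    "prior_fraction": row.prior_fraction, "label": row.label,
                })
    else:
        report.notes.append("no Bayes-factor tables supplied")
    if ancestral_estimates:
        for tag, methods in ancestral_estimates.items():
            report.ancestral[tag] = {
                m: [float(x) for x in vec] for m, vec in methods.items()
            }
    else:
        report.notes.append("no ancestral estimates supplied")
    if rate_vectors and len(rate_vectors) >= 2:
        rs = summarize_rates(rate_vectors)
        report.rate_summary = {
            "combo_names": rs.combo_names,
            "standardized": rs.standardized.tolist(),
            "mean": rs.mean.tolist(),
            "se": rs.se.tolist(),
            "ranking": [[lab, v] for lab, v in rs.ranking],
            "top4": rs.top4,
            "correlations": rs.correlations.tolist(),
            "correlation_p": rs.correlation_p.tolist(),
            "tied": rs.tied,
        }
    else:
        report.notes.append("fewer than two rate vectors; no cross-method summary")
    return report
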