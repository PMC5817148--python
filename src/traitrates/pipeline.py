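"""End-to-end orchestration and command-line interface.

``run_all`` executes the full workflow — ML model selection, the two
phylogenetic-signal tests, one reversible-jump chain per configured prior
mean with a matched prior-only companion, ancestral states for each
tagged clade, and the cross-method rate summary — writing every artifact
plus a manifest into the output directory.  Desk-scale settings are the
defaults; production-scale settings are plain configuration.

Outputs are deterministic for fixed seeds: no timestamps, sorted JSON
keys, repr-formatted floats.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

import click
import numpy as np
import yaml

from . import __version__, mlfit, parsignal, rjmcmc, summarize, synthdata, treeio
from .mklik import RootPrior
from .treeio import TraitData

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    # data: either files or a synthetic scenario
    tree_file: str | None = None
    trait_file: str | None = None
    scenario: str | None = "small"           # used when tree_file is None
    # root prior: "uniform" or "stationary"
    root_prior: str = "uniform"
    # ML options
    ml_n_random_starts: int = 3
    ml_maxfun: int = 1500
    ml_threshold: float = 0.1
    # signal options
    n_permutations: int = 10000
    # MCMC options
    prior_means: tuple = (100.0,)
    n_generations: int = 10**6
    sample_freq: int = 500
    burn_in_frac: float = 0.1
    # clade tags: name -> list of taxa; scenario tags used when empty
    clade_tags: dict = dataclasses.field(default_factory=dict)
    seed: int = 0
    outdir: str = "traitrates_out"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) if str(path).endswith((".yml", ".yaml")) else json.load(fh)
        cfg = cls(**raw)
        cfg.prior_means = tuple(float(m) for m in cfg.prior_means)
        return cfg

    def validate(self) -> None:
        if self.tree_file is not None:
            if not os.path.exists(self.tree_file):
                raise FileNotFoundError(self.tree_file)
            if self.trait_file is None or not os.path.exists(self.trait_file):
                raise FileNotFoundError(self.trait_file or "<trait_file unset>")
        elif self.scenario not in ("small", "large"):
            raise ValueError("scenario must be 'small' or 'large' when no tree file is given")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(cfg: RunConfig):
    if cfg.tree_file is not None:
        trees = treeio.read_newick_file(cfg.tree_file)
        traits = treeio.read_trait_table(cfg.trait_file)
        tags = {k: set(v) for k, v in cfg.clade_tags.items()}
        return trees, traits, tags, None
    scenario = synthdata.wolbachia_like_scenario(cfg.scenario, seed=cfg.seed)
    return [scenario.tree], scenario.traits, dict(scenario.tags), scenario


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; failures are recorded in the manifest and later
    independent stages still run.  Returns the manifest dict."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "stages": {},
        "files": {},
    }
    outputs: list[str] = []

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
                manifest["stages"][name] = {"status": "ok"}
            except Exception as exc:
                logger.exception("stage %s failed", name)
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            logger.info("stage %s: %.1fs", name, time.perf_counter() - t0)

        return deco

    trees, traits, tags, scenario = _load_inputs(cfg)
    tree = trees[0]
    pi = (RootPrior.uniform(traits.k) if cfg.root_prior == "uniform"
          else RootPrior.stationary(mlfit.build_scheme("single").q_matrix([1.0])))
    opts = mlfit.FitOptions(n_random_starts=cfg.ml_n_random_starts,
                            maxfun=cfg.ml_maxfun, seed=cfg.seed)

    results: dict = {"selection": None, "signal": None, "traces": {},
                     "bf": {}, "ancestral": {}, "rate_vectors": {}}

    @stage("emit-inputs")
    def _():
        if scenario is not None:
            paths = scenario.emit(cfg.outdir)
            outputs.extend(paths.values())
        else:
            treeio.write_newick_file(trees, os.path.join(cfg.outdir, "tree.nwk"))
            treeio.write_trait_table(traits, os.path.join(cfg.outdir, "traits.tsv"))
            outputs.extend([os.path.join(cfg.outdir, "tree.nwk"),
                            os.path.join(cfg.outdir, "traits.tsv")])

    @stage("fit-ml")
    def _():
        sel = mlfit.select_best(tree, traits, pi, opts, threshold=cfg.ml_threshold)
        results["selection"] = sel
        sel.to_json(os.path.join(cfg.outdir, "ml_fit.json"))
        sel.to_tsv(os.path.join(cfg.outdir, "ml_fit.tsv"))
        outputs.extend([os.path.join(cfg.outdir, "ml_fit.json"),
                        os.path.join(cfg.outdir, "ml_fit.tsv")])
        results["rate_vectors"]["ml"] = sel.best.pair_rates()

    @stage("signal")
    def _():
        report = parsignal.permutation_test(tree, traits, cfg.n_permutations, seed=cfg.seed)
        report.delta_aic_star = parsignal.star_tree_delta_aic(
            tree, traits, pi, opts, threshold=cfg.ml_threshold)
        results["signal"] = report
        report.to_json(os.path.join(cfg.outdir, "signal.json"))
        report.to_tsv(os.path.join(cfg.outdir, "signal.tsv"))
        outputs.extend([os.path.join(cfg.outdir, "signal.json"),
                        os.path.join(cfg.outdir, "signal.tsv")])

    @stage("mcmc")
    def _():
        for i, mu in enumerate(cfg.prior_means):
            prior = rjmcmc.PriorSpec(mu)
            post = rjmcmc.run_chain(trees, traits, prior, cfg.n_generations,
                                    cfg.sample_freq, seed=cfg.seed + 1000 + i,
                                    pi=pi, burn_in_frac=cfg.burn_in_frac)
            pre = rjmcmc.run_chain(trees, traits, prior, cfg.n_generations,
                                   cfg.sample_freq, seed=cfg.seed + 2000 + i,
                                   prior_only=True, pi=pi,
                                   burn_in_frac=cfg.burn_in_frac)
            tag = f"mu{mu:g}"
            for label, trace in (("posterior", post), ("prior", pre)):
                base = os.path.join(cfg.outdir, f"trace_{tag}_{label}")
                trace.to_tsv(base + ".tsv", base + ".json")
                outputs.extend([base + ".tsv", base + ".json"])
            bf = rjmcmc.bayes_factors(rjmcmc.classify_models(post),
                                      rjmcmc.classify_models(pre))
            bf.to_tsv(os.path.join(cfg.outdir, f"bf_k_{tag}.tsv"), which="classes")
            bf.to_tsv(os.path.join(cfg.outdir, f"bf_models_{tag}.tsv"), which="models")
            outputs.extend([os.path.join(cfg.outdir, f"bf_k_{tag}.tsv"),
                            os.path.join(cfg.outdir, f"bf_models_{tag}.tsv")])
            results["traces"][tag] = post
            results["bf"][tag] = bf
            results["rate_vectors"][f"bayes_{tag}"] = \
                rjmcmc.posterior_rate_means(post).means

    @stage("ancestral")
    def _():
        for tag_name, taxa in sorted(tags.items()):
            methods: dict[str, list] = {}
            if results["selection"] is not None:
                methods["ml"] = list(map(float, mlfit.ml_ancestral(
                    tree, traits, results["selection"].best, taxa, pi)))
            for run_tag, trace in results["traces"].items():
                est = rjmcmc.ancestral_at_mrca(trace, trees, traits, taxa, pi)
                methods[f"bayes_{run_tag}"] = list(map(float, est.probabilities))
            results["ancestral"][tag_name] = methods

    @stage("summarize")
    def _():
        report = summarize.build_report(
            ml_fits={"main": results["selection"]} if results["selection"] else None,
            bf_tables=results["bf"] or None,
            signal_reports={"main": results["signal"]} if results["signal"] else None,
            ancestral_estimates=results["ancestral"] or None,
            rate_vectors=results["rate_vectors"]
            if len(results["rate_vectors"]) >= 2 else None,
        )
        report.to_json(os.path.join(cfg.outdir, "report.json"))
        outputs.append(os.path.join(cfg.outdir, "report.json"))
        outputs.extend(report.write_tables(cfg.outdir))

    for path in outputs:
        manifest["files"][os.path.relpath(path, cfg.outdir)] = _sha256(path)
    with open(os.path.join(cfg.outdir, "manifest.json"), "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Verbose logging.")
@click.option("-q", "--quiet", is_flag=True, help="Errors only.")
def cli(verbose: bool, quiet: bool):
    """Transition-rate analysis of discrete traits on phylogenies."""
    level = logging.DEBUG if verbose else logging.ERROR if quiet else logging.INFO
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@click.option("--variant", type=click.Choice(["small", "large"]), default="small")
@click.option("--seed", type=int, default=0)
@click.option("--out", "outdir", type=click.Path(), required=True)
def simulate(variant, seed, outdir):
    """Generate a synthetic two-clade dataset (tree, traits, truth)."""
    os.makedirs(outdir, exist_ok=True)
    scenario = synthdata.wolbachia_like_scenario(variant, seed=seed)
    paths = scenario.emit(outdir)
    click.echo(json.dumps(paths, indent=2, sort_keys=True))


def _read_data(tree_file, trait_file):
    trees = treeio.read_newick_file(tree_file)
    traits = treeio.read_trait_table(trait_file)
    return trees, traits


@cli.command("fit-ml")
@click.option("--tree", "tree_file", type=click.Path(exists=True), required=True)
@click.option("--traits", "trait_file", type=click.Path(exists=True), required=True)
@click.option("--seed", type=int, default=0)
@click.option("--out", "outdir", type=click.Path(), required=True)
def fit_ml(tree_file, trait_file, seed, outdir):
    """Fit the eight-model family and select by AIC."""
    os.makedirs(outdir, exist_ok=True)
    trees, traits = _read_data(tree_file, trait_file)
    sel = mlfit.select_best(trees[0], traits, opts=mlfit.FitOptions(seed=seed))
    sel.to_json(os.path.join(outdir, "ml_fit.json"))
    sel.to_tsv(os.path.join(outdir, "ml_fit.tsv"))
    click.echo(f"best: {sel.best.model.scheme} (AIC {sel.best.aic:.2f})")


@cli.command()
@click.option("--tree", "tree_file", type=click.Path(exists=True), required=True)
@click.option("--traits", "trait_file", type=click.Path(exists=True), required=True)
@click.option("--n-perm", type=int, default=10000)
@click.option("--star/--no-star", default=True, help="Also run the star-tree AIC comparison.")
@click.option("--seed", type=int, default=0)
@click.option("--out", "outdir", type=click.Path(), required=True)
def signal(tree_file, trait_file, n_perm, star, seed, outdir):
    """Permutation test (and optional star-tree AIC comparison)."""
    os.makedirs(outdir, exist_ok=True)
    trees, traits = _read_data(tree_file, trait_file)
    report = parsignal.permutation_test(trees[0], traits, n_perm, seed=seed)
    if star:
        report.delta_aic_star = parsignal.star_tree_delta_aic(
            trees[0], traits, opts=mlfit.FitOptions(seed=seed))
    report.to_json(os.path.join(outdir, "signal.json"))
    report.to_tsv(os.path.join(outdir, "signal.tsv"))
    click.echo(f"min transitions {report.observed_min_transitions}, p = {report.p_value:g}")


@cli.command()
@click.option("--tree", "tree_file", type=click.Path(exists=True), required=True)
@click.option("--traits", "trait_file", type=click.Path(exists=True), required=True)
@click.option("--mu", type=float, default=100.0, help="Exponential prior mean.")
@click.option("--generations", type=int, default=10**6)
@click.option("--sample-freq", type=int, default=500)
@click.option("--prior-only", is_flag=True)
@click.option("--seed", type=int, default=0)
@click.option("--out", "outdir", type=click.Path(), required=True)
def mcmc(tree_file, trait_file, mu, generations, sample_freq, prior_only, seed, outdir):
    """Run one reversible-jump chain and write its trace."""
    os.makedirs(outdir, exist_ok=True)
    trees, traits = _read_data(tree_file, trait_file)
    trace = rjmcmc.run_chain(trees, traits, rjmcmc.PriorSpec(mu), generations,
                             sample_freq, seed=seed, prior_only=prior_only)
    label = "prior" if prior_only else "posterior"
    base = os.path.join(outdir, f"trace_mu{mu:g}_{label}")
    trace.to_tsv(base + ".tsv", base + ".json")
    click.echo(base + ".tsv")


@cli.command()
@click.option("--tree", "tree_file", type=click.Path(exists=True), required=True)
@click.option("--traits", "trait_file", type=click.Path(exists=True), required=True)
@click.option("--trace", "trace_file", type=click.Path(exists=True), required=True)
@click.option("--trace-meta", type=click.Path(exists=True), required=True)
@click.option("--taxa", required=True, help="Comma-separated leaf names.")
def ancestral(tree_file, trait_file, trace_file, trace_meta, taxa):
    """Bayesian ancestral state probabilities at the MRCA of TAXA."""
    trees, traits = _read_data(tree_file, trait_file)
    trace = rjmcmc.ChainTrace.from_tsv(trace_file, trace_meta)
    est = rjmcmc.ancestral_at_mrca(trace, trees, traits, set(taxa.split(",")))
    for state, p, e in zip(traits.alphabet, est.probabilities, est.mc_error):
        click.echo(f"{state}\t{p:.4f}\t+-{e:.4f}")


@cli.command("summarize")
@click.option("--report", "report_file", type=click.Path(exists=True), required=True)
@click.option("--out", "outdir", type=click.Path(), required=True)
def summarize_cmd(report_file, outdir):
    """Re-emit the TSV tables from a saved JSON report."""
    os.makedirs(outdir, exist_ok=True)
    report = summarize.Report.from_json(report_file)
    for path in report.write_tables(outdir):
        click.echo(path)


@cli.command("run-all")
@click.option("--config", "config_file", type=click.Path(exists=True), default=None,
              help="YAML or JSON RunConfig; defaults applied when omitted.")
@click.option("--seed", type=int, default=None, help="Override the config seed.")
@click.option("--out", "outdir", type=click.Path(), default=None, help="Override the output directory.")
@click.option("--threads", type=int, default=1, show_default=True,
              help="Accepted for interface compatibility; computation is single-threaded.")
def run_all_cmd(config_file, seed, outdir, threads):
    """Execute the full analysis workflow."""
    cfg = RunConfig.from_file(config_file) if config_file else RunConfig()
    if seed is not None:
        cfg.seed = seed
    if outdir is not None:
        cfg.outdir = outdir
    manifest = run_all(cfg)
    failed = [s for s, d in manifest["stages"].items() if d["status"] != "ok"]
    click.echo(json.dumps({s: d["status"] for s, d in manifest["stages"].items()},
                          indent=2, sort_keys=True))
    if failed:
        raise SystemExit(1)


if __name__ == "__main__":  # pragma: no cover
    cli()
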