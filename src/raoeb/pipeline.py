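"""The two-step workflow: screening grids and the end-to-end pipeline.

Step 1 screens model grids with the psi_xi best-fit criterion:

* the archaic grid — 8 replacement-rate (delta) windows crossed with 3
  ancestral-migration regimes, under constant-size modern populations
  and pooled summary statistics;
* the African-expansion grid — 3 onset windows x 5 growth-rate windows,
  scored on the African statistics;
* the bottleneck grid — 5 intensity windows, scored on the two
  non-African populations' statistics.

Step 2 estimates the winning model's parameters by ABC rejection with
local-linear regression adjustment.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import abc as abc_mod
from . import bestfit as bf
from . import coalsim, sumstats
from .demography import ModelVariant
from .io import RunConfig, read_haplotypes
from .priors import PriorSet, default_table2_priors

__all__ = [
    "archaic_grid",
    "expansion_grid",
    "bottleneck_grid",
    "grid_preset",
    "archaic_stat_set",
    "dispersal_stat_set",
    "assignment_experiment",
    "coverage_experiment",
    "pipeline_run",
]

logger = logging.getLogger("raoeb")

DELTA_WINDOWS = {
    "delta=0": 0.0,
    "delta<=0.01": (0.0, 0.01),
    "delta<=0.1": (0.0, 0.1),
    "delta<=0.5": (0.0, 0.5),
    "delta>=0.5": (0.5, 1.0),
    "delta>=0.9": (0.9, 1.0),
    "delta>=0.99": (0.99, 1.0),
    "delta=1": 1.0,
}

ONSET_WINDOWS = {
    "tA<=25k": (0.0, 25000.0),
    "tA_25-50k": (25000.0, 50000.0),
    "tA_50-75k": (50000.0, 75000.0),
}

GROWTH_WINDOWS = {
    "alpha=0": 0.0,
    "alpha<=0.005": (0.0, 0.005),
    "alpha_0.005-0.01": (0.005, 0.01),
    "alpha_0.01-0.015": (0.01, 0.015),
    "alpha_0.015-0.02": (0.015, 0.02),
}

BETA_WINDOWS = {
    "beta=1": 1.0,
    "beta_1-2": (1.0, 2.0),
    "beta_2-20": (2.0, 20.0),
    "beta_20-40": (20.0, 40.0),
    "beta_40-60": (40.0, 60.0),
}


def archaic_screening_priors(base: PriorSet | None = None) -> PriorSet:
    """Stage-1 archaic priors: constant-size modern demes, wide exodus window."""
    base = base or default_table2_priors()
    return base.with_override(
        alpha_A=0.0, alpha_E=0.0, alpha_EA=0.0, beta_OoA=1.0,
        T_OoA=(40000.0, 100000.0))


def archaic_grid(base: PriorSet | None = None
                 ) -> dict[str, tuple[PriorSet, ModelVariant]]:
    """The 24 archaic-replacement models (8 delta windows x 3 m0 regimes)."""
    pri = archaic_screening_priors(base)
    grid = {}
    for dname, dval in DELTA_WINDOWS.items():
        for m0 in ("residual", "equal", "double"):
            grid[f"{dname}|m0_{m0}"] = (
                pri.with_override(delta=dval), ModelVariant("A", m0))
    return grid


def expansion_grid(base: PriorSet | None = None
                   ) -> dict[str, tuple[PriorSet, ModelVariant]]:
    """The 15 African-expansion models (3 onsets x 5 growth windows)."""
    base = base or default_table2_priors()
    grid = {}
    for tname, tval in ONSET_WINDOWS.items():
        for aname, aval in GROWTH_WINDOWS.items():
            grid[f"{tname}|{aname}"] = (
                base.with_override(t_A=tval, alpha_A=aval),
                ModelVariant("A", "residual"))
    return grid


def bottleneck_grid(base: PriorSet | None = None
                    ) -> dict[str, tuple[PriorSet, ModelVariant]]:
    """The 5 out-of-Africa bottleneck-intensity models."""
    base = base or default_table2_priors()
    return {name: (base.with_override(beta_OoA=bval), ModelVariant("A", "residual"))
            for name, bval in BETA_WINDOWS.items()}


def grid_preset(name: str, base: PriorSet | None = None):
    presets = {"fig3A": archaic_grid, "fig3B": expansion_grid,
               "fig3C": bottleneck_grid,
               "archaic": archaic_grid, "expansion": expansion_grid,
               "bottleneck": bottleneck_grid}
    if name not in presets:
        raise ValueError(f"unknown grid preset {name!r}")
    return presets[name](base)


def archaic_stat_set() -> list[str]:
    """Pooled-sample means plus global F_ST (archaic-stage distances)."""
    return [f"pooled_{s}_mean" for s in sumstats.STAT_NAMES] + ["fst_global"]


def expansion_stat_set() -> list[str]:
    return [f"AFR_{s}_mean" for s in sumstats.STAT_NAMES]


def bottleneck_stat_set() -> list[str]:
    return [f"{p}_{s}_mean" for p in ("EUR", "EAS") for s in sumstats.STAT_NAMES]


def dispersal_stat_set() -> list[str]:
    """Pairwise F_ST: the divergence structure separating the dispersal
    topologies (a shared ancestral-Eurasian branch lowers EUR-EAS
    differentiation relative to two independent exoduses)."""
    return ["fst_AFR_EUR", "fst_AFR_EAS", "fst_EUR_EAS"]


GRID_STAT_SETS = {
    "fig3A": archaic_stat_set, "archaic": archaic_stat_set,
    "fig3B": expansion_stat_set, "expansion": expansion_stat_set,
    "fig3C": bottleneck_stat_set, "bottleneck": bottleneck_stat_set,
}


# ---------------------------------------------------------------------------
# validation experiments (model assignment, estimator coverage)
# ---------------------------------------------------------------------------

def scopes_for(stat_set: list[str]) -> tuple[tuple[str, ...], bool, bool]:
    """Scopes, F_ST and pairwise-F_ST requirements of a statistic set."""
    scopes = tuple(dict.fromkeys(
        s.split("_")[0] for s in stat_set
        if s.split("_")[0] in ("AFR", "EUR", "EAS", "pooled")))
    with_fst = any(s.startswith("fst") for s in stat_set)
    pairwise = any(s.startswith("fst_") and s != "fst_global" for s in stat_set)
    return scopes, with_fst, pairwise


def simulate_model_table(model: tuple[PriorSet, ModelVariant], n_sims: int,
                         stat_set: list[str], rng_seed: int,
                         samples=None, n_loci: int = 20,
                         locus_length: int = 1400) -> coalsim.SimulationTable:
    """Reference table for one grid model, restricted to the needed scopes."""
    pri, var = model
    scopes, with_fst, pairwise = scopes_for(stat_set)
    return coalsim.run_batch(pri, var, n_sims, samples=samples,
                             rng_seed=rng_seed, n_loci=n_loci,
                             locus_length=locus_length, scopes=scopes,
                             with_fst=with_fst, fst_pairwise=pairwise)


def assignment_experiment(
    model_a: tuple[PriorSet, ModelVariant],
    model_b: tuple[PriorSet, ModelVariant],
    n_sims: int,
    n_pseudo: int,
    stat_set: list[str],
    rng_seed: int,
    samples=None,
    n_loci: int = 20,
    xi_quantile: float = 0.01,
    table_a: coalsim.SimulationTable | None = None,
    pseudo_a: list | None = None,
) -> float:
    """Fraction of pseudodatasets whose generating model wins on psi.

    Simulates a reference table and ``n_pseudo`` pseudodatasets under
    each model (tables and pseudodatasets for model A may be passed in
    to share them across pairwise comparisons), then assigns every
    pseudodataset to the model with the higher psi_xi.
    """
    if table_a is None:
        table_a = simulate_model_table(model_a, n_sims, stat_set, rng_seed,
                                       samples=samples, n_loci=n_loci)
    table_b = simulate_model_table(model_b, n_sims, stat_set, rng_seed + 1,
                                   samples=samples, n_loci=n_loci)
    if pseudo_a is None:
        pa = simulate_model_table(model_a, n_pseudo, stat_set, rng_seed + 2,
                                  samples=samples, n_loci=n_loci)
        pseudo_a = [row for _, row in pa.df[stat_set].iterrows()]
    pb = simulate_model_table(model_b, n_pseudo, stat_set, rng_seed + 3,
                              samples=samples, n_loci=n_loci)
    pseudo_b = [row for _, row in pb.df[stat_set].iterrows()]
    cfg = bf.DistanceConfig(statistics=stat_set, xi_quantile=xi_quantile)
    return bf.assignment_probability(table_a, table_b, pseudo_a, pseudo_b, cfg)


def coverage_experiment(
    priors: PriorSet,
    variant: ModelVariant | str,
    n_ref: int,
    n_pseudo: int,
    stat_set: list[str],
    rng_seed: int,
    n_accept: int | None = None,
    samples=None,
    n_loci: int = 20,
    params: list[str] | None = None,
    estimators: tuple[str, ...] = ("mean",),
):
    """Simulate reference + pseudodatasets and score the ABC estimators.

    Returns the :class:`~raoeb.abc.AccuracyReport` of re-estimating each
    pseudodataset's known truth with rejection + regression adjustment.
    """
    reference = simulate_model_table((priors, ModelVariant(variant)
                                      if isinstance(variant, str) else variant),
                                     n_ref, stat_set, rng_seed,
                                     samples=samples, n_loci=n_loci)
    pseudo_tab = simulate_model_table((priors, ModelVariant(variant)
                                       if isinstance(variant, str) else variant),
                                      n_pseudo, stat_set, rng_seed + 1,
                                      samples=samples, n_loci=n_loci)
    pseudo = [(row.to_dict(), row[stat_set])
              for _, row in pseudo_tab.df.iterrows()]
    return abc_mod.accuracy_eval(reference, pseudo, {"set": stat_set},
                                 estimators=estimators, params=params,
                                 n_accept=n_accept, priors=priors)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def _load_observed(config: RunConfig):
    if config.fasta:
        ds = read_haplotypes(config.fasta, config.sample_map)
    else:
        from .synthetic_data import make_pseudo_observed

        ds, _ = make_pseudo_observed(rng_seed=config.seed)
    return ds, sumstats.dataset_summary(ds)


def pipeline_run(config: RunConfig, grids: tuple[str, ...] = ("bottleneck",)) -> Path:
    """Run the two-step procedure end to end and write all artifacts.

    Stages (each optional via ``config.stages``): empirical null tests,
    best-fit screening over the configured grids, and ABC estimation
    under the Table-2 priors.  Every stage writes TSV/JSON outputs plus
    a log recording seeds and row counts; any failure halts with the
    stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    samples = coalsim.SampleConfig(config.samples)
    t0 = time.time()
    try:
        logger.info("pipeline start: seed=%s n_sims=%s", config.seed, config.n_sims)
        ds, obs = _load_observed(config)
        obs.values.to_csv(out / "observed_stats.tsv", sep="\t", header=False)

        if "null" in config.stages:
            logger.info("stage null: modes=%s", config.recomb_modes)
            res = sumstats.null_test(
                obs, priors=config.priors, n_sims=max(config.n_sims, 100),
                recomb_modes=config.recomb_modes, rng_seed=config.seed,
                samples=samples, n_loci=config.n_loci,
                locus_length=config.locus_length)
            res.to_csv(out / "null_test.tsv", sep="\t")

        if "bestfit" in config.stages:
            for gname in grids:
                logger.info("stage bestfit: grid=%s", gname)
                grid = grid_preset(gname, config.priors)
                stat_set = GRID_STAT_SETS[gname]()
                tables = {}
                for k, (name, (pri, var)) in enumerate(grid.items()):
                    tables[name] = coalsim.run_batch(
                        pri, var, config.n_sims, samples=samples,
                        rng_seed=config.seed + 1000 + k,
                        n_loci=config.n_loci, locus_length=config.locus_length)
                    logger.info("  model %s: %d rows", name, len(tables[name]))
                cfg = bf.DistanceConfig(statistics=stat_set,
                                        xi_quantile=config.xi_quantile)
                result = bf.compare_models(
                    tables, obs, cfg, rng_seed=config.seed,
                    resample_size=min(10000, config.n_sims))
                result.summary().to_csv(out / f"bestfit_{gname}.tsv", sep="\t")
                with open(out / f"bestfit_{gname}.json", "w") as fh:
                    json.dump({"winners": result.winners, "xi": result.xi,
                               "mean_psi": result.mean_psi.to_dict()}, fh, indent=1)

        if "abc" in config.stages:
            logger.info("stage abc")
            table = coalsim.run_batch(
                config.priors, ModelVariant(config.variant, config.archaic_m0),
                config.n_sims, samples=samples, rng_seed=config.seed + 5000,
                n_loci=config.n_loci, locus_length=config.locus_length,
                checkpoint_path=out / "abc_reference.tsv")
            table.to_tsv(out / "abc_reference.tsv")
            presets = abc_mod.stat_set_presets()
            clean = table.df.dropna(subset=presets["pop_means_sds_fst"])
            n_clean = len(clean)
            n_accept = config.n_accept or max(n_clean // 100, 50)
            n_accept = min(n_accept, n_clean)
            stat_set = ("pop_means_sds_fst"
                        if n_accept > len(presets["pop_means_sds_fst"]) + 1
                        else "pop_means")
            cfg = bf.DistanceConfig(statistics=presets[stat_set])
            acc = abc_mod.reject(table, obs, n_accept, cfg)
            post = abc_mod.regress_adjust(acc, priors=config.priors)
            summary = {}
            for p in post.params:
                point, ci = abc_mod.summarize(post, p, "mean")
                summary[p] = {"point": point, "estimator": "mean",
                              "ci95": list(ci), "n_accept": n_accept,
                              "stat_set": stat_set, "seed": config.seed}
            with open(out / "posterior.json", "w") as fh:
                json.dump(summary, fh, indent=1)
            post.samples.assign(weight=post.weights).to_csv(
                out / "posterior_draws.tsv", sep="\t", index=False)
        logger.info("pipeline done in %.1f s", time.time() - t0)
    except Exception:
        logger.exception("pipeline stage failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
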