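"""Step 1 — best-fit model screening via the psi_xi criterion.

Each candidate model is represented by a table of simulated summary
vectors.  The fit of a model to the observed summary vector is the
proportion ``psi_xi`` of its simulations whose normalised Euclidean
distance to the observation falls below a threshold ``xi``.  Models are
compared by resampling subsets of their simulations, computing ``psi``
per resample, and testing mean-psi differences with Welch t-tests under
a Bonferroni correction over all pairs; every model statistically
indistinguishable from the best one is retained.

The threshold ``xi`` is set to a low quantile (default 1%) of the
distances pooled over all models in a comparison, and the per-statistic
normalisation scales default to the pooled simulation SDs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coalsim import SimulationTable
from .sumstats import SummaryVector

__all__ = [
    "DistanceConfig",
    "ModelFitResult",
    "normalized_distance",
    "psi",
    "compare_models",
    "assignment_probability",
    "pooled_scales",
]


@dataclass
class DistanceConfig:
    """Statistic set, normalisation scales and the xi rule.

    ``statistics`` names the summary-vector entries entering the
    distance; ``scales`` (same order) divides each coordinate.  ``xi``
    may be fixed, else it is derived as the ``xi_quantile`` of the
    pooled distances of a comparison.  ``scale_method`` is ``sd`` or
    ``mad`` when scales are computed from pooled simulations.
    """

    statistics: list[str]
    scales: np.ndarray | None = None
    xi: float | None = None
    xi_quantile: float = 0.01
    scale_method: str = "sd"

    def __post_init__(self) -> None:
        if self.scales is not None:
            self.scales = np.asarray(self.scales, dtype=float)
            if np.any(self.scales <= 0):
                raise ValueError("normalisation scales must be > 0")
        if self.xi is not None and self.xi <= 0:
            raise ValueError("xi must be > 0")


def _stat_matrix(table: SimulationTable | pd.DataFrame, statistics: list[str]) -> np.ndarray:
    df = table.df if isinstance(table, SimulationTable) else table
    missing = [s for s in statistics if s not in df.columns]
    if missing:
        raise ValueError(f"statistics absent from table: {missing}")
    M = df[statistics].to_numpy(dtype=float)
    bad = np.isnan(M).any(axis=1)
    if bad.any():
        import warnings

        warnings.warn(f"dropping {int(bad.sum())} simulated rows with "
                      "undefined statistics")
        M = M[~bad]
    if len(M) == 0:
        raise ValueError("no simulated rows with fully defined statistics")
    return M


def pooled_scales(tables: list, statistics: list[str], method: str = "sd") -> np.ndarray:
    """Per-statistic scale over the pooled simulations of a comparison."""
    M = np.vstack([_stat_matrix(t, statistics) for t in tables])
    if method == "mad":
        s = sps.median_abs_deviation(M, axis=0, scale="normal")
    else:
        s = M.std(axis=0, ddof=1)
    if np.any(s <= 0):
        degenerate = [st for st, v in zip(statistics, s) if v <= 0]
        raise ValueError(f"statistics with zero pooled spread: {degenerate}")
    return s


def _obs_vector(obs, statistics: list[str]) -> np.ndarray:
    if isinstance(obs, SummaryVector):
        v = obs.subset(statistics)
    elif isinstance(obs, pd.Series):
        v = obs[statistics].to_numpy(dtype=float)
    else:
        v = np.asarray(obs, dtype=float)
    if np.isnan(v).any():
        names = [s for s, b in zip(statistics, np.isnan(v)) if b]
        raise ValueError(f"observed statistics undefined: {names}")
    return v


def normalized_distance(sim, obs, config: DistanceConfig) -> np.ndarray:
    """Euclidean norm of (sim - obs) / scales, rowwise for a matrix."""
    if config.scales is None:
        raise ValueError("DistanceConfig.scales not set; use pooled_scales first")
    S = sim if isinstance(sim, np.ndarray) else _stat_matrix(sim, config.statistics)
    o = _obs_vector(obs, config.statistics)
    Z = (np.atleast_2d(S) - o[None, :]) / config.scales[None, :]
    d = np.sqrt((Z ** 2).sum(axis=1))
    return d if np.ndim(S) > 1 else float(d[0])


def psi(distances: np.ndarray, xi: float) -> float:
    """Fraction of distances strictly below the threshold xi."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance list")
    if xi <= 0:
        raise ValueError("xi must be > 0")
    return float(np.mean(d < xi))


@dataclass
class ModelFitResult:
    """Outcome of a multi-model psi comparison."""

    model_names: list[str]
    mean_psi: pd.Series
    psi_per_resample: pd.DataFrame          # (n_resamples, n_models)
    pairwise_p: pd.DataFrame                # raw Welch p-values
    pairwise_p_adjusted: pd.DataFrame       # Bonferroni over pairs
    winners: list[str]
    xi: float = np.nan
    alpha: float = 0.05

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean_psi": self.mean_psi,
            "winner": [m in self.winners for m in self.model_names],
        })


def _resolve_config(tables: list, obs, config: DistanceConfig) -> tuple[DistanceConfig, list[np.ndarray]]:
    cfg = DistanceConfig(
        statistics=list(config.statistics),
        scales=config.scales, xi=config.xi,
        xi_quantile=config.xi_quantile, scale_method=config.scale_method)
    if cfg.scales is None:
        cfg.scales = pooled_scales(tables, cfg.statistics, cfg.scale_method)
    dists = [normalized_distance(t, obs, cfg) for t in tables]
    if cfg.xi is None:
        cfg.xi = float(np.quantile(np.concatenate(dists), cfg.xi_quantile))
        if cfg.xi <= 0:
            cfg.xi = float(np.min([d.min() for d in dists]) + 1e-12)
    return cfg, dists


def compare_models(
    models: dict[str, SimulationTable] | list[SimulationTable],
    obs,
    config: DistanceConfig,
    n_resamples: int = 100,
    resample_size: int = 10000,
    rng_seed: int = 0,
    alpha: float = 0.05,
) -> ModelFitResult:
    """Rank candidate models by mean psi_xi over resampled simulation sets.

    ``xi`` (unless fixed in the config) is the configured quantile of the
    distances pooled over all models.  Each model's psi is recomputed on
    ``n_resamples`` resamples of ``resample_size`` simulations (with
    replacement when a table is smaller); all pairwise Welch t-tests are
    Bonferroni-corrected and the winners are the models that are
    statistically indistinguishable from the highest mean psi.
    """
    if not isinstance(models, dict):
        models = {f"M{i + 1}": t for i, t in enumerate(models)}
    names = list(models)
    cfg, dists = _resolve_config(list(models.values()), obs, config)

    rng = np.random.default_rng(rng_seed)
    psi_rs = np.empty((n_resamples, len(names)))
    for j, d in enumerate(dists):
        replace = len(d) < resample_size
        for r in range(n_resamples):
            idx = rng.choice(len(d), size=min(resample_size, len(d)) if not replace
                             else resample_size, replace=replace)
            psi_rs[r, j] = psi(d[idx], cfg.xi)
    mean_psi = pd.Series(psi_rs.mean(axis=0), index=names)
    if float(mean_psi.max()) == 0.0:
        raise ValueError(
            f"all psi are zero at xi={cfg.xi:.4g}; increase xi_quantile")

    pairs = list(itertools.combinations(range(len(names)), 2))
    n_pairs = len(pairs)
    p_raw = pd.DataFrame(np.nan, index=names, columns=names)
    p_adj = pd.DataFrame(np.nan, index=names, columns=names)
    for i, j in pairs:
        a, b = psi_rs[:, i], psi_rs[:, j]
        if np.allclose(a, b):
            p = 1.0
        else:
            p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        p_b = min(1.0, p * n_pairs)
        p_raw.iloc[i, j] = p_raw.iloc[j, i] = p
        p_adj.iloc[i, j] = p_adj.iloc[j, i] = p_b

    best = mean_psi.idxmax()
    winners = [best] + [
        m for m in names if m != best and p_adj.loc[best, m] >= alpha]
    return ModelFitResult(model_names=names, mean_psi=mean_psi,
                          psi_per_resample=pd.DataFrame(psi_rs, columns=names),
                          pairwise_p=p_raw, pairwise_p_adjusted=p_adj,
                          winners=winners, xi=cfg.xi, alpha=alpha)


def assignment_probability(
    table_a: SimulationTable,
    table_b: SimulationTable,
    pseudo_a: list,
    pseudo_b: list,
    config: DistanceConfig,
) -> float:
    """Fraction of pseudodatasets assigned to their generating model.

    Each pseudodataset (a summary vector simulated under model A or B)
    is assigned to the model with the higher psi against the shared
    reference tables; scales and xi are re-derived per pseudodataset
    because the distances depend on the observation.  Ties count as
    incorrect (conservative).
    """
    correct = 0
    total = 0
    mat_a = _stat_matrix(table_a, config.statistics)
    mat_b = _stat_matrix(table_b, config.statistics)

    def assign(obs) -> int:
        cfg = DistanceConfig(statistics=list(config.statistics),
                             xi=config.xi, xi_quantile=config.xi_quantile,
                             scale_method=config.scale_method)
        pooled = np.vstack([mat_a, mat_b])
        if config.scales is not None:
            cfg.scales = config.scales
        else:
            s = (pooled.std(axis=0, ddof=1) if cfg.scale_method == "sd"
                 else sps.median_abs_deviation(pooled, axis=0, scale="normal"))
            s[s <= 0] = 1.0
            cfg.scales = s
        da = normalized_distance(mat_a, obs, cfg)
        db = normalized_distance(mat_b, obs, cfg)
        xi = cfg.xi if cfg.xi is not None else \
            float(np.quantile(np.concatenate([da, db]), cfg.xi_quantile))
        pa, pb = psi(da, xi), psi(db, xi)
        if pa == pb:
            return 0  # tie: conservative, counts as wrong
        return 1 if pa > pb else -1

    for obs in pseudo_a:
        total += 1
        correct += assign(obs) == 1
    for obs in pseudo_b:
        total += 1
        correct += assign(obs) == -1
    return correct / total
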