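"""Coalescent simulation of multilocus haplotype datasets.

Datasets mirror the study shape: L unlinked noncoding loci (default 20,
1400 bp each) sampled in three continental populations (118 sub-Saharan
African, 47 European and 48 East-Asian diploids).  Ancestry is simulated
with msprime under a resolved :class:`~raoeb.demography.DemographicModel`
and overlaid with finite-site JC69 mutations, so multiply-hit sites keep
all states and are tallied as one segregating column, as they would be
on real sequence data.

``run_batch`` pairs prior draws with summary vectors, the unit of work
of both inference steps.  For throughput its 20 loci share one batched
ancestry call, which requires a single dataset-level recombination rate;
per-locus mutation rates are still drawn independently.
``simulate_dataset`` keeps full per-locus control of both rates.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import pandas as pd
import tskit

from . import sumstats
from .demography import DemographicModel, ModelVariant, build_demography, constant_size_model
from .priors import ParameterDraw, PriorSet, draw_parameters, fit_gamma_prior
from .sumstats import HaplotypeDataset, LocusData, SummaryVector

__all__ = [
    "LocusSpec",
    "SampleConfig",
    "SimulationTable",
    "simulate_dataset",
    "run_batch",
    "simulate_null_reference",
    "RECOMB_MODES",
]

RECOMB_MODES = ("none", "gamma", "fixed_10x")
FIXED_10X_RATE = 1e-7

#: gamma moments (mean, q025, q975) of the null-model effective size
NULL_NE_MOMENTS = (10000.0, 3000.0, 21000.0)


@dataclass(frozen=True)
class LocusSpec:
    """Length and per-generation mutation/recombination rates of one locus."""

    length: int = 1400
    mu: float = 2.5e-8
    rho: float = 1e-8

    def __post_init__(self) -> None:
        if self.length <= 0 or self.mu < 0 or self.rho < 0:
            raise ValueError("need length > 0 and mu, rho >= 0")


@dataclass(frozen=True)
class SampleConfig:
    """Diploid sample counts per population (haplotypes are 2x)."""

    counts: tuple[tuple[str, int], ...] = (("AFR", 118), ("EUR", 47), ("EAS", 48))

    def __post_init__(self) -> None:
        if any(c < 1 for _, c in self.counts):
            raise ValueError("sample counts must be >= 1")

    @property
    def populations(self) -> list[str]:
        return [p for p, _ in self.counts]

    @property
    def n_individuals(self) -> int:
        return sum(c for _, c in self.counts)

    @property
    def n_haplotypes(self) -> int:
        return 2 * self.n_individuals

    def to_msprime(self) -> dict[str, int]:
        # diploid sampling: msprime emits 2 haplotypes per individual
        return dict(self.counts)

    def sample_names(self) -> list[str]:
        return [f"{p}_{i:03d}" for p, c in self.counts for i in range(c)]

    def haplotype_populations(self) -> np.ndarray:
        return np.array([p for p, c in self.counts for _ in range(2 * c)])


def _ts_to_locus(mts: tskit.TreeSequence, length: int,
                 keep_alleles: bool = False) -> LocusData:
    """Convert a mutated tree sequence to a LocusData.

    Allele code 0 is always the site's ancestral state in tskit's
    variant encoding; only sites polymorphic in the sample are kept.
    """
    if mts.num_sites == 0:
        n = mts.num_samples
        return LocusData(length=length, positions=np.empty(0, dtype=int),
                         alleles=np.empty((n, 0), dtype=np.int8),
                         site_alleles=[], ancestral=np.empty(0, dtype=np.int8))
    G = mts.genotype_matrix().astype(np.int8)  # (sites, haplotypes)
    poly = np.array([len(np.unique(col)) > 1 for col in G])
    G = G[poly]
    positions = mts.tables.sites.position.astype(int)[poly]
    if keep_alleles:
        site_alleles = [v.alleles for v, k in zip(mts.variants(), poly) if k]
        site_alleles = [tuple(a for a in al if a is not None) for al in site_alleles]
    else:
        site_alleles = []
    return LocusData(length=length, positions=positions, alleles=G.T.copy(),
                     site_alleles=site_alleles,
                     ancestral=np.zeros(G.shape[0], dtype=np.int8))


def simulate_dataset(
    model: DemographicModel,
    loci: list[LocusSpec],
    samples: SampleConfig | None = None,
    rng_seed: int = 0,
    keep_alleles: bool = True,
) -> HaplotypeDataset:
    """Simulate one haplotype dataset: an independent genealogy per locus.

    Each locus gets a fresh ancestry at its own recombination rate and
    JC69 mutations at its own rate; the ancestral allele is recorded at
    every variant site (known exactly in simulation).  Engine errors are
    re-raised with the locus index and seed for reproducibility.
    """
    samples = samples or SampleConfig()
    rng = np.random.default_rng(rng_seed)
    demog_samples = samples.to_msprime()
    loci_out: list[LocusData] = []
    for i, spec in enumerate(loci):
        seed_anc = int(rng.integers(1, 2 ** 31))
        seed_mut = int(rng.integers(1, 2 ** 31))
        try:
            ts = msprime.sim_ancestry(
                samples=demog_samples, demography=model.demography,
                sequence_length=spec.length, recombination_rate=spec.rho,
                ploidy=2, random_seed=seed_anc)
            mts = msprime.sim_mutations(ts, rate=spec.mu, model=msprime.JC69(),
                                        random_seed=seed_mut)
        except Exception as err:  # pragma: no cover - engine failures
            raise RuntimeError(
                f"simulation failed at locus {i} (seeds {seed_anc}/{seed_mut}): {err}"
            ) from err
        loci_out.append(_ts_to_locus(mts, spec.length, keep_alleles=keep_alleles))
    return HaplotypeDataset(loci=loci_out, samples=samples.sample_names(),
                            populations=samples.haplotype_populations())


def _simulate_summary(
    model: DemographicModel,
    samples: SampleConfig,
    n_loci: int,
    length: int,
    mu_per_locus: np.ndarray,
    rho: float,
    rng: np.random.Generator,
    scopes: tuple[str, ...] | None,
    with_fst: bool,
    fst_pairwise: bool = True,
) -> SummaryVector:
    """Fast path: batched ancestry for all loci of one dataset."""
    reps = msprime.sim_ancestry(
        samples=samples.to_msprime(),
        demography=model.demography, sequence_length=length,
        recombination_rate=rho, ploidy=2,
        random_seed=int(rng.integers(1, 2 ** 31)), num_replicates=n_loci)
    loci = []
    for j, ts in enumerate(reps):
        mts = msprime.sim_mutations(ts, rate=float(mu_per_locus[j]),
                                    model=msprime.JC69(),
                                    random_seed=int(rng.integers(1, 2 ** 31)))
        loci.append(_ts_to_locus(mts, length))
    ds = HaplotypeDataset(loci=loci, samples=samples.sample_names(),
                          populations=samples.haplotype_populations())
    return sumstats.dataset_summary(ds, scopes=scopes, with_fst=with_fst,
                                    fst_pairwise=fst_pairwise)


@dataclass
class SimulationTable:
    """Rows of (parameter draw, summary vector) plus provenance metadata."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    PARAM_COLS = [
        "T_E", "t_A", "alpha_A", "N_prime", "T_OoA", "beta_OoA", "t_E",
        "alpha_E", "t_EA", "alpha_EA", "m", "m0", "delta", "T_EEA", "mu",
        "rho", "T_OoA_2", "N_OoA", "N_A", "N_E", "N_EA",
    ]

    @property
    def param_cols(self) -> list[str]:
        return [c for c in self.PARAM_COLS if c in self.df.columns]

    @property
    def stat_cols(self) -> list[str]:
        return [c for c in self.df.columns if c not in self.PARAM_COLS]

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path) -> None:
        path = Path(path)
        self.df.to_csv(path, sep="\t", index=False)
        with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
            json.dump(self.meta, fh, indent=1, default=str)

    @classmethod
    def from_tsv(cls, path) -> "SimulationTable":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(df=df, meta=meta)


def _priors_digest(priors: PriorSet) -> str:
    buf = _io.StringIO()
    blocks = {name: dataclasses.asdict(s) for name, s in priors.specs.items()}
    json.dump(blocks, buf, sort_keys=True, default=str)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()[:16]


def _draw_for_variant(priors: PriorSet, variant: ModelVariant,
                      rng: np.random.Generator) -> ParameterDraw:
    """One prior draw, handling the two-dispersal exodus-time halves."""
    if variant.tag in ("C", "D"):
        lo, hi = priors.bounds("T_OoA")
        mid = 0.5 * (lo + hi)
        draw = draw_parameters(priors.with_override(T_OoA=(mid, hi)), 1, rng)[0]
        return draw.replace(T_OoA_2=float(rng.uniform(lo, mid)))
    return draw_parameters(priors, 1, rng)[0]


def run_batch(
    priors: PriorSet,
    variant: ModelVariant | str,
    n_sims: int,
    samples: SampleConfig | None = None,
    rng_seed: int = 0,
    n_loci: int = 20,
    locus_length: int = 1400,
    scopes: tuple[str, ...] | None = None,
    with_fst: bool = True,
    fst_pairwise: bool = False,
    checkpoint_path=None,
    checkpoint_every: int = 500,
) -> SimulationTable:
    """Simulate ``n_sims`` datasets under prior draws and summarise each.

    Per row: a fresh parameter draw, a demography, one batched ancestry
    call for the ``n_loci`` loci (sharing the row's recombination rate)
    and per-locus mutation rates drawn from the ``mu`` prior.  Row seeds
    are spawned from the master seed, so any single row can be re-run in
    isolation.  When a checkpoint path is given, completed rows are
    appended there every ``checkpoint_every`` rows and a partial file is
    resumed instead of recomputed.
    """
    if isinstance(variant, str):
        variant = ModelVariant(tag=variant)
    samples = samples or SampleConfig()
    if scopes is None:
        scopes = (*samples.populations, "pooled")
    mu_spec = priors["mu"]

    done: list[pd.DataFrame] = []
    start = 0
    if checkpoint_path is not None and Path(checkpoint_path).exists():
        prev = pd.read_csv(checkpoint_path, sep="\t")
        if len(prev) > 0:
            done.append(prev)
            start = len(prev)

    seed_seqs = np.random.SeedSequence(rng_seed).spawn(n_sims)
    rows: list[pd.Series] = []
    for i in range(start, n_sims):
        rng = np.random.default_rng(seed_seqs[i])
        draw = _draw_for_variant(priors, variant, rng)
        model = build_demography(draw, variant)
        mu = mu_spec.draw(n_loci, rng) if mu_spec.kind != "composite" else \
            np.full(n_loci, draw.mu)
        sv = _simulate_summary(model, samples, n_loci, locus_length, mu,
                               draw.rho, rng, scopes, with_fst, fst_pairwise)
        row = pd.concat([pd.Series(draw.as_dict()), sv.values])
        rows.append(row)
        if checkpoint_path is not None and (
                len(rows) % checkpoint_every == 0 or i == n_sims - 1):
            chunk = pd.DataFrame(rows)
            header = not Path(checkpoint_path).exists()
            chunk.to_csv(checkpoint_path, sep="\t", index=False, mode="a",
                         header=header)
            done.append(chunk)
            rows = []

    frames = done + ([pd.DataFrame(rows)] if rows else [])
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    meta = {
        "variant": variant.tag,
        "archaic_m0": variant.archaic_m0,
        "seed": rng_seed,
        "n_sims": n_sims,
        "n_loci": n_loci,
        "locus_length": locus_length,
        "samples": dict(samples.counts),
        "priors_digest": _priors_digest(priors),
        "engine": f"msprime {msprime.__version__}",
    }
    return SimulationTable(df=df, meta=meta)


def simulate_null_reference(
    n_sims: int = 1000,
    recomb_mode: str = "gamma",
    rng_seed: int = 0,
    samples: SampleConfig | None = None,
    n_loci: int = 20,
    locus_length: int = 1400,
    priors: PriorSet | None = None,
    scopes: tuple[str, ...] | None = None,
    with_fst: bool = False,
    ne_moments: tuple[float, float, float] = NULL_NE_MOMENTS,
) -> pd.DataFrame:
    """Summary-vector table under the constant-population-size null.

    Each replicate draws an independent gamma effective size per
    population (mean ~1e4) and per-locus gamma mutation rates.  The
    recombination treatment is one of ``none`` (rho = 0), ``gamma``
    (drawn from the recombination prior) or ``fixed_10x`` (1e-7, ten
    times the genome-wide expectation).
    """
    if recomb_mode not in RECOMB_MODES:
        raise ValueError(f"recomb_mode must be one of {RECOMB_MODES}")
    samples = samples or SampleConfig()
    mu_gamma = (priors["mu"].fitted_gamma() if priors is not None
                else fit_gamma_prior(2.5e-8, 1.47e-8, 4.03e-8))
    rho_gamma = (priors["rho"].fitted_gamma() if priors is not None
                 else fit_gamma_prior(1e-8, 0.48e-8, 1.43e-8))
    ne_gamma = fit_gamma_prior(*ne_moments)

    seed_seqs = np.random.SeedSequence(rng_seed).spawn(n_sims)
    rows = []
    for i in range(n_sims):
        rng = np.random.default_rng(seed_seqs[i])
        if recomb_mode == "none":
            rho = 0.0
        elif recomb_mode == "fixed_10x":
            rho = FIXED_10X_RATE
        else:
            rho = float(rng.gamma(rho_gamma.shape, rho_gamma.scale))
        mu = rng.gamma(mu_gamma.shape, mu_gamma.scale, size=n_loci)
        # the three populations are independent under the null: one
        # isolated constant-size deme each, with its own gamma size
        blocks: list[list[LocusData]] = []
        for p, n_ind in samples.counts:
            ne = float(rng.gamma(ne_gamma.shape, ne_gamma.scale))
            model = constant_size_model({p: ne})
            reps = msprime.sim_ancestry(
                samples={p: n_ind}, demography=model.demography,
                sequence_length=locus_length, recombination_rate=rho,
                ploidy=2, random_seed=int(rng.integers(1, 2 ** 31)),
                num_replicates=n_loci)
            blocks.append([
                _ts_to_locus(msprime.sim_mutations(
                    ts, rate=float(mu[j]), model=msprime.JC69(),
                    random_seed=int(rng.integers(1, 2 ** 31))), locus_length)
                for j, ts in enumerate(reps)])
        loci = [_stack_population_blocks([b[j] for b in blocks], locus_length)
                for j in range(n_loci)]
        ds = HaplotypeDataset(loci=loci, samples=samples.sample_names(),
                              populations=samples.haplotype_populations())
        sv = sumstats.dataset_summary(ds, scopes=scopes, with_fst=with_fst,
                                      fst_pairwise=False)
        rows.append(sv.values)
    return pd.DataFrame(rows).reset_index(drop=True)


def _stack_population_blocks(blocks: list[LocusData], length: int) -> LocusData:
    """Combine per-population independent simulations of one locus.

    Each population's variants are private to it; the other populations
    carry the ancestral allele (code 0) at those columns.
    """
    n_hap_total = sum(b.n_haplotypes for b in blocks)
    n_sites = sum(b.n_sites for b in blocks)
    alleles = np.zeros((n_hap_total, n_sites), dtype=np.int8)
    positions = []
    row = col = 0
    for b in blocks:
        alleles[row:row + b.n_haplotypes, col:col + b.n_sites] = b.alleles
        positions.append(b.positions)
        row += b.n_haplotypes
        col += b.n_sites
    return LocusData(length=length, positions=np.concatenate(positions),
                     alleles=alleles, site_alleles=[],
                     ancestral=np.zeros(n_sites, dtype=np.int8))
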