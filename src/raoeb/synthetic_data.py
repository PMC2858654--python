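"""Pseudo-observed datasets and deterministic unit-test fixtures.

``make_pseudo_observed`` simulates a dataset with exactly the study
shape — 20 unlinked noncoding loci of ~1.4 kb in 118 sub-Saharan
African, 47 European and 48 East-Asian diploids, with known ancestral
alleles — under the RAOEB model, by default at the co-estimated point
values (60 ky exodus from an ancestral African population of 13,800
with a 5.1-fold bottleneck, Eurasian split 22.5 kya, African expansion
from 27.5 kya at 0.007/generation, migration 1.3e-5).  A truth JSON with
the generating parameters and seed is always written next to generated
files, so accuracy workflows never depend on hidden state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as raoeb_io
from .coalsim import LocusSpec, SampleConfig, simulate_dataset
from .demography import ModelVariant, build_demography
from .priors import ParameterDraw, derive_composites
from .sumstats import HaplotypeDataset, LocusData

__all__ = ["StudyShape", "table3_draw", "make_pseudo_observed", "make_fixture"]


@dataclass(frozen=True)
class StudyShape:
    """Shape of the resequencing panel the generator emulates."""

    n_loci: int = 20
    locus_length: int = 1400
    observed_like: bool = False  # lengths jittered around a ~1330 bp mean
    samples: SampleConfig = field(default_factory=SampleConfig)
    mask_rate: float = 0.0  # optional uniform N-masking of genotypes

    def lengths(self, rng: np.random.Generator | None = None) -> list[int]:
        if not self.observed_like:
            return [self.locus_length] * self.n_loci
        rng = rng or np.random.default_rng(0)
        return [int(x) for x in rng.normal(1330, 180, self.n_loci).clip(800, 2000)]


def table3_draw(mu: float = 2.5e-8, rho: float = 1e-8) -> ParameterDraw:
    """The co-estimated point values as a complete generating truth.

    The Eurasian Neolithic onsets/rates are not reported individually
    (only the composite present-day sizes are), so ``alpha_E`` and
    ``alpha_EA`` are back-solved from N_E = 31,200 and N_EA = 14,500
    with onsets t_E = 12,500 and t_EA = 8,750 years, keeping both rates
    inside their prior boxes.
    """
    n_prime, beta = 13800.0, 5.1
    n_ooa = n_prime / beta
    g = 25.0
    t_e, t_ea = 12500.0, 8750.0
    alpha_e = math.log(31200.0 / n_ooa) * g / t_e
    alpha_ea = math.log(14500.0 / n_ooa) * g / t_ea
    draw = ParameterDraw(
        T_E=1.9e6, t_A=27500.0, alpha_A=0.007, N_prime=n_prime,
        T_OoA=60000.0, beta_OoA=beta, t_E=t_e, alpha_E=alpha_e,
        t_EA=t_ea, alpha_EA=alpha_ea, m=1.3e-5, m0=1.7e-10,
        delta=0.9949, T_EEA=22500.0, mu=mu, rho=rho, generation_time=g)
    return derive_composites(draw)


def make_pseudo_observed(
    params: ParameterDraw | str = "table3",
    variant: ModelVariant | str = "A",
    shape: StudyShape | None = None,
    rng_seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[HaplotypeDataset, dict]:
    """Simulate one pseudo-observed dataset; optionally write it to disk.

    Returns the dataset and its truth record.  With ``out_dir`` set, one
    FASTA per locus (haplotypes ``<sample>_1/_2`` plus an
    ``__ANCESTRAL__`` record), a sample-map TSV and a truth JSON are
    written; identical seeds give byte-identical files.
    """
    shape = shape or StudyShape()
    if isinstance(params, str):
        if params != "table3":
            raise ValueError(f"unknown parameter preset {params!r}")
        params = table3_draw()
    params = derive_composites(params)
    rng = np.random.default_rng(rng_seed)
    model = build_demography(params, variant)
    loci = [LocusSpec(length=length, mu=params.mu, rho=params.rho)
            for length in shape.lengths(rng)]
    ds = simulate_dataset(model, loci, shape.samples,
                          rng_seed=int(rng.integers(1, 2 ** 31)),
                          keep_alleles=True)
    if shape.mask_rate > 0:
        for loc in ds.loci:
            mask = rng.random(loc.alleles.shape) < shape.mask_rate
            loc.alleles[mask] = 4  # N
    truth = {
        "params": params.as_dict(),
        "variant": variant.tag if isinstance(variant, ModelVariant) else variant,
        "seed": rng_seed,
        "shape": {"n_loci": shape.n_loci,
                  "lengths": [l.length for l in loci],
                  "samples": dict(shape.samples.counts)},
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        raoeb_io.write_dataset(ds, out_dir, seed=rng_seed)
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return ds, truth


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

def _locus_from_patterns(patterns: list[str], length: int = 16,
                         ancestral_first: bool = True) -> LocusData:
    H = np.array([[int(c) for c in p] for p in patterns], dtype=np.int8)
    n_sites = H.shape[1]
    positions = np.linspace(2, length - 2, n_sites).astype(int)
    site_alleles = [("A", "T")] * n_sites
    return LocusData(length=length, positions=positions, alleles=H,
                     site_alleles=site_alleles,
                     ancestral=np.zeros(n_sites, dtype=np.int8))


def make_fixture(kind: str, rng_seed: int = 0) -> HaplotypeDataset:
    """Small deterministic datasets for unit tests.

    ``toy4``: the 4-haplotype / 3-site alignment with known statistics
    (S=3, K=4, pi_locus=5/3, D~0.17, Fs~-2.18, H=-2/3).
    ``two_pop_fst``: two populations each fixed for a distinct
    haplotype (F_ST = 1).
    ``constant_null``: a seeded constant-size three-population draw at
    Ne = 1e4, mu = 2.5e-8 and the observed mean length 1330 bp.
    """
    if kind == "toy4":
        loc = _locus_from_patterns(["000", "001", "011", "111"])
        return HaplotypeDataset(loci=[loc], samples=["s1", "s2"],
                                populations=np.array(["P"] * 4))
    if kind == "two_pop_fst":
        loc = _locus_from_patterns(["00", "00", "00", "00",
                                    "11", "11", "11", "11"])
        return HaplotypeDataset(
            loci=[loc], samples=["a1", "a2", "b1", "b2"],
            populations=np.array(["P1"] * 4 + ["P2"] * 4))
    if kind == "constant_null":
        # the null has no shared ancestry across populations: simulate
        # each deme independently and stack the private variants
        from .coalsim import _stack_population_blocks, _ts_to_locus
        from .demography import constant_size_model
        import msprime

        samples = SampleConfig()
        n_loci, length, mu = 20, 1330, 2.5e-8
        rng = np.random.default_rng(rng_seed)
        blocks = []
        for p, n_ind in samples.counts:
            model = constant_size_model({p: 10000.0})
            reps = msprime.sim_ancestry(
                samples={p: n_ind}, demography=model.demography,
                sequence_length=length, ploidy=2,
                random_seed=int(rng.integers(1, 2 ** 31)),
                num_replicates=n_loci)
            blocks.append([
                _ts_to_locus(msprime.sim_mutations(
                    ts, rate=mu, model=msprime.JC69(),
                    random_seed=int(rng.integers(1, 2 ** 31))), length)
                for ts in reps])
        loci = [_stack_population_blocks([b[j] for b in blocks], length)
                for j in range(n_loci)]
        return HaplotypeDataset(loci=loci, samples=samples.sample_names(),
                                populations=samples.haplotype_populations())
    raise ValueError(f"unknown fixture kind {kind!r}")
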