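"""File formats and run configuration.

Sequences travel as per-locus FASTA (haplotype records ``<sample>_1`` /
``<sample>_2`` and an optional ``__ANCESTRAL__`` record), the sample
map as a two-column TSV (``sample<TAB>population``), tables as TSV with
fixed header vocabularies and nested results as JSON — everything
diff-able, no binary formats.  Variant coordinates are 0-based
within-locus alignment columns.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .priors import PriorSet, default_table2_priors
from .sumstats import HaplotypeDataset, LocusData, MISSING_CODE

__all__ = [
    "read_haplotypes",
    "write_dataset",
    "RunConfig",
    "ANCESTRAL_ID",
]

ANCESTRAL_ID = "__ANCESTRAL__"
VALID_CHARS = set("ACGTN-")
BASES = "ACGT"


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _locus_sequences(loc: LocusData, rng: np.random.Generator) -> tuple[list[str], str]:
    """Expand a variant matrix to full sequences plus the ancestral sequence.

    Monomorphic background positions get a reproducible random reference
    base; variant columns use the locus's recorded alleles (or the plain
    base alphabet when the simulation fast path skipped them).
    """
    ref = rng.choice(list(BASES), size=loc.length)
    anc_seq = ref.copy()
    n_hap = loc.n_haplotypes
    seqs = np.tile(ref, (n_hap, 1))
    for j, pos in enumerate(loc.positions):
        alleles = loc.site_alleles[j] if loc.site_alleles else BASES
        codes = loc.alleles[:, j]
        col = np.array([alleles[c] if c < len(alleles) else "N" for c in codes])
        col[codes >= MISSING_CODE] = "N"
        seqs[:, int(pos)] = col
        if loc.ancestral is not None and loc.ancestral[j] < MISSING_CODE:
            anc_seq[int(pos)] = alleles[loc.ancestral[j]]
    return ["".join(s) for s in seqs], "".join(anc_seq)


def write_dataset(dataset: HaplotypeDataset, out_dir, seed: int = 0,
                  prefix: str = "locus") -> list[Path]:
    """Write per-locus FASTA files and the sample map; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    hap_names = [f"{s}_{k}" for s in dataset.samples for k in (1, 2)]
    for i, loc in enumerate(dataset.loci):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        seqs, anc = _locus_sequences(loc, rng)
        records = [SeqRecord(Seq(s), id=name, description="")
                   for name, s in zip(hap_names, seqs)]
        if loc.ancestral is not None:
            records.append(SeqRecord(Seq(anc), id=ANCESTRAL_ID, description=""))
        path = out_dir / f"{prefix}_{i:02d}.fasta"
        SeqIO.write(records, path, "fasta")
        paths.append(path)
    map_path = out_dir / "sample_map.tsv"
    with open(map_path, "w") as fh:
        pops = dataset.populations
        for k, s in enumerate(dataset.samples):
            fh.write(f"{s}\t{pops[2 * k]}\n")
    paths.append(map_path)
    return paths


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _read_sample_map(path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed sample-map line: {line!r}")
            mapping[parts[0]] = parts[1]
    return mapping


def _locus_from_records(records: dict[str, str], samples: list[str],
                        ancestral_seq: str | None) -> LocusData:
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        raise ValueError(f"alignment length mismatch within locus: {sorted(lengths)}")
    length = lengths.pop()
    hap_names = [f"{s}_{k}" for s in samples for k in (1, 2)]
    M = np.array([list(records[h]) for h in hap_names])
    bad = set(M.ravel()) - VALID_CHARS
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    missing = np.isin(M, ["N", "-"])
    poly = []
    for j in range(length):
        col = M[:, j][~missing[:, j]]
        if len(np.unique(col)) > 1:
            poly.append(j)
    positions = np.array(poly, dtype=int)
    n_sites = len(poly)
    alleles = np.zeros((M.shape[0], n_sites), dtype=np.int8)
    site_alleles: list[tuple[str, ...]] = []
    anc_codes = np.full(n_sites, MISSING_CODE, dtype=np.int8) \
        if ancestral_seq is not None else None
    for jj, j in enumerate(positions):
        col = M[:, j]
        obs = [b for b in dict.fromkeys(col) if b in BASES]
        if ancestral_seq is not None and ancestral_seq[j] in BASES:
            anc_base = ancestral_seq[j]
            order = [anc_base] + [b for b in obs if b != anc_base]
            anc_codes[jj] = 0
        else:
            order = obs
        site_alleles.append(tuple(order))
        code_of = {b: c for c, b in enumerate(order)}
        alleles[:, jj] = [code_of.get(b, MISSING_CODE) for b in col]
    return LocusData(length=length, positions=positions, alleles=alleles,
                     site_alleles=site_alleles, ancestral=anc_codes)


def read_haplotypes(fasta_paths, sample_map_path) -> HaplotypeDataset:
    """Load per-locus FASTA alignments into a validated dataset.

    Haplotype records must be named ``<sample>_1`` / ``<sample>_2``;
    every sample must appear in the map with exactly two haplotypes per
    locus; characters outside ``{A,C,G,T,N,-}`` are rejected.  A missing
    ``__ANCESTRAL__`` record simply leaves the derived-allele statistics
    unavailable for that locus.
    """
    mapping = _read_sample_map(sample_map_path)
    samples = list(mapping)
    loci = []
    for path in fasta_paths:
        records: dict[str, str] = {}
        ancestral_seq = None
        per_sample: dict[str, set[int]] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            if rec.id == ANCESTRAL_ID:
                ancestral_seq = seq
                continue
            if "_" not in rec.id:
                raise ValueError(f"{path}: record {rec.id!r} is not <sample>_<1|2>")
            sample, _, idx = rec.id.rpartition("_")
            if not idx.isdigit():
                raise ValueError(f"{path}: record {rec.id!r} is not <sample>_<1|2>")
            if sample not in mapping:
                raise ValueError(f"{path}: sample {sample!r} missing from sample map")
            per_sample.setdefault(sample, set()).add(int(idx))
            records[rec.id] = seq
        for sample, idxs in per_sample.items():
            if idxs != {1, 2}:
                raise ValueError(
                    f"{path}: sample {sample} has {len(idxs)} haplotypes "
                    f"(indices {sorted(idxs)}); expected exactly _1 and _2")
        absent = [s for s in samples if s not in per_sample]
        if absent:
            raise ValueError(f"{path}: samples missing from alignment: {absent}")
        loci.append(_locus_from_records(records, samples, ancestral_seq))
    populations = np.array([mapping[s] for s in samples for _ in (1, 2)])
    return HaplotypeDataset(loci=loci, samples=samples, populations=populations)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated configuration for the two-step pipeline."""

    priors: PriorSet
    variant: str = "A"
    archaic_m0: str = "residual"
    n_sims: int = 1000
    n_accept: int | None = None
    xi_quantile: float = 0.01
    recomb_modes: tuple[str, ...] = ("none",)
    seed: int = 0
    n_loci: int = 20
    locus_length: int = 1400
    samples: tuple[tuple[str, int], ...] = (("AFR", 118), ("EUR", 47), ("EAS", 48))
    fasta: list[str] = field(default_factory=list)
    sample_map: str | None = None
    out_dir: str = "raoeb_out"
    stages: tuple[str, ...] = ("null", "bestfit", "abc")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "seed" not in doc.get("engine", {}):
            raise ValueError("config must set engine.seed explicitly")
        priors_block = doc.get("priors", "table2")
        if priors_block == "table2":
            priors = default_table2_priors()
        else:
            import tempfile

            with tempfile.NamedTemporaryFile("w", suffix=".yaml", delete=False) as tf:
                yaml.safe_dump({"priors": priors_block}, tf)
            priors = PriorSet.from_yaml(tf.name)
        model = doc.get("model", {})
        engine = doc.get("engine", {})
        io_block = doc.get("io", {})
        for p in io_block.get("fasta", []):
            if not Path(p).exists():
                raise ValueError(f"configured path does not exist: {p}")
        sm = io_block.get("sample_map")
        if sm is not None and not Path(sm).exists():
            raise ValueError(f"configured path does not exist: {sm}")
        samples = tuple((k, int(v)) for k, v in
                        doc.get("samples", dict(cls.samples)).items()) \
            if isinstance(doc.get("samples"), dict) else cls.samples
        return cls(
            priors=priors,
            variant=model.get("variant", "A"),
            archaic_m0={"residual": "residual", "equal": "equal",
                        "double": "double"}[model.get("archaic_m0", "residual")],
            n_sims=int(engine.get("n_sims", 1000)),
            n_accept=engine.get("n_accept"),
            xi_quantile=float(engine.get("xi_quantile", 0.01)),
            recomb_modes=tuple(engine.get("recomb_modes", ["none"])),
            seed=int(engine["seed"]),
            n_loci=int(engine.get("n_loci", 20)),
            locus_length=int(engine.get("locus_length", 1400)),
            samples=samples,
            fasta=list(io_block.get("fasta", [])),
            sample_map=sm,
            out_dir=io_block.get("out_dir", "raoeb_out"),
            stages=tuple(doc.get("stages", ["null", "bestfit", "abc"])),
        )

    def as_meta(self) -> dict:
        d = dataclasses.asdict(self)
        d["priors"] = "<PriorSet>"
        return d
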