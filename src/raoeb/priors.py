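"""Prior distributions for the RAOEB demographic model.

The model ("Recent African Origin with Expansion and Bottleneck") is
parameterised by historical times (years before present), exponential
growth rates (per generation), effective population sizes (diploid
individuals), migration rates (proportion of migrants per generation)
and per-site mutation/recombination rates.  Times and onsets are drawn
in years and converted to generations downstream with a generation time
of 25 years.

Three kinds of drawable priors are supported: uniform, log-uniform and
gamma (the gamma parameterised by its mean and 2.5%/97.5% quantiles, as
population-size and rate priors are usually reported).  Composite
parameters (``N_A``, ``N_OoA``, ``N_E``, ``N_EA``) are not drawn: they
are deterministic functions of the drawable parameters and are filled in
by :func:`derive_composites`.  Draws producing a present-day African
size above one billion individuals are rejected and redrawn.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import yaml
from scipy import special, stats

__all__ = [
    "GammaSpec",
    "PriorSpec",
    "PriorSet",
    "ParameterDraw",
    "fit_gamma_prior",
    "derive_composites",
    "draw_parameters",
    "default_table2_priors",
    "N_A_CAP",
]

#: Rejection cap on the present-day sub-Saharan African effective size.
N_A_CAP = 1e9

#: Default generation time in years.
GENERATION_TIME = 25.0

_SHAPE_LO = 0.1
_SHAPE_HI = 1e4


@dataclass(frozen=True)
class GammaSpec:
    """Shape/scale parameterisation of a fitted gamma prior."""

    shape: float
    scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    def quantile(self, q: float) -> float:
        return float(special.gammaincinv(self.shape, q) * self.scale)


def fit_gamma_prior(mean: float, q025: float, q975: float) -> GammaSpec:
    """Fit a gamma distribution from its mean and 2.5% quantile.

    The mean is matched exactly (``scale = mean / shape``) and the shape
    is found by a 1-D root solve so that the 2.5% quantile equals
    ``q025``.  The 97.5% quantile is over-determined by a two-parameter
    family and is treated as a diagnostic only.

    Raises
    ------
    ValueError
        If the inputs do not satisfy ``0 < q025 < mean < q975``, or if no
        shape in ``(0.1, 1e4)`` achieves the requested 2.5% quantile (the
        error message reports the best achievable quantile).
    """
    if not (0 < q025 < mean < q975):
        raise ValueError(
            f"gamma moments must satisfy 0 < q025 < mean < q975, got "
            f"(mean={mean}, q025={q025}, q975={q975})"
        )

    def q025_of(shape: float) -> float:
        return float(special.gammaincinv(shape, 0.025)) * mean / shape

    lo, hi = q025_of(_SHAPE_LO), q025_of(_SHAPE_HI)
    if not (lo <= q025 <= hi):
        best = hi if q025 > hi else lo
        raise ValueError(
            f"no gamma shape in ({_SHAPE_LO}, {_SHAPE_HI}) attains a 2.5% "
            f"quantile of {q025}; best achievable is {best:.6g}"
        )
    from scipy.optimize import brentq

    log_shape = brentq(
        lambda s: q025_of(math.exp(s)) - q025,
        math.log(_SHAPE_LO),
        math.log(_SHAPE_HI),
        xtol=1e-12,
        rtol=1e-14,
    )
    shape = math.exp(log_shape)
    spec = GammaSpec(shape=shape, scale=mean / shape)
    if abs(spec.quantile(0.025) - q025) > 0.02 * q025:
        raise ValueError(
            f"gamma fit for mean={mean} missed q025={q025}: got "
            f"{spec.quantile(0.025):.6g}"
        )
    return spec


@dataclass(frozen=True)
class PriorSpec:
    """Declaration of one parameter's prior."""

    name: str
    kind: str  # uniform | log_uniform | gamma | fixed | composite
    bounds: tuple[float, float] | None = None
    gamma_moments: tuple[float, float, float] | None = None  # (mean, q025, q975)
    value: float | None = None  # for kind == "fixed"
    units: str = ""
    derives_from: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind in ("uniform", "log_uniform"):
            if self.bounds is None or not self.bounds[0] < self.bounds[1]:
                raise ValueError(f"{self.name}: bounded prior needs min < max")
            if self.kind == "log_uniform" and self.bounds[0] <= 0:
                raise ValueError(f"{self.name}: log-uniform needs min > 0")
        elif self.kind == "gamma":
            if self.gamma_moments is None:
                raise ValueError(f"{self.name}: gamma prior needs gamma_moments")
            mean, q025, q975 = self.gamma_moments
            if not (q025 < mean < q975):
                raise ValueError(f"{self.name}: need q025 < mean < q975")
        elif self.kind == "fixed":
            if self.value is None:
                raise ValueError(f"{self.name}: fixed prior needs a value")
        elif self.kind == "composite":
            if self.bounds is not None:
                raise ValueError(f"{self.name}: composite priors have no bounds")
        else:
            raise ValueError(f"{self.name}: unknown prior kind {self.kind!r}")

    def fitted_gamma(self) -> GammaSpec:
        if self.kind != "gamma":
            raise ValueError(f"{self.name} is not a gamma prior")
        return fit_gamma_prior(*self.gamma_moments)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` independent values from this prior."""
        if self.kind == "uniform":
            return rng.uniform(self.bounds[0], self.bounds[1], size=n)
        if self.kind == "log_uniform":
            lo, hi = np.log(self.bounds)
            return np.exp(rng.uniform(lo, hi, size=n))
        if self.kind == "gamma":
            g = self.fitted_gamma()
            x = rng.gamma(g.shape, g.scale, size=n)
            if self.bounds is not None:  # truncation by redraw
                lo, hi = self.bounds
                bad = (x < lo) | (x > hi)
                while bad.any():
                    x[bad] = rng.gamma(g.shape, g.scale, size=int(bad.sum()))
                    bad = (x < lo) | (x > hi)
            return x
        if self.kind == "fixed":
            return np.full(n, float(self.value))
        raise ValueError(f"{self.name}: composite parameters are not drawn")

    def support(self) -> tuple[float, float]:
        """(min, max) of the drawable support; (0, inf) style for gamma."""
        if self.kind in ("uniform", "log_uniform"):
            return self.bounds
        if self.kind == "gamma":
            return self.bounds if self.bounds is not None else (0.0, math.inf)
        if self.kind == "fixed":
            return (self.value, self.value)
        raise ValueError(f"{self.name}: composite has no drawable support")


@dataclass
class ParameterDraw:
    """One realised value for every model parameter.

    Times are years before present; growth rates are per generation;
    sizes are diploid individuals; ``m``/``m0`` are migrant proportions
    per generation; ``mu``/``rho`` are per-site / per-adjacent-bp per
    generation.  ``T_OoA_2`` is only set for the two-dispersal model
    variants C/D, where ``T_OoA`` is the earlier (older) exodus.
    """

    T_E: float
    t_A: float
    alpha_A: float
    N_prime: float
    T_OoA: float
    beta_OoA: float
    t_E: float
    alpha_E: float
    t_EA: float
    alpha_EA: float
    m: float
    m0: float
    delta: float
    T_EEA: float
    mu: float
    rho: float
    generation_time: float = GENERATION_TIME
    T_OoA_2: float | None = None
    # composites, filled by derive_composites
    N_OoA: float | None = None
    N_A: float | None = None
    N_E: float | None = None
    N_EA: float | None = None

    def replace(self, **kwargs) -> "ParameterDraw":
        return dataclasses.replace(self, **kwargs)

    def as_dict(self) -> dict[str, float]:
        d = dataclasses.asdict(self)
        return {k: v for k, v in d.items() if v is not None}


DRAWABLE = [
    "T_E", "t_A", "alpha_A", "N_prime", "T_OoA", "beta_OoA",
    "t_E", "alpha_E", "t_EA", "alpha_EA", "m", "m0", "delta",
    "T_EEA", "mu", "rho",
]
COMPOSITES = ["N_OoA", "N_A", "N_E", "N_EA"]


def derive_composites(draw: ParameterDraw) -> ParameterDraw:
    """Fill in the composite population sizes.

    ``N_OoA = N' / beta_OoA`` (size of the founding Eurasian population,
    the pre/post-exodus size ratio being the bottleneck intensity) and
    each present-day size is the exponential-growth extrapolation from
    its ancestor: ``N_A = N' exp(alpha_A t_A / g)`` and analogously for
    Europe and East Asia growing from ``N_OoA``.
    """
    g = draw.generation_time
    n_ooa = draw.N_prime / draw.beta_OoA
    return draw.replace(
        N_OoA=n_ooa,
        N_A=draw.N_prime * math.exp(draw.alpha_A * draw.t_A / g),
        N_E=n_ooa * math.exp(draw.alpha_E * draw.t_E / g),
        N_EA=n_ooa * math.exp(draw.alpha_EA * draw.t_EA / g),
    )


class PriorSet:
    """An ordered collection of :class:`PriorSpec`, one per parameter."""

    def __init__(self, specs: Iterable[PriorSpec], generation_time: float = GENERATION_TIME):
        self.specs: dict[str, PriorSpec] = {s.name: s for s in specs}
        self.generation_time = float(generation_time)
        missing = [p for p in DRAWABLE if p not in self.specs]
        if missing:
            raise ValueError(f"priors missing for parameters: {missing}")

    def __getitem__(self, name: str) -> PriorSpec:
        return self.specs[name]

    def with_override(self, **overrides: PriorSpec | tuple | float) -> "PriorSet":
        """Return a copy with some priors replaced.

        A tuple value ``(lo, hi)`` replaces the prior with a uniform on
        that range (keeping the original kind for log-uniform priors); a
        scalar pins the parameter to a fixed value.
        """
        specs = dict(self.specs)
        for name, val in overrides.items():
            base = specs[name]
            if isinstance(val, PriorSpec):
                specs[name] = val
            elif isinstance(val, tuple):
                kind = "log_uniform" if base.kind == "log_uniform" else "uniform"
                specs[name] = PriorSpec(name, kind, bounds=(float(val[0]), float(val[1])),
                                        units=base.units)
            else:
                specs[name] = PriorSpec(name, "fixed", value=float(val), units=base.units)
        return PriorSet(specs.values(), self.generation_time)

    def bounds(self, name: str) -> tuple[float, float]:
        return self.specs[name].support()

    # -- serialization ------------------------------------------------
    def to_yaml(self, path) -> None:
        blocks = {}
        for s in self.specs.values():
            b: dict = {"kind": s.kind, "units": s.units}
            if s.bounds is not None:
                b["min"], b["max"] = float(s.bounds[0]), float(s.bounds[1])
            if s.gamma_moments is not None:
                b["mean"], b["q025"], b["q975"] = [float(x) for x in s.gamma_moments]
            if s.value is not None:
                b["value"] = float(s.value)
            if s.derives_from:
                b["derives_from"] = list(s.derives_from)
            blocks[s.name] = b
        doc = {"generation_time": self.generation_time, "priors": blocks}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PriorSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        specs = []
        for name, b in doc["priors"].items():
            bounds = (b["min"], b["max"]) if "min" in b else None
            moments = (b["mean"], b["q025"], b["q975"]) if "mean" in b else None
            specs.append(PriorSpec(
                name, b["kind"], bounds=bounds, gamma_moments=moments,
                value=b.get("value"), units=b.get("units", ""),
                derives_from=tuple(b.get("derives_from", ())),
            ))
        return cls(specs, generation_time=doc.get("generation_time", GENERATION_TIME))


def default_table2_priors() -> PriorSet:
    """Calibrated priors of the best-fit RAOEB model.

    Uniform boxes for event times and growth rates, gamma priors (fitted
    from mean and 95% interval) for the ancestral size and the
    per-locus mutation/recombination rates, log-uniform for the two
    migration rates, and composite declarations for the derived sizes.
    """
    u, g = "years", "per-generation rate"
    specs = [
        PriorSpec("T_E", "uniform", bounds=(1.2e6, 2.5e6), units=u),
        PriorSpec("t_A", "uniform", bounds=(5000, 50000), units=u),
        PriorSpec("alpha_A", "uniform", bounds=(0.002, 0.02), units=g),
        PriorSpec("N_prime", "gamma", gamma_moments=(10000, 3000, 21000),
                  bounds=(500, 40000), units="individuals"),
        PriorSpec("T_OoA", "uniform", bounds=(45020, 87500), units=u),
        PriorSpec("beta_OoA", "uniform", bounds=(1, 30), units="ratio"),
        PriorSpec("t_E", "uniform", bounds=(5000, 12500), units=u),
        PriorSpec("alpha_E", "uniform", bounds=(0.0001, 0.005), units=g),
        PriorSpec("t_EA", "uniform", bounds=(5000, 12500), units=u),
        PriorSpec("alpha_EA", "uniform", bounds=(0.0001, 0.005), units=g),
        PriorSpec("m", "log_uniform", bounds=(1e-6, 4e-3), units="proportion"),
        PriorSpec("m0", "log_uniform", bounds=(1e-11, 4e-9), units="proportion"),
        PriorSpec("delta", "uniform", bounds=(0.99, 1.0), units="proportion"),
        PriorSpec("T_EEA", "uniform", bounds=(12520, 37500), units=u),
        PriorSpec("mu", "gamma", gamma_moments=(2.5e-8, 1.47e-8, 4.03e-8),
                  units="per-site rate"),
        PriorSpec("rho", "gamma", gamma_moments=(1e-8, 0.48e-8, 1.43e-8),
                  units="per-site rate"),
        PriorSpec("N_OoA", "composite", derives_from=("N_prime", "beta_OoA")),
        PriorSpec("N_A", "composite", derives_from=("N_prime", "alpha_A", "t_A")),
        PriorSpec("N_E", "composite", derives_from=("N_OoA", "alpha_E", "t_E")),
        PriorSpec("N_EA", "composite", derives_from=("N_OoA", "alpha_EA", "t_EA")),
    ]
    return PriorSet(specs)


def draw_parameters(
    priors: PriorSet,
    n: int,
    rng_seed: int | np.random.Generator,
    min_acceptance: float = 1e-3,
) -> list[ParameterDraw]:
    """Draw ``n`` accepted parameter vectors from the priors.

    Draws whose composite African size exceeds ``N_A_CAP`` (one billion
    individuals) are rejected and redrawn.  If the acceptance rate falls
    below ``min_acceptance`` the draw aborts, naming the priors involved
    in the cap.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    g = priors.generation_time
    accepted: list[ParameterDraw] = []
    attempts = 0
    while len(accepted) < n:
        chunk = max(n - len(accepted), 64)
        cols = {p: priors[p].draw(chunk, rng) for p in DRAWABLE}
        attempts += chunk
        n_a = cols["N_prime"] * np.exp(cols["alpha_A"] * cols["t_A"] / g)
        ok = n_a <= N_A_CAP
        for i in np.nonzero(ok)[0]:
            if len(accepted) >= n:
                break
            d = ParameterDraw(**{p: float(cols[p][i]) for p in DRAWABLE},
                              generation_time=g)
            accepted.append(derive_composites(d))
        if attempts >= max(2000, 10 * n) and len(accepted) / attempts < min_acceptance:
            raise RuntimeError(
                "prior acceptance rate below "
                f"{min_acceptance} ({len(accepted)}/{attempts}); the "
                "N_A <= 1e9 cap rejects nearly all combinations of the "
                "N_prime, alpha_A and t_A priors"
            )
    return accepted


def rejection_rate(priors: PriorSet, n_probe: int = 10000, rng_seed: int = 0) -> float:
    """Monte-Carlo estimate of the fraction of raw draws rejected by the cap."""
    rng = np.random.default_rng(rng_seed)
    g = priors.generation_time
    n_a = (priors["N_prime"].draw(n_probe, rng)
           * np.exp(priors["alpha_A"].draw(n_probe, rng)
                    * priors["t_A"].draw(n_probe, rng) / g))
    return float(np.mean(n_a > N_A_CAP))
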