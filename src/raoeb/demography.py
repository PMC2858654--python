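"""Demographic event graphs for the RAOEB model and its variants.

Backward in time, the canonical single-dispersal model (variant A) is:
present-day AFR, EUR and EAS demes grow exponentially back to their
onset times; EUR and EAS sit at the post-exodus founding size ``N_OoA``
until they merge into a transient ancestral-Eurasian deme; at the
out-of-Africa exodus the ancestral Eurasians trace back to modern
Africans with probability ``delta`` and to an archaic non-African deme
with probability ``1 - delta``; the archaic deme (constant size ``N'``)
itself split from Africa deep in the past.  Symmetric migration at rate
``m`` connects the modern demes after the exodus, and at the residual
rate ``m0`` connects Africa with the archaic deme before it.

Variants B-D replace the single dispersal by two independent exoduses
(concomitant, or at different times with Europe or East Asia leaving
first), each applying the same bottleneck ratio and replacement rate.

All sizes are diploid individuals and all event times are generations
before present; the builder converts the draw's year-denominated times
with its generation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .priors import ParameterDraw, derive_composites

__all__ = [
    "ModelVariant",
    "DemographicModel",
    "build_demography",
    "constant_size_model",
    "VARIANTS",
]

POPS = ("AFR", "EUR", "EAS")

VARIANTS = {
    "A": "single dispersal, Eurasian split after the exodus",
    "B": "two concomitant dispersals",
    "C": "two dispersals, the earlier seeding Europe",
    "D": "two dispersals, the earlier seeding East Asia",
}

ARCHAIC_M0 = ("residual", "equal", "double")


@dataclass(frozen=True)
class ModelVariant:
    """Dispersal topology plus the ancestral (archaic) migration regime.

    ``archaic_m0`` selects how the pre-exodus migration rate relates to
    the modern rate: ``residual`` uses the draw's ``m0`` (~1e-10 prior),
    ``equal`` uses ``m`` and ``double`` uses ``2m``.
    """

    tag: str = "A"
    archaic_m0: str = "residual"

    def __post_init__(self) -> None:
        if self.tag not in VARIANTS:
            raise ValueError(f"unknown model variant {self.tag!r}")
        if self.archaic_m0 not in ARCHAIC_M0:
            raise ValueError(f"unknown archaic migration config {self.archaic_m0!r}")


@dataclass
class DemographicModel:
    """A resolved demography: msprime backend object plus metadata."""

    demography: msprime.Demography
    variant: ModelVariant | None
    draw: ParameterDraw | None
    sampled_demes: tuple[str, ...] = POPS

    def describe(self) -> pd.DataFrame:
        """Event table (time in generations, description) for inspection."""
        rows = [
            {"time_gen": ev.time, "event": type(ev).__name__,
             "details": str(ev)}
            for ev in self.demography.events
        ]
        return pd.DataFrame(rows)

    def debug(self) -> msprime.DemographyDebugger:
        return self.demography.debug()


def _archaic_rate(draw: ParameterDraw, variant: ModelVariant) -> float:
    if variant.archaic_m0 == "residual":
        return draw.m0
    if variant.archaic_m0 == "equal":
        return draw.m
    return 2.0 * draw.m


def build_demography(draw: ParameterDraw, variant: ModelVariant | str = "A") -> DemographicModel:
    """Translate a parameter draw into an explicit msprime demography.

    The draw must have its composite sizes filled (see
    :func:`raoeb.priors.derive_composites`); if not, they are derived
    here.  Raises ``ValueError`` when the chronological ordering of the
    split/merge events is violated after unit conversion.
    """
    if isinstance(variant, str):
        variant = ModelVariant(tag=variant)
    if draw.N_A is None:
        draw = derive_composites(draw)
    g = draw.generation_time
    t_ooa = draw.T_OoA / g
    t_eea = draw.T_EEA / g
    t_e_archaic = draw.T_E / g
    onset_a, onset_e, onset_ea = draw.t_A / g, draw.t_E / g, draw.t_EA / g
    m0 = _archaic_rate(draw, variant)

    if variant.tag == "A" and not (t_e_archaic > t_ooa > t_eea > max(onset_e, onset_ea)):
        raise ValueError(
            "event ordering violated: need T_E > T_OoA > T_EEA > max(t_E, t_EA) "
            f"in generations, got ({t_e_archaic:.1f}, {t_ooa:.1f}, {t_eea:.1f}, "
            f"{max(onset_e, onset_ea):.1f})"
        )

    d = msprime.Demography()
    # AFR is the ancestral deme of the deep archaic split, which would
    # make msprime deactivate it at time 0 unless told otherwise.
    d.add_population(name="AFR", initial_size=draw.N_A, growth_rate=draw.alpha_A,
                     initially_active=True)
    d.add_population(name="EUR", initial_size=draw.N_E, growth_rate=draw.alpha_E)
    d.add_population(name="EAS", initial_size=draw.N_EA, growth_rate=draw.alpha_EA)
    d.add_population(name="ARCHAIC", initial_size=draw.N_prime)

    d.set_symmetric_migration_rate(["AFR", "EUR", "EAS"], draw.m)
    # growth phases end (backward) at their onsets
    d.add_population_parameters_change(time=onset_a, population="AFR",
                                       initial_size=draw.N_prime, growth_rate=0)
    d.add_population_parameters_change(time=onset_e, population="EUR",
                                       initial_size=draw.N_OoA, growth_rate=0)
    d.add_population_parameters_change(time=onset_ea, population="EAS",
                                       initial_size=draw.N_OoA, growth_rate=0)

    def absorb(pop: str, time: float) -> None:
        """Move `pop`'s lineages into AFR (prob delta) / ARCHAIC (1-delta).

        A population split zeroes the vanished deme's migration rates
        automatically but an admixture event does not, so they are
        zeroed explicitly first (otherwise lineages could migrate into
        the deactivated deme).
        """
        if draw.delta >= 1.0:
            d.add_population_split(time=time, derived=[pop], ancestral="AFR")
        else:
            present = {p.name for p in d.populations}
            for other in ("AFR", "EUR", "EAS", "ANC_EURASIA"):
                if other != pop and other in present:
                    d.add_symmetric_migration_rate_change(
                        time=time, populations=[pop, other], rate=0)
            d.add_admixture(time=time, derived=pop, ancestral=["AFR", "ARCHAIC"],
                            proportions=[draw.delta, 1.0 - draw.delta])

    if variant.tag == "A":
        d.add_population(name="ANC_EURASIA", initial_size=draw.N_OoA,
                         initially_active=False)
        d.add_population_split(time=t_eea, derived=["EUR", "EAS"],
                               ancestral="ANC_EURASIA")
        d.add_symmetric_migration_rate_change(time=t_eea,
                                              populations=["AFR", "ANC_EURASIA"],
                                              rate=draw.m)
        absorb("ANC_EURASIA", t_ooa)
        first_exodus = t_ooa
    elif variant.tag == "B":
        absorb("EUR", t_ooa)
        absorb("EAS", t_ooa)
        first_exodus = t_ooa
    else:
        if draw.T_OoA_2 is None:
            raise ValueError(f"variant {variant.tag} needs T_OoA_2 (second exodus time)")
        t_ooa2 = draw.T_OoA_2 / g
        early, late = ("EUR", "EAS") if variant.tag == "C" else ("EAS", "EUR")
        if not t_ooa > t_ooa2:
            raise ValueError(
                f"event ordering violated: first exodus ({t_ooa:.1f} gen) must "
                f"predate the second ({t_ooa2:.1f} gen)"
            )
        absorb(late, t_ooa2)
        absorb(early, t_ooa)
        first_exodus = t_ooa

    # archaic gene flow between the exodus and the deep split
    d.add_symmetric_migration_rate_change(time=first_exodus,
                                          populations=["AFR", "ARCHAIC"], rate=m0)
    d.add_symmetric_migration_rate_change(time=t_e_archaic,
                                          populations=["AFR", "ARCHAIC"], rate=0)
    d.add_population_split(time=t_e_archaic, derived=["ARCHAIC"], ancestral="AFR")
    d.sort_events()
    return DemographicModel(demography=d, variant=variant, draw=draw)


def constant_size_model(sizes: dict[str, float] | float) -> DemographicModel:
    """Null model: isolated constant-size demes, no events, no migration.

    ``sizes`` maps deme names to diploid effective sizes; a scalar gives
    all three continental demes the same size.
    """
    if np.isscalar(sizes):
        sizes = {p: float(sizes) for p in POPS}
    d = msprime.Demography()
    for name, ne in sizes.items():
        if ne <= 0:
            raise ValueError(f"deme {name} has non-positive size {ne}")
        d.add_population(name=name, initial_size=float(ne))
    return DemographicModel(demography=d, variant=None, draw=None,
                            sampled_demes=tuple(sizes))
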