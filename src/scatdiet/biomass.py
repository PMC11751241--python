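"""Linear biomass correction: convert occurrence frequencies to relative
biomass consumed.

Hair abundance makes small prey over-counted in scats, so occurrence
frequencies are weighted by a feeding-trial regression Y = a + b·X, where X
is the prey's mean body mass (kg) and Y the mass of prey represented by one
scat's worth of remains. The felid and canid defaults are the published
regressions used for snow leopards and wolves respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

from .composition import DietProfile, origin_aggregate
from .records import FrequencyTable, PreySpecies

__all__ = [
    "BiomassCorrectionModel",
    "BiomassProfile",
    "FELID_CORRECTION",
    "CANID_CORRECTION",
    "DEFAULT_CORRECTIONS",
    "correction_factor",
    "relative_biomass",
    "origin_biomass_aggregate",
]


@dataclass(frozen=True)
class BiomassCorrectionModel:
    predator: str
    intercept: float
    slope: float


FELID_CORRECTION = BiomassCorrectionModel("snow_leopard", 1.980, 0.035)
CANID_CORRECTION = BiomassCorrectionModel("wolf", 0.439, 0.008)
DEFAULT_CORRECTIONS = {
    "snow_leopard": FELID_CORRECTION,
    "wolf": CANID_CORRECTION,
}


@dataclass
class BiomassProfile:
    """Per-prey share of total consumed biomass, in percent (sums to 100)."""

    predator: str
    relative_biomass: dict[str, float]

    def as_diet_profile(self) -> DietProfile:
        return DietProfile.from_values(
            self.predator, "biomass", dict(self.relative_biomass)
        )


def correction_factor(model: BiomassCorrectionModel, mass: float) -> float:
    """Y = intercept + slope × mass. Mass 0 is allowed (testing only)."""
    if mass < 0:
        raise ValueError("prey mass must be non-negative")
    return model.intercept + model.slope * mass


def relative_biomass(
    freq: FrequencyTable | dict[str, float],
    model: BiomassCorrectionModel,
    registry: dict[str, PreySpecies],
) -> BiomassProfile:
    """RB_i = 100 · FO_i·Y_i / Σ_j FO_j·Y_j.

    ``freq`` may be a :class:`FrequencyTable` or a plain prey→FO map; the
    result is invariant to rescaling FO, so raw counts and percentages are
    interchangeable.
    """
    if isinstance(freq, FrequencyTable):
        predator, fo = freq.predator, dict(freq.occurrence_counts)
    else:
        predator, fo = model.predator, dict(freq)
    weighted: dict[str, float] = {}
    for prey, f in fo.items():
        if prey not in registry or registry[prey].mean_mass is None:
            raise ValueError(f"no mean mass for prey {prey!r}")
        y = correction_factor(model, registry[prey].mean_mass)
        if y <= 0:
            raise ValueError(
                f"correction factor non-positive for {prey!r} (Y={y})"
            )
        weighted[prey] = f * y
    total = sum(weighted.values())
    if total <= 0:
        raise ValueError("all frequency values are zero")
    return BiomassProfile(
        predator, {p: 100.0 * w / total for p, w in weighted.items()}
    )


def origin_biomass_aggregate(
    profile: BiomassProfile, registry: dict[str, PreySpecies] | dict[str, str]
) -> tuple[float, float]:
    """Split a biomass profile into (wild %, domestic %)."""
    return origin_aggregate(profile.as_diet_profile(), registry)
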