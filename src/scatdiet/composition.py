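"""Diet-composition summaries: RFO profiles, wild/domestic aggregates,
scat-level composition, and prey-accumulation (sample-sufficiency) curves."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import (
    FrequencyTable,
    PreySpecies,
    ScatDataset,
    load_study_profiles,
    occurrence_counts,
)

__all__ = [
    "DietProfile",
    "CompositionSummary",
    "rfo_profile",
    "origin_aggregate",
    "scat_level_summary",
    "accumulation_curve",
    "study_profile",
]

_SUM_TOL = 1e-9


@dataclass
class DietProfile:
    """Per-predator prey proportions on a stated basis (``rfo`` or ``biomass``).

    Proportions are stored normalized (sum to 1); use :meth:`as_percent`
    for reporting.
    """

    predator: str
    basis: str
    proportions: dict[str, float]

    def __post_init__(self) -> None:
        if self.basis not in ("rfo", "biomass"):
            raise ValueError(f"basis must be 'rfo' or 'biomass', got {self.basis!r}")
        if any(v < 0 for v in self.proportions.values()):
            raise ValueError("proportions must be non-negative")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"proportions sum to {total}, expected 1")

    @classmethod
    def from_values(
        cls, predator: str, basis: str, values: dict[str, float]
    ) -> "DietProfile":
        """Build a profile from unnormalized non-negative values (counts or %)."""
        total = sum(values.values())
        if total <= 0:
            raise ValueError("profile values sum to zero")
        return cls(predator, basis, {k: v / total for k, v in values.items()})

    def as_percent(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in self.proportions.items()}

    def vector(self, prey_order: list[str]) -> np.ndarray:
        """Proportions aligned to ``prey_order`` (absent species → 0)."""
        return np.array([self.proportions.get(p, 0.0) for p in prey_order])


@dataclass
class CompositionSummary:
    """Scat-level composition percentages for one predator."""

    predator: str
    n_scats: int
    pct_scats_by_richness: dict[int, float]
    pct_scats_wild_only: float
    pct_scats_livestock_only: float
    pct_diet_wild: float
    pct_diet_domestic: float


def rfo_profile(freq: FrequencyTable) -> DietProfile:
    """Relative frequency of occurrence: each prey's share of all occurrences."""
    if freq.total_occurrences <= 0:
        raise ValueError("frequency table has zero total occurrences")
    n = freq.total_occurrences
    return DietProfile(
        freq.predator,
        "rfo",
        {prey: c / n for prey, c in freq.occurrence_counts.items()},
    )


def _origin_of(registry: dict[str, PreySpecies] | dict[str, str], prey: str) -> str:
    if prey not in registry:
        raise ValueError(f"prey {prey!r} has no origin class in the registry")
    entry = registry[prey]
    return entry if isinstance(entry, str) else entry.origin


def origin_aggregate(
    profile: DietProfile, registry: dict[str, PreySpecies] | dict[str, str]
) -> tuple[float, float]:
    """Split a diet profile into (wild %, domestic %).

    Accepts a full :class:`PreySpecies` registry or a plain name→origin map.
    """
    pct_wild = 100.0 * sum(
        v
        for prey, v in profile.proportions.items()
        if _origin_of(registry, prey) == "wild"
    )
    return pct_wild, 100.0 - pct_wild


def scat_level_summary(
    dataset: ScatDataset,
    predator: str,
    registry: dict[str, PreySpecies] | dict[str, str],
) -> CompositionSummary:
    """Per-scat composition: richness histogram and wild-only/livestock-only
    scat percentages, plus the RFO-basis wild/domestic diet split."""
    recs = dataset.records_for(predator)
    n = len(recs)
    richness_counts: dict[int, int] = {}
    wild_only = livestock_only = 0
    for rec in recs:
        richness_counts[rec.richness] = richness_counts.get(rec.richness, 0) + 1
        origins = {_origin_of(registry, p) for p in rec.prey_items}
        if origins == {"wild"}:
            wild_only += 1
        elif origins == {"domestic"}:
            livestock_only += 1
    profile = rfo_profile(occurrence_counts(dataset, predator))
    pct_wild, pct_dom = origin_aggregate(profile, registry)
    return CompositionSummary(
        predator=predator,
        n_scats=n,
        pct_scats_by_richness={
            k: 100.0 * c / n for k, c in sorted(richness_counts.items())
        },
        pct_scats_wild_only=100.0 * wild_only / n,
        pct_scats_livestock_only=100.0 * livestock_only / n,
        pct_diet_wild=pct_wild,
        pct_diet_domestic=pct_dom,
    )


def accumulation_curve(
    dataset: ScatDataset,
    predator: str,
    n_reps: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Randomized prey-accumulation curve (sample-sufficiency check).

    For m = 1..N scats, the mean and sd over ``n_reps`` random scat orderings
    of the cumulative number of unique prey species in the first m scats.
    Each ordering's curve is monotone non-decreasing; the curve plateauing
    below the full sample size indicates the sample was large enough to
    capture the predator's prey richness.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    recs = dataset.records_for(predator)
    prey_order = sorted(set().union(*(r.prey_items for r in recs)))
    idx = {p: j for j, p in enumerate(prey_order)}
    mat = np.zeros((len(recs), len(prey_order)), dtype=bool)
    for i, rec in enumerate(recs):
        for p in rec.prey_items:
            mat[i, idx[p]] = True
    rng = np.random.default_rng(seed)
    n = len(recs)
    curves = np.empty((n_reps, n))
    for r in range(n_reps):
        order = rng.permutation(n)
        seen = np.logical_or.accumulate(mat[order], axis=0)
        curves[r] = seen.sum(axis=1)
    return pd.DataFrame(
        {
            "n_scats": np.arange(1, n + 1),
            "mean_unique_prey": curves.mean(axis=0),
            "sd_unique_prey": curves.std(axis=0, ddof=0),
        }
    )


def study_profile(predator: str, basis: str = "rfo") -> DietProfile:
    """A :class:`DietProfile` built from the packaged reference table."""
    profiles = load_study_profiles()
    if predator not in profiles:
        raise ValueError(f"unknown predator {predator!r}")
    values = {
        prey: (entry.fo if basis == "rfo" else entry.rb)
        for prey, entry in profiles[predator].items()
    }
    return DietProfile.from_values(predator, basis, values)
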