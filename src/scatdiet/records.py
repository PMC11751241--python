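"""Data model and file I/O for scat-level diet records.

A *scat* is one fecal sample; the prey remains identified in it form a set
of prey species (presence/absence — a species contributes at most one
occurrence per scat). This module defines the core record types, long-format
CSV readers/writers, and the packaged reference diet profiles for a
two-predator (snow leopard / wolf) study system.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "PreySpecies",
    "ScatRecord",
    "ScatDataset",
    "AvailabilityTable",
    "FrequencyTable",
    "StudyProfileEntry",
    "DEFAULT_PREDATORS",
    "canonical_name",
    "read_scat_table",
    "write_scat_table",
    "read_availability",
    "read_prey_attributes",
    "occurrence_counts",
    "load_study_profiles",
    "study_prey_attributes",
]

DEFAULT_PREDATORS = ("snow_leopard", "wolf")

#: Display-name aliases mapped onto canonical registry keys.
PREY_ALIASES = {
    "goat": "domestic_goat",
    "sheep": "domestic_sheep",
    "marmot": "himalayan_marmot",
}


def canonical_name(name: str) -> str:
    """Lowercase, underscore-separate, and resolve known aliases."""
    key = name.strip().lower().replace(" ", "_").replace("-", "_")
    return PREY_ALIASES.get(key, key)


@dataclass(frozen=True)
class PreySpecies:
    """A prey taxon: canonical key, display label, wild/domestic class, mass.

    ``mean_mass`` (kg) is optional and only required for biomass analysis.
    """

    name: str
    origin: str
    common_label: str = ""
    mean_mass: float | None = None

    def __post_init__(self) -> None:
        if self.origin not in ("wild", "domestic"):
            raise ValueError(
                f"origin for {self.name!r} must be 'wild' or 'domestic', "
                f"got {self.origin!r}"
            )
        if self.mean_mass is not None and not self.mean_mass > 0:
            raise ValueError(f"mean_mass for {self.name!r} must be > 0")


@dataclass(frozen=True)
class ScatRecord:
    """One scat: its predator label and the set of prey species found in it."""

    scat_id: str
    predator: str
    prey_items: frozenset[str]
    transect_id: str | None = None

    def __post_init__(self) -> None:
        if not self.prey_items:
            raise ValueError(f"scat {self.scat_id!r} has an empty prey set")

    @property
    def richness(self) -> int:
        return len(self.prey_items)


@dataclass
class ScatDataset:
    """A collection of scat records plus the registry of known prey species."""

    records: list[ScatRecord]
    prey_registry: list[PreySpecies] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = {p.name for p in self.prey_registry}
        if len(known) != len(self.prey_registry):
            raise ValueError("duplicate prey names in registry")
        if known:
            for rec in self.records:
                missing = rec.prey_items - known
                if missing:
                    raise ValueError(
                        f"scat {rec.scat_id!r} references prey not in "
                        f"registry: {sorted(missing)}"
                    )

    @property
    def predators(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.predator, None)
        return list(seen)

    def records_for(self, predator: str) -> list[ScatRecord]:
        recs = [r for r in self.records if r.predator == predator]
        if not recs:
            raise ValueError(f"no scat records for predator {predator!r}")
        return recs

    def prey_names(self) -> list[str]:
        if self.prey_registry:
            return [p.name for p in self.prey_registry]
        names: set[str] = set()
        for rec in self.records:
            names |= rec.prey_items
        return sorted(names)


@dataclass
class AvailabilityTable:
    """Prey availability counts and the proportions derived from them."""

    counts: dict[str, float]

    def __post_init__(self) -> None:
        for name, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative availability count for {name!r}")
        if sum(self.counts.values()) <= 0:
            raise ValueError("availability counts sum to zero")

    @property
    def proportions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        return {name: c / total for name, c in self.counts.items()}


@dataclass
class FrequencyTable:
    """Per-predator occurrence counts: one count per scat per prey species."""

    predator: str
    occurrence_counts: dict[str, int]

    @property
    def total_occurrences(self) -> int:
        return sum(self.occurrence_counts.values())


# ---------------------------------------------------------------------------
# File I/O (long-format CSV: one row per (scat, prey item))
# ---------------------------------------------------------------------------

def read_scat_table(
    path: str | Path,
    predators: Iterable[str] = DEFAULT_PREDATORS,
    prey_registry: list[PreySpecies] | None = None,
) -> ScatDataset:
    """Read a long-format scat CSV into a :class:`ScatDataset`.

    Required columns: ``scat_id``, ``predator``, ``prey_species``
    (``transect_id`` optional). Rows sharing a ``scat_id`` merge into a
    single record; duplicate (scat, prey) rows collapse to one occurrence
    with a warning.
    """
    path = Path(path)
    allowed = set(predators)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        required = {"scat_id", "predator", "prey_species"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        rows = list(reader)
    if not rows:
        raise ValueError(f"{path}: no data rows")

    # scat_id -> (predator, transect, prey set), preserving first-seen order
    scats: dict[str, tuple[str, str | None, set[str]]] = {}
    for row in rows:
        sid = row["scat_id"].strip()
        pred = row["predator"].strip()
        if pred not in allowed:
            raise ValueError(
                f"{path}: unknown predator {pred!r} (allowed: "
                f"{sorted(allowed)})"
            )
        prey = canonical_name(row["prey_species"])
        transect = (row.get("transect_id") or "").strip() or None
        if sid in scats:
            prev_pred, prev_tr, items = scats[sid]
            if prev_pred != pred:
                raise ValueError(
                    f"{path}: scat {sid!r} assigned to both "
                    f"{prev_pred!r} and {pred!r}"
                )
            if prey in items:
                warnings.warn(
                    f"duplicate row for scat {sid!r} prey {prey!r}; "
                    "collapsed to one occurrence",
                    stacklevel=2,
                )
            items.add(prey)
        else:
            scats[sid] = (pred, transect, {prey})

    records = [
        ScatRecord(sid, pred, frozenset(items), transect)
        for sid, (pred, transect, items) in scats.items()
    ]
    return ScatDataset(records, prey_registry or [])


def write_scat_table(dataset: ScatDataset, path: str | Path) -> None:
    """Write a dataset back to long-format CSV (sorted for determinism)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scat_id", "predator", "prey_species", "transect_id"])
        for rec in dataset.records:
            for prey in sorted(rec.prey_items):
                writer.writerow(
                    [rec.scat_id, rec.predator, prey, rec.transect_id or ""]
                )


def read_availability(path: str | Path) -> AvailabilityTable:
    """Read ``prey_species,count`` CSV into an :class:`AvailabilityTable`."""
    counts: dict[str, float] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"prey_species", "count"} <= set(
            reader.fieldnames
        ):
            raise ValueError(f"{path}: expected columns prey_species,count")
        for row in reader:
            name = canonical_name(row["prey_species"])
            counts[name] = counts.get(name, 0.0) + float(row["count"])
    return AvailabilityTable(counts)


def read_prey_attributes(path: str | Path) -> dict[str, PreySpecies]:
    """Read ``prey_species,origin[,mean_mass_kg]`` CSV into a registry map."""
    registry: dict[str, PreySpecies] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"prey_species", "origin"} <= set(
            reader.fieldnames
        ):
            raise ValueError(f"{path}: expected columns prey_species,origin")
        for row in reader:
            name = canonical_name(row["prey_species"])
            raw_mass = (row.get("mean_mass_kg") or "").strip()
            mass = float(raw_mass) if raw_mass else None
            registry[name] = PreySpecies(
                name=name,
                origin=row["origin"].strip().lower(),
                common_label=row.get("common_label", "") or name,
                mean_mass=mass,
            )
    return registry


# ---------------------------------------------------------------------------
# Occurrence counting
# ---------------------------------------------------------------------------

def occurrence_counts(dataset: ScatDataset, predator: str) -> FrequencyTable:
    """Count per-prey occurrences for one predator, one per scat per species.

    ``total_occurrences`` therefore equals the summed per-scat prey richness.
    """
    counts: dict[str, int] = {}
    for rec in dataset.records_for(predator):
        for prey in rec.prey_items:
            counts[prey] = counts.get(prey, 0) + 1
    return FrequencyTable(predator, dict(sorted(counts.items())))


# ---------------------------------------------------------------------------
# Packaged reference profiles (published two-predator diet table)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyProfileEntry:
    """One (prey, predator) cell: FO% and relative-biomass% as published."""

    fo: float
    rb: float


def _study_rows() -> list[dict[str, str]]:
    ref = resources.files("scatdiet.data").joinpath("study_profiles.csv")
    with ref.open(newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def load_study_profiles() -> dict[str, dict[str, StudyProfileEntry]]:
    """Load the packaged reference diet profiles.

    Returns a per-predator mapping prey → (FO%, RB%). Species absent from a
    predator's diet (empty cells) carry no entry — a structural zero.
    """
    out: dict[str, dict[str, StudyProfileEntry]] = {
        p: {} for p in DEFAULT_PREDATORS
    }
    for row in _study_rows():
        for pred in DEFAULT_PREDATORS:
            fo, rb = row[f"{pred}_fo"], row[f"{pred}_rb"]
            if fo and rb:
                out[pred][row["prey_species"]] = StudyProfileEntry(
                    fo=float(fo), rb=float(rb)
                )
    return out


def study_prey_attributes() -> dict[str, PreySpecies]:
    """Prey registry (origin classes, no masses) matching the reference table."""
    return {
        row["prey_species"]: PreySpecies(
            name=row["prey_species"],
            origin=row["origin"],
            common_label=row["common_label"],
        )
        for row in _study_rows()
    }
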