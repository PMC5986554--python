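"""Joint length-height classification of AFM particle measurements.

AFM morphometry of amyloid-beta(1-42) aggregates distinguishes protofibrils
(short intermediate aggregates, here 50-250 nm long and 1-4 nm high) from
mature fibrils (200-1000 nm long and 2-6 nm high).  A particle is assigned
to the first rule, in priority order, whose length AND height intervals
both contain it; fibril takes precedence in the overlapping
200-250 nm x 2-4 nm region because the longer species is the more mature
one.  Intervals are closed on both ends.  Particles matching no rule are
"unclassified".
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .kinetics import ValidationError

__all__ = [
    "Particle",
    "MorphologyRule",
    "SpeciesSummary",
    "UNCLASSIFIED",
    "default_rules",
    "classify_particle",
    "summarize_species",
    "distribution_histogram",
]

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Particle:
    """One AFM measurement: length and height in nm, both > 0."""

    length: float
    height: float
    condition: str = ""

    def __post_init__(self) -> None:
        for name in ("length", "height"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class MorphologyRule:
    """Closed-interval length x height rule; lower priority value wins first."""

    species: str
    length_range: tuple[float, float]
    height_range: tuple[float, float]
    priority: int

    def __post_init__(self) -> None:
        for rng in (self.length_range, self.height_range):
            if rng[0] > rng[1]:
                raise ValidationError(f"interval min must be <= max, got {rng}")

    def matches(self, p: Particle) -> bool:
        return (
            self.length_range[0] <= p.length <= self.length_range[1]
            and self.height_range[0] <= p.height <= self.height_range[1]
        )

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "length_range": list(self.length_range),
            "height_range": list(self.height_range),
            "priority": self.priority,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MorphologyRule":
        return cls(
            species=d["species"],
            length_range=tuple(d["length_range"]),
            height_range=tuple(d["height_range"]),
            priority=int(d["priority"]),
        )


@dataclass(frozen=True)
class SpeciesSummary:
    """Per-species counts and fractions over a particle table, plus unclassified."""

    counts: dict[str, int]
    fractions: dict[str, float]
    total: int

    def to_dict(self) -> dict:
        return {"counts": dict(self.counts), "fractions": dict(self.fractions), "total": self.total}


def default_rules() -> list[MorphologyRule]:
    """The published classification: fibril 200-1000 nm x 2-6 nm (priority 1),
    protofibril 50-250 nm x 1-4 nm (priority 2)."""
    return [
        MorphologyRule("fibril", (200.0, 1000.0), (2.0, 6.0), priority=1),
        MorphologyRule("protofibril", (50.0, 250.0), (1.0, 4.0), priority=2),
    ]


def _check_rules(rules: list[MorphologyRule]) -> list[MorphologyRule]:
    prios = [r.priority for r in rules]
    if len(set(prios)) != len(prios):
        raise ValidationError("rule priorities must be unique")
    return sorted(rules, key=lambda r: r.priority)


def classify_particle(p: Particle, rules: list[MorphologyRule]) -> str:
    """Label of the first matching rule in priority order, else 'unclassified'."""
    for rule in _check_rules(rules):
        if rule.matches(p):
            return rule.species
    return UNCLASSIFIED


def summarize_species(particles: list[Particle], rules: list[MorphologyRule]) -> SpeciesSummary:
    """Count and per-species fraction over a non-empty particle table.

    Every species in the rule set appears in the output (possibly with count
    0) along with 'unclassified'; fractions sum to 1.
    """
    if not particles:
        raise ValidationError("particle table is empty")
    ordered = _check_rules(rules)
    counts = Counter({r.species: 0 for r in ordered} | {UNCLASSIFIED: 0})
    for p in particles:
        counts[classify_particle(p, ordered)] += 1
    total = len(particles)
    fractions = {s: c / total for s, c in counts.items()}
    return SpeciesSummary(counts=dict(counts), fractions=fractions, total=total)


def distribution_histogram(
    particles: list[Particle], axis: str, bin_edges
) -> tuple[np.ndarray, int]:
    """Histogram of particle lengths or heights on the given bin edges.

    Bins are half-open [e_i, e_{i+1}) except the last, which is closed, so
    a particle sitting exactly on the final edge is counted.  Returns
    (counts per bin, number of out-of-range particles); counts sum to the
    number of in-range particles.
    """
    if axis not in ("length", "height"):
        raise ValidationError("axis must be 'length' or 'height'")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin_edges must be >= 2 strictly increasing values")
    values = np.array([getattr(p, axis) for p in particles], dtype=float)
    # np.histogram already uses half-open bins with a closed last bin
    counts, _ = np.histogram(values, bins=edges)
    out_of_range = int(np.sum((values < edges[0]) | (values > edges[-1])))
    return counts, out_of_range
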