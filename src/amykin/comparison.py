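"""Fold-change comparison of nucleation and elongation rate constants
across membrane conditions.

The package ships the published constants for the four conditions
(peptide alone, DOPC vesicles, cholesterol-containing vesicles, and
7-ketocholesterol-containing vesicles) as a small CSV fixture.  Fold
changes are ratios of the printed, already-rounded constants — max/min,
so every ratio is >= 1 and carries an explicit direction — rounded
half-away-from-zero at two decimals to match how such folds are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .kinetics import ValidationError

__all__ = [
    "ConditionConstants",
    "ComparisonResult",
    "PAPER_PAIRS",
    "load_table1",
    "fold_change",
    "compare_conditions",
    "render_report",
    "round_half_away",
]

#: the four published pairwise comparisons, in report order
PAPER_PAIRS = (
    ("Chol", "alone"),
    ("Chol", "DOPC"),
    ("7keto", "alone"),
    ("7keto", "Chol"),
)


@dataclass(frozen=True)
class ConditionConstants:
    """Rate constants of one condition: kn (s^-1) and ke (L mol^-1 s^-1)."""

    condition: str
    kn: float
    ke: float

    def __post_init__(self) -> None:
        if self.kn <= 0 or self.ke <= 0:
            raise ValidationError("rate constants must be > 0")


@dataclass(frozen=True)
class ComparisonResult:
    """Fold change of one constant between condition_a and condition_b.

    ``ratio`` = max/min >= 1; ``direction`` says whether the constant in
    condition_a is increased, decreased or unchanged relative to b.
    """

    parameter: str
    condition_a: str
    condition_b: str
    ratio: float
    ratio_rounded: float
    direction: str

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "ratio": self.ratio,
            "ratio_rounded": self.ratio_rounded,
            "direction": self.direction,
        }


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (2.175 -> 2.18), unlike banker's rounding.

    Works on the shortest decimal representation of x, so literal decimal
    halves behave as a reader of printed values expects.
    """
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def load_table1() -> list[ConditionConstants]:
    """The packaged published constants for the four conditions."""
    with resources.files("amykin.data").joinpath("table1_constants.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        ConditionConstants(condition=row.condition, kn=row.kn_per_s, ke=row.ke_per_mol_s)
        for row in df.itertuples()
    ]


def fold_change(x: float, y: float, parameter: str = "", a: str = "", b: str = "") -> ComparisonResult:
    """Fold change of x (condition a) relative to y (condition b)."""
    if not (x > 0 and y > 0):
        raise ValidationError("fold_change requires positive rates")
    ratio = max(x, y) / min(x, y)
    direction = "increased" if x > y else ("decreased" if x < y else "unchanged")
    return ComparisonResult(
        parameter=parameter,
        condition_a=a,
        condition_b=b,
        ratio=ratio,
        ratio_rounded=round_half_away(ratio, 2),
        direction=direction,
    )


def compare_conditions(
    constants: list[ConditionConstants], pairs: list[tuple[str, str]]
) -> list[ComparisonResult]:
    """One ComparisonResult per (pair x parameter), kn before ke, in pair order."""
    if not pairs:
        raise ValidationError("pairs must be non-empty")
    by_label = {c.condition: c for c in constants}
    results = []
    for a, b in pairs:
        for label in (a, b):
            if label not in by_label:
                known = ", ".join(sorted(by_label))
                raise ValidationError(f"unknown condition {label!r}; known: {known}")
        ca, cb = by_label[a], by_label[b]
        for param in ("kn", "ke"):
            results.append(
                fold_change(getattr(ca, param), getattr(cb, param), parameter=param, a=a, b=b)
            )
    return results


def render_report(
    fits_or_constants=None,
    comparisons: list[ComparisonResult] | None = None,
    morphology_summaries: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Assemble a machine-readable report; sections absent from the input are
    omitted.  The report records the package version, the seed, and the
    normalization/precedence conventions in force, so a run is auditable."""
    from . import __version__

    if fits_or_constants is None and comparisons is None and morphology_summaries is None:
        raise ValidationError("at least one report section is required")
    report: dict = {
        "schema_version": 1,
        "package_version": __version__,
        "conventions": {
            "fold_rounding": "half-away-from-zero, 2 decimals",
            "intensity_normalization": "baseline F0 and amplitude dF fitted jointly",
            "morphology_overlap_precedence": "fibril before protofibril",
            "time_unit_internal": "seconds",
        },
    }
    if seed is not None:
        report["seed"] = seed
    if fits_or_constants is not None:
        if all(isinstance(c, ConditionConstants) for c in fits_or_constants):
            report["constants"] = [
                {"condition": c.condition, "kn_per_s": c.kn, "ke_per_mol_s": c.ke}
                for c in fits_or_constants
            ]
        else:
            report["fits"] = [f.to_dict() for f in fits_or_constants]
    if comparisons is not None:
        report["comparisons"] = [c.to_dict() for c in comparisons]
    if morphology_summaries is not None:
        report["morphology"] = {
            label: s.to_dict() for label, s in morphology_summaries.items()
        }
    return report


def report_to_text(report: dict) -> str:
    """Human-readable rendering of a report dict."""
    lines = [f"amykin report (package {report['package_version']})"]
    if "seed" in report:
        lines.append(f"seed: {report['seed']}")
    if "constants" in report:
        lines.append("\nRate constants:")
        for c in report["constants"]:
            lines.append(
                f"  {c['condition']:>8}: kn = {c['kn_per_s']:.3g} 1/s, "
                f"ke = {c['ke_per_mol_s']:.4g} L/mol/s"
            )
    if "fits" in report:
        lines.append("\nFits:")
        for f in report["fits"]:
            lines.append(
                f"  kn = {f['kn_per_s']:.4g} 1/s, ke = {f['ke_per_M_s']:.4g} L/mol/s, "
                f"r2 = {f['r_squared']:.4f}, sigmoidal = {f['sigmoidal']}"
            )
    if "comparisons" in report:
        lines.append("\nFold changes:")
        for c in report["comparisons"]:
            lines.append(
                f"  {c['parameter']} {c['condition_a']} vs {c['condition_b']}: "
                f"{c['ratio_rounded']:.2f}-fold {c['direction']}"
            )
    if "morphology" in report:
        lines.append("\nMorphology:")
        for label, s in report["morphology"].items():
            fr = ", ".join(f"{k} {v:.1%}" for k, v in sorted(s["fractions"].items()))
            lines.append(f"  {label}: n = {s['total']}; {fr}")
    return "\n".join(lines) + "\n"
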