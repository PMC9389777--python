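"""Green analytical chemistry metrics: eco-scale, AGREE, NEMI/GAPI profiles.

The analytical eco-scale starts from an ideal score of 100 and subtracts
penalty points for reagents (pictogram count x signal-word factor x
amount factor), instrument energy, occupational hazard, and waste.
AGREE condenses the 12 principles of green analytical chemistry into a
weighted mean of per-principle scores in [0, 1].  NEMI (4 quadrants) and
GAPI (15 coloured zones) are categorical profiles; this module tallies
them but does not render pictograms.

Score *engines* live here; the package also ships reconstructed input
fixtures for the FEX/PSE spectrofluorometric assay and its HPLC
comparator (see :mod:`synchrofluor.reference`) whose totals match the
published assessments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

from .errors import ConfigurationError, DataError

__all__ = [
    "EcoScaleEntry",
    "EcoScaleLedger",
    "EcoScaleResult",
    "AgreeAssessment",
    "CategoricalProfile",
    "reagent_penalty",
    "eco_scale_score",
    "agree_overall",
    "profile_summary",
    "round_half_up",
]

ECO_CATEGORIES = ("reagent", "instrument", "occupational", "waste")
SIGNAL_WORD_FACTOR = {"none": 0, "warning": 1, "danger": 2}
AMOUNT_FACTOR = {"<10": 1, "10-100": 2, ">100": 3}
GAPI_ZONE_COUNT = 15
GAPI_COLOURS = ("green", "yellow", "red")


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as used for reported scores."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def reagent_penalty(
    pictogram_count: int, signal_word: str, amount_bracket: str = "<10"
) -> int:
    """Eco-scale reagent penalty: pictograms x signal-word x amount factor.

    ``signal_word`` is the GHS label word (none/warning/danger);
    ``amount_bracket`` is the quantity used per analysis in mL or g
    (``"<10"``, ``"10-100"``, ``">100"``).
    """
    if pictogram_count < 0:
        raise DataError("pictogram_count must be >= 0")
    try:
        word = SIGNAL_WORD_FACTOR[signal_word]
    except KeyError:
        raise ConfigurationError(
            f"unknown signal word {signal_word!r}; expected one of "
            f"{tuple(SIGNAL_WORD_FACTOR)}"
        ) from None
    try:
        amount = AMOUNT_FACTOR[amount_bracket]
    except KeyError:
        raise ConfigurationError(
            f"unknown amount bracket {amount_bracket!r}; expected one of "
            f"{tuple(AMOUNT_FACTOR)}"
        ) from None
    return pictogram_count * word * amount


@dataclass(frozen=True)
class EcoScaleEntry:
    """One penalty line: either a direct point value or, for reagents,
    structured GHS fields from which the points are derived."""

    name: str
    category: str
    penalty_points: int
    note: str = ""
    pictogram_count: int | None = None
    signal_word: str | None = None
    amount_bracket: str | None = None

    def __post_init__(self) -> None:
        if self.category not in ECO_CATEGORIES:
            raise DataError(
                f"{self.name}: category {self.category!r} not in {ECO_CATEGORIES}"
            )
        if self.penalty_points < 0:
            raise DataError(f"{self.name}: negative penalty points")
        if self.pictogram_count is not None:
            expected = reagent_penalty(
                self.pictogram_count, self.signal_word, self.amount_bracket or "<10"
            )
            if expected != self.penalty_points:
                raise DataError(
                    f"{self.name}: penalty_points {self.penalty_points} inconsistent "
                    f"with structured fields (expect {expected})"
                )

    @classmethod
    def reagent(
        cls,
        name: str,
        pictogram_count: int,
        signal_word: str,
        amount_bracket: str = "<10",
        note: str = "",
    ) -> "EcoScaleEntry":
        return cls(
            name=name,
            category="reagent",
            penalty_points=reagent_penalty(pictogram_count, signal_word, amount_bracket),
            note=note,
            pictogram_count=pictogram_count,
            signal_word=signal_word,
            amount_bracket=amount_bracket,
        )


@dataclass(frozen=True)
class EcoScaleLedger:
    entries: tuple[EcoScaleEntry, ...]

    @classmethod
    def from_json(cls, path: str | Path) -> "EcoScaleLedger":
        raw = json.loads(Path(path).read_text())
        entries = []
        for item in raw["entries"]:
            if "pictogram_count" in item:
                entries.append(EcoScaleEntry.reagent(
                    item["name"],
                    item["pictogram_count"],
                    item["signal_word"],
                    item.get("amount_bracket", "<10"),
                    item.get("note", ""),
                ))
            else:
                entries.append(EcoScaleEntry(
                    name=item["name"],
                    category=item["category"],
                    penalty_points=int(item["penalty_points"]),
                    note=item.get("note", ""),
                ))
        return cls(tuple(entries))


@dataclass(frozen=True)
class EcoScaleResult:
    score: int
    total_penalty: int
    subtotals: Mapping[str, int]


def eco_scale_score(ledger: EcoScaleLedger) -> EcoScaleResult:
    """Analytical eco-scale: ``max(0, 100 - total penalty points)``.

    An empty ledger is the ideal green analysis and scores 100.
    """
    subtotals = {cat: 0 for cat in ECO_CATEGORIES}
    for entry in ledger.entries:
        subtotals[entry.category] += entry.penalty_points
    total = sum(subtotals.values())
    return EcoScaleResult(score=max(0, 100 - total), total_penalty=total, subtotals=subtotals)


@dataclass(frozen=True)
class AgreeAssessment:
    """12-principle AGREE profile with weights and the overall score.

    ``overall`` is the unrounded weighted mean; ``reported`` applies the
    conventional 2-decimal half-up rounding.
    """

    principle_scores: tuple[float, ...]
    weights: tuple[float, ...] = field(default_factory=lambda: (1.0,) * 12)

    def __post_init__(self) -> None:
        if len(self.principle_scores) != 12:
            raise DataError(
                f"AGREE requires exactly 12 principle scores, got "
                f"{len(self.principle_scores)}"
            )
        if len(self.weights) != 12:
            raise DataError("AGREE requires exactly 12 weights")
        if any(not 0.0 <= s <= 1.0 for s in self.principle_scores):
            raise DataError("AGREE principle scores must lie in [0, 1]")
        if any(w <= 0 for w in self.weights):
            raise DataError("AGREE weights must be positive")

    @property
    def overall(self) -> float:
        return sum(w * s for w, s in zip(self.weights, self.principle_scores)) / sum(
            self.weights
        )

    @property
    def reported(self) -> float:
        return round_half_up(self.overall, 2)

    @classmethod
    def from_json(cls, path: str | Path) -> "AgreeAssessment":
        raw = json.loads(Path(path).read_text())
        scores = tuple(float(s) for s in raw["principle_scores"])
        weights = raw.get("weights")
        if weights is None:
            return cls(scores)
        return cls(scores, tuple(float(w) for w in weights))


def agree_overall(
    scores: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """Reported AGREE score: weighted mean rounded half-up to 2 decimals."""
    assessment = (
        AgreeAssessment(tuple(float(s) for s in scores))
        if weights is None
        else AgreeAssessment(tuple(float(s) for s in scores), tuple(float(w) for w in weights))
    )
    return assessment.reported


@dataclass(frozen=True)
class CategoricalProfile:
    """NEMI quadrants (booleans) or GAPI zones (green/yellow/red)."""

    tool: str
    fields: Mapping[str, object]

    def __post_init__(self) -> None:
        if self.tool not in ("NEMI", "GAPI"):
            raise ConfigurationError(f"unknown profile tool {self.tool!r}")
        if self.tool == "NEMI":
            if len(self.fields) != 4 or not all(
                isinstance(v, bool) for v in self.fields.values()
            ):
                raise DataError("NEMI profiles have exactly 4 boolean quadrants")
        else:
            if len(self.fields) != GAPI_ZONE_COUNT:
                raise DataError(f"GAPI profiles have exactly {GAPI_ZONE_COUNT} zones")
            bad = {v for v in self.fields.values() if v not in GAPI_COLOURS}
            if bad:
                raise DataError(f"invalid GAPI zone colours: {sorted(map(str, bad))}")

    @classmethod
    def from_json(cls, path: str | Path) -> "CategoricalProfile":
        raw = json.loads(Path(path).read_text())
        return cls(tool=raw["tool"], fields=raw["fields"])


def profile_summary(profile: CategoricalProfile) -> dict[str, int]:
    """Tally a categorical profile.

    GAPI: counts of green/yellow/red zones (summing to 15); NEMI: counts
    of filled (compliant) and empty quadrants (summing to 4).
    """
    if profile.tool == "GAPI":
        return {
            colour: sum(1 for v in profile.fields.values() if v == colour)
            for colour in GAPI_COLOURS
        }
    filled = sum(1 for v in profile.fields.values() if v)
    return {"filled": filled, "empty": len(profile.fields) - filled}
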