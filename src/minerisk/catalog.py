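"""Domain vocabulary and tabulation of coded accident records.

Underground coal mining distinguishes occupational roles ("working types");
six are defined here, of which four — ventilation, gas prevention and fire
extinguishing, blasting, and electrician — are the key types implicated in
gas-explosion causation. Worker actions that deviate from safe operating
rules are coded into one of 13 unsafe-behavior classes following Appendix A
of the Chinese casualty-accident classification standard GB 6441-86.

A coded accident table (one behavior citation per row) is tabulated into an
:class:`OccurrenceTable`, whose cell counts divided by the number of sampled
accidents give the raw occurrence probabilities P' that feed the correction
and risk models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Tuple

__all__ = [
    "BehaviorClass",
    "WorkingType",
    "AccidentRecord",
    "OccurrenceTable",
    "BEHAVIOR_CLASSES",
    "WORKING_TYPES",
    "KEY_WORKING_TYPE_IDS",
    "tabulate_occurrences",
    "occurrence_probability",
    "working_type_share",
]


@dataclass(frozen=True)
class BehaviorClass:
    """One of the 13 unsafe-behavior classes of GB 6441-86 Appendix A."""

    code: str
    description: str


@dataclass(frozen=True)
class WorkingType:
    """An occupational role category in underground coal mining."""

    id: str
    name: str
    is_key: bool


#: The 13 unsafe-behavior classes. Codes are immutable identifiers.
BEHAVIOR_CLASSES: Mapping[str, BehaviorClass] = {
    bc.code: bc
    for bc in (
        BehaviorClass("OIW", "Operating incorrectly, ignoring safety and warning"),
        BehaviorClass("FSD", "Failure of safety device"),
        BehaviorClass("UUD", "Use of unsafe devices"),
        BehaviorClass("HIT", "Hand instead of tool operation"),
        BehaviorClass("ISO", "Insecure storage of objects"),
        BehaviorClass("VDP", "Venture into dangerous places"),
        BehaviorClass("CSU", "Climbing or sitting in unsafe positions"),
        BehaviorClass("WSI", "Working or staying under suspended loads"),
        BehaviorClass(
            "RIW",
            "Repair, inspection, welding, cleaning or similar operations "
            "carried out while the machine is running",
        ),
        BehaviorClass("WHD", "Workers have distracted behaviors"),
        BehaviorClass(
            "PPE",
            "Neglecting personal protective equipment where its use is mandatory",
        ),
        BehaviorClass("UA", "Unsafe attire"),
        BehaviorClass("MFE", "Mishandling of flammable and explosive dangerous goods"),
    )
}

#: The six working types; the first four are key to gas-explosion causation.
WORKING_TYPES: Mapping[str, WorkingType] = {
    wt.id: wt
    for wt in (
        WorkingType("ventilation", "Ventilation", True),
        WorkingType(
            "gas_prevention_fire", "Gas prevention and fire extinguishing", True
        ),
        WorkingType("blasting", "Blasting", True),
        WorkingType("electrician", "Electrician", True),
        WorkingType("mining", "Mining", False),
        WorkingType("transport", "Transport", False),
    )
}

KEY_WORKING_TYPE_IDS: Tuple[str, ...] = tuple(
    wt.id for wt in WORKING_TYPES.values() if wt.is_key
)


@dataclass(frozen=True)
class AccidentRecord:
    """One coded accident: a unique id plus (working type, behavior) citations.

    The reference dataset codes each accident to exactly one key working
    type with one behavior class, but multi-citation accidents are
    supported by the model.
    """

    accident_id: str
    citations: Tuple[Tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "citations", tuple(tuple(c) for c in self.citations))


class UnknownCodeError(ValueError):
    """A citation references an undefined working type or behavior code."""


@dataclass
class OccurrenceTable:
    """Citation counts per (working type, behavior class) over N accidents."""

    n_accidents: int
    counts: dict = field(default_factory=dict)

    def count(self, working_type: str, behavior: str) -> int:
        _validate_tokens(working_type, behavior)
        return self.counts.get((working_type, behavior), 0)

    def type_total(self, working_type: str) -> int:
        if working_type not in WORKING_TYPES:
            raise UnknownCodeError(f"unknown working type {working_type!r}")
        return sum(
            n for (wt, _), n in self.counts.items() if wt == working_type
        )

    def total_citations(self) -> int:
        return sum(self.counts.values())


def _validate_tokens(working_type: str, behavior: str) -> None:
    if working_type not in WORKING_TYPES:
        raise UnknownCodeError(f"unknown working type {working_type!r}")
    if behavior not in BEHAVIOR_CLASSES:
        raise UnknownCodeError(f"unknown behavior code {behavior!r}")


def tabulate_occurrences(records: Iterable[AccidentRecord]) -> OccurrenceTable:
    """Aggregate accident records into per-cell citation counts.

    ``n_accidents`` is the number of distinct ``accident_id`` values; counts
    accumulate citation multiplicity. Rejects citations with undefined
    tokens, naming the offending token and record.
    """
    counts: dict = {}
    ids = set()
    for rec in records:
        if rec.accident_id in ids:
            raise ValueError(f"duplicate accident_id {rec.accident_id!r}")
        ids.add(rec.accident_id)
        for wt, bc in rec.citations:
            try:
                _validate_tokens(wt, bc)
            except UnknownCodeError as exc:
                raise UnknownCodeError(
                    f"{exc.args[0]} in accident {rec.accident_id!r}"
                ) from None
            counts[(wt, bc)] = counts.get((wt, bc), 0) + 1
    return OccurrenceTable(n_accidents=len(ids), counts=counts)


def occurrence_probability(
    table: OccurrenceTable, working_type: str, behavior: str
) -> float:
    """Raw occurrence probability P' = count / n_accidents, in [0, 1]."""
    if table.n_accidents <= 0:
        raise ZeroDivisionError(
            "occurrence probability undefined for an empty accident table"
        )
    return table.count(working_type, behavior) / table.n_accidents


def working_type_share(table: OccurrenceTable, working_type: str) -> float:
    """Percentage of sampled accidents attributed to a working type."""
    if table.n_accidents <= 0:
        raise ZeroDivisionError("share undefined for an empty accident table")
    return 100.0 * table.type_total(working_type) / table.n_accidents
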