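"""Sampling schedule of the dexamethasone time-course study.

Twenty subjects are sampled on four consecutive days at up to three
fixed clock times (morning 7:30, midday 13:30, evening 19:30).  A
single oral dose is given after midday on day 3, so each subject
contributes seven untreated slots (day 1 midday/evening, day 2
morning/midday/evening, day 3 morning/midday) and four treated slots
at +6 h (day 3 evening), +18 h (day 4 morning), +24 h (day 4 midday)
and +30 h (day 4 evening) post dose.

Because many plasma metabolites fluctuate with time of day, treated
slots are only ever compared against untreated slots sharing the same
daytime; the matching rule lives here so every downstream stage uses
the same pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DAYTIMES = ("morning", "midday", "evening")


@dataclass(frozen=True)
class Slot:
    """One scheduled blood draw: (day, time-of-day) with treatment status."""

    day: int
    daytime: str
    treated: bool = False
    hours_post_dose: float | None = None

    @property
    def label(self) -> str:
        return f"d{self.day}_{self.daytime}"

    def __post_init__(self) -> None:
        if self.daytime not in DAYTIMES:
            raise ValueError(f"unknown daytime {self.daytime!r}")
        if self.treated != (self.hours_post_dose is not None):
            raise ValueError(
                f"slot {self.label}: treated flag and hours_post_dose disagree"
            )


@dataclass(frozen=True)
class StudyDesign:
    """Ordered slot schedule plus the daytime-matching rule."""

    slots: tuple[Slot, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        labels = [s.label for s in self.slots]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate slots in design")

    @property
    def slot_labels(self) -> list[str]:
        return [s.label for s in self.slots]

    @property
    def treated_slots(self) -> list[Slot]:
        return [s for s in self.slots if s.treated]

    @property
    def untreated_slots(self) -> list[Slot]:
        return [s for s in self.slots if not s.treated]

    def slot(self, label: str) -> Slot:
        for s in self.slots:
            if s.label == label:
                return s
        raise KeyError(label)

    def matched_untreated(self, daytime: str) -> list[Slot]:
        """Untreated slots sharing ``daytime`` (the comparison reference)."""
        if daytime not in DAYTIMES:
            raise ValueError(f"unknown daytime {daytime!r}")
        return [s for s in self.untreated_slots if s.daytime == daytime]

    def validate_full(self) -> None:
        """Check the canonical 11-slot layout invariants."""
        if len(self.slots) != 11:
            raise ValueError(f"expected 11 slots, got {len(self.slots)}")
        if len(self.treated_slots) != 4:
            raise ValueError("expected exactly 4 treated slots")
        if any(s.day == 1 and s.daytime == "morning" for s in self.slots):
            raise ValueError("day 1 must not have a morning slot")
        for t in self.treated_slots:
            if not self.matched_untreated(t.daytime):
                raise ValueError(f"treated slot {t.label} has no matched untreated slot")


def default_design() -> StudyDesign:
    """The study's 11-slot schedule: 7 untreated then 4 post-dose draws."""
    slots = (
        Slot(1, "midday"),
        Slot(1, "evening"),
        Slot(2, "morning"),
        Slot(2, "midday"),
        Slot(2, "evening"),
        Slot(3, "morning"),
        Slot(3, "midday"),
        Slot(3, "evening", treated=True, hours_post_dose=6.0),
        Slot(4, "morning", treated=True, hours_post_dose=18.0),
        Slot(4, "midday", treated=True, hours_post_dose=24.0),
        Slot(4, "evening", treated=True, hours_post_dose=30.0),
    )
    design = StudyDesign(slots)
    design.validate_full()
    return design
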