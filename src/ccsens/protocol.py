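"""The 19-day behavioral sensitization protocol.

Mice are tested in the open field on nine calendar days. Both arms receive
saline on days 1 and 2 (habituation / baseline). From day 3 the drug-exposed
arm receives cocaine on days 3, 5, 7, 9 and 11 (five consecutive exposures),
a saline challenge on day 12 (conditioned activation), and a final cocaine
challenge on day 19 after a one-week withdrawal (sensitization expression).
The saline-exposed arm receives saline on every test day.
"""
from __future__ import annotations

from dataclasses import dataclass, field

TEST_DAYS: tuple[int, ...] = (1, 2, 3, 5, 7, 9, 11, 12, 19)

SAL = "SAL"
COC = "COC"

COCAINE_DAYS_DRUG_GROUP: tuple[int, ...] = (3, 5, 7, 9, 11, 19)
SALINE_DAYS_DRUG_GROUP: tuple[int, ...] = (1, 2, 12)

#: days 3..11 are the five consecutive cocaine exposures (exposure index 1..5)
SENSITIZATION_DAYS: tuple[int, ...] = (3, 5, 7, 9, 11)

TREATMENT_GROUPS = ("cocaine", "saline")
SEXES = ("F", "M")
SITES = ("JAX", "UNC")


def _default_injection_map() -> dict[tuple[str, int], str]:
    inj: dict[tuple[str, int], str] = {}
    for day in TEST_DAYS:
        inj[("saline", day)] = SAL
        inj[("cocaine", day)] = COC if day in COCAINE_DAYS_DRUG_GROUP else SAL
    return inj


@dataclass(frozen=True)
class ProtocolSchedule:
    """Injection schedule of the two treatment arms across the test days."""

    test_days: tuple[int, ...] = TEST_DAYS
    injection_map: dict[tuple[str, int], str] = field(
        default_factory=_default_injection_map
    )

    def __post_init__(self) -> None:
        if list(self.test_days) != sorted(set(self.test_days)):
            raise ValueError("test_days must be strictly increasing")
        for day in self.test_days:
            if self.injection_map.get(("saline", day)) != SAL:
                raise ValueError(f"saline group must receive SAL on day {day}")
            expected = COC if day in COCAINE_DAYS_DRUG_GROUP else SAL
            if self.injection_map.get(("cocaine", day)) != expected:
                raise ValueError(
                    f"cocaine group injection on day {day} must be {expected}"
                )

    def injection(self, treatment_group: str, day: int) -> str:
        """Injection (SAL or COC) a mouse of `treatment_group` receives on `day`."""
        try:
            return self.injection_map[(treatment_group, day)]
        except KeyError:
            raise KeyError(
                f"no injection scheduled for group {treatment_group!r} day {day}"
            ) from None

    def exposure_index(self, day: int) -> int | None:
        """1-based cocaine exposure index for the drug arm (days 3..11 -> 1..5,
        day 19 -> 6), or None on saline days."""
        if day in SENSITIZATION_DAYS:
            return SENSITIZATION_DAYS.index(day) + 1
        if day == 19:
            return 6
        return None


DEFAULT_SCHEDULE = ProtocolSchedule()
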