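"""Five-year age bands and disease states used throughout the model.

The population is stratified into 5-year bands 0-4 ... 95-99 plus an open
100+ band, and into two sexes.  Disease occupancy is tracked in five
mutually exclusive states: cognitively unimpaired, MCI due to AD, and
mild / moderate / severe AD dementia.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class State(str, Enum):
    UNIMPAIRED = "unimpaired"
    MCI = "mci"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


#: AD dementia stages (the states carrying AD-specific costs and severity ratios).
DEMENTIA_STATES = (State.MILD, State.MODERATE, State.SEVERE)
STATES = tuple(State)
STATE_INDEX = {s: i for i, s in enumerate(STATES)}

SEXES = ("male", "female")
SEX_INDEX = {"male": 0, "female": 1}


@dataclass(frozen=True)
class AgeBand:
    """One 5-year age band; ``upper is None`` marks the open top band."""

    label: str
    lower: int
    upper: int | None

    @property
    def is_open(self) -> bool:
        return self.upper is None

    def contains(self, age: int) -> bool:
        return age >= self.lower and (self.upper is None or age <= self.upper)

    @property
    def midpoint(self) -> float:
        # open band: nominal midpoint 102.5
        return self.lower + 2.5 if self.upper is None else (self.lower + self.upper + 1) / 2


def standard_bands(top: int = 100) -> tuple[AgeBand, ...]:
    """The standard band set 0-4 ... (top-5)-(top-1), top+."""
    bands = [AgeBand(f"{lo}-{lo + 4}", lo, lo + 4) for lo in range(0, top, 5)]
    bands.append(AgeBand(f"{top}+", top, None))
    return tuple(bands)


BANDS: tuple[AgeBand, ...] = standard_bands()
BAND_LABELS: tuple[str, ...] = tuple(b.label for b in BANDS)
BAND_INDEX = {b.label: i for i, b in enumerate(BANDS)}
N_BANDS = len(BANDS)


def validate_band_set(bands: tuple[AgeBand, ...]) -> list[str]:
    """Check contiguity, non-overlap and 5-year width; return problems found."""
    problems: list[str] = []
    for i, b in enumerate(bands):
        if b.upper is None:
            if i != len(bands) - 1:
                problems.append(f"open band {b.label} is not last")
            continue
        if b.upper - b.lower != 4:
            problems.append(f"band {b.label} is not 5 years wide")
        if i + 1 < len(bands) and bands[i + 1].lower != b.upper + 1:
            problems.append(f"gap/overlap between {b.label} and {bands[i + 1].label}")
    return problems
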