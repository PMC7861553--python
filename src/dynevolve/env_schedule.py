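"""Block-structured environment schedules for serial-transfer evolution.

An evolution experiment is a sequence of growth environments, each occupied
for a fixed number of generations per serial-transfer passage (8 by default).
Schedules are written as strings over three single-letter codes:

* ``F`` — glucose medium with fluconazole (24 h per passage),
* ``G`` — glycerol/ethanol medium (48 h per passage),
* ``P`` — the mixed medium, glycerol/ethanol plus fluconazole (48 h).

Generation coordinates are 0-based and half-open, ``[start_gen, end_gen)``:
a generation sitting exactly on a block boundary belongs to the later block,
which makes environment lookups at switches unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ENV_CODES",
    "PASSAGE_HOURS",
    "EnvironmentBlock",
    "EnvironmentSchedule",
    "ScheduleParseError",
    "parse_schedule",
    "get_preset",
    "PRESET_SCHEDULES",
    "time_in_environment",
    "environment_at",
]

ENV_CODES = ("F", "G", "P")

#: Wall-clock hours between passages in each environment. Stored for
#: bookkeeping only; all downstream computations run in generations.
PASSAGE_HOURS = {"F": 24, "G": 48, "P": 48}

#: The eight evolution-experiment schedules (first 192 generations; one
#: letter per 8-generation passage).
PRESET_SCHEDULES = {
    "switch_adap1": "FFFFFFGGGGGGGGGGGGGGGGGG",
    "switch_adap2": "GGGGGGGGGGGGGGGGGGFFFFFF",
    "periodic_smaller1": "FGGGFGGGFGGGFGGGFGGGFGGG",
    "periodic_smaller2": "GGGFGGGFGGGFGGGFGGGFGGGF",
    "random_adap": "GGGGGGGGGGGGGGGGGGFFFGGG",
    "random_smaller1": "GGGFGGGGGGGGGGGGFGGGGGGF",
    "random_smaller2": "FGGGGGGFGGGFFFGGGGGGGGGF",
    "mix": "PPPPPPPPPPPPPPPPPPPPPPPP",
}

#: Alternative names seen for the same experiments (case-insensitive lookup
#: is applied on top of these).
PRESET_ALIASES = {
    "random_adap1": "random_adap",
}


class ScheduleParseError(ValueError):
    """Raised for malformed schedule strings (empty or illegal characters)."""


@dataclass(frozen=True)
class EnvironmentBlock:
    """One contiguous block of a single environment.

    Parameters
    ----------
    label
        Environment code, one of ``F``, ``G``, ``P``.
    start_gen, end_gen
        Half-open generation span ``[start_gen, end_gen)``.
    duration_hours
        Wall-clock hours per passage in this environment.
    """

    label: str
    start_gen: int
    end_gen: int
    duration_hours: int = 0

    def __post_init__(self):
        if self.label not in ENV_CODES:
            raise ScheduleParseError(f"unknown environment code {self.label!r}")
        if self.start_gen < 0 or self.end_gen <= self.start_gen:
            raise ValueError(
                f"invalid block span [{self.start_gen}, {self.end_gen})"
            )

    @property
    def n_generations(self) -> int:
        return self.end_gen - self.start_gen


@dataclass(frozen=True)
class EnvironmentSchedule:
    """An ordered, contiguous sequence of environment blocks."""

    blocks: tuple[EnvironmentBlock, ...]
    gens_per_block: int = 8

    def __post_init__(self):
        prev_end = 0
        for b in self.blocks:
            if b.start_gen != prev_end:
                raise ValueError("schedule blocks must be contiguous")
            prev_end = b.end_gen

    @property
    def total_generations(self) -> int:
        return self.blocks[-1].end_gen if self.blocks else 0

    @property
    def labels(self) -> str:
        return "".join(b.label for b in self.blocks)

    def to_string(self) -> str:
        """Reserialize to the schedule string (inverse of :func:`parse_schedule`)."""
        return self.labels

    def periods(self) -> list[tuple[str, int, int]]:
        """Contiguous same-label runs as ``(label, start_gen, end_gen)``.

        A 24-generation glycerol/ethanol residence written ``GGG`` is one
        period of three blocks.
        """
        out: list[tuple[str, int, int]] = []
        for b in self.blocks:
            if out and out[-1][0] == b.label:
                out[-1] = (b.label, out[-1][1], b.end_gen)
            else:
                out.append((b.label, b.start_gen, b.end_gen))
        return out

    def __len__(self) -> int:
        return len(self.blocks)


def parse_schedule(schedule_string: str, gens_per_block: int = 8) -> EnvironmentSchedule:
    """Parse a schedule string (one letter per passage) into a schedule.

    Raises
    ------
    ScheduleParseError
        If the string is empty or contains a character outside ``{F, G, P}``;
        the message names the 1-based offending position.
    """
    if gens_per_block < 1:
        raise ValueError("gens_per_block must be >= 1")
    if not schedule_string:
        raise ScheduleParseError("empty schedule string")
    blocks = []
    for i, ch in enumerate(schedule_string):
        if ch not in ENV_CODES:
            raise ScheduleParseError(
                f"illegal environment code {ch!r} at position {i + 1}"
            )
        blocks.append(
            EnvironmentBlock(
                label=ch,
                start_gen=i * gens_per_block,
                end_gen=(i + 1) * gens_per_block,
                duration_hours=PASSAGE_HOURS[ch],
            )
        )
    return EnvironmentSchedule(blocks=tuple(blocks), gens_per_block=gens_per_block)


def get_preset(name: str, gens_per_block: int = 8) -> EnvironmentSchedule:
    """Return one of the named experiment schedules (aliases accepted)."""
    key = name.lower()
    key = PRESET_ALIASES.get(key, key)
    if key not in PRESET_SCHEDULES:
        known = sorted(set(PRESET_SCHEDULES) | set(PRESET_ALIASES))
        raise KeyError(f"unknown schedule preset {name!r}; known presets: {known}")
    return parse_schedule(PRESET_SCHEDULES[key], gens_per_block=gens_per_block)


def time_in_environment(schedule: EnvironmentSchedule, label: str) -> int:
    """Total generations the schedule spends in environment ``label``."""
    if label not in ENV_CODES:
        raise ValueError(f"unknown environment code {label!r}")
    return sum(b.n_generations for b in schedule.blocks if b.label == label)


def environment_at(schedule: EnvironmentSchedule, generation: float) -> str:
    """Environment code at a generation coordinate (half-open block lookup)."""
    total = schedule.total_generations
    if not (0 <= generation < total):
        raise ValueError(
            f"generation {generation} outside schedule range [0, {total})"
        )
    idx = int(generation // schedule.gens_per_block)
    return schedule.blocks[idx].label
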