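"""Subtask taxonomy for operating-room cleaning sessions.

The activity coding scheme distinguishes 27 subtasks, pooled into 17
analysis groups.  Several groups contain a single subtask with the same
name (e.g. ``Floor cleaning``); features and statistics always operate at
the group level.
"""

from __future__ import annotations

# group -> tuple of subtask labels
GROUPS: dict[str, tuple[str, ...]] = {
    "Waste disposal": ("Waste pickup", "Garbage disposal"),
    "Handling of lighting": (
        "Lighting protections removal",
        "Lighting switching off",
        "Lighting cleaning",
        "Radiography device handling",
    ),
    "Handling around the patient": (
        "Patient unequipping",
        "Patient equipping",
        "Patient holding",
        "Installing patient on stretcher",
    ),
    "Cables and pipes handling": ("Pipe disconnection", "Cables untangling"),
    "Patient transfer": ("Patient transfer",),
    "Surfaces and tools cleaning": ("Equipments cleaning", "Sink cleaning"),
    "Various objects moving": ("Various objects moving", "Water disinfection"),
    "Floor cleaning": ("Floor cleaning",),
    "Box lifting": ("Box lifting",),
    "Water tanks handling": ("Water tanks handling",),
    "Pressure washing": ("Pressure washing",),
    "Operating table moving": ("Operating table moving",),
    "Stretcher moving": ("Stretcher moving",),
    "Operating table cleaning": ("Operating table cleaning",),
    "Operating table disassembly": ("Operating table disassembly",),
    "Sheets moving": ("Sheets moving",),
    "Trolley moving": ("Trolley moving",),
}

#: subtask label -> group label
SUBTASK_TO_GROUP: dict[str, str] = {
    sub: group for group, subs in GROUPS.items() for sub in subs
}

GROUP_LABELS: tuple[str, ...] = tuple(GROUPS)

#: reserved label for frames not covered by any annotation
UNASSIGNED = "(unassigned)"
#: reserved label for whole-session (global) features
SESSION = "(session)"


class TaxonomyError(ValueError):
    """A subtask label outside the 27-label coding scheme."""


def group_of(subtask: str) -> str:
    """Return the analysis group a subtask label belongs to."""
    try:
        return SUBTASK_TO_GROUP[subtask]
    except KeyError:
        raise TaxonomyError(
            f"unknown subtask label {subtask!r}; expected one of the "
            f"{len(SUBTASK_TO_GROUP)} coded subtasks"
        ) from None
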