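"""Factor levels shared across the package.

Locations are *retinal* quadrant labels (the convention used throughout);
the retina-to-visual-field mapping lives in :mod:`blursim.stimuli`.
"""

from typing import NamedTuple

LOCATIONS: tuple[str, ...] = ("temporal", "nasal", "superior", "inferior")

#: Radially opposite quadrant (used for incongruent cue placement).
OPPOSITE: dict[str, str] = {
    "temporal": "nasal",
    "nasal": "temporal",
    "superior": "inferior",
    "inferior": "superior",
}

BLUR_LEVELS: tuple[str, str] = ("clear", "blurred")
CUE_LEVELS: tuple[str, str] = ("congruent", "incongruent")

HORIZONTAL: tuple[str, str] = ("temporal", "nasal")
VERTICAL: tuple[str, str] = ("superior", "inferior")


class Condition(NamedTuple):
    """One cell of the location x blur x cue factorial design."""

    location: str
    blur: str
    cue: str
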