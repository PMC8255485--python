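"""Closed vocabulary of rat ultrasonic-vocalization labels.

The 50-kHz family comprises the fourteen sonographic subtypes of the
standard classification scheme, plus ``Unclear`` for calls whose shape
fits none of them.  ``22kHz`` denotes the long aversive/alarm call
category, which lives outside the 50-kHz scoring universe.
"""

from __future__ import annotations

#: The fourteen 50-kHz sonographic subtypes.
SUBTYPES_50KHZ: tuple[str, ...] = (
    "Trill",
    "Flat",
    "Complex",
    "Composite",
    "Short",
    "Flat-Trill-combination",
    "Split",
    "Trill-with-Jump",
    "Step-Down",
    "Inverted-U",
    "Step-Up",
    "Multi-Step",
    "Downward-Ramp",
    "Upward-Ramp",
)

UNCLEAR = "Unclear"
KHZ22 = "22kHz"

#: Every label an accepted file may carry (16 symbols).
VOCABULARY: tuple[str, ...] = SUBTYPES_50KHZ + (UNCLEAR, KHZ22)

#: The 15-subtype universe entering the combined vocalization score:
#: all 50-kHz subtypes plus Unclear, excluding only the 22-kHz category.
CVS_SUBTYPES: tuple[str, ...] = SUBTYPES_50KHZ + (UNCLEAR,)

#: Two-letter field codes used in figures and compact tables.
SHORT_CODES: dict[str, str] = {
    "Trill": "Tr",
    "Flat": "Fl",
    "Complex": "Cx",
    "Composite": "Ce",
    "Short": "Sh",
    "Flat-Trill-combination": "Ft",
    "Split": "Sp",
    "Trill-with-Jump": "Tj",
    "Step-Down": "Sd",
    "Inverted-U": "Iu",
    "Step-Up": "Su",
    "Multi-Step": "Ms",
    "Downward-Ramp": "Dr",
    "Upward-Ramp": "Ur",
    "Unclear": "Un",
    "22kHz": "22k",
}

CODE_TO_SUBTYPE: dict[str, str] = {v: k for k, v in SHORT_CODES.items()}

# Integer codes for the frame raster: 0 is silence, subtypes are 1-based
# in VOCABULARY order.
SILENCE_CODE = 0
SUBTYPE_CODES: dict[str, int] = {s: i + 1 for i, s in enumerate(VOCABULARY)}
CODE_TO_LABEL: dict[int, str] = {i + 1: s for i, s in enumerate(VOCABULARY)}


def validate_subtype(name: str) -> str:
    """Return *name* if it is in the closed vocabulary, else raise ValueError."""
    if name not in SUBTYPE_CODES:
        raise ValueError(f"unknown subtype {name!r}")
    return name
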