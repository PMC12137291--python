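"""The fixed six-class patch label scheme.

Patches cut from side-view images of a single *Brassica napus* plant on a
dark background carry exactly one label: either ``background`` (no plant
material) or one of five organ/structure classes.  The ordering below is
canonical — integer codes, CSV column order and every deterministic
tie-break in the package follow it.
"""

from __future__ import annotations

#: Canonical class ordering; index = integer code.
CLASSES: tuple[str, ...] = ("background", "branch", "leaf", "bud", "flower", "pod")

#: The five organ classes (everything but background), in canonical order.
PLANT_CLASSES: tuple[str, ...] = CLASSES[1:]

#: name -> integer code
CODE: dict[str, int] = {name: i for i, name in enumerate(CLASSES)}

#: code for the background class
BACKGROUND: int = 0

N_CLASSES: int = len(CLASSES)


def check_label(label: str) -> str:
    """Return *label* if it is in the scheme, else raise ``ValueError``."""
    if label not in CODE:
        raise ValueError(f"label not in scheme: {label!r} (expected one of {CLASSES})")
    return label


def to_codes(labels) -> "list[int]":
    """Map an iterable of class names to integer codes (validating each)."""
    return [CODE[check_label(l)] for l in labels]
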