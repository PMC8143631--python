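"""Degron motif definitions shared by the scanner and the simulators.

A motif is a fixed-length window with anchored residues at stated offsets
and free (wildcard) positions elsewhere:

* ``D_min`` — minimal destruction box, RxxL (length 4);
* ``D_ext`` — extended destruction box, RxxLxxxxN (length 9);
* ``KEN``   — KEN box, the tripeptide KEN.

The ABBA motif is recognised by the APC/C but has no settled consensus, so
no default pattern ships; register one with :func:`register_motif_class`.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: class -> (length, {0-based offset: anchored residue})
MOTIF_TEMPLATES: dict[str, tuple[int, dict[int, str]]] = {
    "D_min": (4, {0: "R", 3: "L"}),
    "D_ext": (9, {0: "R", 3: "L", 8: "N"}),
    "KEN": (3, {0: "K", 1: "E", 2: "N"}),
}

DEFAULT_CLASSES = frozenset(MOTIF_TEMPLATES)


def register_motif_class(name: str, length: int, anchors: dict[int, str]) -> None:
    """Register a user-defined motif class (e.g. a lab's ABBA consensus).

    ``anchors`` maps 0-based offsets to required residues; all other
    positions are wildcards.
    """
    if length < 1:
        raise ValueError("motif length must be >= 1")
    for off, res in anchors.items():
        if not 0 <= off < length:
            raise ValueError(f"anchor offset {off} outside motif of length {length}")
        if res not in AMINO_ACIDS:
            raise ValueError(f"anchored residue {res!r} is not a standard amino acid")
    MOTIF_TEMPLATES[name] = (length, dict(anchors))
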