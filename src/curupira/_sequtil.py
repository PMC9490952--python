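"""Small sequence helpers shared across modules."""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")

#: purine/pyrimidine membership used to classify substitutions
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: transition partner of each base (A<->G, C<->T)
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: the two transversion partners of each base
TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def is_transition(a: str, b: str) -> bool:
    """True when a->b is a purine<->purine or pyrimidine<->pyrimidine change."""
    if a == b:
        return False
    return (a in PURINES) == (b in PURINES)
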