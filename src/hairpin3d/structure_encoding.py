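"""Case-coded characteristic sequences.

A folded hairpin is rewritten so that letter case carries the pairing
state of each base: an unpaired base (dot in the dot-bracket string) keeps
its uppercase letter, a paired base (either bracket) becomes lowercase.
The three-state dot-bracket information is retained alongside the letters
so downstream feature extraction can distinguish the 5' from the 3' side
of a stem, which the case alone cannot.

``UPPERCASE_IS_UNPAIRED`` pins the convention (uppercase = non-bonded);
flipping this one constant inverts the case-coding throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputError, StructureError
from .hairpin_io import StructuredRecord, SequenceRecord

UPPERCASE_IS_UNPAIRED = True


@dataclass(frozen=True)
class CharacteristicSequence:
    """Per-base letters carrying base identity plus pairing state."""

    letters: str
    states: str

    def __post_init__(self):
        if len(self.letters) != len(self.states):
            raise StructureError("letters and states lengths differ")
        # bracket balance is a StructuredRecord concern; a fragment of a
        # characteristic sequence (e.g. one arm of a stem) is still valid
        for i, (ch, st) in enumerate(zip(self.letters, self.states)):
            if ch.upper() not in "ACGU":
                raise InputError(f"illegal letter {ch!r} at position {i + 1}")
            if st not in ".()":
                raise StructureError(f"illegal state {st!r} at position {i + 1}")
            upper_ok = ch.isupper() == (st == ".")
            if upper_ok != UPPERCASE_IS_UNPAIRED:
                raise StructureError(
                    f"case/state inconsistency at position {i + 1}: "
                    f"{ch!r} with state {st!r}"
                )

    def __len__(self) -> int:
        return len(self.letters)


def encode(structured: StructuredRecord) -> CharacteristicSequence:
    """Case-code a folded record: unpaired bases uppercase, paired lowercase."""
    letters = []
    for base, state in zip(structured.record.sequence, structured.structure):
        unpaired = state == "."
        if unpaired == UPPERCASE_IS_UNPAIRED:
            letters.append(base.upper())
        else:
            letters.append(base.lower())
    return CharacteristicSequence("".join(letters), structured.structure)


def decode(cs: CharacteristicSequence) -> tuple:
    """Invert :func:`encode`: recover (uppercase sequence, structure)."""
    return cs.letters.upper(), cs.states


def decode_record(cs: CharacteristicSequence, record_id: str = "decoded") -> StructuredRecord:
    sequence, structure = decode(cs)
    return StructuredRecord(SequenceRecord(id=record_id, sequence=sequence), structure)
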