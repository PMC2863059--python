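"""Sequence-derived features: length, amino-acid composition, SS composition."""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import CANONICAL_RESIDUES, SS_ALPHABET, ValidationError

__all__ = ["CompositionVector", "SSComposition", "aa_composition", "ss_composition", "sequence_length"]

_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)


@dataclass
class CompositionVector:
    """Per-residue occurrence frequencies over the 20 canonical amino acids."""

    freqs: dict[str, float]

    def as_list(self) -> list[float]:
        """Frequencies in the fixed (alphabetical) residue order."""
        return [self.freqs[a] for a in CANONICAL_RESIDUES]


@dataclass
class SSComposition:
    """Fractions of residues in helix (H), strand (E) and coil (C) states."""

    helix: float
    sheet: float
    coil: float


def aa_composition(sequence: str, strict: bool = True) -> CompositionVector:
    """Occurrence frequency of each canonical residue in the sequence.

    In lenient mode non-canonical residues are excluded from both the counts
    and the denominator; an all-non-canonical sequence is an error.
    """
    if len(sequence) == 0:
        raise ValidationError("empty sequence")
    sequence = sequence.upper()
    counts = {a: 0 for a in CANONICAL_RESIDUES}
    denom = 0
    for pos, ch in enumerate(sequence, start=1):
        if ch in _CANONICAL_SET:
            counts[ch] += 1
            denom += 1
        elif strict:
            raise ValidationError(f"illegal residue {ch!r} at position {pos}")
    if denom == 0:
        raise ValidationError("sequence contains no canonical residues")
    return CompositionVector(freqs={a: counts[a] / denom for a in CANONICAL_RESIDUES})


def ss_composition(ss_string: str) -> SSComposition:
    """Fractions of H, E and C in a 3-state secondary-structure string."""
    if len(ss_string) == 0:
        raise ValidationError("empty secondary-structure string")
    for pos, ch in enumerate(ss_string, start=1):
        if ch not in SS_ALPHABET:
            raise ValidationError(f"illegal secondary-structure character {ch!r} at position {pos}")
    n = len(ss_string)
    return SSComposition(
        helix=ss_string.count("H") / n,
        sheet=ss_string.count("E") / n,
        coil=ss_string.count("C") / n,
    )


def sequence_length(sequence: str) -> int:
    """Number of residues in the chain."""
    return len(sequence)
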