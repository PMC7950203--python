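"""In-silico tryptic digestion and predicted-peptide counting.

Trypsin cleaves C-terminal to lysine (K) and arginine (R); with the Keil rule
enabled, a K/R immediately followed by proline is not cleaved. Only fully
tryptic peptides are produced: both ends lie on a cleavage site or a sequence
terminus. The predicted-peptide count is the denominator of the RPSM
abundance statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from rhizoquant.io import AMINO_ACIDS, FormatError

CLEAVAGE_RESIDUES = frozenset("KR")


@dataclass(frozen=True)
class DigestOptions:
    """Digestion settings.

    ``max_missed_cleavages`` defaults to 0 and ``min_length`` to 6: the
    RPSM denominator convention of distinct observable zero-missed peptides.
    Search-engine emulation uses ``max_missed_cleavages=2``. ``max_length``
    of ``None`` means unlimited.
    """

    max_missed_cleavages: int = 0
    apply_proline_rule: bool = False
    min_length: int = 6
    max_length: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.max_missed_cleavages <= 5:
            raise ValueError("max_missed_cleavages must be in 0..5")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_length is not None and self.max_length < self.min_length:
            raise ValueError("max_length must be >= min_length")


class Peptide(NamedTuple):
    sequence: str
    start: int  # 0-based offset in the parent sequence
    missed_cleavages: int


def _validate(sequence: str) -> None:
    for pos, aa in enumerate(sequence, start=1):
        if aa not in AMINO_ACIDS:
            raise FormatError(f"invalid amino-acid character {aa!r} at position {pos}")


def cleavage_boundaries(sequence: str, apply_proline_rule: bool = False) -> list[int]:
    """Segment boundaries: 0, every position after a cleavable K/R, and the end.

    A K/R at the C-terminus contributes no extra boundary beyond the terminus.
    """
    bounds = [0]
    last = len(sequence) - 1
    for i, aa in enumerate(sequence):
        if aa in CLEAVAGE_RESIDUES and i < last:
            if apply_proline_rule and sequence[i + 1] == "P":
                continue
            bounds.append(i + 1)
    bounds.append(len(sequence))
    return bounds


def digest(sequence: str, opts: DigestOptions = DigestOptions()) -> list[Peptide]:
    """Enumerate fully tryptic peptides of ``sequence``.

    Returns peptides with missed-cleavage count <= ``opts.max_missed_cleavages``
    and length within [min_length, max_length], sorted by start position then
    length. Deterministic.
    """
    if not sequence:
        return []
    _validate(sequence)
    bounds = cleavage_boundaries(sequence, opts.apply_proline_rule)
    n_segments = len(bounds) - 1
    peptides: list[Peptide] = []
    for j in range(n_segments):
        for missed in range(min(opts.max_missed_cleavages, n_segments - 1 - j) + 1):
            start, end = bounds[j], bounds[j + 1 + missed]
            length = end - start
            if length < opts.min_length:
                continue
            if opts.max_length is not None and length > opts.max_length:
                continue
            peptides.append(Peptide(sequence[start:end], start, missed))
    peptides.sort(key=lambda p: (p.start, len(p.sequence)))
    return peptides


def count_predicted_peptides(
    sequence: str, opts: DigestOptions = DigestOptions()
) -> int:
    """Number of predicted tryptic peptides under ``opts`` (RPSM denominator)."""
    return len(digest(sequence, opts))


def count_closed_form(n_segments: int, max_missed: int) -> int:
    """Peptide count when all segment unions pass the length filter.

    With s zero-missed segments and up to m missed cleavages the count is
    sum_{j=0..min(m, s-1)} (s - j); useful as an independent check.
    """
    if n_segments <= 0:
        return 0
    return sum(n_segments - j for j in range(min(max_missed, n_segments - 1) + 1))


def digest_proteome(
    records, opts: DigestOptions = DigestOptions()
) -> dict[str, int]:
    """Predicted-peptide counts for a list of :class:`ProteinRecord`."""
    return {rec.id: count_predicted_peptides(rec.sequence, opts) for rec in records}
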