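"""Mining nodule-specific cysteine-rich (NCR) peptides.

NCR peptides are defensin-like plant peptides (4 or 6 conserved cysteines in
the mature region) delivered to bacteroids in IRLC legume nodules. This
module mines them from proteomic de-novo peptide lists and nodule transcript
contigs:

1. derive conserved 3-residue tags from a reference NCR alignment;
2. screen de-novo peptides for those tags (Leu/Ile treated as equivalent,
   since de-novo sequencing cannot distinguish the isobaric pair);
3. six-frame translate transcript contigs into stop-free ORFs;
4. match tag-positive peptides to ORFs by Smith-Waterman local alignment
   (BLOSUM62, gap open 11 / extend 1) with strict identity (>90%) and
   coverage (>50%) cut-offs;
5. derive the mature peptide from an externally predicted signal-peptide
   cleavage site, compute its isoelectric point, and bin it as anionic
   (pI < 6.5), neutral (6.5-7.5) or cationic (pI > 7.5).
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Mapping, NamedTuple, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from rhizoquant.io import FormatError

GAP_CHARS = frozenset("-.")
DNA_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


# ---------------------------------------------------------------------------
# conserved-tag derivation and search


@dataclass(frozen=True)
class TagSet:
    """Conserved 3-residue tags derived from a reference NCR alignment."""

    tags: frozenset[str]
    positions: Mapping[str, int]  # tag -> 0-based alignment column of window start
    conservation: Mapping[str, float]  # tag -> min column conservation in window

    def __len__(self) -> int:
        return len(self.tags)


def build_tag_set(
    alignment: Sequence[tuple[str, str]], min_conservation: float = 0.8
) -> TagSet:
    """Derive 3-residue tags from gap-free, conserved alignment windows.

    Every window of 3 consecutive columns in which no sequence has a gap and
    the majority residue of each column reaches ``min_conservation`` yields
    the majority triple as a tag; duplicate triples collapse (keeping the
    first window position).
    """
    if len(alignment) < 2:
        raise ValueError("reference alignment needs at least 2 sequences")
    seqs = [seq.upper() for _, seq in alignment]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise FormatError("ragged alignment: sequences have unequal lengths")
    columns = []
    for col in range(length):
        residues = [s[col] for s in seqs]
        if any(r in GAP_CHARS for r in residues):
            columns.append(None)
            continue
        tally = Counter(residues)
        # deterministic majority: ties resolved toward the alphabetically
        # smallest residue with the maximal count
        best = max(tally.values())
        residue = min(r for r, c in tally.items() if c == best)
        columns.append((residue, best / len(seqs)))
    tags: dict[str, int] = {}
    conservation: dict[str, float] = {}
    for start in range(length - 2):
        window = columns[start : start + 3]
        if any(c is None for c in window):
            continue
        if all(frac >= min_conservation for _, frac in window):
            tag = "".join(residue for residue, _ in window)
            if tag not in tags:
                tags[tag] = start
                conservation[tag] = min(frac for _, frac in window)
    return TagSet(frozenset(tags), tags, conservation)


def _il_normalize(seq: str) -> str:
    return seq.replace("L", "I")


class TagMatch(NamedTuple):
    peptide: str
    matches: tuple[tuple[str, int], ...]  # (tag, 0-based position in peptide)


def tag_search(peptides: Iterable[str], tags: TagSet) -> list[TagMatch]:
    """Retain peptides containing at least one tag as an exact substring.

    Matching treats I and L as equivalent. Reported positions are 0-based.
    """
    if not tags.tags:
        raise ValueError("tag set is empty")
    norm_tags = {(_il_normalize(t)): t for t in sorted(tags.tags)}
    results: list[TagMatch] = []
    for peptide in peptides:
        norm = _il_normalize(peptide.upper())
        hits: list[tuple[str, int]] = []
        for norm_tag, tag in norm_tags.items():
            start = norm.find(norm_tag)
            while start != -1:
                hits.append((tag, start))
                start = norm.find(norm_tag, start + 1)
        if hits:
            hits.sort(key=lambda h: (h[1], h[0]))
            results.append(TagMatch(peptide, tuple(hits)))
    return results


# ---------------------------------------------------------------------------
# six-frame translation of contigs


class ORF(NamedTuple):
    contig_id: str
    frame: int  # +1..+3 forward, -1..-3 reverse
    peptide: str
    start: int  # 1-based inclusive, forward-strand coordinates
    end: int  # 1-based inclusive, forward-strand coordinates


def translate_contigs(
    contigs: Iterable[tuple[str, str]], min_orf_length: int = 30
) -> list[ORF]:
    """Six-frame translation into maximal stop-free ORFs.

    A start codon is not required (NCR fragments may be internal to longer
    contig ORFs). Ambiguous codons translate to X. Coordinates are 1-based
    inclusive on the forward strand.
    """
    orfs: list[ORF] = []
    for contig_id, seq in contigs:
        seq = seq.upper()
        if not seq:
            warnings.warn(f"contig {contig_id!r}: empty sequence, skipped")
            continue
        n = len(seq)
        rc = seq.translate(DNA_COMPLEMENT)[::-1]
        for strand, strand_seq in ((1, seq), (-1, rc)):
            for offset in range(3):
                frame = strand * (offset + 1)
                usable = (len(strand_seq) - offset) // 3 * 3
                if usable <= 0:
                    continue
                aa = str(Seq(strand_seq[offset : offset + usable]).translate())
                pos = 0
                for chunk in aa.split("*"):
                    if len(chunk) >= min_orf_length:
                        # coordinates of the chunk on its own strand (0-based nt)
                        s_nt = offset + 3 * pos
                        e_nt = s_nt + 3 * len(chunk) - 1
                        if strand == 1:
                            start, end = s_nt + 1, e_nt + 1
                        else:
                            start, end = n - e_nt, n - s_nt
                        orfs.append(ORF(contig_id, frame, chunk, start, end))
                    pos += len(chunk) + 1  # account for the stop codon
    return orfs


# ---------------------------------------------------------------------------
# local-alignment matching of candidates against ORFs


@dataclass(frozen=True)
class NCRCandidate:
    """A de-novo peptide with its best contig-ORF match."""

    peptide: str
    matched_tags: tuple[str, ...]
    contig_id: str
    frame: int
    orf_start: int
    identity: float  # percent
    coverage: float  # percent
    score: float


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _identity_and_coverage(alignment, query: str) -> tuple[float, float]:
    """Percent identity over aligned columns (I=L) and query coverage."""
    aligned_q, aligned_t = alignment[0], alignment[1]
    matches = 0
    aligned_cols = 0
    aligned_query_residues = 0
    for q, t in zip(aligned_q, aligned_t):
        if q == "-" or t == "-":
            continue
        aligned_cols += 1
        aligned_query_residues += 1
        if _il_normalize(q) == _il_normalize(t):
            matches += 1
    if aligned_cols == 0:
        return 0.0, 0.0
    identity = 100.0 * matches / aligned_cols
    coverage = 100.0 * aligned_query_residues / len(query)
    return identity, coverage


def match_candidates(
    tag_matches: Sequence[TagMatch],
    orfs: Sequence[ORF],
    min_identity: float = 90.0,
    min_coverage: float = 50.0,
) -> list[NCRCandidate]:
    """Best local-alignment ORF match for each tag-positive peptide.

    A candidate is retained iff identity > ``min_identity`` AND coverage >
    ``min_coverage`` (both strict). Ties on alignment score are broken by
    lexicographic contig id, then frame.
    """
    if not orfs:
        return []
    aligner = _make_aligner()
    ordered_orfs = sorted(orfs, key=lambda o: (o.contig_id, o.frame, o.start))
    results: list[NCRCandidate] = []
    for tm in tag_matches:
        query = tm.peptide.upper()
        best: NCRCandidate | None = None
        for orf in ordered_orfs:
            if not orf.peptide:
                continue
            try:
                alignments = aligner.align(query, orf.peptide)
                alignment = alignments[0] if len(alignments) else None
            except (ValueError, OverflowError):
                alignment = None
            if alignment is None or alignment.score <= 0:
                continue
            identity, coverage = _identity_and_coverage(alignment, query)
            if best is None or alignment.score > best.score:
                best = NCRCandidate(
                    peptide=tm.peptide,
                    matched_tags=tuple(dict.fromkeys(t for t, _ in tm.matches)),
                    contig_id=orf.contig_id,
                    frame=orf.frame,
                    orf_start=orf.start,
                    identity=identity,
                    coverage=coverage,
                    score=alignment.score,
                )
        if best is not None and best.identity > min_identity and best.coverage > min_coverage:
            results.append(best)
    return results


# ---------------------------------------------------------------------------
# mature-peptide derivation, isoelectric point, charge class


def predict_mature(precursor: str, cleavage_position: int) -> str:
    """Mature peptide: the precursor suffix after the signal-peptide cleavage.

    ``cleavage_position`` is 1-based, the last residue of the signal peptide;
    it must satisfy 1 <= position < len(precursor).
    """
    if not 1 <= cleavage_position < len(precursor):
        raise ValueError(
            f"cleavage position {cleavage_position} out of range for a "
            f"{len(precursor)}-residue precursor"
        )
    return precursor[cleavage_position:]


def heuristic_cleavage_position(precursor: str, window: int = 40) -> int | None:
    """Fallback signal-peptide cleavage guess (off by default in the pipeline).

    Returns the most C-terminal position p within the first ``window``
    residues such that residues p-2 and p (the (-3,-1) positions of the
    cleavage site) are both small (A, G, S, C, T or V), or None.
    """
    small = set("AGSCTV")
    limit = min(window, len(precursor) - 1)
    for p in range(limit, 2, -1):
        if precursor[p - 3] in small and precursor[p - 1] in small:
            return p
    return None


def _load_default_pka() -> dict:
    with resources.files("rhizoquant.data").joinpath("pka_table.json").open() as fh:
        return json.load(fh)


_DEFAULT_PKA: dict | None = None


def default_pka_table() -> dict:
    """EMBOSS-style pKa values shipped with the package (editable data file)."""
    global _DEFAULT_PKA
    if _DEFAULT_PKA is None:
        _DEFAULT_PKA = _load_default_pka()
    return _DEFAULT_PKA


def net_charge(peptide: str, ph: float, pka: Mapping | None = None) -> float:
    """Net charge at a given pH via Henderson-Hasselbalch.

    Basic groups (N-terminus, K, R, H) contribute 1/(1+10^(pH-pKa)); acidic
    groups (C-terminus, D, E, C, Y) contribute -1/(1+10^(pKa-pH)). Strictly
    decreasing in pH, so the isoelectric point is a unique root.
    """
    table = pka or default_pka_table()
    counts = Counter(peptide.upper())
    charge = 1.0 / (1.0 + 10.0 ** (ph - table["n_term"]))
    charge -= 1.0 / (1.0 + 10.0 ** (table["c_term"] - ph))
    for aa in ("K", "R", "H"):
        charge += counts[aa] / (1.0 + 10.0 ** (ph - table["side_chains"][aa]))
    for aa in ("D", "E", "C", "Y"):
        charge -= counts[aa] / (1.0 + 10.0 ** (table["side_chains"][aa] - ph))
    return charge


def compute_pi(peptide: str, pka: Mapping | None = None, tol: float = 1e-6) -> float:
    """Isoelectric point: the pH at which the net charge is zero.

    Solved by bisection on [0, 14] to |Q| < ``tol``.
    """
    if not peptide:
        raise ValueError("empty peptide")
    lo, hi = 0.0, 14.0
    q_lo = net_charge(peptide, lo, pka)
    if q_lo < 0:
        return lo
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(peptide, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def classify_charge(pi: float, boundaries: tuple[float, float] = (6.5, 7.5)) -> str:
    """Charge class from pI: anionic (<6.5), neutral (6.5-7.5), cationic (>7.5).

    Both boundaries belong to the neutral class. Values outside the usual
    [4, 10] NCR range are still classified, with a warning.
    """
    lo, hi = boundaries
    if pi < 4.0 or pi > 10.0:
        warnings.warn(f"pI {pi:.2f} outside the typical [4, 10] NCR range")
    if pi < lo:
        return "anionic"
    if pi <= hi:
        return "neutral"
    return "cationic"


@dataclass(frozen=True)
class NCRPeptide:
    """A full NCR precursor with its processed (mature) form and pI class."""

    id: str
    precursor: str
    cleavage_position: int
    mature: str = field(init=False, default="")
    cysteine_count: int = field(init=False, default=0)
    pi: float = field(init=False, default=0.0)
    charge_class: str = field(init=False, default="")

    def __post_init__(self) -> None:
        mature = predict_mature(self.precursor, self.cleavage_position)
        object.__setattr__(self, "mature", mature)
        object.__setattr__(self, "cysteine_count", mature.count("C"))
        pi = compute_pi(mature)
        object.__setattr__(self, "pi", pi)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            object.__setattr__(self, "charge_class", classify_charge(pi))


def charge_distribution(peptides: Sequence[NCRPeptide]) -> dict[str, int]:
    """Percentage of anionic/neutral/cationic peptides, to 0 decimals.

    Percentages are rounded half away from zero and sum to 100 +/- 1.
    """
    if not peptides:
        raise ValueError("cannot summarise an empty peptide list")
    counts = Counter(p.charge_class for p in peptides)
    total = len(peptides)
    return {
        cls: int(
            Decimal(repr(100.0 * counts.get(cls, 0) / total)).quantize(
                Decimal("1"), rounding=ROUND_HALF_UP
            )
        )
        for cls in ("anionic", "neutral", "cationic")
    }
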