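"""Domain types, file readers/writers, configuration and logging.

All tabular interchange is tab-separated text with a header row; sequences are
FASTA. Percentages in reports are rendered to one decimal with
round-half-away-from-zero, matching the convention of published replicon
distribution tables.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

logger = logging.getLogger("rhizoquant")


def setup_logging(level: int = logging.INFO) -> None:
    """Configure stage-tagged log lines on standard error."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its replicon (chromosome/plasmid) assignment."""

    id: str
    replicon: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein {self.id!r}: empty sequence")
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in AMINO_ACIDS:
                raise FormatError(
                    f"protein {self.id!r}: invalid amino-acid character "
                    f"{aa!r} at position {pos}"
                )


@dataclass(frozen=True)
class PSMTable:
    """Per-replicate spectral counts for one host.

    Proteins absent from the table are treated as zero in every replicate
    downstream; absence is evidence of non-detection, not missing data.
    """

    host: str
    replicate_counts: Mapping[str, tuple[int, ...]]
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for pid, counts in self.replicate_counts.items():
            if len(counts) != self.n_replicates:
                raise ValueError(
                    f"protein {pid!r}: expected {self.n_replicates} replicate "
                    f"counts, got {len(counts)}"
                )
            if any(c < 0 for c in counts):
                raise ValueError(f"protein {pid!r}: negative spectral count")

    def counts(self, protein_id: str) -> tuple[int, ...]:
        """Replicate counts for a protein; all zeros when not listed."""
        return self.replicate_counts.get(protein_id, (0,) * self.n_replicates)

    @property
    def ids(self) -> set[str]:
        return set(self.replicate_counts)


@dataclass(frozen=True)
class ITRAQRecord:
    """Per-protein pea/lentil iTRAQ ratio and its classification."""

    id: str
    ratio: float
    label: str  # pea_over | lentil_over | not_significant

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ValueError(f"protein {self.id!r}: iTRAQ ratio must be positive")
        if self.label not in {"pea_over", "lentil_over", "not_significant"}:
            raise ValueError(f"unknown iTRAQ label {self.label!r}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Cut-offs and options shared across pipeline stages.

    Defaults are the study conventions: >=10 accumulated spectra for a
    host-specific call, an iTRAQ significance ratio of 2 (inclusive), pI bin
    boundaries at 6.5 and 7.5, identity/coverage cut-offs of 90%/50% (strict)
    for candidate-to-contig matching.
    """

    min_accumulated_spectra: int = 10
    itraq_threshold: float = 2.0
    max_missed_cleavages: int = 0
    apply_proline_rule: bool = False
    min_peptide_length: int = 6
    pi_bin_boundaries: tuple[float, float] = (6.5, 7.5)
    min_identity: float = 90.0
    min_coverage: float = 50.0
    min_tag_conservation: float = 0.8
    min_orf_length: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_accumulated_spectra < 0:
            raise ValueError("min_accumulated_spectra must be non-negative")
        if self.itraq_threshold <= 1:
            raise ValueError("itraq_threshold must exceed 1")
        lo, hi = self.pi_bin_boundaries
        if not lo < hi:
            raise ValueError("pI bin boundaries must be strictly increasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pi_bin_boundaries" in raw:
            raw["pi_bin_boundaries"] = tuple(raw["pi_bin_boundaries"])
        return cls(**raw)

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


def format_percent(value: float) -> str:
    """Render a percentage to 1 decimal, rounding half away from zero.

    100*901/1104 renders "81.6".
    """
    return str(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _parse_replicon_map(path: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 tab-separated columns")
        mapping[parts[0]] = parts[1]
    return mapping


def read_proteome(
    path: str | Path, replicon_map: str | Path | None = None
) -> list[ProteinRecord]:
    """Read a proteome FASTA, resolving replicon labels.

    The replicon may be encoded in the header as a ``replicon=LABEL`` token or
    supplied through a two-column TSV (id, replicon). Records with no known
    assignment get replicon ``"unassigned"``. Input order is preserved.

    Raises :class:`FormatError` on a duplicated id (naming it) or on any
    character outside the 20 standard amino acids (with its position).
    """
    mapping = _parse_replicon_map(replicon_map) if replicon_map is not None else {}
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        replicon = "unassigned"
        for token in rec.description.split():
            if token.startswith("replicon="):
                replicon = token.split("=", 1)[1]
        if rec.id in mapping:
            replicon = mapping[rec.id]
        records.append(ProteinRecord(rec.id, replicon, str(rec.seq).upper()))
    return records


def write_proteome(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} replicon={rec.replicon}\n{rec.sequence}\n")


def read_psm_table(path: str | Path, host: str) -> PSMTable:
    """Read a per-replicate spectral count TSV.

    Header ``protein_id<TAB>rep1...repN``; every cell a non-negative integer.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file (header row required)")
    header = lines[0].split("\t")
    if header[0] != "protein_id" or len(header) < 2:
        raise FormatError(f"{path}: header must be 'protein_id<TAB>rep1...repN'")
    n_replicates = len(header) - 1
    counts: dict[str, tuple[int, ...]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != n_replicates + 1:
            raise FormatError(
                f"{path}: line {lineno}: expected {n_replicates + 1} columns, "
                f"got {len(cells)}"
            )
        row: list[int] = []
        for col, cell in enumerate(cells[1:], start=2):
            try:
                value = int(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}, column {col}: non-integer cell {cell!r}"
                ) from None
            if value < 0:
                raise FormatError(
                    f"{path}: line {lineno}, column {col}: negative count {value}"
                )
            row.append(value)
        if cells[0] in counts:
            raise FormatError(f"{path}: line {lineno}: duplicate protein id {cells[0]!r}")
        counts[cells[0]] = tuple(row)
    return PSMTable(host=host, replicate_counts=counts, n_replicates=n_replicates)


def write_psm_table(table: PSMTable, path: str | Path) -> None:
    """Write a PSMTable so that :func:`read_psm_table` round-trips it exactly."""
    with open(path, "w") as fh:
        reps = "\t".join(f"rep{i + 1}" for i in range(table.n_replicates))
        fh.write(f"protein_id\t{reps}\n")
        for pid in table.replicate_counts:
            row = "\t".join(str(c) for c in table.replicate_counts[pid])
            fh.write(f"{pid}\t{row}\n")


def write_report(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write result tables as TSV files with deterministic column order.

    Returns the written paths. Re-running on identical inputs produces
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(tables):
        path = out / f"{name}.tsv"
        tables[name].to_csv(path, sep="\t", index=False, lineterminator="\n")
        written.append(path)
        logger.info("report: wrote %s (%d rows)", path, len(tables[name]))
    return written


def read_fasta_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Read any FASTA as (id, sequence) pairs, order preserved."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(pairs: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in pairs:
            fh.write(f">{name}\n{seq}\n")
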