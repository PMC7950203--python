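"""RPSM computation, replicate aggregation and replicon summaries.

RPSM normalises a protein's spectral count (PSM) by the number of tryptic
peptides the protein can theoretically yield, so that long proteins do not
dominate the abundance ranking:

    RPSM = 100 * PSM / n_predicted_tryptic_peptides

Also includes the percentage arithmetic used for symbiotic-performance
comparisons (percent reduction of a treatment mean versus a reference mean).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from rhizoquant.io import ProteinRecord, PSMTable, format_percent


@dataclass(frozen=True)
class QuantRecord:
    """Per-protein RPSM values and replicate aggregates."""

    id: str
    rpsm_per_replicate: tuple[float, ...]
    mean_rpsm: float
    accumulated_psm: int
    n_predicted_peptides: int
    in_all_replicates: bool

    @property
    def dispersion(self) -> float:
        """(max - min) / mean of per-replicate RPSM; 0 when the mean is 0."""
        if self.mean_rpsm == 0:
            return 0.0
        return (max(self.rpsm_per_replicate) - min(self.rpsm_per_replicate)) / self.mean_rpsm


@dataclass(frozen=True)
class RepliconSummary:
    """Identified-protein counts and percentages per replicon."""

    counts: Mapping[str, int]
    total: int
    denominator: int

    @property
    def percentages(self) -> dict[str, float]:
        return {rep: 100.0 * n / self.denominator for rep, n in self.counts.items()}

    @property
    def formatted_percentages(self) -> dict[str, str]:
        return {rep: format_percent(p) for rep, p in self.percentages.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "replicon": rep,
                "count": n,
                "percent": f"({self.formatted_percentages[rep]}%)",
            }
            for rep, n in self.counts.items()
        ]
        rows.append({"replicon": "Total", "count": self.total, "percent": ""})
        return pd.DataFrame(rows, columns=["replicon", "count", "percent"])

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, int], denominator: int | None = None
    ) -> "RepliconSummary":
        total = sum(counts.values())
        denom = total if denominator is None else denominator
        if denom <= 0:
            raise ValueError("summary denominator must be positive")
        return cls(counts=dict(counts), total=total, denominator=denom)


def compute_rpsm(psm: int, n_predicted: int) -> float:
    """RPSM = 100 * PSM / predicted tryptic peptides."""
    if psm < 0:
        raise ValueError("PSM count must be non-negative")
    if n_predicted < 1:
        raise ValueError("protein yields no predicted peptides")
    return 100.0 * psm / n_predicted


def aggregate_replicates(
    table: PSMTable, denominators: Mapping[str, int]
) -> list[QuantRecord]:
    """Per-protein RPSM aggregates over the replicates of one host.

    Proteins detected in at least one replicate are retained, flagged with
    ``in_all_replicates``. A protein listed in the table but missing from
    ``denominators`` is a hard error.
    """
    records: list[QuantRecord] = []
    for pid in table.replicate_counts:
        if pid not in denominators:
            raise KeyError(f"no predicted-peptide denominator for protein {pid!r}")
        counts = table.counts(pid)
        rpsm = tuple(compute_rpsm(c, denominators[pid]) for c in counts)
        records.append(
            QuantRecord(
                id=pid,
                rpsm_per_replicate=rpsm,
                mean_rpsm=sum(rpsm) / len(rpsm),
                accumulated_psm=sum(counts),
                n_predicted_peptides=denominators[pid],
                in_all_replicates=all(c > 0 for c in counts),
            )
        )
    return records


def replicon_summary(
    ids: Iterable[str],
    proteome: Sequence[ProteinRecord],
    denominator: int | None = None,
) -> RepliconSummary:
    """Distribution of a set of identified proteins across replicons.

    Percentages are computed against the column total by default, or against
    an explicitly supplied denominator (used e.g. when a published genome
    total differs from the sum of per-replicon counts).
    """
    by_id = {rec.id: rec.replicon for rec in proteome}
    replicon_order: list[str] = []
    for rec in proteome:
        if rec.replicon not in replicon_order:
            replicon_order.append(rec.replicon)
    counts = {rep: 0 for rep in replicon_order}
    for pid in sorted(set(ids)):
        if pid not in by_id:
            raise KeyError(f"protein {pid!r} not present in the proteome")
        counts[by_id[pid]] += 1
    return RepliconSummary.from_counts(counts, denominator)


def percent_reduction(mean_reference: float, mean_treatment: float) -> int:
    """Percent decrease of a treatment mean versus a reference mean.

    Returned rounded to the nearest integer (half away from zero), the
    reporting convention for symbiotic-performance comparisons.
    """
    if mean_reference <= 0:
        raise ValueError("reference mean must be positive")
    value = 100.0 * (mean_reference - mean_treatment) / mean_reference
    return int(Decimal(repr(value)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def quant_frame(records: Sequence[QuantRecord]) -> pd.DataFrame:
    """QuantRecords as a tidy table, one row per protein."""
    return pd.DataFrame(
        {
            "protein_id": [r.id for r in records],
            "mean_rpsm": [round(r.mean_rpsm, 1) for r in records],
            "accumulated_psm": [r.accumulated_psm for r in records],
            "n_predicted_peptides": [r.n_predicted_peptides for r in records],
            "in_all_replicates": [r.in_all_replicates for r in records],
        }
    )
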