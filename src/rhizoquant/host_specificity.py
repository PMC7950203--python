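"""Differential calls between two hosts: presence/absence and iTRAQ ratios.

A protein is host-specific when it is detected in every replicate from one
host, with an accumulated spectral count of at least ``min_accumulated``
(default 10) in that host, and has zero spectra in every replicate from the
other host. The iTRAQ classifier labels a pea/lentil ratio as significant
when it reaches 2 (pea-overrepresented) or 0.5 (lentil-overrepresented);
both boundaries are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from rhizoquant.io import ITRAQRecord, PSMTable


@dataclass(frozen=True)
class HostSpecificCall:
    """A protein called specific to one host."""

    id: str
    host: str
    accumulated_psm_in_host: int
    presence_flags: tuple[bool, ...]


def _specific_to(
    pid: str, own: tuple[int, ...], other: tuple[int, ...], min_accumulated: int
) -> bool:
    return (
        all(c > 0 for c in own)
        and sum(own) >= min_accumulated
        and all(c == 0 for c in other)
    )


def call_host_specific(
    table_a: PSMTable, table_b: PSMTable, min_accumulated: int = 10
) -> tuple[list[HostSpecificCall], list[HostSpecificCall]]:
    """Host-specific proteins for each of two hosts.

    A protein absent from a table counts as zero in all of that host's
    replicates. The two returned sets are necessarily disjoint. Results are
    sorted by protein id.
    """
    if min_accumulated < 0:
        raise ValueError("min_accumulated must be non-negative")
    calls_a: list[HostSpecificCall] = []
    calls_b: list[HostSpecificCall] = []
    for pid in sorted(table_a.ids | table_b.ids):
        a, b = table_a.counts(pid), table_b.counts(pid)
        if _specific_to(pid, a, b, min_accumulated):
            calls_a.append(
                HostSpecificCall(pid, table_a.host, sum(a), tuple(c > 0 for c in a))
            )
        elif _specific_to(pid, b, a, min_accumulated):
            calls_b.append(
                HostSpecificCall(pid, table_b.host, sum(b), tuple(c > 0 for c in b))
            )
    return calls_a, calls_b


def classify_itraq(ratio: float, threshold: float = 2.0) -> str:
    """Classify a pea/lentil iTRAQ ratio.

    ``ratio >= threshold`` -> ``"pea_over"``; ``ratio <= 1/threshold`` ->
    ``"lentil_over"``; otherwise ``"not_significant"``. Boundaries are
    inclusive: ratios printed as 2.00 and 0.50 are significant.
    """
    if threshold <= 1:
        raise ValueError("iTRAQ threshold must exceed 1")
    if not ratio > 0:
        raise ValueError("iTRAQ ratio must be positive")
    if ratio >= threshold:
        return "pea_over"
    if ratio <= 1.0 / threshold:
        return "lentil_over"
    return "not_significant"


def classify_itraq_table(
    ratios: Mapping[str, float], threshold: float = 2.0
) -> list[ITRAQRecord]:
    return [
        ITRAQRecord(pid, ratio, classify_itraq(ratio, threshold))
        for pid, ratio in ratios.items()
    ]


def reconcile_calls(
    presence_calls: Iterable[HostSpecificCall],
    itraq_records: Sequence[ITRAQRecord],
    host_a: str = "pea",
) -> pd.DataFrame:
    """Merge presence/absence calls with iTRAQ labels per protein.

    A protein specific to one host is usually not measurable by iTRAQ (it is
    absent in the other channel); its iTRAQ column then reads
    ``"not_measurable"`` and the methods agree. The two methods conflict only
    when both speak and point at different hosts.
    """
    itraq_by_id = {rec.id: rec for rec in itraq_records}
    label_host = {"pea_over": host_a, "lentil_over": _other(host_a)}
    rows = []
    calls_by_id = {c.id: c for c in presence_calls}
    for pid in sorted(set(calls_by_id) | set(itraq_by_id)):
        call = calls_by_id.get(pid)
        itraq = itraq_by_id.get(pid)
        presence_host = call.host if call else ""
        if itraq is None:
            itraq_label = "not_measurable"
        else:
            itraq_label = itraq.label
        itraq_host = label_host.get(itraq_label)
        if call is None or itraq_host is None or itraq_label == "not_significant":
            agreement = True  # one method silent
        else:
            agreement = itraq_host == presence_host
        rows.append(
            {
                "protein_id": pid,
                "presence_call": presence_host,
                "itraq_label": itraq_label,
                "itraq_ratio": itraq.ratio if itraq else float("nan"),
                "agreement": agreement,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "presence_call", "itraq_label", "itraq_ratio", "agreement"],
    )


def _other(host_a: str) -> str:
    return "lentil" if host_a == "pea" else "pea"
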