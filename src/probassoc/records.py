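"""The identification-record stream: one row per individual identification.

The canonical in-memory container is a pandas DataFrame with columns
``individual`` (str), ``event`` (str, the collection event such as
encounter x photographer), ``ordinal`` (numeric clock value within the
event — frame number or seconds), ``date`` (the sampling period, a calendar
date) and any number of extra attribute columns (e.g. ``data_type``,
``effort``, ``unit``).  A lightweight dataclass is provided for row-wise
construction; every analysis function accepts either form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import pandas as pd

__all__ = ["IdentificationRecord", "REQUIRED_COLUMNS", "records_to_frame"]

REQUIRED_COLUMNS = ("individual", "event", "ordinal", "date")


@dataclass(frozen=True)
class IdentificationRecord:
    """A single identification of one individual.

    Two individuals photographed in the same frame share an (event, ordinal)
    pair; duplicate ordinals within an event are therefore legitimate.
    """

    individual: str
    event: str
    ordinal: float
    date: Any  # datetime.date or ISO-8601 string
    attributes: Mapping[str, Any] = field(default_factory=dict)


def records_to_frame(records) -> pd.DataFrame:
    """Normalize a record stream to the canonical DataFrame.

    Accepts a DataFrame (validated and returned as-is, attribute columns
    preserved) or an iterable of :class:`IdentificationRecord` (attribute
    mappings expanded to columns).
    """
    if isinstance(records, pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"record table missing required columns: {missing}")
        if len(records) == 0:
            raise ValueError("empty record table")
        return records

    records = list(records)
    if not records:
        raise ValueError("empty record stream")
    rows = []
    for r in records:
        if not isinstance(r, IdentificationRecord):
            raise TypeError(f"expected IdentificationRecord, got {type(r).__name__}")
        row = {
            "individual": r.individual,
            "event": r.event,
            "ordinal": r.ordinal,
            "date": r.date,
        }
        row.update(r.attributes)
        rows.append(row)
    return pd.DataFrame(rows)
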