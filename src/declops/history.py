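"""Append-only execution log enabling provenance reconstruction.

Each execution that produced or overwrote an output appends one record
carrying the canonical request key, a stable digest of the resolved
InfoTree, and the identity of the written object.  The tree itself is not
stored — the digest is reconstructable by replaying the match against an
identical environment.
"""

from __future__ import annotations

import time
from dataclasses import dataclass


@dataclass(frozen=True)
class HistoryRecord:
    timestamp: float
    request_key: str
    tree_digest: str
    output_id: int


class OpHistory:
    def __init__(self) -> None:
        self.records: list[HistoryRecord] = []

    def record(self, request_key: str, tree_digest: str, output_id: int) -> HistoryRecord:
        rec = HistoryRecord(time.time(), request_key, tree_digest, output_id)
        self.records.append(rec)
        return rec

    def by_output(self, output_id: int) -> list[HistoryRecord]:
        """All records that wrote the object with this identity, oldest first."""
        return [r for r in self.records if r.output_id == output_id]

    def producing_digest(self, output_id: int) -> str | None:
        """Tree digest of the most recent op that wrote this object."""
        recs = self.by_output(output_id)
        return recs[-1].tree_digest if recs else None

    def __len__(self) -> int:
        return len(self.records)
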