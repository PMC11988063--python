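"""Quality-control audit ledger.

Every filtering stage in the pipeline reports a :class:`QCLedgerEntry`
(threshold used, how many units were screened, retained and dropped).  A
:class:`QCLedger` collects the entries of a multi-stage run and can compose
marginal drop counts into a cumulative retained count, which is how the
published-style summary tables are reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["QCLedgerEntry", "QCLedger"]


@dataclass(frozen=True)
class QCLedgerEntry:
    """One audit row: a filter, its threshold and its bookkeeping.

    Invariant: ``retained + dropped == screened``; violated entries refuse to
    construct so downstream arithmetic can trust the ledger.
    """

    stage_name: str
    threshold: str
    screened: int
    retained: int
    dropped: int
    unit: str = "records"

    def __post_init__(self) -> None:
        if self.screened < 0 or self.retained < 0 or self.dropped < 0:
            raise ValueError(f"negative count in ledger entry {self.stage_name!r}")
        if self.retained + self.dropped != self.screened:
            raise ValueError(
                f"ledger entry {self.stage_name!r} does not conserve counts: "
                f"{self.retained} + {self.dropped} != {self.screened}"
            )


@dataclass
class QCLedger:
    """Ordered collection of audit rows for a QC run."""

    entries: list[QCLedgerEntry] = field(default_factory=list)

    def append(self, entry: QCLedgerEntry) -> None:
        self.entries.append(entry)

    def extend(self, entries) -> None:
        for e in entries:
            self.append(e)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def cumulative_retained(self, unit: str, screened: int | None = None) -> int:
        """Compose marginal drop counts for one unit into a final retained count.

        Summary tables often report each filter against the same screened
        total; sequential application means the final count is the initial
        screened total minus the sum of marginal drops.
        """
        rows = [e for e in self.entries if e.unit == unit]
        if not rows:
            raise ValueError(f"no ledger entries with unit {unit!r}")
        start = rows[0].screened if screened is None else screened
        return start - sum(e.dropped for e in rows)

    def total_dropped(self, unit: str | None = None) -> int:
        rows = self.entries if unit is None else [e for e in self.entries if e.unit == unit]
        return sum(e.dropped for e in rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": e.stage_name,
                    "threshold": e.threshold,
                    "unit": e.unit,
                    "screened": e.screened,
                    "retained": e.retained,
                    "dropped": e.dropped,
                }
                for e in self.entries
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
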