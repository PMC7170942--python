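"""Injectable clocks.

The ledger timestamps blocks and the auth server expires tokens; both draw
from one clock object so tests can advance time deterministically.
"""

from __future__ import annotations

import time
from datetime import datetime, timezone

__all__ = ["SystemClock", "ManualClock", "epoch_to_iso"]


def epoch_to_iso(epoch: float) -> str:
    """Fixed-width ISO-8601 UTC; lexicographic order equals time order."""
    return datetime.fromtimestamp(epoch, tz=timezone.utc).strftime(
        "%Y-%m-%dT%H:%M:%S.%fZ"
    )


class SystemClock:
    def epoch(self) -> float:
        return time.time()

    def iso(self) -> str:
        return epoch_to_iso(self.epoch())


class ManualClock:
    """Deterministic clock: each reading advances by ``step`` seconds."""

    def __init__(self, start: float = 1_700_000_000.0, step: float = 1.0) -> None:
        self.now = start
        self.step = step

    def epoch(self) -> float:
        current = self.now
        self.now += self.step
        return current

    def iso(self) -> str:
        return epoch_to_iso(self.epoch())

    def advance(self, seconds: float) -> None:
        self.now += seconds
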