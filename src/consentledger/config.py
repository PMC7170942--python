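"""System configuration: keys, token lifetime, block/endorsement policy."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

__all__ = ["Config"]


@dataclass
class Config:
    """Everything an operator tunes, in one JSON-serializable record.

    ``seed`` makes key generation, UUIDs, passwords and nonces reproducible
    (tests, demos); leave it None in production for OS entropy.
    """

    seed: Optional[int] = None
    server_key_hex: Optional[str] = None  # 32-byte field-encryption key
    admin_seed_hex: Optional[str] = None  # network admin's Ed25519 seed
    client_id: str = "portal"
    client_secret: Optional[str] = None
    token_lifetime_s: float = 3600.0
    n_endorsers: int = 2
    batch_size: int = 1  # transactions per block; 1 = flush-per-transaction
    auto_flush: bool = True  # False models asynchronous consent commits

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Config":
        return cls(**json.loads(text))

    @classmethod
    def load(cls, path: str | Path) -> "Config":
        return cls.from_json(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())
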