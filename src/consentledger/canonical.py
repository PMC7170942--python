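"""Canonical byte serialization for ledger payloads.

Every hash and signature in the chain is computed over bytes produced here,
so the encoding must be bit-stable: UTF-8 JSON with lexicographically sorted
keys and no insignificant whitespace. Two structurally equal records always
serialize to identical byte strings.
"""

from __future__ import annotations

import json
import math
from typing import Any

__all__ = ["SerializationError", "canonical_serialize", "canonical_deserialize"]


class SerializationError(ValueError):
    """Raised when a record cannot be canonically encoded."""


_SCALARS = (type(None), bool, int, float, str)


def _check(value: Any, path: str) -> None:
    if isinstance(value, float):
        if not math.isfinite(value):
            raise SerializationError(f"non-finite number at {path}: {value!r}")
        return
    if isinstance(value, _SCALARS):
        return
    if isinstance(value, (list, tuple)):
        for i, item in enumerate(value):
            _check(item, f"{path}[{i}]")
        return
    if isinstance(value, dict):
        for key, item in value.items():
            if not isinstance(key, str):
                raise SerializationError(f"non-string key at {path}: {key!r}")
            _check(item, f"{path}.{key}")
        return
    raise SerializationError(f"unserializable value at {path}: {type(value).__name__}")


def canonical_serialize(record: Any) -> bytes:
    """Encode ``record`` to deterministic UTF-8 JSON bytes.

    Only finite scalars, strings, lists/tuples and string-keyed maps are
    accepted. Key order in the input is irrelevant: keys are sorted.
    """
    _check(record, "$")
    return json.dumps(
        record, sort_keys=True, separators=(",", ":"), ensure_ascii=False, allow_nan=False
    ).encode("utf-8")


def canonical_deserialize(data: bytes) -> Any:
    """Inverse of :func:`canonical_serialize` (accepts any valid JSON)."""
    try:
        return json.loads(data.decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise SerializationError(str(exc)) from exc
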