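"""Salted password hashing (PBKDF2-HMAC-SHA256, stdlib).

Stored form: ``pbkdf2_sha256$<iterations>$<salt hex>$<dk hex>``. Iteration
count is configurable and recorded per hash, so it can be raised later
without invalidating existing records.
"""

from __future__ import annotations

import hashlib
import hmac
import secrets
from random import Random

__all__ = ["hash_password", "verify_password"]

_DEFAULT_ITERATIONS = 50_000
_SALT_LEN = 16


def hash_password(
    password: str,
    iterations: int = _DEFAULT_ITERATIONS,
    rng: Random | None = None,
) -> str:
    if rng is None:
        salt = secrets.token_bytes(_SALT_LEN)
    else:
        salt = rng.getrandbits(_SALT_LEN * 8).to_bytes(_SALT_LEN, "big")
    dk = hashlib.pbkdf2_hmac("sha256", password.encode("utf-8"), salt, iterations)
    return f"pbkdf2_sha256${iterations}${salt.hex()}${dk.hex()}"


def verify_password(password: str, stored: str) -> bool:
    try:
        scheme, iters, salt_hex, dk_hex = stored.split("$")
        if scheme != "pbkdf2_sha256":
            return False
        salt = bytes.fromhex(salt_hex)
        expected = bytes.fromhex(dk_hex)
        iterations = int(iters)
    except (ValueError, AttributeError):
        return False
    dk = hashlib.pbkdf2_hmac("sha256", password.encode("utf-8"), salt, iterations)
    return hmac.compare_digest(dk, expected)
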