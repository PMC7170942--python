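"""Authenticated symmetric encryption (encrypt-then-MAC, stdlib only).

Layout of a sealed blob: ``nonce(16) || ciphertext || tag(32)``.

The keystream is HMAC-SHA256 in counter mode keyed with a derived
encryption subkey; the tag is HMAC-SHA256 over nonce+ciphertext with a
distinct MAC subkey. Decryption verifies the tag in constant time before
touching the ciphertext, so truncation or any bit flip fails closed.
"""

from __future__ import annotations

import hmac
import hashlib
import secrets
from random import Random

__all__ = ["AuthenticationError", "seal", "open_box"]

_NONCE_LEN = 16
_TAG_LEN = 32
_BLOCK = 32


class AuthenticationError(ValueError):
    """Ciphertext failed authentication (tampered, truncated, wrong key)."""


def _subkeys(key: bytes) -> tuple[bytes, bytes]:
    if len(key) != 32:
        raise ValueError("box key must be 32 bytes")
    enc = hmac.new(key, b"consentledger.box.enc", hashlib.sha256).digest()
    mac = hmac.new(key, b"consentledger.box.mac", hashlib.sha256).digest()
    return enc, mac


def _keystream(enc_key: bytes, nonce: bytes, length: int) -> bytes:
    out = bytearray()
    counter = 0
    while len(out) < length:
        out += hmac.new(
            enc_key, nonce + counter.to_bytes(8, "big"), hashlib.sha256
        ).digest()
        counter += 1
    return bytes(out[:length])


def seal(key: bytes, plaintext: bytes, rng: Random | None = None) -> bytes:
    """Encrypt and authenticate ``plaintext`` under ``key`` (32 bytes).

    ``rng`` makes the nonce reproducible in tests; production callers leave
    it None and get an OS-random nonce.
    """
    enc_key, mac_key = _subkeys(key)
    if rng is None:
        nonce = secrets.token_bytes(_NONCE_LEN)
    else:
        nonce = rng.getrandbits(_NONCE_LEN * 8).to_bytes(_NONCE_LEN, "big")
    stream = _keystream(enc_key, nonce, len(plaintext))
    ciphertext = bytes(a ^ b for a, b in zip(plaintext, stream))
    tag = hmac.new(mac_key, nonce + ciphertext, hashlib.sha256).digest()
    return nonce + ciphertext + tag


def open_box(key: bytes, blob: bytes) -> bytes:
    """Verify and decrypt a blob produced by :func:`seal`."""
    enc_key, mac_key = _subkeys(key)
    if len(blob) < _NONCE_LEN + _TAG_LEN:
        raise AuthenticationError("blob too short")
    nonce = blob[:_NONCE_LEN]
    ciphertext = blob[_NONCE_LEN:-_TAG_LEN]
    tag = blob[-_TAG_LEN:]
    expected = hmac.new(mac_key, nonce + ciphertext, hashlib.sha256).digest()
    if not hmac.compare_digest(tag, expected):
        raise AuthenticationError("authentication tag mismatch")
    stream = _keystream(enc_key, nonce, len(ciphertext))
    return bytes(a ^ b for a, b in zip(ciphertext, stream))
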