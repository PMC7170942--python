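"""Ed25519 digital signatures (RFC 8032, pure Python).

Implements the twisted Edwards curve edwards25519 with extended homogeneous
coordinates. Deterministic signing per RFC 8032: the per-message nonce is
derived from the key's hashed prefix, so signing the same payload with the
same key always yields the same signature — a property the ledger's
byte-identical-chain determinism relies on.

Performance note: scalar multiplication is plain double-and-add on Python
big ints (~ms per operation), ample for a consent ledger whose transaction
rate is human-scale.
"""

from __future__ import annotations

import hashlib
from typing import Tuple

__all__ = ["KeyError_", "generate_keypair", "public_from_seed", "sign", "verify"]


class KeyError_(ValueError):
    """Raised for malformed key or signature material."""


_P = 2**255 - 19
_L = 2**252 + 27742317777372353535851937790883648493
_D = (-121665 * pow(121666, _P - 2, _P)) % _P
_SQRT_M1 = pow(2, (_P - 1) // 4, _P)

# Extended homogeneous coordinates (X, Y, Z, T) with x = X/Z, y = Y/Z, T = XY/Z.
_Point = Tuple[int, int, int, int]
_IDENTITY: _Point = (0, 1, 1, 0)


def _sha512(data: bytes) -> bytes:
    return hashlib.sha512(data).digest()


def _point_add(p: _Point, q: _Point) -> _Point:
    x1, y1, z1, t1 = p
    x2, y2, z2, t2 = q
    a = (y1 - x1) * (y2 - x2) % _P
    b = (y1 + x1) * (y2 + x2) % _P
    c = t1 * 2 * _D * t2 % _P
    d = z1 * 2 * z2 % _P
    e = b - a
    f = d - c
    g = d + c
    h = b + a
    return (e * f % _P, g * h % _P, f * g % _P, e * h % _P)


def _point_mul(scalar: int, p: _Point) -> _Point:
    q = _IDENTITY
    while scalar:
        if scalar & 1:
            q = _point_add(q, p)
        p = _point_add(p, p)
        scalar >>= 1
    return q


def _point_equal(p: _Point, q: _Point) -> bool:
    # Cross-multiply to avoid inversions: x1/z1 == x2/z2, y1/z1 == y2/z2.
    return (
        (p[0] * q[2] - q[0] * p[2]) % _P == 0
        and (p[1] * q[2] - q[1] * p[2]) % _P == 0
    )


def _recover_x(y: int, sign: int) -> int | None:
    if y >= _P:
        return None
    x2 = (y * y - 1) * pow(_D * y * y + 1, _P - 2, _P) % _P
    if x2 == 0:
        return None if sign else 0
    x = pow(x2, (_P + 3) // 8, _P)
    if (x * x - x2) % _P != 0:
        x = x * _SQRT_M1 % _P
    if (x * x - x2) % _P != 0:
        return None
    if (x & 1) != sign:
        x = _P - x
    return x


_BY = 4 * pow(5, _P - 2, _P) % _P
_BX = _recover_x(_BY, 0)
assert _BX is not None
_B: _Point = (_BX, _BY, 1, _BX * _BY % _P)


def _point_compress(p: _Point) -> bytes:
    zinv = pow(p[2], _P - 2, _P)
    x = p[0] * zinv % _P
    y = p[1] * zinv % _P
    return int.to_bytes(y | ((x & 1) << 255), 32, "little")


def _point_decompress(data: bytes) -> _Point | None:
    if len(data) != 32:
        return None
    y = int.from_bytes(data, "little")
    sign = y >> 255
    y &= (1 << 255) - 1
    x = _recover_x(y, sign)
    if x is None:
        return None
    return (x, y, 1, x * y % _P)


def _secret_expand(seed: bytes) -> Tuple[int, bytes]:
    if len(seed) != 32:
        raise KeyError_("signing seed must be 32 bytes")
    h = _sha512(seed)
    a = int.from_bytes(h[:32], "little")
    a &= (1 << 254) - 8
    a |= 1 << 254
    return a, h[32:]


def public_from_seed(seed: bytes) -> bytes:
    """Derive the 32-byte public verification key from a 32-byte seed."""
    a, _ = _secret_expand(seed)
    return _point_compress(_point_mul(a, _B))


def generate_keypair(seed: bytes) -> Tuple[bytes, bytes]:
    """Return ``(seed, public_key)`` for a caller-supplied 32-byte seed.

    The seed is the private key; callers draw it from their own entropy
    source (``secrets.token_bytes`` or a seeded test RNG).
    """
    return seed, public_from_seed(seed)


def sign(seed: bytes, message: bytes) -> bytes:
    """Produce a 64-byte detached signature over ``message``."""
    a, prefix = _secret_expand(seed)
    public = _point_compress(_point_mul(a, _B))
    r = int.from_bytes(_sha512(prefix + message), "little") % _L
    r_point = _point_compress(_point_mul(r, _B))
    k = int.from_bytes(_sha512(r_point + public + message), "little") % _L
    s = (r + k * a) % _L
    return r_point + int.to_bytes(s, 32, "little")


def verify(public: bytes, message: bytes, signature: bytes) -> bool:
    """True iff ``signature`` is a valid Ed25519 signature by ``public``.

    Never raises on malformed input: bad lengths or non-curve points
    simply verify as False.
    """
    if not isinstance(public, bytes) or not isinstance(signature, bytes):
        return False
    if len(public) != 32 or len(signature) != 64:
        return False
    a_point = _point_decompress(public)
    if a_point is None:
        return False
    r_bytes = signature[:32]
    r_point = _point_decompress(r_bytes)
    if r_point is None:
        return False
    s = int.from_bytes(signature[32:], "little")
    if s >= _L:
        return False
    k = int.from_bytes(_sha512(r_bytes + public + message), "little") % _L
    sb = _point_mul(s, _B)
    rka = _point_add(r_point, _point_mul(k, a_point))
    return _point_equal(sb, rka)
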