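import hashlib
import io
import json
from random import Random

import pytest

from consentledger.config import Config
from consentledger.system import ConsentSystem


@pytest.fixture
def system() -> ConsentSystem:
    """Seeded in-memory system: deterministic keys, UUIDs and clock."""
    return ConsentSystem(config=Config(seed=42))


@pytest.fixture
def rng() -> Random:
    return Random(20_240_101)


def random_digests(rng: Random, n: int) -> list[bytes]:
    return [
        hashlib.sha256(rng.getrandbits(64).to_bytes(8, "big")).digest()
        for _ in range(n)
    ]


def wsgi_call(app, method, path, body=None, token=None, query=""):
    """Drive a WSGI app in-process; returns (status_code, parsed_json)."""
    raw = json.dumps(body).encode() if body is not None else b""
    environ = {
        "REQUEST_METHOD": method,
        "PATH_INFO": path,
        "QUERY_STRING": query,
        "CONTENT_LENGTH": str(len(raw)),
        "wsgi.input": io.BytesIO(raw),
    }
    if token is not None:
        environ["HTTP_AUTHORIZATION"] = f"Bearer {token}"
    captured = {}

    def start_response(status, headers):
        captured["status"] = status

    payload = b"".join(app(environ, start_response))
    return int(captured["status"].split()[0]), json.loads(payload)
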