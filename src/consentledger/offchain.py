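"""The erasable half of the architecture: the off-chain identity store.

The portal knows partners only by a biobank-assigned pseudonym (their
login username); personal fields (name, email, contact) are stored as
authenticated ciphertext under a single server key; passwords as salted
hashes. For each study a partner joins, a fresh random UUID — their
on-chain identity — is issued and packaged in an identity card that starts
without credentials and is later credentialed with encrypted Ed25519 key
material.

The link table (pseudonym, study, uuid) is the ONLY mapping between portal
identities and on-chain identities. The right to erasure is implemented as
link severance: hard-deleting a partner's rows makes their on-chain assets
unattributable while the chain itself — lengths, hashes, verdicts — is
untouched.
"""

from __future__ import annotations

import sqlite3
import string
import uuid as uuid_module
from dataclasses import dataclass
from random import Random
from typing import Callable, List, Optional, Tuple

from consentledger.crypto import box, passwords

__all__ = [
    "OffchainError",
    "DuplicateError",
    "UnknownPartnerError",
    "PartnerRecord",
    "IdentityCard",
    "OffchainStore",
    "linkage_audit",
]


class OffchainError(ValueError):
    pass


class DuplicateError(OffchainError):
    pass


class UnknownPartnerError(OffchainError):
    pass


@dataclass(frozen=True)
class PartnerRecord:
    pseudonym: str
    email_encrypted: bytes
    name_encrypted: bytes
    contact_encrypted: bytes
    password_hash: str
    created_at: str


@dataclass(frozen=True)
class IdentityCard:
    pseudonym: str
    study_id: str
    uuid: str
    status: str  # issued | credentialed
    credentials_encrypted: Optional[bytes]


_SCHEMA = """
CREATE TABLE IF NOT EXISTS partners (
    pseudonym TEXT PRIMARY KEY,
    email_enc BLOB NOT NULL,
    name_enc BLOB NOT NULL,
    contact_enc BLOB NOT NULL,
    password_hash TEXT NOT NULL,
    created_at TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS researchers (
    researcher_id TEXT PRIMARY KEY,
    name_enc BLOB NOT NULL
);
CREATE TABLE IF NOT EXISTS managers (
    manager_id TEXT PRIMARY KEY
);
CREATE TABLE IF NOT EXISTS studies (
    study_id TEXT PRIMARY KEY,
    created_at TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS study_researchers (
    study_id TEXT NOT NULL,
    researcher_id TEXT NOT NULL,
    PRIMARY KEY (study_id, researcher_id)
);
CREATE TABLE IF NOT EXISTS cards (
    pseudonym TEXT NOT NULL,
    study_id TEXT NOT NULL,
    uuid TEXT NOT NULL UNIQUE,
    status TEXT NOT NULL,
    credentials_enc BLOB,
    PRIMARY KEY (pseudonym, study_id)
);
CREATE TABLE IF NOT EXISTS links (
    pseudonym TEXT NOT NULL,
    study_id TEXT NOT NULL,
    uuid TEXT NOT NULL,
    PRIMARY KEY (pseudonym, study_id)
);
CREATE TABLE IF NOT EXISTS interest_queue (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    name TEXT NOT NULL,
    contact TEXT NOT NULL,
    created_at TEXT NOT NULL
);
"""

_PASSWORD_ALPHABET = string.ascii_letters + string.digits
_PASSWORD_LEN = 16


class OffchainStore:
    """Relational store for partners, studies, cards and links.

    ``rng`` drives password, nonce, UUID and key-seed generation; seed it
    for reproducible tests, leave the default for OS entropy via the
    underlying primitives.
    """

    def __init__(
        self,
        server_key: bytes,
        path: str = ":memory:",
        rng: Optional[Random] = None,
        clock: Optional[Callable[[], str]] = None,
    ) -> None:
        self.server_key = server_key
        self.rng = rng if rng is not None else Random()
        self.clock = clock or (lambda: "1970-01-01T00:00:00Z")
        self.db = sqlite3.connect(path)
        self.db.executescript(_SCHEMA)
        self.db.commit()

    # -- partner registry ---------------------------------------------------

    def register_partner(
        self, pseudonym: str, name: str, email: str, contact: str
    ) -> Tuple[PartnerRecord, str]:
        """Create a partner profile; returns the record and the generated
        password (credential delivery is outside this system)."""
        cur = self.db.execute(
            "SELECT 1 FROM partners WHERE pseudonym = ?", (pseudonym,)
        )
        if cur.fetchone():
            raise DuplicateError(f"pseudonym {pseudonym!r} already registered")
        password = "".join(
            self.rng.choice(_PASSWORD_ALPHABET) for _ in range(_PASSWORD_LEN)
        )
        record = PartnerRecord(
            pseudonym=pseudonym,
            email_encrypted=box.seal(self.server_key, email.encode(), self.rng),
            name_encrypted=box.seal(self.server_key, name.encode(), self.rng),
            contact_encrypted=box.seal(self.server_key, contact.encode(), self.rng),
            password_hash=passwords.hash_password(password, rng=self.rng),
            created_at=self.clock(),
        )
        self.db.execute(
            "INSERT INTO partners VALUES (?,?,?,?,?,?)",
            (
                record.pseudonym,
                record.email_encrypted,
                record.name_encrypted,
                record.contact_encrypted,
                record.password_hash,
                record.created_at,
            ),
        )
        self.db.commit()
        return record, password

    def get_partner(self, pseudonym: str) -> Optional[PartnerRecord]:
        cur = self.db.execute(
            "SELECT pseudonym, email_enc, name_enc, contact_enc, password_hash,"
            " created_at FROM partners WHERE pseudonym = ?",
            (pseudonym,),
        )
        row = cur.fetchone()
        if row is None:
            return None
        return PartnerRecord(*row)

    def decrypt_field(self, ciphertext: bytes) -> str:
        return box.open_box(self.server_key, ciphertext).decode()

    def partner_pseudonyms(self) -> List[str]:
        return [r[0] for r in self.db.execute("SELECT pseudonym FROM partners")]

    # -- researchers / studies ---------------------------------------------

    def add_researcher(self, researcher_id: str, name: str) -> None:
        try:
            self.db.execute(
                "INSERT INTO researchers VALUES (?,?)",
                (researcher_id, box.seal(self.server_key, name.encode(), self.rng)),
            )
        except sqlite3.IntegrityError as exc:
            raise DuplicateError(str(exc)) from exc
        self.db.commit()

    def add_study(self, study_id: str, researcher_ids: List[str] = ()) -> None:
        try:
            self.db.execute(
                "INSERT INTO studies VALUES (?,?)", (study_id, self.clock())
            )
        except sqlite3.IntegrityError as exc:
            raise DuplicateError(f"study {study_id!r} already exists") from exc
        for rid in researcher_ids:
            self.db.execute(
                "INSERT OR IGNORE INTO study_researchers VALUES (?,?)",
                (study_id, rid),
            )
        self.db.commit()

    def researcher_attached(self, researcher_id: str, study_id: str) -> bool:
        cur = self.db.execute(
            "SELECT 1 FROM study_researchers WHERE study_id=? AND researcher_id=?",
            (study_id, researcher_id),
        )
        return cur.fetchone() is not None

    # -- identity cards ------------------------------------------------------

    def _fresh_uuid(self) -> str:
        return str(uuid_module.UUID(int=self.rng.getrandbits(128), version=4))

    def issue_identity(self, pseudonym: str, study_id: str) -> IdentityCard:
        """Issue (or return the existing) per-(partner, study) identity.

        A fresh version-4 UUID, distinct from every prior one and from the
        biobank pseudonym, becomes the partner's on-chain identity for this
        study; one link-table row records the mapping.
        """
        if self.get_partner(pseudonym) is None:
            raise UnknownPartnerError(f"no partner {pseudonym!r}")
        existing = self.resolve_identity(pseudonym, study_id)
        if existing is not None:
            return existing
        new_uuid = self._fresh_uuid()
        card = IdentityCard(
            pseudonym=pseudonym,
            study_id=study_id,
            uuid=new_uuid,
            status="issued",
            credentials_encrypted=None,
        )
        self.db.execute(
            "INSERT INTO cards VALUES (?,?,?,?,?)",
            (pseudonym, study_id, new_uuid, "issued", None),
        )
        self.db.execute(
            "INSERT INTO links VALUES (?,?,?)", (pseudonym, study_id, new_uuid)
        )
        self.db.commit()
        return card

    def resolve_identity(
        self, pseudonym: str, study_id: str
    ) -> Optional[IdentityCard]:
        cur = self.db.execute(
            "SELECT pseudonym, study_id, uuid, status, credentials_enc"
            " FROM cards WHERE pseudonym=? AND study_id=?",
            (pseudonym, study_id),
        )
        row = cur.fetchone()
        return IdentityCard(*row) if row else None

    def credential_card(self, pseudonym: str, study_id: str) -> IdentityCard:
        """issued → credentialed: generate and encrypt signing-key material.

        Idempotent: a card that already has credentials is returned as-is,
        so it is reusable across sessions without re-credentialing.
        """
        card = self.resolve_identity(pseudonym, study_id)
        if card is None:
            raise UnknownPartnerError(
                f"no identity card for ({pseudonym!r}, {study_id!r})"
            )
        if card.status == "credentialed":
            return card
        seed = self.rng.getrandbits(256).to_bytes(32, "big")
        enc = box.seal(self.server_key, seed, self.rng)
        self.db.execute(
            "UPDATE cards SET status='credentialed', credentials_enc=?"
            " WHERE pseudonym=? AND study_id=?",
            (enc, pseudonym, study_id),
        )
        self.db.commit()
        return IdentityCard(pseudonym, study_id, card.uuid, "credentialed", enc)

    def card_signing_seed(self, pseudonym: str, study_id: str) -> bytes:
        card = self.resolve_identity(pseudonym, study_id)
        if card is None or card.status != "credentialed":
            raise UnknownPartnerError("card missing or not credentialed")
        assert card.credentials_encrypted is not None
        return box.open_box(self.server_key, card.credentials_encrypted)

    def cards_for(self, pseudonym: str) -> List[IdentityCard]:
        cur = self.db.execute(
            "SELECT pseudonym, study_id, uuid, status, credentials_enc"
            " FROM cards WHERE pseudonym=?",
            (pseudonym,),
        )
        return [IdentityCard(*row) for row in cur.fetchall()]

    def link_rows(self) -> List[Tuple[str, str, str]]:
        return list(self.db.execute("SELECT pseudonym, study_id, uuid FROM links"))

    # -- erasure -------------------------------------------------------------

    def erase_partner(self, pseudonym: str) -> dict:
        """Right to erasure by link severance: hard-delete the partner's
        profile, cards, links and login credentials. On-chain data are not
        touched — they simply become unattributable.
        """
        if self.get_partner(pseudonym) is None:
            raise UnknownPartnerError(f"no partner {pseudonym!r}")
        n_cards = self.db.execute(
            "SELECT COUNT(*) FROM cards WHERE pseudonym=?", (pseudonym,)
        ).fetchone()[0]
        n_links = self.db.execute(
            "SELECT COUNT(*) FROM links WHERE pseudonym=?", (pseudonym,)
        ).fetchone()[0]
        self.db.execute("DELETE FROM cards WHERE pseudonym=?", (pseudonym,))
        self.db.execute("DELETE FROM links WHERE pseudonym=?", (pseudonym,))
        self.db.execute("DELETE FROM partners WHERE pseudonym=?", (pseudonym,))
        self.db.commit()
        return {"pseudonym": pseudonym, "cards": n_cards, "links": n_links}

    # -- interest queue ------------------------------------------------------

    def express_interest(self, name: str, contact: str) -> dict:
        if not name.strip() or not contact.strip():
            raise OffchainError("name and contact are required")
        cur = self.db.execute(
            "INSERT INTO interest_queue (name, contact, created_at) VALUES (?,?,?)",
            (name, contact, self.clock()),
        )
        self.db.commit()
        return {"id": cur.lastrowid, "name": name, "contact": contact}

    def interest_queue(self) -> List[dict]:
        return [
            {"id": i, "name": n, "contact": c, "created_at": t}
            for i, n, c, t in self.db.execute(
                "SELECT id, name, contact, created_at FROM interest_queue"
            )
        ]

    # -- raw view for at-rest inspection -------------------------------------

    def raw_dump(self) -> bytes:
        """Every byte persisted in the store, for at-rest leakage checks."""
        out = []
        for line in self.db.iterdump():
            out.append(line.encode("utf-8", "surrogateescape"))
        return b"\n".join(out)


def linkage_audit(
    pseudonyms: List[str],
    chain_serialization: bytes,
    link_rows: Optional[List[Tuple[str, str, str]]] = None,
) -> dict:
    """What pseudonym→UUID mappings can an attacker recover?

    With the chain alone, recovery requires a pseudonym to appear somewhere
    in the serialized chain — which never happens, because on-chain
    identities are per-study UUIDs. With the link table, every non-erased
    partner's mapping is trivially covered. The report quantifies both.
    """
    from_chain = set()
    for pseudonym in pseudonyms:
        if pseudonym.encode() in chain_serialization:
            from_chain.add(pseudonym)
    pairs = set()
    if link_rows:
        for pseudonym, _study, uuid in link_rows:
            pairs.add((pseudonym, uuid))
    # Chain-only recoverable pairs: pseudonyms leaked on-chain (none, by
    # construction) could be tied to the uuids of the txs they appear in.
    chain_only_pairs = {(p, "*") for p in from_chain}
    return {
        "pseudonyms_checked": len(pseudonyms),
        "pseudonyms_on_chain": sorted(from_chain),
        "recoverable_pairs_chain_only": sorted(chain_only_pairs),
        "recoverable_pairs_with_links": sorted(pairs),
        "coverage_with_links": sorted({p for p, _ in pairs}),
    }
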