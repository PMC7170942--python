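"""Token issuance and request validation (client-credentials style), plus
portal sessions.

The portal is the single registered client: it authenticates with its
client id and secret and requests short-lived access tokens scoped to named
capabilities and bound to the user on whose behalf it acts. The resource
side validates expiry, scope and ownership — a research partner's token
reaches only their own records unless a scope grants administrative reach.

Tokens are opaque random strings stored server-side, so erasing a partner
can revoke every outstanding token acting for them.
"""

from __future__ import annotations

import secrets
from dataclasses import dataclass
from random import Random
from typing import Dict, FrozenSet, Optional

from consentledger.clockutil import SystemClock
from consentledger.crypto import passwords

__all__ = ["AuthError", "AccessToken", "PortalSession", "Decision", "AuthServer"]

# Scopes whose holders may reach records they do not own.
ADMIN_SCOPES = frozenset({"manage_partners", "manage_researchers",
                          "manage_studies", "view_study_consents"})

DEFAULT_TOKEN_LIFETIME_S = 3600.0


class AuthError(ValueError):
    pass


@dataclass(frozen=True)
class AccessToken:
    token: str
    client_id: str
    acting_user: str
    scopes: FrozenSet[str]
    expires_at: float


@dataclass(frozen=True)
class PortalSession:
    pseudonym: str
    session_token: str
    expires_at: float


@dataclass(frozen=True)
class Decision:
    allow: bool
    reason: Optional[str] = None  # expired | scope | ownership | unknown

    def __bool__(self) -> bool:
        return self.allow


class AuthServer:
    def __init__(
        self,
        clock=None,
        rng: Optional[Random] = None,
        token_lifetime_s: float = DEFAULT_TOKEN_LIFETIME_S,
        session_lifetime_s: float = 8 * 3600.0,
    ) -> None:
        self.clock = clock or SystemClock()
        self.rng = rng
        self.token_lifetime_s = token_lifetime_s
        self.session_lifetime_s = session_lifetime_s
        self._clients: Dict[str, str] = {}  # client_id -> secret hash
        self._tokens: Dict[str, AccessToken] = {}
        self._sessions: Dict[str, PortalSession] = {}

    def _random_token(self) -> str:
        if self.rng is None:
            return secrets.token_hex(32)
        return self.rng.getrandbits(256).to_bytes(32, "big").hex()

    # -- clients -------------------------------------------------------------

    def register_client(self, client_id: str, secret: str) -> None:
        """Store the client's secret as a salted hash, never in plaintext."""
        self._clients[client_id] = passwords.hash_password(secret, rng=self.rng)

    # -- tokens --------------------------------------------------------------

    def issue_token(
        self, client_id: str, secret: str, scopes, acting_user: str
    ) -> AccessToken:
        stored = self._clients.get(client_id)
        if stored is None or not passwords.verify_password(secret, stored):
            raise AuthError("unknown client or bad secret")
        token = AccessToken(
            token=self._random_token(),
            client_id=client_id,
            acting_user=acting_user,
            scopes=frozenset(scopes),
            expires_at=self.clock.epoch() + self.token_lifetime_s,
        )
        self._tokens[token.token] = token
        return token

    def validate_request(
        self, token: str, required_scope: str, resource_owner: str
    ) -> Decision:
        """Allow iff the token exists, is unexpired, carries the scope, and
        either acts for the resource owner or holds an admin-reach scope."""
        record = self._tokens.get(token)
        if record is None:
            return Decision(False, "unknown")
        if self.clock.epoch() >= record.expires_at:
            return Decision(False, "expired")
        if required_scope not in record.scopes:
            return Decision(False, "scope")
        if record.acting_user != resource_owner and not (
            record.scopes & ADMIN_SCOPES
        ):
            return Decision(False, "ownership")
        return Decision(True)

    def token_record(self, token: str) -> Optional[AccessToken]:
        return self._tokens.get(token)

    def revoke_user_tokens(self, acting_user: str) -> int:
        doomed = [t for t, rec in self._tokens.items() if rec.acting_user == acting_user]
        for t in doomed:
            del self._tokens[t]
        return len(doomed)

    # -- portal sessions ------------------------------------------------------

    def create_session(self, pseudonym: str) -> PortalSession:
        session = PortalSession(
            pseudonym=pseudonym,
            session_token=self._random_token(),
            expires_at=self.clock.epoch() + self.session_lifetime_s,
        )
        self._sessions[session.session_token] = session
        return session

    def session_user(self, session_token: str) -> Optional[str]:
        """The portal-session strategy: is this user logged in, and who are
        they? Returns the pseudonym, or None for missing/expired sessions."""
        session = self._sessions.get(session_token)
        if session is None or self.clock.epoch() >= session.expires_at:
            return None
        return session.pseudonym

    def drop_user_sessions(self, pseudonym: str) -> int:
        doomed = [
            t for t, s in self._sessions.items() if s.pseudonym == pseudonym
        ]
        for t in doomed:
            del self._sessions[t]
        return len(doomed)
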