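"""REST surface: a plain WSGI JSON application over :class:`ConsentSystem`.

Framework-free so it runs anywhere a WSGI server does (and is testable
in-process without sockets). Bearer tokens in the Authorization header;
all denials return structured reason codes.

Routes
------
POST   /oauth/token                     client-credentials token issuance
POST   /login                           portal login → session token
POST   /partners                        manager: register partner
DELETE /partners/<pseudonym>            erasure (manager or self)
POST   /studies                         manager: create study
POST   /identities                      issue/fetch per-study identity
POST   /credentials                     credential an identity card
POST   /consent                         give/withdraw consent (signed)
GET    /consent/trail                   partner's own trail
GET    /consent/status                  partner's own current status
GET    /studies/<id>/consents           manager: all changes in a study
GET    /studies/<id>/aggregate          researcher: consented count only
POST   /interest                        public interest form
GET    /interest                        manager: queued interest records
GET    /chain/verify                    chain verification verdict
GET    /chain/dump                      chain as JSON lines
"""

from __future__ import annotations

import json
import re
from typing import Callable, Iterable, List, Tuple
from urllib.parse import parse_qs

from consentledger.access import AccessDenied
from consentledger.auth import AuthError
from consentledger.ledger import ValidationError
from consentledger.network import IdentityError, NotFoundError
from consentledger.offchain import DuplicateError, OffchainError, UnknownPartnerError
from consentledger.system import ConsentSystem

__all__ = ["RestApp", "serve"]

StartResponse = Callable[[str, List[Tuple[str, str]]], None]


class _HttpError(Exception):
    def __init__(self, status: int, reason: str):
        self.status = status
        self.reason = reason


def _status_line(code: int) -> str:
    names = {200: "OK", 201: "Created", 400: "Bad Request", 401: "Unauthorized",
             403: "Forbidden", 404: "Not Found", 409: "Conflict"}
    return f"{code} {names.get(code, 'Error')}"


class RestApp:
    """WSGI callable; one instance wraps one live system."""

    def __init__(self, system: ConsentSystem) -> None:
        self.system = system
        self.routes = [
            ("POST", re.compile(r"^/oauth/token$"), self._token),
            ("POST", re.compile(r"^/login$"), self._login),
            ("POST", re.compile(r"^/partners$"), self._create_partner),
            ("DELETE", re.compile(r"^/partners/(?P<pseudonym>[^/]+)$"), self._erase),
            ("POST", re.compile(r"^/studies$"), self._create_study),
            ("POST", re.compile(r"^/identities$"), self._identity),
            ("POST", re.compile(r"^/credentials$"), self._credential),
            ("POST", re.compile(r"^/consent$"), self._set_consent),
            ("GET", re.compile(r"^/consent/trail$"), self._trail),
            ("GET", re.compile(r"^/consent/status$"), self._status),
            ("GET", re.compile(r"^/studies/(?P<study_id>[^/]+)/consents$"),
             self._study_consents),
            ("GET", re.compile(r"^/studies/(?P<study_id>[^/]+)/aggregate$"),
             self._aggregate),
            ("POST", re.compile(r"^/interest$"), self._interest),
            ("GET", re.compile(r"^/interest$"), self._interest_queue),
            ("GET", re.compile(r"^/chain/verify$"), self._chain_verify),
            ("GET", re.compile(r"^/chain/dump$"), self._chain_dump),
        ]

    # -- WSGI ---------------------------------------------------------------

    def __call__(self, environ: dict, start_response: StartResponse) -> Iterable[bytes]:
        method = environ.get("REQUEST_METHOD", "GET")
        path = environ.get("PATH_INFO", "/")
        try:
            for verb, pattern, handler in self.routes:
                match = pattern.match(path)
                if match and verb == method:
                    status, payload = handler(environ, **match.groupdict())
                    break
            else:
                raise _HttpError(404, "no such endpoint")
        except _HttpError as exc:
            status, payload = exc.status, {"error": exc.reason}
        except (AccessDenied, AuthError) as exc:
            status, payload = 403, {"error": str(exc)}
        except (DuplicateError,) as exc:
            status, payload = 409, {"error": str(exc)}
        except (UnknownPartnerError, NotFoundError) as exc:
            status, payload = 404, {"error": str(exc)}
        except (IdentityError, ValidationError, OffchainError, ValueError) as exc:
            status, payload = 400, {"error": str(exc)}
        body = json.dumps(payload).encode()
        start_response(
            _status_line(status),
            [("Content-Type", "application/json"),
             ("Content-Length", str(len(body)))],
        )
        return [body]

    # -- helpers ------------------------------------------------------------

    @staticmethod
    def _body(environ: dict) -> dict:
        try:
            length = int(environ.get("CONTENT_LENGTH") or 0)
        except ValueError:
            length = 0
        raw = environ["wsgi.input"].read(length) if length else b""
        if not raw:
            return {}
        try:
            return json.loads(raw)
        except json.JSONDecodeError:
            raise _HttpError(400, "invalid JSON body")

    @staticmethod
    def _query(environ: dict) -> dict:
        return {k: v[0] for k, v in parse_qs(environ.get("QUERY_STRING", "")).items()}

    @staticmethod
    def _bearer(environ: dict) -> str:
        header = environ.get("HTTP_AUTHORIZATION", "")
        if not header.startswith("Bearer "):
            raise _HttpError(401, "missing bearer token")
        return header[len("Bearer "):]

    def _require(self, environ: dict, scope: str, owner: str) -> str:
        token = self._bearer(environ)
        decision = self.system.auth.validate_request(token, scope, owner)
        if not decision:
            raise _HttpError(403, f"denied: {decision.reason}")
        return token

    # -- handlers ------------------------------------------------------------

    def _token(self, environ: dict):
        body = self._body(environ)
        try:
            token = self.system.auth.issue_token(
                body["client_id"], body["client_secret"],
                body.get("scopes", []), body["acting_user"],
            )
        except AuthError as exc:
            raise _HttpError(401, str(exc))
        return 200, {
            "access_token": token.token,
            "token_type": "bearer",
            "expires_at": token.expires_at,
            "scopes": sorted(token.scopes),
        }

    def _login(self, environ: dict):
        body = self._body(environ)
        session = self.system.portal_login(body["pseudonym"], body["password"])
        return 200, {"session_token": session.session_token,
                     "pseudonym": session.pseudonym}

    def _create_partner(self, environ: dict):
        self._require(environ, "manage_partners", "manager")
        body = self._body(environ)
        _, password = self.system.register_partner(
            body["pseudonym"], body["name"], body["email"], body["contact"]
        )
        return 201, {"pseudonym": body["pseudonym"], "password": password}

    def _erase(self, environ: dict, pseudonym: str):
        token = self._bearer(environ)
        record = self.system.auth.token_record(token)
        if record is None:
            raise _HttpError(403, "denied: unknown")
        if record.acting_user == pseudonym:
            decision = self.system.auth.validate_request(
                token, "request_destruction", pseudonym)
            role = "research_partner"
            actor = pseudonym
        else:
            decision = self.system.auth.validate_request(
                token, "manage_partners", "manager")
            role = "biobank_manager"
            actor = "manager"
        if not decision:
            raise _HttpError(403, f"denied: {decision.reason}")
        report = self.system.erase_partner(pseudonym, actor=actor, actor_role=role)
        return 200, report

    def _create_study(self, environ: dict):
        self._require(environ, "manage_studies", "manager")
        body = self._body(environ)
        self.system.create_study(body["study_id"], body.get("researchers", []))
        return 201, {"study_id": body["study_id"]}

    def _identity(self, environ: dict):
        body = self._body(environ)
        card = self.system.get_identity(
            body["session_token"], body["pseudonym"], body["study_id"]
        )
        return 200, {"uuid": card.uuid, "status": card.status,
                     "study_id": card.study_id}

    def _credential(self, environ: dict):
        body = self._body(environ)
        card = self.system.credential_card(
            body["session_token"], body["pseudonym"], body["study_id"]
        )
        return 200, {"uuid": card.uuid, "status": card.status}

    def _set_consent(self, environ: dict):
        body = self._body(environ)
        token = self._bearer(environ)
        asset_id = self.system.set_consent(
            token, body["pseudonym"], body["study_id"], bool(body["consent"]),
            quiz_passed=bool(body.get("quiz_passed", True)),
        )
        return 201, {"asset_id": asset_id}

    def _trail(self, environ: dict):
        query = self._query(environ)
        token = self._bearer(environ)
        trail = self.system.consent_trail(
            token, query["pseudonym"], query["study_id"]
        )
        return 200, {"trail": trail}

    def _status(self, environ: dict):
        query = self._query(environ)
        token = self._bearer(environ)
        value = self.system.has_consented(
            token, query["pseudonym"], query["study_id"]
        )
        return 200, {"consented": value}

    def _study_consents(self, environ: dict, study_id: str):
        token = self._bearer(environ)
        changes = self.system.study_consent_changes(token, study_id)
        return 200, {"changes": changes}

    def _aggregate(self, environ: dict, study_id: str):
        token = self._bearer(environ)
        return 200, self.system.aggregate_view(token, study_id)

    def _interest(self, environ: dict):
        body = self._body(environ)
        record = self.system.express_interest(
            body.get("name", ""), body.get("contact", "")
        )
        return 201, record

    def _interest_queue(self, environ: dict):
        self._require(environ, "manage_partners", "manager")
        return 200, {"queue": self.system.interest_queue("biobank_manager")}

    def _chain_verify(self, environ: dict):
        verdict = self.system.verify_chain()
        return 200, {"valid": verdict.valid,
                     "first_bad_height": verdict.first_bad_height}

    def _chain_dump(self, environ: dict):
        return 200, {"chain": self.system.chain_dump()}


def serve(system: ConsentSystem, host: str = "127.0.0.1", port: int = 8080) -> None:
    """Serve the app with the stdlib WSGI reference server (dev/demo)."""
    from wsgiref.simple_server import make_server

    with make_server(host, port, RestApp(system)) as httpd:
        httpd.serve_forever()
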