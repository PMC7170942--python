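"""The assembled consent-management system.

Wires the four layers together behind one facade:

* the off-chain store (pseudonyms, encrypted personal fields, identity
  cards, the link table — the erasable half),
* the permissioned ledger and consent network (the immutable half),
* the auth service (portal sessions, scoped access tokens),
* a structured event log (actor, capability, decision).

The canonical partner workflow is: ``portal_login`` → ``get_identity``
(issue or fetch the per-study UUID) → ``credential_card`` (generate and
bind signing keys) → ``set_consent`` (a transaction signed by the
partner's own key) → ``consent_trail``. Erasure severs every off-chain
row and credential for a pseudonym while leaving the chain bit-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from random import Random
from typing import List, Optional

from consentledger import access
from consentledger.auth import AuthError, AuthServer, Decision, PortalSession
from consentledger.chain import Chain, ChainVerdict, verify_chain
from consentledger.clockutil import ManualClock, SystemClock
from consentledger.config import Config
from consentledger.crypto import ed25519, passwords
from consentledger.ledger import Ledger
from consentledger.network import HANDLERS, ConsentNetwork, IdentityError, NotFoundError
from consentledger.offchain import IdentityCard, OffchainStore, linkage_audit

__all__ = ["ConsentSystem"]


class ConsentSystem:
    def __init__(
        self,
        config: Optional[Config] = None,
        clock=None,
        db_path: str = ":memory:",
    ) -> None:
        self.config = config or Config()
        cfg = self.config
        self.rng = Random(cfg.seed) if cfg.seed is not None else Random()
        if clock is None:
            clock = ManualClock() if cfg.seed is not None else SystemClock()
        self.clock = clock

        if cfg.server_key_hex is None:
            cfg.server_key_hex = self.rng.getrandbits(256).to_bytes(32, "big").hex()
        if cfg.admin_seed_hex is None:
            cfg.admin_seed_hex = self.rng.getrandbits(256).to_bytes(32, "big").hex()
        if cfg.client_secret is None:
            cfg.client_secret = self.rng.getrandbits(128).to_bytes(16, "big").hex()

        self.store = OffchainStore(
            server_key=bytes.fromhex(cfg.server_key_hex),
            path=db_path,
            rng=self.rng,
            clock=self.clock.iso,
        )
        self.ledger = Ledger(
            HANDLERS,
            clock=self.clock.iso,
            n_endorsers=cfg.n_endorsers,
            batch_size=cfg.batch_size,
        )
        self.network = ConsentNetwork(self.ledger, bytes.fromhex(cfg.admin_seed_hex))
        self.auth = AuthServer(
            clock=self.clock, rng=self.rng, token_lifetime_s=cfg.token_lifetime_s
        )
        self.auth.register_client(cfg.client_id, cfg.client_secret)
        self.events: List[dict] = []

    # -- logging -------------------------------------------------------------

    def _log(self, actor: str, capability: str, decision: str, **detail) -> None:
        self.events.append(
            {"actor": actor, "capability": capability, "decision": decision, **detail}
        )

    # -- administration ------------------------------------------------------

    def register_partner(
        self, pseudonym: str, name: str, email: str, contact: str,
        actor_role: str = "biobank_manager",
    ):
        access.require(actor_role, "manage_partners", "other")
        record, password = self.store.register_partner(pseudonym, name, email, contact)
        self._log("manager", "manage_partners", "allow", pseudonym=pseudonym)
        return record, password

    def add_researcher(
        self, researcher_id: str, name: str, actor_role: str = "biobank_manager"
    ) -> None:
        access.require(actor_role, "manage_researchers", "other")
        self.store.add_researcher(researcher_id, name)

    def create_study(
        self, study_id: str, researcher_ids: List[str] = (),
        actor_role: str = "biobank_manager",
    ) -> None:
        access.require(actor_role, "manage_studies", "other")
        self.store.add_study(study_id, list(researcher_ids))
        self.network.create_study(study_id, actor_role)
        self._log("manager", "manage_studies", "allow", study_id=study_id)

    # -- partner session + identity ------------------------------------------

    def portal_login(self, pseudonym: str, password: str) -> PortalSession:
        record = self.store.get_partner(pseudonym)
        if record is None:
            self._log(pseudonym, "portal_login", "deny", reason="unknown_user")
            raise AuthError("unknown user")
        if not passwords.verify_password(password, record.password_hash):
            self._log(pseudonym, "portal_login", "deny", reason="bad_password")
            raise AuthError("bad password")
        session = self.auth.create_session(pseudonym)
        self._log(pseudonym, "portal_login", "allow")
        return session

    def get_identity(
        self, session_token: str, pseudonym: str, study_id: str
    ) -> IdentityCard:
        """Resolve the partner's per-study identity, issuing it on first use.

        Issuing registers the fresh UUID as an on-chain participant (with no
        key yet — cards start uncredentialed). Revisiting a study returns
        the same card, so one partner holds exactly one UUID per study.
        """
        if self.auth.session_user(session_token) != pseudonym:
            raise access.AccessDenied("session does not belong to this partner")
        existing = self.store.resolve_identity(pseudonym, study_id)
        if existing is not None:
            return existing
        card = self.store.issue_identity(pseudonym, study_id)
        self.network.register_participant(card.uuid, None, "biobank_manager")
        self._log(pseudonym, "issue_identity", "allow", study_id=study_id)
        return card

    def credential_card(
        self, session_token: str, pseudonym: str, study_id: str
    ) -> IdentityCard:
        """issued → credentialed; binds the new public key on-chain.

        Idempotent for already-credentialed cards; denied for a session
        token belonging to another pseudonym.
        """
        if self.auth.session_user(session_token) != pseudonym:
            raise access.AccessDenied("session does not belong to this partner")
        card = self.store.resolve_identity(pseudonym, study_id)
        if card is None:
            raise NotFoundError("identity was never issued for this study")
        if card.status == "credentialed":
            return card
        card = self.store.credential_card(pseudonym, study_id)
        seed = self.store.card_signing_seed(pseudonym, study_id)
        self.network.bind_participant_key(
            card.uuid, ed25519.public_from_seed(seed), "biobank_manager"
        )
        self._log(pseudonym, "credential_card", "allow", study_id=study_id)
        return card

    # -- tokens ---------------------------------------------------------------

    def issue_token(self, scopes, acting_user: str, client_secret: Optional[str] = None):
        secret = self.config.client_secret if client_secret is None else client_secret
        return self.auth.issue_token(self.config.client_id, secret, scopes, acting_user)

    def _authorize(self, token: str, scope: str, owner: str) -> Decision:
        decision = self.auth.validate_request(token, scope, owner)
        record = self.auth.token_record(token)
        actor = record.acting_user if record else "?"
        self._log(actor, scope, "allow" if decision else f"deny:{decision.reason}")
        if not decision:
            raise access.AccessDenied(f"denied: {decision.reason}")
        return decision

    # -- consent --------------------------------------------------------------

    def set_consent(
        self, token: str, pseudonym: str, study_id: str, consent: bool,
        quiz_passed: bool = True,
    ) -> str:
        self._authorize(token, "set_consent", pseudonym)
        card = self.store.resolve_identity(pseudonym, study_id)
        if card is None or card.status != "credentialed":
            raise IdentityError("identity missing or not credentialed")
        seed = self.store.card_signing_seed(pseudonym, study_id)
        asset_id = self.network.set_consent(
            card.uuid, study_id, consent, seed,
            quiz_passed=quiz_passed, flush=self.config.auto_flush,
        )
        return asset_id

    def flush(self):
        """Drain queued (asynchronously committed) consent transactions."""
        return self.ledger.flush()

    def consent_trail(self, token: str, pseudonym: str, study_id: str) -> List[dict]:
        self._authorize(token, "view_trail", pseudonym)
        card = self.store.resolve_identity(pseudonym, study_id)
        if card is None:
            return []
        return self.network.consent_trail(card.uuid, study_id, card.uuid)

    def has_consented(self, token: str, pseudonym: str, study_id: str) -> bool:
        self._authorize(token, "view_trail", pseudonym)
        card = self.store.resolve_identity(pseudonym, study_id)
        if card is None:
            return False
        return self.network.has_consented(card.uuid, study_id, card.uuid)

    def study_consent_changes(self, token: str, study_id: str) -> List[dict]:
        self._authorize(token, "view_study_consents", "manager")
        return self.network.study_consent_changes(study_id, "biobank_manager")

    def aggregate_view(self, token: str, study_id: str) -> dict:
        record = self.auth.token_record(token)
        researcher_id = record.acting_user if record else "?"
        self._authorize(token, "view_aggregate", researcher_id)
        attached = self.store.researcher_attached(researcher_id, study_id)
        return self.network.aggregate_study_view(
            study_id, "researcher", attached=attached
        )

    # -- erasure ---------------------------------------------------------------

    def erase_partner(
        self, pseudonym: str, actor: str, actor_role: str = "biobank_manager"
    ) -> dict:
        """GDPR right to erasure by off-chain link severance.

        Permitted to the biobank manager (for any partner) and to a partner
        for themself. The chain — length, hashes, verify verdict — is
        untouched; the partner's logins, cards, links and tokens are gone.
        """
        relation = "own" if actor == pseudonym else "other"
        if not (
            access.check_access(actor_role, "manage_partners", relation)
            or access.check_access(actor_role, "request_destruction", relation)
        ):
            raise access.AccessDenied("erasure requires the partner or the manager")
        report = self.store.erase_partner(pseudonym)
        report["tokens_revoked"] = self.auth.revoke_user_tokens(pseudonym)
        report["sessions_dropped"] = self.auth.drop_user_sessions(pseudonym)
        self._log(actor, "erase_partner", "allow", pseudonym=pseudonym)
        return report

    def linkage_audit(self, include_links: bool = False) -> dict:
        return linkage_audit(
            self.store.partner_pseudonyms(),
            self.chain_dump().encode(),
            self.store.link_rows() if include_links else None,
        )

    # -- public --------------------------------------------------------------

    def express_interest(self, name: str, contact: str) -> dict:
        record = self.store.express_interest(name, contact)
        self._log("public", "express_interest", "allow")
        return record

    def interest_queue(self, actor_role: str) -> List[dict]:
        access.require(actor_role, "manage_partners", "other")
        return self.store.interest_queue()

    # -- chain inspection ------------------------------------------------------

    def verify_chain(self) -> ChainVerdict:
        return verify_chain(self.ledger.chain)

    def chain_dump(self) -> str:
        return self.ledger.chain.dumps()

    def replay_matches(self, verify_signatures: bool = True) -> bool:
        return self.ledger.replay(verify_signatures=verify_signatures) == self.ledger.state

    def export_state(self) -> dict:
        return json.loads(self.ledger.state.to_bytes().decode())

    # -- persistence (CLI) -----------------------------------------------------

    def save(self, data_dir: str | Path) -> None:
        data_dir = Path(data_dir)
        data_dir.mkdir(parents=True, exist_ok=True)
        (data_dir / "chain.jsonl").write_text(self.chain_dump())
        self.config.save(data_dir / "config.json")
        runtime = {
            "rng_state": _jsonable(self.rng.getstate()),
            "clock_now": getattr(self.clock, "now", None),
            "ledger_seq": self.ledger._seq,
            "consent_counter": self.network._consent_counter,
        }
        (data_dir / "runtime.json").write_text(json.dumps(runtime))

    @classmethod
    def load(cls, data_dir: str | Path) -> "ConsentSystem":
        data_dir = Path(data_dir)
        config = Config.load(data_dir / "config.json")
        runtime = json.loads((data_dir / "runtime.json").read_text())
        clock = None
        if runtime.get("clock_now") is not None:
            clock = ManualClock(start=runtime["clock_now"])
        system = cls(config=config, clock=clock, db_path=str(data_dir / "offchain.db"))
        if runtime.get("rng_state") is not None:
            system.rng.setstate(_tupleize(runtime["rng_state"]))
        chain_path = data_dir / "chain.jsonl"
        if chain_path.exists():
            system.ledger.chain = Chain.loads(chain_path.read_text())
            system.ledger.state = system.ledger.replay(verify_signatures=True)
        system.ledger._seq = runtime.get("ledger_seq", 0)
        system.network._consent_counter = runtime.get("consent_counter", 0)
        return system


def _jsonable(state):
    if isinstance(state, tuple):
        return ["__tuple__", [_jsonable(x) for x in state]]
    return state


def _tupleize(state):
    if isinstance(state, list) and len(state) == 2 and state[0] == "__tuple__":
        return tuple(_tupleize(x) for x in state[1])
    return state
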