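"""The consent business network.

Participants are pseudonymous on-chain identities (UUIDs) bound to a
verification key; studies are bare identifiers (no title or description is
ever stored on-chain); every consent action — give or withdraw — creates a
brand-new immutable ConsentChange asset carrying a boolean and the
commit timestamp. Nothing is ever updated in place: the current consent
status is the latest change, defaulting to "not consented" for an empty
trail.

Three queries mirror the operational needs: a partner's own trail in one
study, their current status, and (for the biobank manager only) every
change in a study across partners. Access control propagates to queries:
partners reach only their own records, researchers only aggregate counts
for studies they are attached to.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Optional

from consentledger import access
from consentledger.crypto import ed25519
from consentledger.ledger import Ledger, ValidationError, WorldState

__all__ = [
    "ConflictError",
    "NotFoundError",
    "IdentityError",
    "HANDLERS",
    "ConsentNetwork",
    "latest_consent",
]


class ConflictError(ValidationError):
    """Asset or participant already exists."""


class NotFoundError(ValidationError):
    """Referenced participant or study does not exist."""


class IdentityError(ValidationError):
    """Identity unusable (no bound key) or signer mismatch."""


# ---------------------------------------------------------------------------
# Transaction handlers (the chaincode)


def _h_register_participant(state: WorldState, action: dict, timestamp: str) -> dict:
    uuid = action["uuid"]
    if uuid in state.participants:
        raise ConflictError(f"participant {uuid} already registered")
    record = {"uuid": uuid, "public_key": action.get("public_key")}
    state.participants[uuid] = record
    return {f"participant:{uuid}": record}


def _h_bind_participant_key(state: WorldState, action: dict, timestamp: str) -> dict:
    uuid = action["uuid"]
    record = state.participants.get(uuid)
    if record is None:
        raise NotFoundError(f"participant {uuid} not registered")
    record["public_key"] = action["public_key"]
    return {f"participant:{uuid}": record}


def _h_create_study(state: WorldState, action: dict, timestamp: str) -> dict:
    study_id = action["study_id"]
    key = f"study:{study_id}"
    if key in state.assets:
        raise ConflictError(f"study {study_id} already exists")
    record = {"study_id": study_id}
    state.assets[key] = record
    return {key: record}


def _h_set_consent(state: WorldState, action: dict, timestamp: str) -> dict:
    uuid = action["participant_uuid"]
    participant = state.participants.get(uuid)
    if participant is None:
        raise NotFoundError(f"participant {uuid} not registered")
    if not participant.get("public_key"):
        raise IdentityError(f"participant {uuid} has no bound signing key")
    study_key = f"study:{action['study_id']}"
    if study_key not in state.assets:
        raise NotFoundError(f"study {action['study_id']} not found")
    asset_id = action["asset_id"]
    key = f"consent:{asset_id}"
    if key in state.assets:
        raise ConflictError(f"consent asset {asset_id} already exists")
    seq = sum(1 for k in state.assets if k.startswith("consent:"))
    record = {
        "asset_id": asset_id,
        "participant_uuid": uuid,
        "study_id": action["study_id"],
        "consent": bool(action["consent"]),
        "timestamp": timestamp,
        "seq": seq,
    }
    state.assets[key] = record
    return {key: record}


HANDLERS: Dict[str, Callable[[WorldState, dict, str], dict]] = {
    "register_participant": _h_register_participant,
    "bind_participant_key": _h_bind_participant_key,
    "create_study": _h_create_study,
    "set_consent": _h_set_consent,
}


def latest_consent(changes: List[dict]) -> bool:
    """Latest-change-wins reduction; empty trail means not consented."""
    if not changes:
        return False
    return bool(changes[-1]["consent"])


# ---------------------------------------------------------------------------
# Network surface


class ConsentNetwork:
    """Capability-checked operations over a :class:`Ledger`.

    Administrative transactions (registrations, study creation, key binds)
    are signed with the network admin's key; consent changes are signed by
    the partner's own per-study key — accountability lives in the chain.
    """

    def __init__(self, ledger: Ledger, admin_seed: bytes) -> None:
        self.ledger = ledger
        self.admin_seed = admin_seed
        self.admin_public = ed25519.public_from_seed(admin_seed)
        self._consent_counter = 0

    # -- administrative transactions ---------------------------------------

    def register_participant(
        self, uuid: str, public_key: Optional[bytes], actor_role: str,
        flush: bool = True,
    ) -> dict:
        access.require(actor_role, "manage_partners", "other")
        self.ledger.submit(
            {
                "type": "register_participant",
                "uuid": uuid,
                "public_key": public_key.hex() if public_key else None,
            },
            actor="admin",
            signing_seed=self.admin_seed,
            flush=flush,
        )
        return {"uuid": uuid}

    def bind_participant_key(
        self, uuid: str, public_key: bytes, actor_role: str, flush: bool = True
    ) -> None:
        access.require(actor_role, "manage_partners", "other")
        self.ledger.submit(
            {
                "type": "bind_participant_key",
                "uuid": uuid,
                "public_key": public_key.hex(),
            },
            actor="admin",
            signing_seed=self.admin_seed,
            flush=flush,
        )

    def create_study(self, study_id: str, actor_role: str, flush: bool = True) -> dict:
        access.require(actor_role, "manage_studies", "other")
        self.ledger.submit(
            {"type": "create_study", "study_id": study_id},
            actor="admin",
            signing_seed=self.admin_seed,
            flush=flush,
        )
        return {"study_id": study_id}

    # -- consent ------------------------------------------------------------

    def set_consent(
        self,
        participant_uuid: str,
        study_id: str,
        consent: bool,
        signing_seed: bytes,
        quiz_passed: bool = True,
        flush: bool = True,
    ) -> str:
        """Append a new ConsentChange, signed by the partner's own key.

        The quiz gate models the portal's comprehension test; the content
        of the quiz is outside this system — only the boolean outcome
        reaches the ledger layer.
        """
        if not quiz_passed:
            raise access.AccessDenied("consent quiz not passed")
        participant = self.ledger.state.participants.get(participant_uuid)
        if participant is None:
            raise NotFoundError(f"participant {participant_uuid} not registered")
        bound = participant.get("public_key")
        if not bound:
            raise IdentityError(
                f"identity {participant_uuid} is not credentialed"
            )
        if ed25519.public_from_seed(signing_seed).hex() != bound:
            raise access.AccessDenied(
                "signing key does not belong to this identity"
            )
        self._consent_counter += 1
        asset_id = f"cc-{self._consent_counter:06d}"
        self.ledger.submit(
            {
                "type": "set_consent",
                "asset_id": asset_id,
                "participant_uuid": participant_uuid,
                "study_id": study_id,
                "consent": bool(consent),
            },
            actor=participant_uuid,
            signing_seed=signing_seed,
            flush=flush,
        )
        return asset_id

    # -- queries (access control propagates here too) -----------------------

    def _changes_for(self, participant_uuid: str, study_id: str) -> List[dict]:
        changes = [
            rec
            for key, rec in self.ledger.state.assets.items()
            if key.startswith("consent:")
            and rec["participant_uuid"] == participant_uuid
            and rec["study_id"] == study_id
        ]
        changes.sort(key=lambda rec: (rec["timestamp"], rec["seq"]))
        return changes

    def consent_trail(
        self, participant_uuid: str, study_id: str, requester_uuid: str,
        requester_role: str = "research_partner",
    ) -> List[dict]:
        relation = "own" if requester_uuid == participant_uuid else "other"
        access.require(requester_role, "view_trail", relation)
        return self._changes_for(participant_uuid, study_id)

    def has_consented(
        self, participant_uuid: str, study_id: str, requester_uuid: str,
        requester_role: str = "research_partner",
    ) -> bool:
        relation = "own" if requester_uuid == participant_uuid else "other"
        access.require(requester_role, "view_trail", relation)
        return latest_consent(self._changes_for(participant_uuid, study_id))

    def study_consent_changes(self, study_id: str, actor_role: str) -> List[dict]:
        """Administrator query: every partner's changes in one study."""
        access.require(actor_role, "view_study_consents", "other")
        changes = [
            rec
            for key, rec in self.ledger.state.assets.items()
            if key.startswith("consent:") and rec["study_id"] == study_id
        ]
        changes.sort(key=lambda rec: rec["seq"])
        return changes

    def aggregate_study_view(
        self, study_id: str, actor_role: str, attached: bool
    ) -> dict:
        """Counts only — no uuid, pseudonym, or trail leaves this query."""
        access.require(
            actor_role, "view_aggregate", "own" if attached else "other"
        )
        per_participant: Dict[str, List[dict]] = {}
        for key, rec in self.ledger.state.assets.items():
            if key.startswith("consent:") and rec["study_id"] == study_id:
                per_participant.setdefault(rec["participant_uuid"], []).append(rec)
        consented = 0
        for changes in per_participant.values():
            changes.sort(key=lambda rec: (rec["timestamp"], rec["seq"]))
            if latest_consent(changes):
                consented += 1
        return {"study_id": study_id, "consented_count": consented}

    @staticmethod
    def check_access(role: str, capability: str, ownership_relation: str) -> bool:
        return access.check_access(role, capability, ownership_relation)
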