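"""Permissioned-ledger semantics over the block substrate.

The ledger is two-piece: an append-only transaction log (the chain) and a
current *world state* — a key-value view of all assets and participants
that is, by construction and by test, always equal to replaying the log
from genesis.

Commit pipeline, mirroring a permissioned fabric:

1. ``endorse`` — n simulated endorsing peers each execute the proposed
   action against a *copy* of the world state and record the serialized
   post-state delta; the ledger itself is not updated.
2. ``accept_or_reject`` — the proposal is accepted only if all endorser
   responses are byte-identical; divergence (nondeterminism) rejects it
   with zero observable effect.
3. ``order_and_commit`` — accepted proposals are timestamped by the
   ordering step, sorted chronologically (ties broken by intake sequence),
   grouped into blocks per policy (default: one transaction per block),
   appended to the chain, and applied to the live world state.

Endorsers run in-process; the semantics, not the transport, is the point.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Callable, Dict, List, Optional, Tuple

from consentledger.canonical import canonical_deserialize, canonical_serialize
from consentledger.chain import (
    Chain,
    ChainError,
    SignedTransaction,
    sign_transaction,
    verify_chain,
    verify_transaction,
)

__all__ = [
    "LedgerError",
    "ValidationError",
    "EndorsementError",
    "WorldState",
    "Proposal",
    "Ledger",
    "ENDORSEMENT_TIMESTAMP_PLACEHOLDER",
]


class LedgerError(ValueError):
    """Generic ledger failure."""


class ValidationError(LedgerError):
    """Action failed schema or access validation during endorsement."""


class EndorsementError(LedgerError):
    """Proposal rejected (diverging endorser responses)."""


# Endorsement executes with a fixed placeholder timestamp so that all
# endorser responses are comparable; the real timestamp is assigned by the
# ordering step at commit.
ENDORSEMENT_TIMESTAMP_PLACEHOLDER = "0000-00-00T00:00:00Z"


class WorldState:
    """Current key-value view: assets and participants."""

    def __init__(self) -> None:
        self.assets: Dict[str, dict] = {}
        self.participants: Dict[str, dict] = {}

    def copy(self) -> "WorldState":
        other = WorldState()
        other.assets = copy.deepcopy(self.assets)
        other.participants = copy.deepcopy(self.participants)
        return other

    def to_bytes(self) -> bytes:
        return canonical_serialize(
            {"assets": self.assets, "participants": self.participants}
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, WorldState) and self.to_bytes() == other.to_bytes()

    def get(self, key: str) -> Optional[dict]:
        return self.assets.get(key)


# A handler executes one action type against a world state and returns the
# delta (the records it wrote), which endorsers serialize for comparison.
Handler = Callable[[WorldState, dict, str], dict]


@dataclass
class Proposal:
    action: dict
    actor: str
    signing_seed: bytes
    submitted_seq: int
    responses: List[bytes] = field(default_factory=list)
    commit_timestamp: Optional[str] = None


class Ledger:
    def __init__(
        self,
        handlers: Dict[str, Handler],
        clock: Callable[[], str],
        n_endorsers: int = 2,
        batch_size: int = 1,
    ) -> None:
        if n_endorsers < 1:
            raise LedgerError("need at least one endorser")
        self.handlers = handlers
        self.clock = clock
        self.n_endorsers = n_endorsers
        self.batch_size = batch_size
        self.chain = Chain()
        self.state = WorldState()
        self._seq = 0
        self._pending: List[Proposal] = []

    # -- pipeline -----------------------------------------------------------

    def endorse(
        self, action: dict, actor: str, signing_seed: bytes,
        n_endorsers: Optional[int] = None,
    ) -> Proposal:
        """Execute the action on isolated state copies, once per endorser."""
        n = self.n_endorsers if n_endorsers is None else n_endorsers
        handler = self.handlers.get(action.get("type", ""))
        if handler is None:
            raise ValidationError(f"unknown action type {action.get('type')!r}")
        responses: List[bytes] = []
        for _ in range(n):
            scratch = self.state.copy()
            delta = handler(scratch, action, ENDORSEMENT_TIMESTAMP_PLACEHOLDER)
            responses.append(canonical_serialize(delta))
        self._seq += 1
        return Proposal(
            action=action,
            actor=actor,
            signing_seed=signing_seed,
            submitted_seq=self._seq,
            responses=responses,
        )

    @staticmethod
    def accept_or_reject(proposal: Proposal) -> bool:
        """Accept iff all endorser responses are byte-identical."""
        if not proposal.responses:
            raise LedgerError("proposal has no endorsement responses")
        return all(r == proposal.responses[0] for r in proposal.responses)

    def order_and_commit(self, accepted: List[Proposal]) -> List:
        """Timestamp, sort, batch, append and apply accepted proposals.

        Atomic per block: a chain append failure leaves the world state
        untouched for that block's proposals.
        """
        for proposal in accepted:
            proposal.commit_timestamp = self.clock()
        ordered = sorted(
            accepted, key=lambda pr: (pr.commit_timestamp, pr.submitted_seq)
        )
        blocks = []
        for start in range(0, len(ordered), self.batch_size):
            batch = ordered[start : start + self.batch_size]
            timestamp = batch[0].commit_timestamp
            assert timestamp is not None
            txs = [
                sign_transaction(
                    canonical_serialize(
                        {"action": pr.action, "actor": pr.actor}
                    ),
                    pr.signing_seed,
                    pr.submitted_seq,
                )
                for pr in batch
            ]
            # Dry-run the whole batch on a scratch state first so a handler
            # failure (e.g. a conflict with an earlier queued proposal) can
            # never leave the chain and the live state out of step.
            scratch = self.state.copy()
            for pr in batch:
                self.handlers[pr.action["type"]](scratch, pr.action, timestamp)
            block = self.chain.append_block(txs, timestamp)
            self.state = scratch
            blocks.append(block)
        return blocks

    def submit(
        self, action: dict, actor: str, signing_seed: bytes, flush: bool = True
    ) -> Proposal:
        """endorse → accept → queue (→ commit when ``flush``)."""
        proposal = self.endorse(action, actor, signing_seed)
        if not self.accept_or_reject(proposal):
            raise EndorsementError(
                "endorser responses differ (nondeterministic action); rejected"
            )
        self._pending.append(proposal)
        if flush:
            self.flush()
        return proposal

    def flush(self) -> List:
        """Commit every queued accepted proposal (async-commit drain point)."""
        pending, self._pending = self._pending, []
        if not pending:
            return []
        return self.order_and_commit(pending)

    # -- queries ------------------------------------------------------------

    def state_get(self, key: str) -> Optional[dict]:
        """Pure world-state lookup; never scans the log."""
        return self.state.get(key)

    def replay(self, verify_signatures: bool = True) -> WorldState:
        return replay(self.chain, self.handlers, verify_signatures=verify_signatures)


def replay(
    chain: Chain,
    handlers: Dict[str, Handler],
    verify_signatures: bool = True,
) -> WorldState:
    """Rebuild a world state by applying every logged transaction in order.

    Raises :class:`ChainError` before producing any state if the chain (or,
    when enabled, any signature) fails verification. Requires an unpruned
    chain — pruned transactions cannot be re-executed.
    """
    if verify_signatures:
        verdict = verify_chain(chain)
        if not verdict:
            raise ChainError(
                f"refusing to replay tampered chain (bad height {verdict.first_bad_height})"
            )
    state = WorldState()
    for block in chain.blocks:
        if len(block.transactions) != block.n_leaves:
            raise ChainError("cannot replay a pruned block")
        for tx in block.transactions:
            envelope = canonical_deserialize(tx.payload)
            action = envelope["action"]
            handler = handlers.get(action.get("type", ""))
            if handler is None:
                raise ChainError(f"no handler for logged action {action.get('type')!r}")
            handler(state, action, block.header.timestamp)
    return state
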