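"""Immutable block/transaction substrate.

A chain is a list of blocks, each holding signed transactions summarized by
a Merkle root and linked to its predecessor by the SHA-256 hash of that
predecessor's header. Tampering with any committed byte breaks either a
signature, a Merkle root, or a hash link, and :func:`verify_chain` reports
the lowest inconsistent height.

Blocks can be *pruned*: transactions no longer of interest are dropped and
replaced by the minimal set of sibling digests needed to recompute the
Merkle root, so the header hash — and hence the chain linkage — survives
unchanged.

Conventions (the source design names none): SHA-256 throughout; Ed25519
detached signatures; canonical JSON payload bytes; odd leaf counts
duplicate the last hash at each level; internal nodes hash left‖right in
leaf order; the genesis block's prev_hash is 32 zero bytes; the structural
nonce field is fixed at 0 (no proof-of-work in a permissioned setting).
"""

from __future__ import annotations

import base64
import hashlib
import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from consentledger.canonical import canonical_serialize
from consentledger.crypto import ed25519

__all__ = [
    "ChainError",
    "SignedTransaction",
    "MerkleTree",
    "BlockHeader",
    "Block",
    "Chain",
    "ChainVerdict",
    "GENESIS_PREV_HASH",
    "sign_transaction",
    "verify_transaction",
    "tx_hash",
    "build_merkle",
    "merkle_proof",
    "verify_merkle_proof",
    "prune_block",
    "verify_chain",
]

GENESIS_PREV_HASH = b"\x00" * 32


class ChainError(ValueError):
    """Structural violation: bad signature, unknown tx, invalid append."""


def _sha256(data: bytes) -> bytes:
    return hashlib.sha256(data).digest()


# ---------------------------------------------------------------------------
# Transactions


@dataclass(frozen=True)
class SignedTransaction:
    """A payload bound to its signer by a detached Ed25519 signature."""

    tx_id: str
    payload: bytes
    public_key: bytes
    signature: bytes
    submitted_seq: int


def sign_transaction(
    payload: bytes, signing_seed: bytes, submitted_seq: int, tx_id: str | None = None
) -> SignedTransaction:
    """Sign ``payload`` with the Ed25519 seed and wrap it in a transaction.

    ``tx_id`` defaults to a digest of (payload, signer, intake sequence),
    which is unique chain-wide because the intake counter never repeats.
    """
    public = ed25519.public_from_seed(signing_seed)
    signature = ed25519.sign(signing_seed, payload)
    if tx_id is None:
        tx_id = _sha256(
            payload + public + submitted_seq.to_bytes(8, "big")
        ).hex()[:32]
    return SignedTransaction(
        tx_id=tx_id,
        payload=payload,
        public_key=public,
        signature=signature,
        submitted_seq=submitted_seq,
    )


def verify_transaction(tx: SignedTransaction) -> bool:
    """True iff the signature verifies for (payload, public_key)."""
    try:
        return ed25519.verify(tx.public_key, tx.payload, tx.signature)
    except Exception:
        return False


@lru_cache(maxsize=65536)
def _verify_cached(public_key: bytes, payload: bytes, signature: bytes) -> bool:
    return ed25519.verify(public_key, payload, signature)


def tx_hash(tx: SignedTransaction) -> bytes:
    """Merkle leaf digest of a transaction (covers every field)."""
    return _sha256(
        canonical_serialize(
            {
                "tx_id": tx.tx_id,
                "payload": base64.b64encode(tx.payload).decode("ascii"),
                "public_key": tx.public_key.hex(),
                "signature": tx.signature.hex(),
                "submitted_seq": tx.submitted_seq,
            }
        )
    )


# ---------------------------------------------------------------------------
# Merkle trees


@dataclass(frozen=True)
class MerkleTree:
    """Full Merkle tree: ``levels[0]`` is the leaves, ``levels[-1]`` = [root]."""

    leaves: Tuple[bytes, ...]
    levels: Tuple[Tuple[bytes, ...], ...]
    root: bytes

    @property
    def height(self) -> int:
        return len(self.levels) - 1


def _next_level(level: Sequence[bytes]) -> List[bytes]:
    out = []
    for i in range(0, len(level), 2):
        left = level[i]
        right = level[i + 1] if i + 1 < len(level) else level[i]  # odd: duplicate
        out.append(_sha256(left + right))
    return out


def build_merkle(leaf_hashes: Sequence[bytes]) -> MerkleTree:
    """Build the tree bottom-up; a one-leaf tree's root is that leaf."""
    if not leaf_hashes:
        raise ChainError("cannot build a Merkle tree with no leaves")
    levels: List[Tuple[bytes, ...]] = [tuple(leaf_hashes)]
    while len(levels[-1]) > 1:
        levels.append(tuple(_next_level(levels[-1])))
    return MerkleTree(leaves=levels[0], levels=tuple(levels), root=levels[-1][0])


def merkle_proof(tree: MerkleTree, leaf_index: int) -> List[bytes]:
    """Sibling digests from leaf to root, one per level above the leaves."""
    if not 0 <= leaf_index < len(tree.leaves):
        raise ChainError(f"leaf index {leaf_index} out of range")
    proof: List[bytes] = []
    idx = leaf_index
    for level in tree.levels[:-1]:
        sibling = idx ^ 1
        # odd level end: the node is paired with itself
        proof.append(level[sibling] if sibling < len(level) else level[idx])
        idx //= 2
    return proof


def verify_merkle_proof(
    leaf_hash: bytes, proof: Sequence[bytes], root: bytes, leaf_index: int
) -> bool:
    """Fold the leaf through the proof; left/right order follows the index path."""
    h = leaf_hash
    idx = leaf_index
    for sibling in proof:
        if idx % 2 == 0:
            h = _sha256(h + sibling)
        else:
            h = _sha256(sibling + h)
        idx //= 2
    return h == root and idx == 0


# ---------------------------------------------------------------------------
# Blocks


@dataclass(frozen=True)
class BlockHeader:
    height: int
    prev_hash: bytes
    merkle_root: bytes
    timestamp: str  # ISO-8601 UTC, assigned at commit
    nonce: int = 0  # structural placeholder; no mining

    def hash(self) -> bytes:
        return _sha256(
            canonical_serialize(
                {
                    "height": self.height,
                    "prev_hash": self.prev_hash.hex(),
                    "merkle_root": self.merkle_root.hex(),
                    "timestamp": self.timestamp,
                    "nonce": self.nonce,
                }
            )
        )


@dataclass(frozen=True)
class Block:
    """Possibly-pruned block.

    ``tx_positions[i]`` is the Merkle leaf index of ``transactions[i]``;
    ``retained_hashes`` maps (level, index) → digest for the minimal sibling
    set a pruned block keeps so its root stays recomputable.
    """

    header: BlockHeader
    transactions: Tuple[SignedTransaction, ...]
    tx_positions: Tuple[int, ...]
    n_leaves: int
    retained_hashes: Dict[Tuple[int, int], bytes] = field(default_factory=dict)

    def tx_by_id(self, tx_id: str) -> Optional[SignedTransaction]:
        for tx in self.transactions:
            if tx.tx_id == tx_id:
                return tx
        return None


def _level_sizes(n_leaves: int) -> List[int]:
    sizes = [n_leaves]
    while sizes[-1] > 1:
        sizes.append((sizes[-1] + 1) // 2)
    return sizes


def recompute_root(block: Block) -> Optional[bytes]:
    """Recompute the Merkle root from kept transactions plus retained digests.

    Returns None when the partial data are insufficient. A fully pruned
    block (no transactions) vouches for its root via the header alone.
    """
    if block.n_leaves <= 0:
        return None
    if not block.transactions and not block.retained_hashes:
        return block.header.merkle_root
    known: Dict[Tuple[int, int], bytes] = dict(block.retained_hashes)
    for pos, tx in zip(block.tx_positions, block.transactions):
        known[(0, pos)] = tx_hash(tx)
    sizes = _level_sizes(block.n_leaves)
    for level in range(1, len(sizes)):
        for i in range(sizes[level]):
            if (level, i) in known:
                continue
            left = known.get((level - 1, 2 * i))
            ri = 2 * i + 1
            right = known.get((level - 1, ri)) if ri < sizes[level - 1] else left
            if left is not None and right is not None:
                known[(level, i)] = _sha256(left + right)
    return known.get((len(sizes) - 1, 0))


def prune_block(block: Block, keep_tx_ids: Iterable[str]) -> Block:
    """Drop all transactions except ``keep_tx_ids``, retaining the minimal
    sibling digests that keep the Merkle root recomputable. The header is
    untouched, so the block's hash — and the chain — stay intact.
    """
    keep = set(keep_tx_ids)
    have = {tx.tx_id for tx in block.transactions}
    unknown = keep - have
    if unknown:
        raise ChainError(f"unknown tx ids: {sorted(unknown)}")

    # Rebuild the full node map from what the block still has.
    known: Dict[Tuple[int, int], bytes] = dict(block.retained_hashes)
    for pos, tx in zip(block.tx_positions, block.transactions):
        known[(0, pos)] = tx_hash(tx)
    sizes = _level_sizes(block.n_leaves)
    for level in range(1, len(sizes)):
        for i in range(sizes[level]):
            if (level, i) in known:
                continue
            left = known.get((level - 1, 2 * i))
            ri = 2 * i + 1
            right = known.get((level - 1, ri)) if ri < sizes[level - 1] else left
            if left is not None and right is not None:
                known[(level, i)] = _sha256(left + right)

    kept = [
        (pos, tx)
        for pos, tx in zip(block.tx_positions, block.transactions)
        if tx.tx_id in keep
    ]
    kept_positions = {pos for pos, _ in kept}
    if not kept_positions:
        return replace(
            block, transactions=(), tx_positions=(), retained_hashes={}
        )

    # A node is "covered" if its subtree contains a kept leaf. Retain every
    # known node that is NOT covered but whose parent is — the classic
    # minimal sibling cover along the kept leaves' paths to the root.
    covered = {(0, pos) for pos in kept_positions}
    for level in range(1, len(sizes)):
        for i in range(sizes[level]):
            ri = 2 * i + 1
            if (level - 1, 2 * i) in covered or (
                ri < sizes[level - 1] and (level - 1, ri) in covered
            ):
                covered.add((level, i))

    retained: Dict[Tuple[int, int], bytes] = {}
    for level in range(len(sizes) - 1):
        for i in range(sizes[level]):
            node = (level, i)
            if node in covered:
                continue
            parent = (level + 1, i // 2)
            if parent in covered:
                if node not in known:
                    raise ChainError("block too pruned to re-prune to this subset")
                retained[node] = known[node]

    return replace(
        block,
        transactions=tuple(tx for _, tx in kept),
        tx_positions=tuple(pos for pos, _ in kept),
        retained_hashes=retained,
    )


# ---------------------------------------------------------------------------
# The chain


@dataclass(frozen=True)
class ChainVerdict:
    valid: bool
    first_bad_height: Optional[int] = None

    def __bool__(self) -> bool:
        return self.valid


class Chain:
    """Append-only list of blocks with hash linkage."""

    def __init__(self) -> None:
        self.blocks: List[Block] = []

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def head_hash(self) -> bytes:
        return self.blocks[-1].header.hash() if self.blocks else GENESIS_PREV_HASH

    def append_block(
        self, transactions: Sequence[SignedTransaction], timestamp: str
    ) -> Block:
        """Commit a block; atomic — one bad signature rejects the whole batch."""
        if not transactions:
            raise ChainError("no empty blocks")
        for tx in transactions:
            if not verify_transaction(tx):
                raise ChainError(f"invalid signature on tx {tx.tx_id}")
        seen = {tx.tx_id for b in self.blocks for tx in b.transactions}
        for tx in transactions:
            if tx.tx_id in seen:
                raise ChainError(f"duplicate tx_id {tx.tx_id}")
            seen.add(tx.tx_id)
        tree = build_merkle([tx_hash(tx) for tx in transactions])
        header = BlockHeader(
            height=len(self.blocks),
            prev_hash=self.head_hash,
            merkle_root=tree.root,
            timestamp=timestamp,
        )
        block = Block(
            header=header,
            transactions=tuple(transactions),
            tx_positions=tuple(range(len(transactions))),
            n_leaves=len(transactions),
        )
        self.blocks.append(block)
        return block

    def replace_block(self, height: int, block: Block) -> None:
        """Swap in a pruned variant of an existing block (same header only)."""
        if block.header.hash() != self.blocks[height].header.hash():
            raise ChainError("replacement block alters the header")
        self.blocks[height] = block

    # -- serialization ------------------------------------------------------

    def dumps(self) -> str:
        """One JSON object per line per block; loads() round-trips losslessly."""
        lines = []
        for block in self.blocks:
            lines.append(
                json.dumps(
                    {
                        "header": {
                            "height": block.header.height,
                            "prev_hash": block.header.prev_hash.hex(),
                            "merkle_root": block.header.merkle_root.hex(),
                            "timestamp": block.header.timestamp,
                            "nonce": block.header.nonce,
                        },
                        "n_leaves": block.n_leaves,
                        "transactions": [
                            {
                                "tx_id": tx.tx_id,
                                "payload": base64.b64encode(tx.payload).decode(),
                                "public_key": tx.public_key.hex(),
                                "signature": tx.signature.hex(),
                                "submitted_seq": tx.submitted_seq,
                                "position": pos,
                            }
                            for tx, pos in zip(block.transactions, block.tx_positions)
                        ],
                        "retained_hashes": [
                            [level, idx, digest.hex()]
                            for (level, idx), digest in sorted(
                                block.retained_hashes.items()
                            )
                        ],
                    },
                    sort_keys=True,
                )
            )
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def loads(cls, text: str) -> "Chain":
        chain = cls()
        for line in text.splitlines():
            if not line.strip():
                continue
            obj = json.loads(line)
            header = BlockHeader(
                height=obj["header"]["height"],
                prev_hash=bytes.fromhex(obj["header"]["prev_hash"]),
                merkle_root=bytes.fromhex(obj["header"]["merkle_root"]),
                timestamp=obj["header"]["timestamp"],
                nonce=obj["header"]["nonce"],
            )
            txs, positions = [], []
            for t in obj["transactions"]:
                txs.append(
                    SignedTransaction(
                        tx_id=t["tx_id"],
                        payload=base64.b64decode(t["payload"]),
                        public_key=bytes.fromhex(t["public_key"]),
                        signature=bytes.fromhex(t["signature"]),
                        submitted_seq=t["submitted_seq"],
                    )
                )
                positions.append(t["position"])
            chain.blocks.append(
                Block(
                    header=header,
                    transactions=tuple(txs),
                    tx_positions=tuple(positions),
                    n_leaves=obj["n_leaves"],
                    retained_hashes={
                        (level, idx): bytes.fromhex(digest)
                        for level, idx, digest in obj["retained_hashes"]
                    },
                )
            )
        return chain


def verify_chain(chain: Chain, expected_head: Optional[bytes] = None) -> ChainVerdict:
    """Validate linkage, Merkle roots and signatures block by block.

    Checks per block, in order: the prev_hash link, root recomputability,
    then each retained signature. Reports the lowest bad height.

    ``expected_head`` is an externally trusted anchor (the last header hash
    a verifier recorded). Without it, fields of the newest header that
    nothing references yet (timestamp, nonce) cannot be cross-checked.
    """
    prev = GENESIS_PREV_HASH
    seen_ids: set[str] = set()
    for height, block in enumerate(chain.blocks):
        if block.header.height != height or block.header.prev_hash != prev:
            return ChainVerdict(False, height)
        root = recompute_root(block)
        if root is None or root != block.header.merkle_root:
            return ChainVerdict(False, height)
        for tx in block.transactions:
            if tx.tx_id in seen_ids or not _verify_cached(
                tx.public_key, tx.payload, tx.signature
            ):
                return ChainVerdict(False, height)
            seen_ids.add(tx.tx_id)
        prev = block.header.hash()
    if expected_head is not None and prev != expected_head:
        return ChainVerdict(False, max(len(chain.blocks) - 1, 0))
    return ChainVerdict(True, None)
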