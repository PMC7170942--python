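"""Block chaining, tamper detection, pruning and serialization."""

import dataclasses
from random import Random

import pytest

from consentledger.chain import (
    Chain,
    ChainError,
    GENESIS_PREV_HASH,
    SignedTransaction,
    prune_block,
    recompute_root,
    sign_transaction,
    tx_hash,
    verify_chain,
    verify_transaction,
)
from consentledger.clockutil import ManualClock


def _seed(rng: Random) -> bytes:
    return rng.getrandbits(256).to_bytes(32, "big")


def _build_chain(n_blocks: int, txs_per_block: int = 1, seed: int = 99) -> Chain:
    rng = Random(seed)
    clock = ManualClock()
    chain = Chain()
    counter = 0
    for _ in range(n_blocks):
        txs = []
        for _ in range(txs_per_block):
            counter += 1
            txs.append(
                sign_transaction(
                    b'{"n":%d}' % counter, _seed(rng), submitted_seq=counter
                )
            )
        chain.append_block(txs, clock.iso())
    return chain


def test_sign_and_verify_round_trip(rng):
    tx = sign_transaction(b"payload", _seed(rng), submitted_seq=1)
    assert verify_transaction(tx)
    flipped = dataclasses.replace(tx, payload=b"pAyload")
    assert not verify_transaction(flipped)


def test_genesis_conventions():
    chain = _build_chain(1)
    block = chain.blocks[0]
    assert block.header.height == 0
    assert block.header.prev_hash == GENESIS_PREV_HASH
    assert block.header.nonce == 0


def test_blocks_link_by_header_hash():
    chain = _build_chain(2)
    assert chain.blocks[1].header.prev_hash == chain.blocks[0].header.hash()


def test_append_rejects_bad_signature_atomically(rng):
    chain = _build_chain(1)
    good = sign_transaction(b"ok", _seed(rng), submitted_seq=10)
    bad = dataclasses.replace(
        sign_transaction(b"bad", _seed(rng), submitted_seq=11),
        signature=b"\x00" * 64,
    )
    with pytest.raises(ChainError):
        chain.append_block([good, bad], "2024-01-01T00:00:00Z")
    assert len(chain) == 1


def test_empty_block_rejected():
    chain = Chain()
    with pytest.raises(ChainError):
        chain.append_block([], "2024-01-01T00:00:00Z")


def test_untampered_chain_is_valid():
    chain = _build_chain(10)
    verdict = verify_chain(chain)
    assert verdict.valid and verdict.first_bad_height is None


def test_payload_mutation_detected_at_its_height():
    chain = _build_chain(10)
    target = chain.blocks[4]
    tampered_tx = dataclasses.replace(
        target.transactions[0],
        payload=target.transactions[0].payload + b"!",
    )
    chain.blocks[4] = dataclasses.replace(target, transactions=(tampered_tx,))
    verdict = verify_chain(chain)
    assert not verdict.valid
    assert verdict.first_bad_height == 4


def test_recomputed_header_after_substitution_detected_at_next_height(rng):
    """An attacker swaps in their own validly-signed transaction and fixes
    block 4's Merkle root and header — the break surfaces at block 5, whose
    stored prev_hash no longer matches."""
    chain = _build_chain(10)
    forged = sign_transaction(b'{"evil":1}', _seed(rng), submitted_seq=999)
    old = chain.blocks[4]
    from consentledger.chain import build_merkle

    new_root = build_merkle([tx_hash(forged)]).root
    new_header = dataclasses.replace(old.header, merkle_root=new_root)
    chain.blocks[4] = dataclasses.replace(
        old, header=new_header, transactions=(forged,)
    )
    verdict = verify_chain(chain)
    assert verdict.first_bad_height == 5


def test_duplicate_tx_id_rejected(rng):
    chain = Chain()
    seed = _seed(rng)
    tx = sign_transaction(b"x", seed, submitted_seq=1)
    chain.append_block([tx], "t1")
    with pytest.raises(ChainError):
        chain.append_block([tx], "t2")


# -- pruning -----------------------------------------------------------------


def test_prune_keep_one_of_four_retains_two_digests(rng):
    chain = _build_chain(1, txs_per_block=4)
    block = chain.blocks[0]
    keep = block.transactions[3].tx_id
    pruned = prune_block(block, [keep])
    assert [tx.tx_id for tx in pruned.transactions] == [keep]
    hashes = [tx_hash(tx) for tx in block.transactions]
    import hashlib

    h12 = hashlib.sha256(hashes[0] + hashes[1]).digest()
    assert set(pruned.retained_hashes.values()) == {hashes[2], h12}
    assert pruned.header.hash() == block.header.hash()
    assert recompute_root(pruned) == block.header.merkle_root


def test_prune_keep_all_is_identity(rng):
    chain = _build_chain(1, txs_per_block=4)
    block = chain.blocks[0]
    pruned = prune_block(block, [tx.tx_id for tx in block.transactions])
    assert pruned.retained_hashes == {}
    assert pruned.transactions == block.transactions


def test_prune_keep_none_leaves_header_only_block():
    chain = _build_chain(3, txs_per_block=4)
    pruned = prune_block(chain.blocks[1], [])
    chain.replace_block(1, pruned)
    assert pruned.transactions == ()
    assert verify_chain(chain).valid


def test_prune_unknown_tx_id_errors():
    chain = _build_chain(1, txs_per_block=2)
    with pytest.raises(ChainError):
        prune_block(chain.blocks[0], ["nope"])


@pytest.mark.parametrize("n_txs", [1, 2, 3, 5, 8])
def test_pruning_conserves_header_and_verdict(n_txs):
    """Every keep-subset leaves the header hash and chain verdict intact."""
    chain = _build_chain(3, txs_per_block=n_txs, seed=5)
    block = chain.blocks[1]
    ids = [tx.tx_id for tx in block.transactions]
    before = block.header.hash()
    for mask in range(2 ** len(ids)):
        keep = [tx_id for i, tx_id in enumerate(ids) if mask >> i & 1]
        pruned = prune_block(block, keep)
        assert pruned.header.hash() == before
        chain.replace_block(1, pruned)
        assert verify_chain(chain).valid
        chain.replace_block(1, block)


def test_retained_hash_tamper_detected():
    chain = _build_chain(2, txs_per_block=4)
    pruned = prune_block(chain.blocks[1], [chain.blocks[1].transactions[0].tx_id])
    (key, value) = next(iter(pruned.retained_hashes.items()))
    bad = dict(pruned.retained_hashes)
    bad[key] = bytes([value[0] ^ 1]) + value[1:]
    chain.replace_block(1, dataclasses.replace(pruned, retained_hashes=bad))
    assert verify_chain(chain).first_bad_height == 1


# -- serialization ------------------------------------------------------------


def test_dump_load_round_trip_including_pruned_blocks():
    chain = _build_chain(4, txs_per_block=3)
    chain.replace_block(
        2, prune_block(chain.blocks[2], [chain.blocks[2].transactions[1].tx_id])
    )
    text = chain.dumps()
    reloaded = Chain.loads(text)
    assert reloaded.dumps() == text
    assert verify_chain(reloaded).valid
    assert reloaded.blocks[2].retained_hashes == chain.blocks[2].retained_hashes


def test_identical_inputs_yield_byte_identical_chains():
    assert _build_chain(5, 2, seed=7).dumps() == _build_chain(5, 2, seed=7).dumps()
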