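# Methods

This note documents the models, procedures and design choices behind
`consentledger`: what each layer assumes, which parameters matter, what
the synthetic-data generator does and does not emulate, and where the
design was genuinely open.

## The ledger model

The chain is a linear sequence of blocks. Each block header carries its
height, the SHA-256 hash of the previous header (32 zero bytes for the
genesis block), the Merkle root of its transactions, a commit timestamp,
and a structural `nonce` fixed at 0 — in a permissioned deployment there
is no mining and no incentive to race, so proof-of-work is deliberately
absent. A transaction is a canonical-JSON payload (UTF-8, sorted keys, no
insignificant whitespace — the encoding every hash and signature in the
system is computed over) plus a detached Ed25519 signature and the
signer's verification key.

Merkle trees hash `left ‖ right` pairs in leaf order; a level with an odd
node count duplicates its last hash, the convention of the original
cryptocurrency design the block structure descends from (the degenerate
one-leaf tree's root is the leaf itself). Proofs are the sibling digests
along the leaf-to-root path; verification folds the leaf through them,
taking left/right from the bits of the leaf index. Pruning replaces
dropped transactions with the minimal sibling cover — the known nodes
whose subtree holds no kept leaf but whose parent's does — so the root,
the header hash, and therefore the whole chain linkage survive unchanged.
A block pruned to nothing vouches for its root through its header alone.

`verify_chain` checks, per block and in this order: the prev-hash link,
Merkle-root recomputability, then each retained signature, and reports the
lowest failing height. An optional *trusted head anchor* (the last header
hash a verifier previously recorded) closes the one gap this leaves:
fields of the newest header that nothing references yet. Signature
verification is memoized on `(key, payload, signature)`, so re-verifying
a largely unchanged chain is cheap while any mutation misses the cache.

## Permissioned commit semantics

A proposed action is executed by `n_endorsers` (default 2) in-process
endorsers, each against an isolated copy of the world state; the ledger
itself is untouched at this stage. The serialized post-state deltas must
agree byte-for-byte or the proposal is rejected — the standard defense
against nondeterministic transaction code — with zero observable effect.
Accepted proposals receive their timestamp from the ordering step (an
injectable clock; UTC ISO-8601 with microsecond precision, whose
lexicographic order is time order), are sorted by (timestamp, intake
sequence), and grouped into blocks of `batch_size` transactions. The
default is one transaction per block, which makes tests and audit
reasoning simple; batching is a configuration choice. Endorsement runs
with a fixed placeholder timestamp so endorser outputs are comparable;
the committed state is produced with the real block timestamp. Before a
block is appended the whole batch is dry-run on a scratch state, so a
late conflict can never leave the chain and the live state out of step.

The world state (assets + participants) is maintained incrementally and
is, by contract and by test, equal to replaying the full log from
genesis. `replay` verifies the chain (and every signature) before
producing any state; callers that have already verified signatures at
append time may disable that re-verification, which keeps
replay-after-every-commit soaks linear instead of quadratic in signature
checks.

## The consent network

On-chain records are minimal by design: participants are `(UUID,
verification key)`, studies are bare identifiers, and every consent
action appends a new immutable asset `(asset id, participant UUID, study
id, boolean, timestamp)`. Nothing is ever updated. The current status is
the latest change, and an empty trail means "not consented" — the
reduction rule is latest-change-wins. Repeated identical changes (consent
after consent) are accepted and recorded: the trail is an audit log of
user actions, not a state diff. Consent transactions must be signed by
the key bound to the acting identity; a signature by any other key is an
access violation, which is how accountability is anchored in the chain
rather than in application logs. A boolean quiz gate (the portal's
comprehension test; its content is out of scope here) guards the consent
path.

The role matrix is total and default-deny. Managers create/edit/remove
partners, researchers and studies and may list all consent changes in a
study; researchers see only an aggregate count of currently consented
identities for studies they are attached to (the attachment is an
off-chain relation, enforced at the API layer); partners set consent and
view trails for themselves only, and may request destruction/erasure of
their own data; the public can view governance material, follow study
updates, and submit an interest form. These checks propagate into the
query layer — the same rule that stops a partner consenting for someone
else stops them reading a foreign trail.

## Identities and erasure

The off-chain store is the erasable half. Partners are keyed by a
biobank-assigned pseudonym (their login username); name, email and
contact are stored only as authenticated ciphertext under a single server
key; passwords as salted PBKDF2-HMAC-SHA256 hashes (50 000 iterations,
recorded per hash). For each study a partner joins, a fresh version-4
UUID is issued and recorded in the link table — the only place the
pseudonym-to-UUID mapping exists. Identity cards start `issued` (no key
material; the corresponding on-chain participant is registered with a
null key) and become `credentialed` when a valid portal session triggers
generation of an Ed25519 seed, which is encrypted at rest and whose
public half is bound on-chain in a second transaction. Credentialing is
idempotent; cards are reused across sessions.

Erasure hard-deletes the partner's profile, cards, links, sessions and
outstanding tokens — no tombstones, so exports and backups regenerate
without the partner. The chain is untouched: its length, hashes and
verification verdict are bit-identical before and after. The linkage
audit quantifies the guarantee: scanning the serialized chain for any
registered pseudonym finds nothing (pseudonyms never go on-chain), so a
chain-only attacker recovers zero pseudonym↔UUID pairs, and after erasure
even the link-table view no longer covers the erased partner. Per-study
UUIDs additionally ensure that compromising one identity says nothing
about the partner's other studies. The mapping between pseudonyms and
real-world identities is held physically by the biobank and is modeled
as external to this system.

## Authentication

The portal is the single registered OAuth-style client (client id +
salted-hashed secret). Tokens are opaque random 256-bit strings stored
server-side — chosen over self-encoded tokens precisely so erasure can
revoke them — carrying a scope set fixed at issuance, an acting user, and
an expiry (default 3600 s; the configuration owns the number). Resource
validation denies with a structured reason — `unknown`, `expired`,
`scope`, or `ownership` — where ownership passes only if the token acts
for the resource owner or carries an administrative scope. Portal
sessions are the separate, longer-lived login primitive used to
credential cards. All expiry logic reads an injectable clock.

## Cryptographic primitives

No third-party cryptography is used. Ed25519 is implemented from the RFC
8032 specification (extended twisted-Edwards coordinates, deterministic
nonces) and validated against the RFC's published test vectors; signing
and verification run in a few milliseconds, ample for human-scale consent
traffic. Field encryption is an encrypt-then-MAC construction over
HMAC-SHA256 — a counter-mode keystream under a derived encryption subkey,
a constant-time-verified tag under a distinct MAC subkey — with a 16-byte
nonce per blob. Password hashing is stdlib PBKDF2. These are sound,
conservative constructions; swapping in hardware-accelerated equivalents
would be a drop-in change behind the same module surface.

## Synthetic cohorts

`generate_scenario(n_partners, n_studies, n_actions, seed)` emulates a
small biobank cohort: pseudonyms `P0001…`, fabricated names/contacts,
studies `S001…`, and a time-ordered event stream drawn as 55% consent
grants, 35% withdrawals and 10% erasure requests — grants lead because a
functioning cohort consents more than it leaves; the erasure rate is kept
rare but non-negligible so every run exercises the severance path. Events
never reference an erased partner, and the stream ends early if the whole
cohort erases itself. Everything derives from the seed.

`run_scenario` pushes every event through the complete stack — login,
identity issue/reuse, credentialing, token issuance, a partner-signed
consent transaction, or erasure — and reports chain length, per-study
consented counts, the verification verdict, replay equivalence, and the
chain-only linkage count. What the generator does *not* emulate: real
enrollment timing (the clock ticks uniformly), concurrent sessions,
network failures, malicious clients, or realistic personal data. Passing
tests therefore demonstrate the architectural invariants — append-only
audit, log/state equivalence, access control, unlinkability after
erasure — not performance or adversarial robustness of a deployment.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, chosen so the
properties are exercised exhaustively where the space is small (all 256
keep-subsets of an 8-transaction block; every leaf of every tree size
1–32; the full role × capability × relation matrix) and by seeded
sampling where it is not (one bit flip per field class per block across a
50-block chain; a 15-partner, 4-study, 120-action cohort; replay
equality re-checked after each of 200 committed actions). Timestamps are
fixed-width ISO strings so string order is time order; ties break on the
intake sequence counter. Degenerate inputs are defined rather than
accidental: empty blocks are rejected, a one-leaf Merkle tree's root is
the leaf, an empty consent trail reads as "not consented", and a fully
pruned block remains verifiable through its header.

## Known limitations

Endorsers are simulated in-process; there is no networking, membership
service or multi-organization ordering. The REST surface is a
single-process WSGI app intended for one trusted portal client, not a
hardened public endpoint. Key rotation (server key, admin key) is out of
scope, as are email delivery, password reset and two-factor
authentication. Whether erased partners' historical consent changes
should be excluded from manager-facing aggregates is a policy question;
here they remain, unattributable, in the counts.
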