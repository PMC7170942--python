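# consentledger

Dynamic consent management for biobanks on a permissioned, append-only
ledger — with a working GDPR right to erasure.

## The problem

Biobanks curate biospecimens and linked health data for reuse in future
research. Classical one-off consent (broad or study-specific) leaves the
donor — the *research partner* — out of the loop for decades. **Dynamic
consent** replaces it with an ongoing, revisable digital process: partners
give or withdraw consent per study, at any time, and can audit exactly
what they agreed to and when.

That audit trail must be tamper-evident (the biobank should not be able to
rewrite history), but the GDPR also grants a right to erasure — seemingly
incompatible with an immutable ledger. This package implements the
architecture that reconciles the two:

* **On-chain** — an append-only hash chain stores *only* consent changes:
  `(participant UUID, study id, boolean, timestamp)`, each signed by the
  partner's own key. Blocks carry a SHA-256 Merkle root over their
  transactions and link to their predecessor by header hash, so any
  mutation of committed data is detectable; blocks can be pruned down to
  a minimal sibling-digest set without breaking verification.
* **Off-chain** — an erasable relational store holds the pseudonym (the
  login username assigned by the biobank), encrypted personal fields, and
  the *only* mapping from pseudonyms to on-chain UUIDs. A partner gets a
  fresh random UUID **per study**, so one leaked identity reveals nothing
  about their other participation.
* **Erasure = link severance** — deleting a partner's off-chain rows makes
  their on-chain consent assets unattributable. The chain stays
  bit-identical and fully verifiable; the person is gone.

Ledger semantics follow the permissioned-fabric model: proposed
transactions are executed by n in-process endorsers against isolated state
copies, accepted only if all responses agree byte-for-byte (rejecting
nondeterminism), ordered chronologically into blocks, and applied to a
*world state* that is provably equal to replaying the transaction log.
Role-based access control (biobank manager / researcher / research
partner / public) is enforced down to the query level, and short-lived
scoped tokens bound to an acting user gate every API operation.

## Worked example

```python
from consentledger import Config, ConsentSystem

system = ConsentSystem(config=Config(seed=7))   # seeded => reproducible

# biobank manager registers a partner and a study
record, password = system.register_partner(
    "P001", "Jane Doe", "jane@example.org", "+356-5550001")
system.create_study("S001")

# the partner workflow: login -> per-study identity -> credentials -> consent
session = system.portal_login("P001", password)
card = system.get_identity(session.session_token, "P001", "S001")
system.credential_card(session.session_token, "P001", "S001")
token = system.issue_token(["set_consent", "view_trail"], "P001")
system.set_consent(token.token, "P001", "S001", True)
system.set_consent(token.token, "P001", "S001", False)
for change in system.consent_trail(token.token, "P001", "S001"):
    print(change["timestamp"], "consent =", change["consent"])

# right to erasure: off-chain links go, the chain does not move
print(system.erase_partner("P001", actor="P001", actor_role="research_partner"))
print(len(system.ledger.chain), system.verify_chain().valid)
```

Output:

```
2023-11-14T22:13:30.000000Z consent = True
2023-11-14T22:13:32.000000Z consent = False
{'pseudonym': 'P001', 'cards': 1, 'links': 1, 'tokens_revoked': 1, 'sessions_dropped': 1}
5 True
```

The chain holds 5 transactions (study creation, identity registration,
key binding, two consent changes) and still verifies after erasure; the
trail shows one grant and one withdrawal, so the partner's final status is
"not consented". After erasure no off-chain query, login or linkage audit
can tie `P001` to the UUID that signed those changes.

The same capabilities are available over a CLI
(`consentledger init/partner/study/consent/token/scenario/chain/serve`) and
a framework-free WSGI REST API (`consentledger.rest.RestApp`), both thin
wrappers over the library.

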