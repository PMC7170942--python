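"""The assembled system: the end-to-end partner workflow, identity
multiplexing, erasure soundness, and asynchronous commit draining."""

import pytest

from consentledger.access import AccessDenied
from consentledger.auth import AuthError
from consentledger.config import Config
from consentledger.network import IdentityError, NotFoundError
from consentledger.system import ConsentSystem


def _enroll_partner(system, pseudonym="P001", studies=("S1",)):
    _, password = system.register_partner(
        pseudonym, "Jane Doe", "jane@example.org", "+356-5550001"
    )
    for study in studies:
        if system.store.db.execute(
            "SELECT 1 FROM studies WHERE study_id=?", (study,)
        ).fetchone() is None:
            system.create_study(study)
    return password


def _full_workflow(system, pseudonym, password, study, consent=True):
    session = system.portal_login(pseudonym, password)
    card = system.get_identity(session.session_token, pseudonym, study)
    system.credential_card(session.session_token, pseudonym, study)
    token = system.issue_token(["set_consent", "view_trail"], pseudonym)
    system.set_consent(token.token, pseudonym, study, consent)
    return session, card, token


def test_end_to_end_workflow_succeeds(system):
    password = _enroll_partner(system)
    _, card, token = _full_workflow(system, "P001", password, "S1")
    trail = system.consent_trail(token.token, "P001", "S1")
    assert [c["consent"] for c in trail] == [True]
    assert system.has_consented(token.token, "P001", "S1") is True
    assert system.verify_chain().valid
    # every transaction in the chain verifies, including the partner-signed one
    assert system.replay_matches()


def test_workflow_fails_at_exactly_the_broken_step(system):
    password = _enroll_partner(system)

    # step 1: wrong password -> login fails, nothing downstream exists
    with pytest.raises(AuthError):
        system.portal_login("P001", "not-the-password")

    session = system.portal_login("P001", password)

    # step 2: a foreign session cannot operate on this partner's identity
    pw2 = _enroll_partner(system, "P002")
    with pytest.raises(AccessDenied):
        system.get_identity(session.session_token, "P002", "S1")

    card = system.get_identity(session.session_token, "P001", "S1")
    assert card.status == "issued"

    # step 3: consent before credentialing fails with an identity error
    token = system.issue_token(["set_consent", "view_trail"], "P001")
    with pytest.raises(IdentityError):
        system.set_consent(token.token, "P001", "S1", True)

    # step 3b: a foreign session cannot credential the card either
    other_session = system.portal_login("P002", pw2)
    with pytest.raises(AccessDenied):
        system.credential_card(other_session.session_token, "P001", "S1")

    system.credential_card(session.session_token, "P001", "S1")

    # step 4: an invalid token fails exactly at authorization
    with pytest.raises(AccessDenied):
        system.set_consent("bogus-token", "P001", "S1", True)

    # with every credential in place the workflow completes
    system.set_consent(token.token, "P001", "S1", True)
    assert system.has_consented(token.token, "P001", "S1")


def test_identity_multiplexing_one_uuid_per_study(system):
    password = _enroll_partner(system, studies=("S1", "S2", "S3"))
    session = system.portal_login("P001", password)
    uuids = {
        system.get_identity(session.session_token, "P001", s).uuid
        for s in ("S1", "S2", "S3")
    }
    assert len(uuids) == 3
    again = system.get_identity(session.session_token, "P001", "S2")
    assert again.uuid in uuids
    # uuids share no linkable relationship with the pseudonym
    assert all("P001" not in u for u in uuids)


def test_credential_is_idempotent_and_signature_verifies_on_chain(system):
    password = _enroll_partner(system)
    session = system.portal_login("P001", password)
    system.get_identity(session.session_token, "P001", "S1")
    card1 = system.credential_card(session.session_token, "P001", "S1")
    card2 = system.credential_card(session.session_token, "P001", "S1")
    assert card1.credentials_encrypted == card2.credentials_encrypted
    token = system.issue_token(["set_consent"], "P001")
    system.set_consent(token.token, "P001", "S1", True)
    # the consent transaction is signed by the card's own key and the whole
    # chain (replay with signature verification) accepts it
    assert system.replay_matches(verify_signatures=True)


def test_erasure_severs_links_but_not_the_chain(system):
    pw1 = _enroll_partner(system, "P001", studies=("S1", "S2"))
    pw2 = _enroll_partner(system, "P002")
    _full_workflow(system, "P001", pw1, "S1")
    _full_workflow(system, "P001", pw1, "S2")
    _full_workflow(system, "P002", pw2, "S1")

    chain_before = system.chain_dump()
    verdict_before = system.verify_chain().valid
    token = system.issue_token(["view_trail"], "P001")

    report = system.erase_partner("P001", actor="P001", actor_role="research_partner")
    assert report["cards"] == 2 and report["links"] == 2

    # (a) the chain is bit-identical and still valid
    assert system.chain_dump() == chain_before
    assert system.verify_chain().valid == verdict_before
    # (b) nothing maps the pseudonym to any uuid anywhere off-chain
    assert system.store.resolve_identity("P001", "S1") is None
    assert b"P001" not in system.store.raw_dump()
    assert system.linkage_audit(include_links=True)["coverage_with_links"] == ["P002"]
    # (c) login now fails as unknown user; outstanding tokens are revoked
    with pytest.raises(AuthError):
        system.portal_login("P001", pw1)
    with pytest.raises(AccessDenied):
        system.consent_trail(token.token, "P001", "S1")
    # other partners unaffected
    token2 = system.issue_token(["view_trail"], "P002")
    assert system.has_consented(token2.token, "P002", "S1")


def test_erasure_requires_the_partner_or_the_manager(system):
    _enroll_partner(system)
    with pytest.raises(AccessDenied):
        system.erase_partner("P001", actor="P002", actor_role="research_partner")
    with pytest.raises(AccessDenied):
        system.erase_partner("P001", actor="r1", actor_role="researcher")
    report = system.erase_partner("P001", actor="manager")
    assert report["pseudonym"] == "P001"


def test_async_commit_queues_until_flush():
    system = ConsentSystem(config=Config(seed=11, auto_flush=False))
    password = _enroll_partner(system)
    session = system.portal_login("P001", password)
    system.get_identity(session.session_token, "P001", "S1")
    system.credential_card(session.session_token, "P001", "S1")
    token = system.issue_token(["set_consent", "view_trail"], "P001")
    length_before = len(system.ledger.chain)
    system.set_consent(token.token, "P001", "S1", True)
    assert len(system.ledger.chain) == length_before  # queued, not committed
    assert system.consent_trail(token.token, "P001", "S1") == []
    system.flush()
    assert len(system.ledger.chain) == length_before + 1
    assert [c["consent"] for c in system.consent_trail(token.token, "P001", "S1")] == [True]


def test_aggregate_view_requires_attachment(system):
    system.add_researcher("r1", "Dr. One")
    system.add_researcher("r2", "Dr. Two")
    system.create_study("S1", ["r1"])
    password = _enroll_partner(system, studies=())
    _full_workflow(system, "P001", password, "S1")
    t_attached = system.issue_token(["view_aggregate"], "r1")
    t_foreign = system.issue_token(["view_aggregate"], "r2")
    assert system.aggregate_view(t_attached.token, "S1")["consented_count"] == 1
    with pytest.raises(AccessDenied):
        system.aggregate_view(t_foreign.token, "S1")


def test_interest_queue_is_manager_only(system):
    system.express_interest("Alice Vella", "alice@example.org")
    assert system.interest_queue("biobank_manager")[0]["name"] == "Alice Vella"
    with pytest.raises(AccessDenied):
        system.interest_queue("research_partner")
    with pytest.raises(ValueError):
        system.express_interest("", "x")


def test_event_log_records_decisions(system):
    password = _enroll_partner(system)
    system.portal_login("P001", password)
    try:
        system.portal_login("P001", "bad")
    except AuthError:
        pass
    decisions = [(e["capability"], e["decision"]) for e in system.events]
    assert ("portal_login", "allow") in decisions
    assert ("portal_login", "deny") in [
        (c, d.split(":")[0]) for c, d in decisions
    ]
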