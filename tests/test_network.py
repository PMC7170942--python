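"""Consent business network: participants, studies, consent assets,
queries, and access-control enforcement that propagates to queries."""

from random import Random

import pytest

from consentledger import access
from consentledger.access import AccessDenied
from consentledger.clockutil import ManualClock
from consentledger.crypto import ed25519
from consentledger.ledger import Ledger
from consentledger.network import (
    ConflictError,
    ConsentNetwork,
    HANDLERS,
    IdentityError,
    NotFoundError,
    latest_consent,
)


def _seed(rng: Random) -> bytes:
    return rng.getrandbits(256).to_bytes(32, "big")


@pytest.fixture
def net(rng):
    ledger = Ledger(dict(HANDLERS), clock=ManualClock().iso)
    return ConsentNetwork(ledger, admin_seed=_seed(rng))


def _enroll(net, rng, uuid="u-1", study="S1"):
    seed = _seed(rng)
    net.create_study(study, "biobank_manager")
    net.register_participant(uuid, None, "biobank_manager")
    net.bind_participant_key(uuid, ed25519.public_from_seed(seed), "biobank_manager")
    return seed


def test_manager_registers_participant(net):
    net.register_participant("u-1", None, "biobank_manager")
    assert "u-1" in net.ledger.state.participants


def test_duplicate_uuid_conflicts(net):
    net.register_participant("u-1", None, "biobank_manager")
    with pytest.raises(ConflictError):
        net.register_participant("u-1", None, "biobank_manager")


def test_partner_cannot_register_participants(net):
    with pytest.raises(AccessDenied):
        net.register_participant("u-2", None, "research_partner")


def test_researcher_cannot_create_study(net):
    with pytest.raises(AccessDenied):
        net.create_study("S1", "researcher")


def test_duplicate_study_conflicts(net):
    net.create_study("S1", "biobank_manager")
    with pytest.raises(ConflictError):
        net.create_study("S1", "biobank_manager")


def test_consent_appends_new_assets_never_updates(net, rng):
    seed = _enroll(net, rng)
    net.set_consent("u-1", "S1", True, seed)
    trail1 = net.consent_trail("u-1", "S1", "u-1")
    assert [c["consent"] for c in trail1] == [True]
    assert net.has_consented("u-1", "S1", "u-1") is True
    net.set_consent("u-1", "S1", False, seed)
    trail2 = net.consent_trail("u-1", "S1", "u-1")
    assert [c["consent"] for c in trail2] == [True, False]
    assert net.has_consented("u-1", "S1", "u-1") is False
    # earlier assets untouched
    assert trail2[0] == trail1[0]
    # repeated identical values are new assets too
    net.set_consent("u-1", "S1", False, seed)
    assert len(net.consent_trail("u-1", "S1", "u-1")) == 3


def test_uncredentialed_identity_cannot_consent(net, rng):
    seed = _seed(rng)
    net.create_study("S1", "biobank_manager")
    net.register_participant("u-1", None, "biobank_manager")
    with pytest.raises(IdentityError):
        net.set_consent("u-1", "S1", True, seed)


def test_foreign_key_cannot_sign_consent(net, rng):
    _enroll(net, rng, uuid="u-1")
    other = _seed(rng)
    with pytest.raises(AccessDenied):
        net.set_consent("u-1", "S1", True, other)


def test_unknown_study_not_found(net, rng):
    seed = _seed(rng)
    net.register_participant("u-1", None, "biobank_manager")
    net.bind_participant_key("u-1", ed25519.public_from_seed(seed), "biobank_manager")
    with pytest.raises(NotFoundError):
        net.set_consent("u-1", "S404", True, seed)


def test_quiz_gate_blocks_consent(net, rng):
    seed = _enroll(net, rng)
    with pytest.raises(AccessDenied):
        net.set_consent("u-1", "S1", True, seed, quiz_passed=False)


def test_trail_is_owner_only(net, rng):
    seed = _enroll(net, rng)
    net.set_consent("u-1", "S1", True, seed)
    with pytest.raises(AccessDenied):
        net.consent_trail("u-1", "S1", "u-other")
    with pytest.raises(AccessDenied):
        net.has_consented("u-1", "S1", "u-other")


def test_empty_trail_means_not_consented(net, rng):
    _enroll(net, rng)
    assert net.consent_trail("u-1", "S1", "u-1") == []
    assert net.has_consented("u-1", "S1", "u-1") is False
    assert latest_consent([]) is False


def test_study_consent_changes_is_manager_only(net, rng):
    seed1 = _enroll(net, rng, uuid="u-1")
    seed2 = _seed(rng)
    net.register_participant("u-2", None, "biobank_manager")
    net.bind_participant_key("u-2", ed25519.public_from_seed(seed2), "biobank_manager")
    for seed, uuid in ((seed1, "u-1"), (seed2, "u-2")):
        net.set_consent(uuid, "S1", True, seed)
        net.set_consent(uuid, "S1", False, seed)
    changes = net.study_consent_changes("S1", "biobank_manager")
    assert len(changes) == 4
    for role in ("research_partner", "researcher", "public"):
        with pytest.raises(AccessDenied):
            net.study_consent_changes("S1", role)
    assert net.study_consent_changes("S-empty", "biobank_manager") == []


def test_aggregate_counts_currently_consented_only(net, rng):
    uuids = ["u-1", "u-2", "u-3", "u-4"]
    net.create_study("S1", "biobank_manager")
    seeds = {}
    for uuid in uuids:
        seed = _seed(rng)
        seeds[uuid] = seed
        net.register_participant(uuid, None, "biobank_manager")
        net.bind_participant_key(
            uuid, ed25519.public_from_seed(seed), "biobank_manager"
        )
        net.set_consent(uuid, "S1", True, seed)
    net.set_consent("u-4", "S1", False, seeds["u-4"])  # one withdrawal
    view = net.aggregate_study_view("S1", "researcher", attached=True)
    assert view == {"study_id": "S1", "consented_count": 3}
    # counts only: no identifier-bearing fields in the response
    assert set(view) == {"study_id", "consented_count"}


def test_unattached_researcher_denied_aggregate(net):
    net.create_study("S1", "biobank_manager")
    with pytest.raises(AccessDenied):
        net.aggregate_study_view("S1", "researcher", attached=False)


# -- the role/capability matrix ------------------------------------------------

EXPECTED_GRANTS = {
    ("biobank_manager", "manage_partners"): "all",
    ("biobank_manager", "manage_researchers"): "all",
    ("biobank_manager", "manage_studies"): "all",
    ("biobank_manager", "view_study_consents"): "all",
    ("researcher", "view_aggregate"): "aggregate",
    ("research_partner", "set_consent"): "own",
    ("research_partner", "view_trail"): "own",
    ("research_partner", "request_destruction"): "own",
    ("public", "view_governance_docs"): "all",
    ("public", "express_interest"): "all",
    ("public", "view_study_updates"): "all",
}


def test_access_matrix_matches_role_table_exactly():
    """Exhaustive (role x capability x own/other) enumeration reproduces the
    granted capabilities and nothing more."""
    matrix = access.full_matrix()
    assert set(matrix) == {
        (r, c) for r in access.ROLES for c in access.CAPABILITIES
    }
    for key, scope in matrix.items():
        assert scope == EXPECTED_GRANTS.get(key, "none")
    for (role, capability), scope in matrix.items():
        for relation in ("own", "other"):
            allowed = access.check_access(role, capability, relation)
            if scope == "none":
                assert not allowed
            elif scope == "all":
                assert allowed
            else:  # own / aggregate reach own records only
                assert allowed == (relation == "own")


def test_spot_checks_from_role_table():
    assert access.check_access("research_partner", "set_consent", "own")
    assert not access.check_access("research_partner", "set_consent", "other")
    assert access.check_access("public", "view_governance_docs", "other")
    assert not access.check_access("researcher", "view_trail", "other")
    assert not access.check_access("researcher", "view_study_consents", "own")
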