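"""Synthetic cohort scenarios: generation and full-stack execution.

A scenario stands in for a recruited cohort: pseudonymous partners with
fabricated personal fields, a handful of studies, and a time-ordered
stream of consent events (give / withdraw / erase). Everything derives
from one integer seed, so a scenario is fully reproducible and contains
no real personal data.

Defaults model a small biobank cohort where most events are consent
grants, withdrawals are common, and erasure requests are rare:
55% give / 35% withdraw / 10% erase. Events never reference a partner
who has already been erased.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from random import Random
from typing import List, Optional

from consentledger.config import Config
from consentledger.system import ConsentSystem

__all__ = ["Scenario", "generate_scenario", "run_scenario"]

_FIRST = ["Ana", "Ben", "Carla", "David", "Elena", "Frank", "Gina", "Hugo",
          "Iris", "Jonas", "Karen", "Luis", "Mara", "Nico", "Olga", "Pau"]
_LAST = ["Attard", "Borg", "Camilleri", "Dalli", "Ellis", "Farrugia",
         "Grech", "Hill", "Inglott", "Jensen", "Klein", "Lopez"]

_ACTION_WEIGHTS = (("give", 0.55), ("withdraw", 0.35), ("erase", 0.10))


@dataclass
class Scenario:
    seed: int
    partners: List[dict] = field(default_factory=list)
    studies: List[str] = field(default_factory=list)
    actions: List[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Scenario":
        return cls(**json.loads(text))


def generate_scenario(
    n_partners: int, n_studies: int, n_actions: int, seed: int
) -> Scenario:
    """Deterministic synthetic cohort for the given seed.

    Every action references a generated partner and study; erase events
    can only target partners that are still present, and no later action
    targets an erased partner. If every partner has been erased the action
    stream ends early.
    """
    if min(n_partners, n_studies, n_actions) < 0:
        raise ValueError("counts must be non-negative")
    rng = Random(seed)
    partners = [
        {
            "pseudonym": f"P{i + 1:04d}",
            "name": f"{rng.choice(_FIRST)} {rng.choice(_LAST)}",
            "email": f"partner{i + 1}@example.org",
            "contact": f"+356-{rng.randrange(10 ** 7, 10 ** 8)}",
        }
        for i in range(n_partners)
    ]
    studies = [f"S{j + 1:03d}" for j in range(n_studies)]
    actions: List[dict] = []
    alive = [p["pseudonym"] for p in partners]
    kinds = [k for k, _ in _ACTION_WEIGHTS]
    weights = [w for _, w in _ACTION_WEIGHTS]
    while len(actions) < n_actions and alive and studies:
        kind = rng.choices(kinds, weights=weights)[0]
        pseudonym = rng.choice(alive)
        study = rng.choice(studies)
        actions.append({"pseudonym": pseudonym, "study": study, "kind": kind})
        if kind == "erase":
            alive.remove(pseudonym)
    return Scenario(seed=seed, partners=partners, studies=studies, actions=actions)


def run_scenario(
    scenario: Scenario,
    db_path: str = ":memory:",
    config: Optional[Config] = None,
) -> dict:
    """Replay a scenario through the full stack and report the outcome.

    Each consent event runs the complete partner workflow — login,
    identity issue/reuse, card credentialing, token issuance, a signed
    consent transaction — and erase events exercise the right to erasure.
    The report includes the final chain length, per-study consented
    counts, the chain verification verdict, and a replay-equivalence
    check; any invariant breach surfaces as an exception from the layer
    that owns it.
    """
    if config is None:
        config = Config(seed=scenario.seed)
    system = ConsentSystem(config=config, db_path=db_path)

    passwords = {}
    for partner in scenario.partners:
        _, password = system.register_partner(
            partner["pseudonym"], partner["name"], partner["email"],
            partner["contact"],
        )
        passwords[partner["pseudonym"]] = password
    for study in scenario.studies:
        system.create_study(study)

    counts = {"give": 0, "withdraw": 0, "erase": 0}
    registrations = 0
    for action in scenario.actions:
        pseudonym, study, kind = (
            action["pseudonym"], action["study"], action["kind"],
        )
        if kind == "erase":
            system.erase_partner(pseudonym, actor=pseudonym,
                                 actor_role="research_partner")
            counts["erase"] += 1
            continue
        session = system.portal_login(pseudonym, passwords[pseudonym])
        fresh = system.store.resolve_identity(pseudonym, study) is None
        system.get_identity(session.session_token, pseudonym, study)
        if fresh:
            registrations += 1
        system.credential_card(session.session_token, pseudonym, study)
        token = system.issue_token(["set_consent", "view_trail"], pseudonym)
        system.set_consent(token.token, pseudonym, study, kind == "give")
        counts[kind] += 1
    system.flush()

    per_study = {}
    manager_token = system.issue_token(["view_study_consents"], "manager")
    for study in scenario.studies:
        changes = system.study_consent_changes(manager_token.token, study)
        latest = {}
        for change in changes:
            latest[change["participant_uuid"]] = change["consent"]
        per_study[study] = sum(1 for value in latest.values() if value)

    verdict = system.verify_chain()
    return {
        "seed": scenario.seed,
        "n_partners": len(scenario.partners),
        "n_studies": len(scenario.studies),
        "n_actions": len(scenario.actions),
        "counts": counts,
        "identity_registrations": registrations,
        "chain_length": len(system.ledger.chain),
        "n_consent_transactions": counts["give"] + counts["withdraw"],
        "per_study_consented": per_study,
        "verify_chain": "valid" if verdict else f"bad@{verdict.first_bad_height}",
        "replay_equivalent": system.replay_matches(verify_signatures=False),
        "chain_only_recoverable_pairs": len(
            system.linkage_audit()["recoverable_pairs_chain_only"]
        ),
        "system": system,
    }
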