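"""Role/capability access matrix for the consent network.

Four roles — biobank manager, researcher, research partner, general
public — each with a fixed capability set. The table is total: every
(role, capability) pair maps to a scope, with ``none`` (deny) as the
default for anything not explicitly granted.

Scopes:
  * ``all``       — the capability reaches every subject's records.
  * ``own``       — only the actor's own records (or their own person).
  * ``aggregate`` — only de-identified counts over studies the actor is
                    attached to; no identifiers, no trails.
  * ``none``      — denied.
"""

from __future__ import annotations

from typing import Dict, Tuple

__all__ = [
    "ROLES",
    "CAPABILITIES",
    "GRANTS",
    "full_matrix",
    "check_access",
    "require",
    "AccessDenied",
]


class AccessDenied(PermissionError):
    """Raised when a capability check fails."""


ROLES = (
    "biobank_manager",
    "researcher",
    "research_partner",
    "public",
)

CAPABILITIES = (
    # biobank manager: create, edit, remove partners / researchers / studies
    "manage_partners",
    "manage_researchers",
    "manage_studies",
    # manager: list of partners who consented in research studies
    "view_study_consents",
    # researcher: aggregate counts over their associated studies
    "view_aggregate",
    # research partner rights
    "set_consent",
    "view_trail",
    "request_destruction",
    # general public
    "view_governance_docs",
    "express_interest",
    "view_study_updates",
)

# The explicit grant table; everything absent is scope "none".
GRANTS: Dict[Tuple[str, str], str] = {
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


def full_matrix() -> Dict[Tuple[str, str], str]:
    """The total (role, capability) → scope table, defaults filled in."""
    table = {(r, c): "none" for r in ROLES for c in CAPABILITIES}
    table.update(GRANTS)
    return table


def check_access(role: str, capability: str, ownership_relation: str = "own") -> bool:
    """Decide allow/deny for an actor's capability over a target relation.

    ``ownership_relation`` is ``own`` when the target is the actor's own
    record (or an attached study, for aggregate scope) and ``other``
    otherwise. Deny by default.
    """
    scope = full_matrix().get((role, capability), "none")
    if scope == "none":
        return False
    if scope == "all":
        return True
    # own / aggregate reach only the actor's own (or attached) records
    return ownership_relation == "own"


def require(role: str, capability: str, ownership_relation: str = "own") -> None:
    if not check_access(role, capability, ownership_relation):
        raise AccessDenied(
            f"role {role!r} lacks {capability!r} over {ownership_relation!r} records"
        )
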