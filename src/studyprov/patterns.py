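"""Declarative provenance patterns.

A *provenance pattern* states, for one activity type, which entity types it
must/can use and generate (with cardinalities), whether an agent is
required, and which attributes each participant must carry. The builder
matches every incoming activity against its pattern before chaining it into
the study graph; activities that do not match are discarded to the error
log.

Patterns are specified in YAML::

    patterns:
      - activity: SpecifyingSimulationExperiment
        uses:
          - {entity: SimulationModel, min: 1}
          - {entity: Assumption}            # min defaults to 0 (optional)
        generates:
          - {entity: SimulationExperiment, min: 1, max: 1}
        agent: {required: true, required_attributes: [name]}

Defaults: ``min`` 0, ``max`` unbounded, ``required_attributes``
``[name, path]`` for entities and ``[name]`` for agents. A required
cardinality (``min >= 1``) encodes "always uses/produces"; ``min == 0``
encodes "can sometimes use".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence, Union

import yaml

from .model import ActivityType, EntityType

__all__ = [
    "EntityConstraint",
    "ProvenancePattern",
    "PatternSet",
    "MatchViolation",
    "MatchResult",
    "PatternError",
    "PatternParseError",
    "PatternSchemaError",
    "load_patterns",
    "default_patterns",
    "match_activity",
]

UNBOUNDED = None  # max_count sentinel


class PatternError(Exception):
    pass


class PatternParseError(PatternError):
    """The YAML text itself is malformed."""


class PatternSchemaError(PatternError):
    """Well-formed YAML that violates the pattern dialect."""


@dataclass(frozen=True)
class EntityConstraint:
    """Cardinality + attribute rule for one entity type in one role."""

    entity_type: EntityType
    role: str  # "used" | "generated"
    min_count: int = 0
    max_count: Optional[int] = UNBOUNDED
    required_attributes: tuple = ("name", "path")
    optional_attributes: tuple = ()

    def __post_init__(self) -> None:
        if self.role not in ("used", "generated"):
            raise PatternSchemaError(f"bad role {self.role!r}")
        if self.min_count < 0:
            raise PatternSchemaError("min must be >= 0")
        if self.max_count is not UNBOUNDED:
            if self.max_count < 1:
                raise PatternSchemaError("max must be >= 1")
            if self.min_count > self.max_count:
                raise PatternSchemaError(
                    f"{self.entity_type.value}: min {self.min_count} > max {self.max_count}"
                )
        overlap = set(self.required_attributes) & set(self.optional_attributes)
        if overlap:
            raise PatternSchemaError(
                f"attributes both required and optional: {sorted(overlap)}"
            )


@dataclass(frozen=True)
class ProvenancePattern:
    """Validity rule for one activity type."""

    activity_type: ActivityType
    used_constraints: tuple = ()
    generated_constraints: tuple = ()
    agent_required: bool = True
    agent_required_attributes: tuple = ("name",)

    def __post_init__(self) -> None:
        if not any(c.min_count >= 1 for c in self.generated_constraints):
            raise PatternSchemaError(
                f"{self.activity_type.value}: every activity must generate "
                "something (need one generated constraint with min >= 1)"
            )
        for cs, role in ((self.used_constraints, "used"),
                         (self.generated_constraints, "generated")):
            seen = set()
            for c in cs:
                if c.role != role:
                    raise PatternSchemaError("constraint role/list mismatch")
                if c.entity_type in seen:
                    raise PatternSchemaError(
                        f"duplicate {role} constraint for {c.entity_type.value}"
                    )
                seen.add(c.entity_type)

    def constraint_for(self, role: str, entity_type: EntityType) -> Optional[EntityConstraint]:
        cs = self.used_constraints if role == "used" else self.generated_constraints
        for c in cs:
            if c.entity_type == entity_type:
                return c
        return None


@dataclass(frozen=True)
class PatternSet:
    """One pattern per activity type (user sets may cover a subset)."""

    patterns: dict

    def get(self, activity_type: ActivityType) -> Optional[ProvenancePattern]:
        return self.patterns.get(activity_type)

    def __len__(self) -> int:
        return len(self.patterns)


# -- match results -----------------------------------------------------

#: violation codes
MISSING_ENTITY = "missing-entity"
EXCESS_ENTITY = "excess-entity"
UNKNOWN_ENTITY = "unknown-entity"
MISSING_ATTRIBUTE = "missing-attribute"
MISSING_AGENT = "missing-agent"
UNKNOWN_ACTIVITY = "unknown-activity"


@dataclass(frozen=True)
class MatchViolation:
    code: str
    detail: str

    def to_dict(self) -> dict:
        return {"code": self.code, "detail": self.detail}


@dataclass(frozen=True)
class MatchResult:
    violations: tuple = ()
    warnings: tuple = ()

    @property
    def valid(self) -> bool:
        return not self.violations


# -- YAML loading ------------------------------------------------------


def _parse_max(raw) -> Optional[int]:
    if raw in (None, "unbounded"):
        return UNBOUNDED
    if isinstance(raw, bool) or not isinstance(raw, int):
        raise PatternSchemaError(f"max must be an integer or 'unbounded', got {raw!r}")
    return raw


def _parse_constraint(item: dict, role: str) -> EntityConstraint:
    if not isinstance(item, dict) or "entity" not in item:
        raise PatternSchemaError(f"each {role} item needs an 'entity' key: {item!r}")
    try:
        etype = EntityType.parse(item["entity"])
    except ValueError as exc:
        raise PatternSchemaError(str(exc)) from None
    known = {"entity", "min", "max", "required_attributes", "optional_attributes"}
    unknown = set(item) - known
    if unknown:
        raise PatternSchemaError(f"unknown constraint keys: {sorted(unknown)}")
    return EntityConstraint(
        entity_type=etype,
        role=role,
        min_count=int(item.get("min", 0)),
        max_count=_parse_max(item.get("max", "unbounded")),
        required_attributes=tuple(item.get("required_attributes", ("name", "path"))),
        optional_attributes=tuple(item.get("optional_attributes", ())),
    )


def load_patterns(yaml_text: str) -> PatternSet:
    """Parse pattern YAML into a :class:`PatternSet`.

    Raises :class:`PatternParseError` for malformed YAML and
    :class:`PatternSchemaError` for unknown labels, ``min > max``, or
    structural mistakes.
    """
    try:
        doc = yaml.safe_load(yaml_text)
    except yaml.YAMLError as exc:
        raise PatternParseError(f"malformed YAML: {exc}") from exc
    if not isinstance(doc, dict) or "patterns" not in doc:
        raise PatternSchemaError("document must have a top-level 'patterns' list")
    items = doc["patterns"]
    if not isinstance(items, list):
        raise PatternSchemaError("'patterns' must be a list")
    patterns: dict = {}
    for item in items:
        if not isinstance(item, dict) or "activity" not in item:
            raise PatternSchemaError(f"each pattern needs an 'activity' key: {item!r}")
        try:
            atype = ActivityType.parse(item["activity"])
        except ValueError as exc:
            raise PatternSchemaError(str(exc)) from None
        if atype in patterns:
            raise PatternSchemaError(f"duplicate pattern for {atype.value}")
        agent_spec = item.get("agent", {}) or {}
        if not isinstance(agent_spec, dict):
            raise PatternSchemaError("'agent' must be a mapping")
        patterns[atype] = ProvenancePattern(
            activity_type=atype,
            used_constraints=tuple(
                _parse_constraint(c, "used") for c in (item.get("uses") or [])
            ),
            generated_constraints=tuple(
                _parse_constraint(c, "generated") for c in (item.get("generates") or [])
            ),
            agent_required=bool(agent_spec.get("required", True)),
            agent_required_attributes=tuple(
                agent_spec.get("required_attributes", ("name",))
            ),
        )
    return PatternSet(patterns=patterns)


def default_patterns() -> PatternSet:
    """The shipped default pattern set covering all eight activity types."""
    text = resources.files("studyprov.data").joinpath("default_patterns.yaml").read_text()
    return load_patterns(text)


# -- matching ----------------------------------------------------------


def _resolve_types(
    instances: Sequence, role: str, violations: list
) -> list[tuple[EntityType, dict]]:
    resolved = []
    for raw_type, attrs in instances:
        if isinstance(raw_type, EntityType):
            resolved.append((raw_type, attrs))
            continue
        try:
            resolved.append((EntityType.parse(raw_type), attrs))
        except ValueError:
            violations.append(
                MatchViolation(UNKNOWN_ENTITY, f"{role} entity has unknown type {raw_type!r}")
            )
    return resolved


def match_activity(
    patterns: PatternSet,
    activity_type: Union[ActivityType, str],
    used: Sequence,
    generated: Sequence,
    agent: Optional[tuple] = None,
    strict: bool = True,
) -> MatchResult:
    """Match one activity (entity instances + agent) against its pattern.

    ``used``/``generated`` are sequences of ``(entity_type, attributes)``
    pairs; ``agent`` is ``(name, attributes)`` or ``None``. Valid iff every
    per-type count lies within its constraint's ``[min, max]``, no entity
    type outside the pattern's constraints is attached (downgraded to a
    warning when ``strict`` is false), every present participant carries
    its required attributes non-empty, and an agent is present whenever the
    pattern requires one. Pure function: no inputs are mutated.
    """
    violations: list[MatchViolation] = []
    warnings: list[MatchViolation] = []

    if not isinstance(activity_type, ActivityType):
        try:
            activity_type = ActivityType.parse(activity_type)
        except ValueError:
            return MatchResult(
                violations=(
                    MatchViolation(UNKNOWN_ACTIVITY, f"unknown activity type {activity_type!r}"),
                )
            )
    pattern = patterns.get(activity_type)
    if pattern is None:
        return MatchResult(
            violations=(
                MatchViolation(
                    UNKNOWN_ACTIVITY, f"no pattern covers {activity_type.value}"
                ),
            )
        )

    for role, instances, constraints in (
        ("used", used, pattern.used_constraints),
        ("generated", generated, pattern.generated_constraints),
    ):
        typed = _resolve_types(instances, role, violations)
        counts: dict[EntityType, int] = {}
        for etype, _ in typed:
            counts[etype] = counts.get(etype, 0) + 1
        by_type = {c.entity_type: c for c in constraints}
        for c in constraints:
            n = counts.get(c.entity_type, 0)
            if n < c.min_count:
                violations.append(
                    MatchViolation(
                        MISSING_ENTITY,
                        f"{activity_type.value} requires at least {c.min_count} "
                        f"{role} {c.entity_type.value}, found {n}",
                    )
                )
            if c.max_count is not UNBOUNDED and n > c.max_count:
                violations.append(
                    MatchViolation(
                        EXCESS_ENTITY,
                        f"{activity_type.value} allows at most {c.max_count} "
                        f"{role} {c.entity_type.value}, found {n}",
                    )
                )
        for etype in counts:
            if etype not in by_type:
                v = MatchViolation(
                    UNKNOWN_ENTITY,
                    f"{etype.value} is not a valid {role} entity for {activity_type.value}",
                )
                (violations if strict else warnings).append(v)
        for etype, attrs in typed:
            c = by_type.get(etype)
            if c is None:
                continue
            for key in c.required_attributes:
                if not attrs.get(key):
                    violations.append(
                        MatchViolation(
                            MISSING_ATTRIBUTE,
                            f"{role} {etype.value} "
                            f"({attrs.get('name') or attrs.get('path') or '?'}) "
                            f"is missing required attribute {key!r}",
                        )
                    )

    if agent is None:
        if pattern.agent_required:
            violations.append(
                MatchViolation(MISSING_AGENT, f"{activity_type.value} requires an agent")
            )
    else:
        _, agent_attrs = agent
        for key in pattern.agent_required_attributes:
            if not agent_attrs.get(key):
                violations.append(
                    MatchViolation(
                        MISSING_ATTRIBUTE, f"agent is missing required attribute {key!r}"
                    )
                )

    return MatchResult(violations=tuple(violations), warnings=tuple(warnings))
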