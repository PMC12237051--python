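"""Reference provenance capturers.

Two capture styles cover most modeling tools:

* a *file-tracking* capturer (the editor-plugin contract): the modeler
  creates a typed entity file, optionally citing existing conceptual
  entities; each save with changed content emits a ``specifying_*`` event
  carrying the new content and the previous content hash. Edit detection
  is content-hash based, so capture is deterministic and needs no
  filesystem watcher.
* an *execution-wrapping* helper (the utility-library contract): the
  modeler wraps the call that runs a simulation experiment or analysis
  script; the wrapper runs it, hashes the output file and emits an
  ``executing_simulation_experiment`` (or ``analyzing_simulation_data``)
  event. A failing run still emits its event, flagged ``failed`` with an
  empty output descriptor, so dead ends stay visible in the study graph.

Entity types are inferred from a file-name prefix convention
(``model_*`` -> SimulationModel, ``assumption_*`` -> Assumption, ...);
when no convention applies the type must be made explicit by the modeler
— the SDK never guesses.
"""

from __future__ import annotations

import hashlib
import json
import platform
import sys
import uuid
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Optional, Union

import yaml

from .builder import AgentDescriptor, EntityDescriptor, Event
from .model import ActivityType, EntityIdentity, EntityType, canonical_path

__all__ = [
    "CaptureError",
    "DuplicateRegistrationError",
    "UntrackedFileError",
    "TrackedFile",
    "CaptureSession",
    "infer_entity_type",
    "load_conventions",
]


class CaptureError(Exception):
    pass


class DuplicateRegistrationError(CaptureError):
    """The path is already tracked by this session."""


class UntrackedFileError(CaptureError):
    """detect_edit was called for a path that was never registered."""


#: entity types that have a dedicated ``specifying_*`` activity; the other
#: types (QualitativeModel, Data, Script, ...) enter the graph as
#: used-descriptors, bootstrapped to version 1 by the builder.
SPECIFIABLE = {
    EntityType.REFERENCE: ActivityType.SPECIFYING_REFERENCE,
    EntityType.RESEARCH_QUESTION: ActivityType.SPECIFYING_RESEARCH_QUESTION,
    EntityType.REQUIREMENT: ActivityType.SPECIFYING_REQUIREMENT,
    EntityType.ASSUMPTION: ActivityType.SPECIFYING_ASSUMPTION,
    EntityType.SIMULATION_MODEL: ActivityType.SPECIFYING_SIMULATION_MODEL,
    EntityType.SIMULATION_EXPERIMENT: ActivityType.SPECIFYING_SIMULATION_EXPERIMENT,
}


def _sha256(data: Union[str, bytes]) -> str:
    if isinstance(data, str):
        data = data.encode("utf-8")
    return hashlib.sha256(data).hexdigest()


def load_conventions(text: Optional[str] = None) -> dict:
    """Load the (editable) file-naming convention table.

    Returns ``{prefix: EntityType}``; the shipped default maps
    ``reference_``, ``question_``, ``requirement_``, ``assumption_``,
    ``qualitative_``, ``data_``, ``model_``, ``experiment_`` and
    ``script_`` prefixes.
    """
    if text is None:
        text = resources.files("studyprov.data").joinpath("naming_conventions.yaml").read_text()
    doc = yaml.safe_load(text)
    table = {}
    for prefix, label in (doc.get("prefixes") or {}).items():
        table[str(prefix)] = EntityType.parse(label)
    return table


_DEFAULT_CONVENTIONS: Optional[dict] = None


def infer_entity_type(path: str, conventions: Optional[dict] = None) -> Optional[EntityType]:
    """Infer an entity type from the file name, or ``None`` when no
    convention applies (the modeler must then make the type explicit)."""
    global _DEFAULT_CONVENTIONS
    if conventions is None:
        if _DEFAULT_CONVENTIONS is None:
            _DEFAULT_CONVENTIONS = load_conventions()
        conventions = _DEFAULT_CONVENTIONS
    basename = canonical_path(path).rsplit("/", 1)[-1].casefold()
    for prefix, etype in sorted(conventions.items(), key=lambda kv: -len(kv[0])):
        if basename.startswith(prefix.casefold()):
            return etype
    return None


@dataclass
class TrackedFile:
    identity: EntityIdentity
    last_content_hash: str
    used_conceptual_ids: tuple = ()


@dataclass
class CaptureSession:
    """One tool session: an agent, a sink, and the files it tracks.

    ``sink`` may be a callable (e.g. an HTTP poster), a JSONL file path to
    append to, or ``None``; every emitted event is also kept in
    ``emitted``. ``id_factory``/``clock`` are injectable for deterministic
    streams (defaults: UUID4 ids, empty timestamps).
    """

    agent_name: str
    agent_version: Optional[str] = None
    sink: Union[None, str, Path, Callable[[Event], None]] = None
    conventions: Optional[dict] = None
    id_factory: Callable[[], str] = lambda: uuid.uuid4().hex
    clock: Callable[[], str] = lambda: ""
    tracked: dict = field(default_factory=dict)
    emitted: list = field(default_factory=list)

    def _agent(self) -> AgentDescriptor:
        return AgentDescriptor(name=self.agent_name, version=self.agent_version)

    def _emit(self, event: Event) -> Event:
        self.emitted.append(event)
        if callable(self.sink):
            self.sink(event)
        elif self.sink is not None:
            with open(self.sink, "a", encoding="utf-8") as fh:
                fh.write(event.to_json() + "\n")
        return event

    def _descriptor(self, identity: EntityIdentity, **kw) -> EntityDescriptor:
        return EntityDescriptor(
            entity_type=identity.type_label,
            name=identity.name or identity.path.rsplit("/", 1)[-1],
            path=identity.path,
            **kw,
        )

    # -- file tracking ------------------------------------------------

    def register_entity(
        self,
        path: str,
        entity_type: Optional[EntityType] = None,
        name: Optional[str] = None,
        used: Iterable[EntityIdentity] = (),
        content: str = "",
    ) -> Event:
        """Create/track a typed entity file and emit its specifying event.

        ``entity_type`` may be omitted when the naming convention
        determines it. ``used`` lists already-existing conceptual entities
        the new one draws on (the modeler's selection).
        """
        cpath = canonical_path(path)
        if cpath in self.tracked:
            raise DuplicateRegistrationError(f"{cpath!r} is already tracked")
        if entity_type is None:
            entity_type = infer_entity_type(cpath, self.conventions)
            if entity_type is None:
                raise CaptureError(
                    f"cannot infer entity type of {cpath!r}; pass entity_type explicitly"
                )
        activity = SPECIFIABLE.get(entity_type)
        if activity is None:
            raise CaptureError(
                f"{entity_type.value} has no specifying activity; it enters the "
                "graph as a used-descriptor of another activity"
            )
        identity = EntityIdentity(entity_type, cpath, name or cpath.rsplit("/", 1)[-1])
        chash = _sha256(content)
        event = Event(
            event_id=self.id_factory(),
            event_type=activity.event_name,
            timestamp=self.clock(),
            agent=self._agent(),
            used=[self._descriptor(u) for u in used],
            generated=[
                self._descriptor(identity, content=content, content_hash=chash)
            ],
        )
        self.tracked[cpath] = TrackedFile(
            identity=identity, last_content_hash=chash, used_conceptual_ids=tuple(used)
        )
        return self._emit(event)

    def detect_edit(self, path: str, new_content: str) -> Optional[Event]:
        """Handle a save of a tracked file.

        Emits a specifying event iff the content hash changed (identical
        re-saves produce no spurious version); the event carries the new
        content and the previous hash.
        """
        cpath = canonical_path(path)
        tf = self.tracked.get(cpath)
        if tf is None:
            raise UntrackedFileError(f"{cpath!r} is not tracked by this session")
        chash = _sha256(new_content)
        if chash == tf.last_content_hash:
            return None
        activity = SPECIFIABLE[tf.identity.entity_type]
        event = Event(
            event_id=self.id_factory(),
            event_type=activity.event_name,
            timestamp=self.clock(),
            agent=self._agent(),
            used=[],
            generated=[
                self._descriptor(tf.identity, content=new_content, content_hash=chash)
            ],
            extras={"previous_content_hash": tf.last_content_hash},
        )
        tf.last_content_hash = chash
        return self._emit(event)

    # -- execution wrapping -------------------------------------------

    def wrap_execution(
        self,
        experiment_path: str,
        model_path: str,
        output_path: str,
        run_callable: Callable[[], object],
        activity: str = "executing_simulation_experiment",
        used_extra: Iterable[EntityIdentity] = (),
        output_type: EntityType = EntityType.SIMULATION_DATA,
    ) -> tuple:
        """Run a simulation/analysis callable and emit its event.

        Returns ``(result, event)``. On failure the result is ``None`` and
        the event is still emitted, flagged ``failed`` with the error text
        and an empty output descriptor — a dead-end iteration remains part
        of the provenance. Collected environment metadata goes to
        ``extras`` (best effort; never required by patterns).
        """
        failed = False
        error_text = None
        result = None
        try:
            result = run_callable()
        except Exception as exc:  # noqa: BLE001 - the event must record any failure
            failed = True
            error_text = f"{type(exc).__name__}: {exc}"

        out = Path(output_path)
        if out.exists():
            content_hash = _sha256(out.read_bytes())
            size = out.stat().st_size
        else:
            content_hash = _sha256(b"")
            size = 0

        exp_id = EntityIdentity(EntityType.SIMULATION_EXPERIMENT, experiment_path)
        model_id = EntityIdentity(EntityType.SIMULATION_MODEL, model_path)
        out_id = EntityIdentity(output_type, canonical_path(output_path))
        extras = {
            "status": "failed" if failed else "ok",
            "environment": {
                "python": sys.version.split()[0],
                "platform": platform.system(),
            },
            "output_size_bytes": size,
        }
        if error_text:
            extras["error"] = error_text
        event = Event(
            event_id=self.id_factory(),
            event_type=activity,
            timestamp=self.clock(),
            agent=self._agent(),
            used=[self._descriptor(exp_id), self._descriptor(model_id)]
            + [self._descriptor(u) for u in used_extra],
            generated=[self._descriptor(out_id, content_hash=content_hash)],
            extras=extras,
        )
        return result, self._emit(event)
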