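"""Actor base class, lifecycle states, and the run log."""

from __future__ import annotations

import json
import threading
import time
from dataclasses import dataclass
from enum import Enum
from typing import Any

from .queues import EdgeQueue, Message, MessageKind
from .store import DataKey, DataStore

__all__ = ["ActorStateEnum", "RunLog", "Actor"]


class ActorStateEnum(str, Enum):
    CREATED = "created"
    SETUP = "setup"
    RUNNING = "running"
    FAILED = "failed"
    STOPPED = "stopped"


_LEGAL = {
    ActorStateEnum.CREATED: {ActorStateEnum.SETUP},
    ActorStateEnum.SETUP: {ActorStateEnum.RUNNING},
    ActorStateEnum.RUNNING: {ActorStateEnum.FAILED, ActorStateEnum.STOPPED},
    ActorStateEnum.FAILED: set(),
    ActorStateEnum.STOPPED: set(),
}


@dataclass
class LogEvent:
    t_mono: float
    t_wall: float
    actor: str
    kind: str
    detail: str

    def to_dict(self) -> dict:
        return {
            "t_mono": self.t_mono,
            "t_wall": self.t_wall,
            "actor": self.actor,
            "kind": self.kind,
            "detail": self.detail,
        }


class RunLog:
    """Append-only event log; one record per fault, drop, eviction, etc."""

    def __init__(self):
        self._events: list[LogEvent] = []
        self._lock = threading.Lock()

    def log(self, actor: str, kind: str, detail: str = "") -> None:
        ev = LogEvent(
            t_mono=time.monotonic(),
            t_wall=time.time(),
            actor=actor,
            kind=kind,
            detail=detail,
        )
        with self._lock:
            self._events.append(ev)

    @property
    def events(self) -> list[LogEvent]:
        with self._lock:
            return list(self._events)

    def count(self, kind: str) -> int:
        return sum(1 for e in self.events if e.kind == kind)

    def of_kind(self, kind: str) -> list[LogEvent]:
        return [e for e in self.events if e.kind == kind]

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for ev in self.events:
                fh.write(json.dumps(ev.to_dict()) + "\n")


class Actor:
    """Base class for pipeline actors.

    Subclasses override :meth:`setup`, :meth:`step` and :meth:`teardown`.
    Non-source actors receive one :class:`Message` per ``step`` call; source
    actors (``is_source = True``) are stepped with ``None`` and emit at their
    own pace until the run's stop condition or until they set ``self.done``.
    """

    is_source = False

    def __init__(self, name: str, params: dict, store: DataStore, log: RunLog):
        self.name = name
        self.params = dict(params)
        self.store = store
        self.runlog = log
        self.done = False
        self.state = ActorStateEnum.CREATED
        self._outputs: dict[str, list[EdgeQueue]] = {}
        self._inputs: dict[str, list[EdgeQueue]] = {}

    # -- lifecycle ---------------------------------------------------------
    def _transition(self, new: ActorStateEnum) -> None:
        if new not in _LEGAL[self.state]:
            raise RuntimeError(f"illegal actor state transition {self.state} -> {new}")
        self.state = new

    def setup(self) -> None:  # pragma: no cover - default no-op
        pass

    def step(self, message: Message | None) -> None:
        raise NotImplementedError

    def teardown(self) -> None:  # pragma: no cover - default no-op
        pass

    # -- plumbing helpers --------------------------------------------------
    def put(self, topic: str, payload: Any) -> DataKey:
        return self.store.put(topic, payload)

    def get(self, key: DataKey) -> Any:
        return self.store.get(key)

    def emit(self, keys, port: str = "out") -> None:
        """Publish a data message carrying one or more store keys."""
        if isinstance(keys, DataKey):
            keys = (keys,)
        msg = Message(keys=tuple(keys), kind=MessageKind.DATA)
        for q in self._outputs.get(port, []):
            q.put(msg)

    def emit_payload(self, topic: str, payload: Any, port: str = "out") -> DataKey:
        """Store a payload and emit its key in one call."""
        key = self.put(topic, payload)
        self.emit(key, port=port)
        return key

    def emit_eos(self) -> None:
        from .queues import EOS

        for queues in self._outputs.values():
            for q in queues:
                q.put(EOS)

    def poll(self, port: str = "in") -> Message | None:
        """Non-blocking read of a (feedback) input port; used by sources."""
        for q in self._inputs.get(port, []):
            msg = q.get_nowait()
            if msg is not None:
                return msg
        return None

    def log(self, kind: str, detail: str = "") -> None:
        self.runlog.log(self.name, kind, detail)
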