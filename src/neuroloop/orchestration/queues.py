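"""Bounded FIFO message queues connecting actors.

Policy: when a data message arrives at a full queue, the *oldest* queued data
message is dropped (and logged) — staying current is preferred over
completeness.  Control messages (end-of-stream) are never dropped.  A sealed
queue (its consumer faulted) silently drops everything, with a log event.
"""

from __future__ import annotations

import threading
from collections import deque
from dataclasses import dataclass
from enum import Enum
from typing import Callable

from .store import DataKey

__all__ = ["MessageKind", "Message", "EdgeQueue", "DEFAULT_CAPACITY"]

DEFAULT_CAPACITY = 256


class MessageKind(str, Enum):
    DATA = "data"
    CONTROL = "control"
    END_OF_STREAM = "end-of-stream"


@dataclass(frozen=True)
class Message:
    keys: tuple[DataKey, ...] = ()
    kind: MessageKind = MessageKind.DATA

    def __post_init__(self):
        if self.kind == MessageKind.DATA and len(self.keys) == 0:
            raise ValueError("data messages must carry at least one key")
        if self.kind == MessageKind.END_OF_STREAM and self.keys:
            raise ValueError("end-of-stream messages carry no keys")


EOS = Message(kind=MessageKind.END_OF_STREAM)


class EdgeQueue:
    """One directed edge: src.port -> dst.port, bounded, drop-oldest."""

    def __init__(
        self,
        name: str,
        capacity: int = DEFAULT_CAPACITY,
        log: Callable[[str, str, str], None] | None = None,
    ):
        self.name = name
        self.capacity = capacity
        self._dq: deque[Message] = deque()
        self._lock = threading.Lock()
        self._log = log or (lambda actor, kind, detail: None)
        self.sealed = False
        self.dropped = 0
        self.max_occupancy = 0

    def __len__(self) -> int:
        return len(self._dq)

    def seal(self) -> None:
        with self._lock:
            self.sealed = True
            self._dq.clear()

    def put(self, msg: Message) -> bool:
        """Returns True if the message was enqueued."""
        with self._lock:
            if self.sealed:
                self._log("queue", "sealed-drop", f"{self.name}: dropped {msg.kind.value}")
                return False
            if msg.kind == MessageKind.DATA and len(self._dq) >= self.capacity:
                # drop the oldest *data* message to make room
                for i, queued in enumerate(self._dq):
                    if queued.kind == MessageKind.DATA:
                        del self._dq[i]
                        self.dropped += 1
                        self._log("queue", "overflow-drop", f"{self.name}: dropped oldest")
                        break
            self._dq.append(msg)
            self.max_occupancy = max(self.max_occupancy, len(self._dq))
            return True

    def get_nowait(self) -> Message | None:
        with self._lock:
            if self._dq:
                return self._dq.popleft()
            return None
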