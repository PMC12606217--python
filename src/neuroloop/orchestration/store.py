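"""Shared in-memory, key-addressed data store.

Actors never pass payloads to each other: a producer puts a payload into the
store once and forwards only the resulting :class:`DataKey`.  Any number of
consumers read the same entry, so a payload consumed by *m* actors still
occupies a single store slot.  Entries are immutable after the put.

Retention is bounded: each topic keeps at most ``retention`` entries (newest
first) and the store as a whole can enforce a byte budget.  The newest entry
of a topic is never evicted, even when it alone exceeds the byte budget.
"""

from __future__ import annotations

import itertools
import time
from collections import OrderedDict
from dataclasses import dataclass
from typing import Any, Callable

__all__ = [
    "DataKey",
    "StoreEntry",
    "DataStore",
    "MissingKeyError",
    "StoreCapacityError",
]


@dataclass(frozen=True)
class DataKey:
    """Address of one item in the shared store.

    ``seq`` increases strictly (0, 1, 2, ...) within a topic; ``timestamp``
    comes from a monotonic clock so ordering survives wall-clock jumps.
    """

    id: int
    topic: str
    seq: int
    timestamp: float


@dataclass
class StoreEntry:
    key: DataKey
    payload: Any
    size_bytes: int


class MissingKeyError(KeyError):
    """Raised when a key is unknown or its entry has been evicted."""

    def __init__(self, key: DataKey):
        super().__init__(f"no entry for topic={key.topic!r} seq={key.seq}")
        self.key = key


class StoreCapacityError(RuntimeError):
    pass


def _nbytes(payload: Any) -> int:
    nb = getattr(payload, "nbytes", None)
    if nb is not None:
        return int(nb)
    try:
        return len(payload)
    except TypeError:
        return 64  # flat estimate for scalars / small records


@dataclass
class RetentionPolicy:
    """Per-topic retention: keep the newest ``max_entries`` per topic and/or
    stay under ``max_bytes`` total (oldest-first eviction, newest entry of a
    topic is always retained)."""

    max_entries: int | None = 200
    max_bytes: int | None = None


class DataStore:
    """Single centralized store; one per pipeline run."""

    def __init__(
        self,
        retention: RetentionPolicy | None = None,
        hard_capacity_entries: int | None = None,
        log: Callable[[str, str, str], None] | None = None,
    ):
        self._entries: "OrderedDict[int, StoreEntry]" = OrderedDict()
        self._topic_seq: dict[str, int] = {}
        self._topic_keys: dict[str, list[int]] = {}
        self._ids = itertools.count()
        self.retention = retention or RetentionPolicy()
        self.hard_capacity_entries = hard_capacity_entries
        self._log = log or (lambda actor, kind, detail: None)
        self.total_bytes = 0

    def __len__(self) -> int:
        return len(self._entries)

    def topic_entries(self, topic: str) -> list[DataKey]:
        return [self._entries[i].key for i in self._topic_keys.get(topic, [])]

    def put(self, topic: str, payload: Any) -> DataKey:
        if (
            self.hard_capacity_entries is not None
            and len(self._entries) >= self.hard_capacity_entries
        ):
            raise StoreCapacityError(
                f"store at hard capacity ({self.hard_capacity_entries} entries)"
            )
        seq = self._topic_seq.get(topic, -1) + 1
        self._topic_seq[topic] = seq
        key = DataKey(
            id=next(self._ids), topic=topic, seq=seq, timestamp=time.monotonic()
        )
        entry = StoreEntry(key=key, payload=payload, size_bytes=_nbytes(payload))
        self._entries[key.id] = entry
        self._topic_keys.setdefault(topic, []).append(key.id)
        self.total_bytes += entry.size_bytes
        return key

    def get(self, key: DataKey) -> Any:
        entry = self._entries.get(key.id)
        if entry is None:
            raise MissingKeyError(key)
        return entry.payload

    def __contains__(self, key: DataKey) -> bool:
        return key.id in self._entries

    def _remove(self, entry_id: int) -> None:
        entry = self._entries.pop(entry_id)
        self._topic_keys[entry.key.topic].remove(entry_id)
        self.total_bytes -= entry.size_bytes

    def evict(self, policy: RetentionPolicy | None = None) -> int:
        """Apply the retention policy; returns the number of removed entries.

        Best-effort: never raises, never removes the newest entry of a topic.
        Logs one event per batch that removed anything.
        """
        policy = policy or self.retention
        removed = 0
        if policy.max_entries is not None:
            for topic, ids in self._topic_keys.items():
                excess = len(ids) - policy.max_entries
                for entry_id in list(ids[:max(excess, 0)]):
                    self._remove(entry_id)
                    removed += 1
        if policy.max_bytes is not None and self.total_bytes > policy.max_bytes:
            # oldest-id order approximates global oldest-first
            for entry_id in list(self._entries):
                if self.total_bytes <= policy.max_bytes:
                    break
                entry = self._entries[entry_id]
                topic_ids = self._topic_keys[entry.key.topic]
                if topic_ids[-1] == entry_id:  # newest of its topic: keep
                    self._log(
                        "store",
                        "retention-warning",
                        f"newest entry of topic {entry.key.topic!r} exceeds "
                        f"byte budget; retained anyway",
                    )
                    continue
                self._remove(entry_id)
                removed += 1
        if removed:
            self._log("store", "eviction", f"evicted {removed} entries")
        return removed
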