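"""Pipeline execution: concurrent (threaded) and cooperative executors.

The framework drives each actor through setup -> step* -> teardown.  Faults
inside an actor's ``step`` are contained: the actor transitions to ``failed``,
its input queues are sealed (messages sent to it are dropped with a log
event), end-of-stream is propagated downstream, and every other actor keeps
running until the pipeline's stop condition.

Two executors implement the same observable contract (per-edge FIFO order,
isolation, fault containment):

* ``"thread"`` — one thread per actor, the deployment mode;
* ``"inline"`` — a deterministic cooperative round-robin scheduler in the
  calling thread, used for reproducible property tests.
"""

from __future__ import annotations

import threading
import time
import traceback

from .actors import Actor, ActorStateEnum, RunLog
from .graph import PipelineGraph, resolve_impl
from .queues import DEFAULT_CAPACITY, EdgeQueue, Message, MessageKind
from .store import DataStore, RetentionPolicy

__all__ = ["PipelineRunner", "PipelineAbort", "run_pipeline"]


class PipelineAbort(RuntimeError):
    """Raised when an actor fails during setup (pre-run, hard abort)."""

    def __init__(self, actor: str, cause: BaseException):
        super().__init__(f"actor {actor!r} failed during setup: {cause}")
        self.actor = actor
        self.cause = cause


class _Harness:
    """Bookkeeping the runner keeps per actor."""

    def __init__(self, actor: Actor, in_queues: list[EdgeQueue], out_queues: list[EdgeQueue]):
        self.actor = actor
        self.in_queues = in_queues
        self.out_queues = out_queues
        self.eos_seen: set[int] = set()  # indices into in_queues
        self.steps = 0

    @property
    def terminal(self) -> bool:
        return self.actor.state in (ActorStateEnum.FAILED, ActorStateEnum.STOPPED)


class PipelineRunner:
    def __init__(
        self,
        graph: PipelineGraph,
        store: DataStore | None = None,
        executor: str = "thread",
        queue_capacity: int = DEFAULT_CAPACITY,
        retention: RetentionPolicy | None = None,
        extra_params: dict | None = None,
    ):
        if executor not in ("thread", "inline"):
            raise ValueError(f"unknown executor {executor!r}")
        graph.validate(resolve=True)
        self.graph = graph
        self.executor = executor
        self.log = RunLog()
        self.store = store or DataStore(
            retention=retention or RetentionPolicy(), log=self.log.log
        )
        self.store._log = self.log.log
        self.queue_capacity = queue_capacity
        self.extra_params = extra_params or {}

        self.actors: dict[str, Actor] = {}
        self.harness: dict[str, _Harness] = {}
        self.queues: dict[str, EdgeQueue] = {}
        self._upstream_of_queue: dict[int, str] = {}
        self._build()
        self._stop_event = threading.Event()
        self.faulted: list[str] = []

    # -- construction ------------------------------------------------------
    def _build(self) -> None:
        for name, spec in self.graph.nodes.items():
            cls = resolve_impl(spec.impl)
            params = {**spec.params, **self.extra_params.get(name, {})}
            self.actors[name] = cls(name=name, params=params, store=self.store, log=self.log)
        for edge in self.graph.edges:
            q = EdgeQueue(str(edge), capacity=self.queue_capacity, log=self.log.log)
            self.queues[str(edge)] = q
            self._upstream_of_queue[id(q)] = edge.src
            src = self.actors[edge.src]
            dst = self.actors[edge.dst]
            src._outputs.setdefault(edge.src_port, []).append(q)
            dst._inputs.setdefault(edge.dst_port, []).append(q)
        for name, actor in self.actors.items():
            in_qs = [q for qs in actor._inputs.values() for q in qs]
            out_qs = [q for qs in actor._outputs.values() for q in qs]
            self.harness[name] = _Harness(actor, in_qs, out_qs)

    # -- fault handling ----------------------------------------------------
    def handle_fault(self, actor: Actor, error: BaseException) -> None:
        """Contain a step-time fault: fail the actor, seal its inputs,
        propagate end-of-stream downstream, keep everything else running."""
        tb = "".join(traceback.format_exception(type(error), error, error.__traceback__))
        self.log.log(actor.name, "fault", tb)
        actor._transition(ActorStateEnum.FAILED)
        self.faulted.append(actor.name)
        for q in self.harness[actor.name].in_queues:
            q.seal()
        actor.emit_eos()

    def _finish_actor(self, actor: Actor) -> None:
        actor.emit_eos()
        try:
            actor.teardown()
        except Exception as exc:  # teardown faults are logged, not fatal
            self.log.log(actor.name, "teardown-error", repr(exc))
        if actor.state == ActorStateEnum.RUNNING:
            actor._transition(ActorStateEnum.STOPPED)
        self.log.log(actor.name, "actor-stop", "")

    def _inputs_exhausted(self, h: _Harness) -> bool:
        """A non-source actor can stop when every inbound edge has delivered
        end-of-stream, or its upstream actor is terminal and the queue is
        drained."""
        for i, q in enumerate(h.in_queues):
            if i in h.eos_seen:
                continue
            upstream = self.harness[self._upstream_of_queue[id(q)]]
            if upstream.terminal and len(q) == 0:
                continue
            return False
        return True

    # -- stepping ----------------------------------------------------------
    def _source_budget_left(self, h: _Harness, frames: int | None, deadline: float | None) -> bool:
        if self._stop_event.is_set() or h.actor.done:
            return False
        if frames is not None and h.steps >= frames:
            return False
        if deadline is not None and time.monotonic() >= deadline:
            return False
        return True

    def _step_source(self, h: _Harness) -> bool:
        try:
            h.actor.step(None)
            h.steps += 1
            return True
        except Exception as exc:
            self.handle_fault(h.actor, exc)
            return False

    def _step_consumer(self, h: _Harness, msg: Message, q_index: int) -> None:
        if msg.kind == MessageKind.END_OF_STREAM:
            h.eos_seen.add(q_index)
            return
        try:
            h.actor.step(msg)
            h.steps += 1
        except Exception as exc:
            self.handle_fault(h.actor, exc)

    # -- run ---------------------------------------------------------------
    def run(self, frames: int | None = None, duration: float | None = None) -> RunLog:
        self.log.log("run", "run-start", f"executor={self.executor}")
        deadline = time.monotonic() + duration if duration is not None else None
        for name, actor in self.actors.items():
            actor._transition(ActorStateEnum.SETUP)
            try:
                actor.setup()
            except Exception as exc:
                self.log.log(name, "setup-fault", repr(exc))
                raise PipelineAbort(name, exc)
            actor._transition(ActorStateEnum.RUNNING)
            self.log.log(name, "actor-start", "")
        if self.executor == "thread":
            self._run_threaded(frames, deadline)
        else:
            self._run_inline(frames, deadline)
        self.store.evict()
        self.log.log("run", "run-end", f"faults={len(self.faulted)}")
        return self.log

    def _run_threaded(self, frames, deadline) -> None:
        threads = []
        for name, h in self.harness.items():
            target = self._source_loop if h.actor.is_source else self._consumer_loop
            t = threading.Thread(target=target, args=(h, frames, deadline), name=name)
            threads.append(t)
        for t in threads:
            t.start()
        if deadline is not None:
            remaining = deadline - time.monotonic()
            if remaining > 0:
                time.sleep(remaining)
            self._stop_event.set()
        for t in threads:
            t.join()

    def _source_loop(self, h: _Harness, frames, deadline) -> None:
        rate_hz = h.actor.params.get("rate_hz")
        interval = 1.0 / rate_hz if rate_hz else None
        next_t = time.monotonic()
        while self._source_budget_left(h, frames, deadline):
            if not self._step_source(h):
                return
            if interval is not None:
                next_t += interval
                delay = next_t - time.monotonic()
                if delay > 0:
                    time.sleep(delay)
        if not h.terminal:
            self._finish_actor(h.actor)

    def _consumer_loop(self, h: _Harness, frames, deadline) -> None:
        while True:
            progressed = False
            for i, q in enumerate(h.in_queues):
                if h.terminal:
                    return
                msg = q.get_nowait()
                if msg is not None:
                    self._step_consumer(h, msg, i)
                    progressed = True
            if h.terminal:
                return
            if not progressed:
                if self._inputs_exhausted(h) or (
                    self._stop_event.is_set() and all(len(q) == 0 for q in h.in_queues)
                ):
                    break
                time.sleep(0.0005)
        self._finish_actor(h.actor)

    def _run_inline(self, frames, deadline) -> None:
        order = list(self.harness)
        while True:
            alive = False
            progressed = False
            for name in order:
                h = self.harness[name]
                if h.terminal:
                    continue
                if h.actor.is_source:
                    if self._source_budget_left(h, frames, deadline):
                        self._step_source(h)
                        alive = True
                        progressed = True
                    else:
                        self._finish_actor(h.actor)
                        progressed = True
                else:
                    drained = False
                    for i, q in enumerate(h.in_queues):
                        while not h.terminal:
                            msg = q.get_nowait()
                            if msg is None:
                                break
                            self._step_consumer(h, msg, i)
                            drained = True
                    if h.terminal:
                        progressed = True
                        continue
                    if drained:
                        alive = True
                        progressed = True
                    elif self._inputs_exhausted(h):
                        self._finish_actor(h.actor)
                        progressed = True
                    else:
                        alive = True  # waiting on an upstream that is alive
            if not alive:
                break
            if not progressed:
                # only mutually waiting actors remain (a cycle with no live
                # source): stop rather than spin
                self.log.log("run", "stall", "no progress among waiting actors")
                for h in self.harness.values():
                    if not h.terminal:
                        self._finish_actor(h.actor)
                break


def run_pipeline(
    graph: PipelineGraph,
    frames: int | None = None,
    duration: float | None = None,
    executor: str = "inline",
    **kwargs,
) -> RunLog:
    """Validate, build, and run a pipeline; returns its :class:`RunLog`."""
    runner = PipelineRunner(graph, executor=executor, **kwargs)
    return runner.run(frames=frames, duration=duration)
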