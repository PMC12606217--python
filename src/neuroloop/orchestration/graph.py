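"""Pipeline graphs and their text-file (YAML) configuration dialect.

A config document has two sections::

    actors:
      acquirer:  {impl: mypkg.actors.FrameSource, params: {n_frames: 100}}
      processor: {impl: mypkg.actors.Downsampler}
    connections:
      - acquirer.out -> processor.in

Cycles are legal (closed-loop designs feed an analysis actor back into a
stimulus actor), but every weakly connected component must contain a source:
a node with no inbound edges, or one whose implementation declares
``is_source = True`` (a frame grabber inside a feedback loop).
"""

from __future__ import annotations

import importlib
import re
from dataclasses import dataclass, field

import yaml

__all__ = [
    "ActorSpec",
    "Edge",
    "PipelineGraph",
    "ConfigParseError",
    "GraphValidationError",
    "parse_config",
    "resolve_impl",
]


class ConfigParseError(ValueError):
    pass


class GraphValidationError(ValueError):
    pass


@dataclass
class ActorSpec:
    name: str
    impl: str
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Edge:
    src: str
    src_port: str
    dst: str
    dst_port: str

    def __str__(self) -> str:
        return f"{self.src}.{self.src_port} -> {self.dst}.{self.dst_port}"


def resolve_impl(path: str):
    """Resolve a dotted ``module.ClassName`` implementation reference."""
    module_name, _, cls_name = path.rpartition(".")
    if not module_name:
        raise GraphValidationError(f"impl {path!r} is not a dotted path")
    try:
        module = importlib.import_module(module_name)
    except ImportError as exc:
        raise GraphValidationError(f"cannot import module for impl {path!r}: {exc}")
    try:
        return getattr(module, cls_name)
    except AttributeError:
        raise GraphValidationError(f"impl {path!r} not found in {module_name!r}")


@dataclass
class PipelineGraph:
    nodes: dict[str, ActorSpec]
    edges: list[Edge]

    def in_edges(self, name: str) -> list[Edge]:
        return [e for e in self.edges if e.dst == name]

    def out_edges(self, name: str) -> list[Edge]:
        return [e for e in self.edges if e.src == name]

    def validate(self, resolve: bool = True) -> None:
        names = set(self.nodes)
        for edge in self.edges:
            for endpoint in (edge.src, edge.dst):
                if endpoint not in names:
                    raise GraphValidationError(
                        f"connection {edge} references undeclared actor "
                        f"{endpoint!r}"
                    )
        impls = {}
        if resolve:
            for spec in self.nodes.values():
                impls[spec.name] = resolve_impl(spec.impl)
        # every weakly connected component needs a source
        parent = {n: n for n in names}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for e in self.edges:
            parent[find(e.src)] = find(e.dst)
        has_inbound = {e.dst for e in self.edges}
        comp_has_source: dict[str, bool] = {}
        for n in names:
            root = find(n)
            is_src = n not in has_inbound or (
                resolve and getattr(impls.get(n), "is_source", False)
            )
            comp_has_source[root] = comp_has_source.get(root, False) or is_src
        for root, ok in comp_has_source.items():
            if not ok:
                members = sorted(n for n in names if find(n) == root)
                raise GraphValidationError(
                    f"component {members} has no source actor"
                )


_CONN_RE = re.compile(
    r"^\s*(?P<src>[\w-]+)(?:\.(?P<sport>[\w-]+))?\s*->\s*"
    r"(?P<dst>[\w-]+)(?:\.(?P<dport>[\w-]+))?\s*$"
)


def parse_config(text: str, validate: bool = True, resolve: bool = True) -> PipelineGraph:
    """Parse a YAML pipeline config into a :class:`PipelineGraph`.

    Parameters are preserved verbatim.  Malformed YAML raises
    :class:`ConfigParseError` naming the offending line; connections naming
    undeclared actors raise :class:`GraphValidationError` naming the actor.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigParseError(f"malformed config{line}: {exc}")
    if not isinstance(doc, dict) or "actors" not in doc:
        raise ConfigParseError("config must be a mapping with an 'actors' section")
    nodes: dict[str, ActorSpec] = {}
    for name, spec in (doc.get("actors") or {}).items():
        spec = spec or {}
        if "impl" not in spec:
            raise ConfigParseError(f"actor {name!r} has no 'impl'")
        nodes[name] = ActorSpec(
            name=name, impl=spec["impl"], params=dict(spec.get("params") or {})
        )
    edges: list[Edge] = []
    for conn in doc.get("connections") or []:
        m = _CONN_RE.match(str(conn))
        if not m:
            raise ConfigParseError(f"cannot parse connection {conn!r}")
        edges.append(
            Edge(
                src=m["src"],
                src_port=m["sport"] or "out",
                dst=m["dst"],
                dst_port=m["dport"] or "in",
            )
        )
    graph = PipelineGraph(nodes=nodes, edges=edges)
    if validate:
        graph.validate(resolve=resolve)
    return graph
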