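"""Rule-file reading/writing, bundled fixture networks and graph export.

Rule-file grammar
-----------------
One rule per line, ``<name>* = <expr>`` (the ``*`` marks the future state
and is optional on input).  ``#`` starts a comment.  Source nodes are
declared with directives::

    #@ source Stimuli = 1     # clamped ON
    #@ source PDGF            # free input

Node order is the order of first declaration (directive or rule line) and
defines the bit order of state encodings.

Fixtures
--------
Three transcriptions of the T-cell large granular lymphocyte (T-LGL)
leukemia survival signaling model ship with the package:

``tlgl60``
    the full 60-node survival network with its six external inputs
    (antigen stimulation, IL15 and PDGF clamped ON; secondary stimuli,
    CD45 and the viral protein TAX clamped OFF by default),
``tlgl18``
    the 18-node sub-network that remains after logical steady state
    analysis of the full model under those inputs,
``tlgl6``
    the 6-node apoptotic core obtained from the 18-node model by removing
    the receptor oscillator (TCR/CTLA4) and merging simple mediator nodes.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, TextIO, Union

import networkx as nx

from .logic import Expr, ParseError, parse_expression, to_canonical, write_expression
from .network import BooleanNetwork, NetworkError

__all__ = [
    "FIXTURES",
    "FormatError",
    "read_network",
    "parse_network",
    "write_network",
    "network_to_string",
    "load_fixture",
    "dependency_graph",
    "export_graph",
]


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Reading and writing rule files
# ---------------------------------------------------------------------------

def _iter_lines(text: str):
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if raw.lstrip().startswith("#@"):
            yield lineno, "directive", raw.lstrip()[2:].strip()
            continue
        line = raw.split("#", 1)[0].strip()
        if line:
            yield lineno, "rule", line


def parse_network(text: str) -> BooleanNetwork:
    """Parse rule-file text into a :class:`BooleanNetwork`."""
    order: list[str] = []
    rule_text: dict[str, tuple[int, str]] = {}
    frozen: dict[str, int] = {}
    sources: set[str] = set()

    for lineno, kind, line in _iter_lines(text):
        if kind == "directive":
            parts = line.split()
            if not parts or parts[0] != "source":
                raise FormatError(f"line {lineno}: unknown directive {line!r}")
            rest = " ".join(parts[1:])
            if "=" in rest:
                name, value = (s.strip() for s in rest.split("=", 1))
                if value not in ("0", "1"):
                    raise FormatError(
                        f"line {lineno}: frozen value must be 0 or 1, got {value!r}"
                    )
                frozen[name] = int(value)
            else:
                name = rest.strip()
            if not name:
                raise FormatError(f"line {lineno}: source directive without a name")
            if name in sources:
                raise FormatError(f"line {lineno}: duplicate source {name!r}")
            sources.add(name)
            order.append(name)
            continue

        if "=" not in line:
            raise FormatError(f"line {lineno}: expected '<name>* = <expr>'")
        lhs, rhs = (s.strip() for s in line.split("=", 1))
        if lhs.endswith("*"):
            lhs = lhs[:-1].strip()
        if not lhs:
            raise FormatError(f"line {lineno}: missing node name")
        if lhs in rule_text:
            raise FormatError(f"line {lineno}: duplicate rule for node {lhs!r}")
        if lhs in sources:
            raise FormatError(f"line {lineno}: node {lhs!r} already declared a source")
        rule_text[lhs] = (lineno, rhs)
        order.append(lhs)

    if not rule_text:
        raise FormatError("no rules found in input")

    vocabulary = frozenset(order)
    rules: dict[str, Expr] = {}
    for name, (lineno, rhs) in rule_text.items():
        try:
            rules[name] = parse_expression(rhs, vocabulary)
        except ParseError as exc:
            raise FormatError(f"line {lineno} ({name}): {exc}") from exc
    try:
        return BooleanNetwork(tuple(order), rules, frozen)
    except NetworkError as exc:  # pragma: no cover - parse covers most cases
        raise FormatError(str(exc)) from exc


def read_network(source: Union[str, Path, TextIO]) -> BooleanNetwork:
    """Read a network from a rule file (path or open text handle)."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    return parse_network(text)


def network_to_string(network: BooleanNetwork) -> str:
    lines = []
    for name in network.nodes:
        if name in network.rules:
            lines.append(f"{name}* = {write_expression(network.rules[name])}")
        elif name in network.frozen:
            lines.append(f"#@ source {name} = {network.frozen[name]}")
        else:
            lines.append(f"#@ source {name}")
    return "\n".join(lines) + "\n"


def write_network(network: BooleanNetwork, path: Union[str, Path, TextIO]) -> None:
    text = network_to_string(network)
    if isinstance(path, (str, Path)):
        Path(path).write_text(text)
    else:
        path.write(text)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Fixture:
    filename: str
    note: str


FIXTURES: Mapping[str, _Fixture] = {
    "tlgl60": _Fixture(
        "tlgl60.txt",
        "Full 60-node T-LGL survival signaling network; six external inputs "
        "clamped to the disease-condition values by default.",
    ),
    "tlgl18": _Fixture(
        "tlgl18.txt",
        "18-node sub-network remaining after logical steady state analysis "
        "of the full model under the default inputs.",
    ),
    "tlgl6": _Fixture(
        "tlgl6.txt",
        "6-node apoptotic core reached by mediator merging of the 18-node "
        "model's lower component.",
    ),
}


def load_fixture(name: str) -> BooleanNetwork:
    """Load one of the bundled T-LGL networks (``tlgl60``/``tlgl18``/``tlgl6``)."""
    try:
        fixture = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    text = resources.files("lglnet.data").joinpath(fixture.filename).read_text()
    return parse_network(text)


# ---------------------------------------------------------------------------
# Graph export
# ---------------------------------------------------------------------------

def dependency_graph(network: BooleanNetwork) -> nx.DiGraph:
    """Signed regulator graph: edge u->v with sign +, - or +/-."""
    g = nx.DiGraph()
    for name in network.nodes:
        g.add_node(name, kind="source" if name not in network.rules else "node")
    for name, expr in network.rules.items():
        signs: dict[str, set[bool]] = {}
        try:
            clause_sets = to_canonical(expr).clause_sets()
        except ValueError:
            continue  # constant rule: no regulators
        for clause in clause_sets:
            for reg, pol in clause:
                signs.setdefault(reg, set()).add(pol)
        for reg, pols in signs.items():
            sign = "+/-" if len(pols) == 2 else ("+" if True in pols else "-")
            g.add_edge(reg, name, sign=sign)
    return g


def _as_graph(graph) -> nx.DiGraph:
    if isinstance(graph, nx.DiGraph):
        return graph
    if isinstance(graph, BooleanNetwork):
        return dependency_graph(graph)
    to_nx = getattr(graph, "to_networkx", None)
    if to_nx is not None:
        return to_nx()
    raise TypeError(f"cannot export object of type {type(graph).__name__}")


def _dot_escape(name: str) -> str:
    return '"' + str(name).replace('"', r"\"") + '"'


def export_graph(graph, fmt: str, path: Union[str, Path, TextIO]) -> None:
    """Export a graph-like object as DOT, GraphML or an edge-list TSV.

    Accepts a :class:`BooleanNetwork` (exported as its signed dependency
    graph), a state transition graph or an expanded network (anything with
    ``to_networkx``), or a plain :class:`networkx.DiGraph`.  Vertex ordering
    in the output is deterministic.
    """
    g = _as_graph(graph)
    fmt = fmt.lower()
    if fmt not in {"dot", "graphml", "tsv"}:
        raise ValueError(f"unsupported format {fmt!r}; use dot, graphml or tsv")

    if g.is_multigraph():
        edge_list = [
            (u, v, dict(data)) for u, v, data in g.edges(data=True)
        ]
    else:
        edge_list = [(u, v, dict(g.edges[u, v])) for u, v in g.edges]
    edge_list.sort(key=lambda e: (str(e[0]), str(e[1]), sorted(e[2].items())))

    own = isinstance(path, (str, Path))
    handle: TextIO = open(path, "w") if own else path
    try:
        if fmt == "dot":
            handle.write("digraph G {\n")
            for node in sorted(g.nodes, key=str):
                attrs = g.nodes[node]
                label = ",".join(f"{k}={v}" for k, v in sorted(attrs.items()))
                suffix = f" [{label}]" if label else ""
                handle.write(f"  {_dot_escape(node)}{suffix};\n")
            for u, v, attrs in edge_list:
                label = ",".join(f"{k}={v_}" for k, v_ in sorted(attrs.items()))
                suffix = f" [{label}]" if label else ""
                handle.write(
                    f"  {_dot_escape(u)} -> {_dot_escape(v)}{suffix};\n"
                )
            handle.write("}\n")
        elif fmt == "graphml":
            buf = _io.BytesIO()
            # relabel to strings for GraphML compatibility
            g2 = nx.relabel_nodes(g, {n: str(n) for n in g.nodes}, copy=True)
            nx.write_graphml(g2, buf)
            handle.write(buf.getvalue().decode())
        else:  # tsv
            for u, v, _ in edge_list:
                handle.write(f"{u}\t{v}\n")
    finally:
        if own:
            handle.close()
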