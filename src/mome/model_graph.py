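"""Path-model syntax, validation, and path queries.

A recursive path model is a list of regression equations written in an
``outcome ~ term + term + ...`` syntax, one equation per line.  Plain terms
induce directed edges ``predictor -> outcome``; interaction (product) terms
are registered separately and never become edges themselves -- the moderator
contributes an edge only through its own main effect.  Interactions can be
declared inline as ``w:x`` (the product column is computed at fit time) or
as a pre-computed column registered through a ``{"w1x1": ("w1", "x1")}``
mapping, matching the two conventions used in practice (formula interfaces
versus hand-computed product columns).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx

from .exceptions import (
    CycleError,
    DisconnectedModelError,
    ModelSyntaxError,
    PathDirectionError,
    PathNotFoundError,
)

__all__ = [
    "EquationSpec",
    "ProductTerm",
    "PathModel",
    "PathQuery",
    "parse_model",
    "validate_path",
    "enumerate_paths",
    "check_connected",
    "MAX_PATHS",
]

log = logging.getLogger(__name__)

#: Hard cap on path enumeration, guarding against pathological dense DAGs.
MAX_PATHS = 10_000

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*$")


@dataclass(frozen=True)
class EquationSpec:
    """One regression equation: an outcome and its ordered predictor terms."""

    outcome: str
    terms: tuple[str, ...]

    def __post_init__(self):
        if self.outcome in self.terms:
            raise ModelSyntaxError(
                f"outcome {self.outcome!r} appears among its own predictors"
            )
        if len(set(self.terms)) != len(self.terms):
            raise ModelSyntaxError(
                f"duplicate terms in equation for {self.outcome!r}"
            )


@dataclass(frozen=True)
class ProductTerm:
    """An interaction column: ``column`` holds moderator x focal, row-wise."""

    column: str
    moderator: str
    focal: str


@dataclass(frozen=True)
class PathQuery:
    """A path from ``x`` through ordered mediators ``m`` to ``y``."""

    x: str
    m: tuple[str, ...] = ()
    y: str = ""

    def __post_init__(self):
        object.__setattr__(self, "m", tuple(self.m))
        if self.x == self.y:
            raise ModelSyntaxError("path start and end must differ")
        if len(set(self.m)) != len(self.m):
            raise ModelSyntaxError("mediators must be distinct")
        if self.x in self.m or self.y in self.m:
            raise ModelSyntaxError("mediators must exclude the path endpoints")

    @property
    def nodes(self) -> tuple[str, ...]:
        return (self.x, *self.m, self.y)

    def __str__(self) -> str:
        return " -> ".join(self.nodes)


@dataclass
class PathModel:
    """A validated recursive path model: equations plus a product registry."""

    equations: list[EquationSpec]
    products: list[ProductTerm] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for eq in self.equations:
            if eq.outcome in seen:
                raise ModelSyntaxError(f"duplicate outcome {eq.outcome!r}")
            seen.add(eq.outcome)
        self._product_columns = {p.column: p for p in self.products}
        self._graph = self._build_graph()
        cycles = list(nx.simple_cycles(self._graph))
        if cycles:
            raise CycleError(cycles[0])
        for p in self.products:
            for v in (p.moderator, p.focal):
                if v not in self.variables:
                    raise ModelSyntaxError(
                        f"product term {p.column!r} refers to {v!r}, "
                        "which is not a model variable"
                    )

    def _build_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for eq in self.equations:
            g.add_node(eq.outcome)
            for term in eq.terms:
                if term in self._product_columns:
                    continue  # product columns never act as edges
                g.add_node(term)
                g.add_edge(term, eq.outcome)
        return g

    # -- variable sets -----------------------------------------------------
    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    @property
    def variables(self) -> frozenset[str]:
        return frozenset(self._graph.nodes)

    @property
    def endogenous(self) -> frozenset[str]:
        return frozenset(eq.outcome for eq in self.equations)

    @property
    def exogenous(self) -> frozenset[str]:
        return self.variables - self.endogenous

    @property
    def product_columns(self) -> dict[str, ProductTerm]:
        return dict(self._product_columns)

    @property
    def exo_columns(self) -> list[str]:
        """Exogenous variables plus product columns, in a stable order."""
        return sorted(self.exogenous) + [p.column for p in self.products]

    @property
    def endo_order(self) -> list[str]:
        """Endogenous variables in topological (causal) order."""
        order = list(nx.topological_sort(self._graph))
        return [v for v in order if v in self.endogenous]

    # -- lookups -----------------------------------------------------------
    def equation_for(self, outcome: str) -> EquationSpec:
        for eq in self.equations:
            if eq.outcome == outcome:
                return eq
        raise ModelSyntaxError(f"{outcome!r} is not an outcome in the model")

    def has_edge(self, u: str, v: str) -> bool:
        return self._graph.has_edge(u, v)

    def edges(self) -> list[tuple[str, str]]:
        return list(self._graph.edges)

    def moderators_of_edge(self, edge: tuple[str, str]) -> set[tuple[str, str]]:
        """All ``(moderator, product-column)`` pairs moderating ``edge``.

        A product term moderates an edge when its focal variable is the
        edge's source and its column appears in the target's equation.
        """
        u, v = edge
        if not self.has_edge(u, v):
            raise PathNotFoundError(f"edge {u} -> {v} does not exist in the model")
        eq_terms = set(self.equation_for(v).terms)
        return {
            (p.moderator, p.column)
            for p in self.products
            if p.focal == u and p.column in eq_terms
        }

    def to_syntax(self) -> str:
        """Serialize back to model syntax (round-trips through parse_model)."""
        return "\n".join(
            f"{eq.outcome} ~ " + " + ".join(eq.terms) for eq in self.equations
        )


def _check_name(name: str, lineno: int) -> None:
    if not _NAME_RE.match(name):
        raise ModelSyntaxError(f"line {lineno}: invalid variable name {name!r}")


def parse_model(syntax: str, products: dict | None = None) -> PathModel:
    """Parse model syntax into a :class:`PathModel`.

    Parameters
    ----------
    syntax:
        One ``outcome ~ t1 + t2 + ...`` equation per line.  ``#`` starts a
        comment; blank lines are skipped; covariance lines (``~~``) are
        accepted but ignored with a logged notice.  ``a:b`` declares an
        interaction with moderator ``a`` and focal variable ``b``.
    products:
        Optional mapping of pre-computed product columns,
        ``{"w1x1": ("w1", "x1")}`` (moderator first).
    """
    if not syntax or not syntax.strip():
        raise ModelSyntaxError("empty model syntax")
    registered = {
        col: (str(pair[0]), str(pair[1])) for col, pair in (products or {}).items()
    }
    equations: list[EquationSpec] = []
    prods: dict[str, ProductTerm] = {}
    for lineno, raw in enumerate(syntax.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "~~" in line:
            log.info("line %d: covariance specification ignored: %s", lineno, line)
            continue
        if line.count("~") != 1:
            raise ModelSyntaxError(
                f"line {lineno}: expected exactly one '~': {line!r}"
            )
        lhs, rhs = (part.strip() for part in line.split("~"))
        _check_name(lhs, lineno)
        terms = []
        for term in rhs.split("+"):
            term = term.strip()
            if not term:
                raise ModelSyntaxError(f"line {lineno}: empty term in {line!r}")
            if ":" in term:
                mod, _, focal = (s.strip() for s in term.partition(":"))
                _check_name(mod, lineno)
                _check_name(focal, lineno)
                column = f"{mod}:{focal}"
                prods.setdefault(column, ProductTerm(column, mod, focal))
                terms.append(column)
            else:
                _check_name(term, lineno)
                if term in registered:
                    mod, focal = registered[term]
                    prods.setdefault(term, ProductTerm(term, mod, focal))
                terms.append(term)
        equations.append(EquationSpec(lhs, tuple(terms)))
    if not equations:
        raise ModelSyntaxError("model syntax contains no equations")
    return PathModel(equations, list(prods.values()))


def validate_path(model: PathModel, q: PathQuery) -> list[tuple[str, str]]:
    """Return the edge list of ``q``, or raise if the path is invalid.

    Raises :class:`PathNotFoundError` when a required edge is absent, and
    :class:`PathDirectionError` when the mediators are ordered against the
    model's causal direction (the reversed sequence would be a valid path,
    or a required edge exists only in the opposite direction).
    """
    for name in q.nodes:
        if name not in model.variables:
            raise PathNotFoundError(f"{name!r} is not a variable in the model")
    nodes = q.nodes
    edges = list(zip(nodes[:-1], nodes[1:]))
    for u, v in edges:
        if model.has_edge(u, v):
            continue
        reversed_ok = all(
            model.has_edge(a, b)
            for a, b in zip(
                (q.x, *reversed(q.m), q.y)[:-1], (q.x, *reversed(q.m), q.y)[1:]
            )
        )
        if reversed_ok or model.has_edge(v, u):
            raise PathDirectionError(
                f"the path {q} is invalid because the direction is wrong"
            )
        raise PathNotFoundError(
            f"the path {q} does not exist in the model (no edge {u} -> {v})"
        )
    return edges


def enumerate_paths(model: PathModel, x: str, y: str) -> list[PathQuery]:
    """All simple directed paths from ``x`` to ``y`` as mediator lists.

    The direct path (if the edge exists) appears as an empty mediator list.
    Ordering is deterministic: shortest paths first, ties lexicographic.
    Raises :class:`ModelSyntaxError` past :data:`MAX_PATHS` paths.
    """
    for name in (x, y):
        if name not in model.variables:
            raise PathNotFoundError(f"{name!r} is not a variable in the model")
    if x == y:
        raise ModelSyntaxError("path start and end must differ")
    out = []
    for path in nx.all_simple_paths(model.graph, x, y):
        out.append(PathQuery(x, tuple(path[1:-1]), y))
        if len(out) > MAX_PATHS:
            raise ModelSyntaxError(
                f"more than {MAX_PATHS} paths from {x} to {y}; refusing to enumerate"
            )
    out.sort(key=lambda q: (len(q.m), q.m))
    return out


def check_connected(model: PathModel) -> bool:
    """Pass iff all model variables form one connected (undirected) component.

    Raises :class:`DisconnectedModelError` listing the components otherwise.
    """
    components = list(nx.connected_components(model.graph.to_undirected()))
    if len(components) > 1:
        raise DisconnectedModelError(components)
    return True
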