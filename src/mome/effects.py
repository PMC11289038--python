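"""Effect algebra on fitted path models.

An indirect effect along x -> m1 -> ... -> y is the product of the path
coefficients of its component edges.  When an edge u -> v is moderated, its
coefficient is conditional: b_{v~u} + sum_k d_k * w_k over the product terms
whose focal variable is u, evaluated at supplied moderator values (missing
moderators default to 0 with a warning, in which case the "unconditional"
effect is really the effect at moderators = 0).  Standardization multiplies
by SD(x) and/or divides by SD(y); the same recipe is applied replicate-wise
to bootstrap or Monte Carlo parameter sets -- per-replicate SDs, never
point-estimate SDs -- and percentile intervals are read off the replicate
vector of the final effect.

Also here: sums/differences of effects (total and total indirect effects),
the index of moderated mediation (unit change in a moderator), the index of
moderated moderated mediation (double difference over two moderators), the
difference between two conditional indirect effects (a 1-SD change gives
the z-index of moderated mediation), and the proportion of effect mediated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .estimation import ParamEstimates
from .exceptions import EffectError
from .model_graph import PathQuery, enumerate_paths, validate_path
from .resampling import CIResult, ReplicateStore, percentile_ci
from .wlevels import WLevels, WRow

__all__ = [
    "EffectResult",
    "EffectTable",
    "IndexResult",
    "PathComponent",
    "conditional_coefficient",
    "indirect_effect",
    "cond_indirect_effects",
    "effect_add",
    "effect_subtract",
    "index_of_mome",
    "index_of_momome",
    "cond_indirect_diff",
    "indirect_proportion",
]


def _fmt(v: float) -> str:
    return f"({v:.5f})"


@dataclass(frozen=True)
class PathComponent:
    """One edge of a path: its raw coefficient and conditional value."""

    edge: tuple[str, str]
    base: float
    value: float
    moderators: tuple[tuple[str, str, float, float], ...] = ()
    # (moderator, product column, d coefficient, moderator value)

    @property
    def label(self) -> str:
        u, v = self.edge
        return f"{v}~{u}"

    @property
    def formula(self) -> str:
        u, v = self.edge
        core = f"b.{v}~{u}"
        for mod, col, _, _ in self.moderators:
            core += f" + (b.{col})*({mod})"
        return f"({core})"

    @property
    def computation(self) -> str:
        if not self.moderators:
            return _fmt(self.base)
        parts = [_fmt(self.base)]
        parts += [f"{_fmt(d)}*{_fmt(w)}" for _, _, d, w in self.moderators]
        return "(" + " + ".join(parts) + ")"


@dataclass
class EffectResult:
    """A computed (conditional, possibly standardized) effect."""

    value: float
    query: PathQuery | None
    wvalues: dict[str, float] = field(default_factory=dict)
    std_x: bool = False
    std_y: bool = False
    trace: str = ""
    computation: str = ""
    components: tuple[PathComponent, ...] = ()
    replicates: np.ndarray | None = None
    ci: CIResult | None = None
    store_tag: tuple | None = None
    parts: tuple["EffectResult", ...] = ()

    @property
    def paths(self) -> tuple[PathQuery, ...]:
        if self.parts:
            return tuple(p for part in self.parts for p in part.paths)
        return (self.query,) if self.query is not None else ()

    def _combine(self, other: "EffectResult", sign: int) -> "EffectResult":
        if not isinstance(other, EffectResult):
            return NotImplemented
        if (self.std_x, self.std_y) != (other.std_x, other.std_y):
            raise EffectError("cannot combine effects with different "
                              "standardization flags")
        if (self.replicates is None) != (other.replicates is None):
            raise EffectError("cannot combine an effect with replicates and "
                              "one without")
        replicates = ci = None
        tag = self.store_tag
        if self.replicates is not None:
            if self.store_tag != other.store_tag:
                raise EffectError(
                    "replicates come from different stores "
                    f"({self.store_tag} vs {other.store_tag})"
                )
            replicates = self.replicates + sign * other.replicates
            level = self.ci.level if self.ci else 0.95
            ci = percentile_ci(replicates, level)
        op = "+" if sign > 0 else "-"
        mine = self.trace if self.parts else f"({self.query})".replace(" -> ", "->")
        theirs = (
            other.trace if other.parts else f"({other.query})".replace(" -> ", "->")
        )
        return EffectResult(
            value=self.value + sign * other.value,
            query=None,
            wvalues={**self.wvalues, **other.wvalues},
            std_x=self.std_x,
            std_y=self.std_y,
            trace=f"{mine}{op}{theirs}",
            computation=f"{_fmt(self.value)}{op}{_fmt(other.value)}",
            replicates=replicates,
            ci=ci,
            store_tag=tag,
            parts=(self, other),
        )

    def __add__(self, other):
        return self._combine(other, +1)

    def __sub__(self, other):
        return self._combine(other, -1)


def effect_add(a: EffectResult, b: EffectResult) -> EffectResult:
    return a + b


def effect_subtract(a: EffectResult, b: EffectResult) -> EffectResult:
    return a - b


def _edge_moderators(est: ParamEstimates, edge, wvalues, warn=True):
    """Sorted (moderator, column, d, w) tuples for the edge's product terms."""
    mods = sorted(est.model.moderators_of_edge(edge), key=lambda mc: mc[1])
    out = []
    for moderator, column in mods:
        if wvalues is None or moderator not in wvalues:
            if warn:
                warnings.warn(
                    f"edge {edge[0]} -> {edge[1]} is moderated by "
                    f"{moderator!r} but no value was supplied; using 0 "
                    "(the effect is conditional on this moderator being 0)",
                    stacklevel=3,
                )
            w = 0.0
        else:
            w = float(wvalues[moderator])
        d = est.coefficient(edge[1], column)
        out.append((moderator, column, d, w))
    return tuple(out)


def conditional_coefficient(
    est: ParamEstimates, edge: tuple[str, str], wvalues=None, warn: bool = True
) -> float:
    """Conditional edge coefficient b + sum_k d_k * w_k."""
    base = est.coefficient(edge[1], edge[0])
    mods = _edge_moderators(est, edge, wvalues, warn=warn)
    return base + sum(d * w for _, _, d, w in mods)


def _component(est, edge, wvalues, warn=True) -> PathComponent:
    base = est.coefficient(edge[1], edge[0])
    mods = _edge_moderators(est, edge, wvalues, warn=warn)
    return PathComponent(
        edge=edge,
        base=base,
        value=base + sum(d * w for _, _, d, w in mods),
        moderators=mods,
    )


def _edge_replicates(store: ReplicateStore, comp: PathComponent) -> np.ndarray:
    u, v = comp.edge
    vec = store.coef_replicates(v, u).copy()
    for _, column, _, w in comp.moderators:
        vec += store.coef_replicates(v, column) * w
    return vec


def indirect_effect(
    est: ParamEstimates,
    x: str | None = None,
    m=(),
    y: str | None = None,
    *,
    query: PathQuery | None = None,
    wvalues: dict[str, float] | None = None,
    std_x: bool = False,
    std_y: bool = False,
    store: ReplicateStore | None = None,
    level: float = 0.95,
    warn: bool = True,
) -> EffectResult:
    """(Conditional) indirect effect along one path, with optional CI.

    With ``m`` empty this is the direct effect of ``x`` on ``y``.  When the
    path crosses moderated edges and ``wvalues`` leaves their moderators
    unset, the effect is computed at moderator values of 0 with a warning.
    Standardization: x ``std_x`` multiplies by SD(x); ``std_y`` divides by
    SD(y).  With a ``store``, the effect is recomputed replicate-wise
    (per-replicate SDs for standardization) and a percentile CI attached.
    """
    q = query if query is not None else PathQuery(x, tuple(m), y)
    edges = validate_path(est.model, q)
    wvalues = dict(wvalues or {})
    components = tuple(_component(est, e, wvalues, warn=warn) for e in edges)

    value = float(np.prod([c.value for c in components]))
    trace = "*".join(c.formula if c.moderators else f"(b.{c.label})"
                     for c in components)
    computation = "*".join(c.computation for c in components)
    if std_x:
        value *= float(est.sds[q.x])
        trace += f"*sd_{q.x}"
        computation += f"*{_fmt(float(est.sds[q.x]))}"
    if std_y:
        value /= float(est.sds[q.y])
        trace += f"/sd_{q.y}"
        computation += f"/{_fmt(float(est.sds[q.y]))}"

    replicates = ci = tag = None
    if store is not None:
        vec = np.ones(store.R)
        for comp in components:
            vec = vec * _edge_replicates(store, comp)
        if std_x:
            vec = vec * store.sds[q.x]
        if std_y:
            vec = vec / store.sds[q.y]
        replicates = vec
        ci = percentile_ci(vec, level)
        tag = store.tag

    used = {mod: w for c in components for mod, _, _, w in c.moderators}
    return EffectResult(
        value=value,
        query=q,
        wvalues=used,
        std_x=std_x,
        std_y=std_y,
        trace=trace,
        computation=computation,
        components=components,
        replicates=replicates,
        ci=ci,
        store_tag=tag,
    )


@dataclass
class EffectTable:
    """Conditional effects for each row of a moderator-level table."""

    query: PathQuery
    wlevels: WLevels
    rows: list[tuple[WRow, EffectResult]]
    std_x: bool = False
    std_y: bool = False
    level: float = 0.95

    def __len__(self):
        return len(self.rows)

    def effect(self, row: int) -> EffectResult:
        """Effect for a one-based row number, as printed."""
        return self.rows[row - 1][1]

    def wrow(self, row: int) -> WRow:
        return self.rows[row - 1][0]

    @property
    def values(self) -> list[float]:
        return [e.value for _, e in self.rows]


def _resolve_wlevels(est: ParamEstimates, wlevels) -> WLevels:
    from .wlevels import default_levels, merge_mod_levels, mod_levels

    if isinstance(wlevels, WLevels):
        return wlevels
    names = [wlevels] if isinstance(wlevels, str) else list(wlevels)
    k = default_levels(len(names))
    tables = [mod_levels(est, w, method="sd", n_levels=k) for w in names]
    return merge_mod_levels(tables)


def cond_indirect_effects(
    est: ParamEstimates,
    wlevels,
    x: str | None = None,
    m=(),
    y: str | None = None,
    *,
    query: PathQuery | None = None,
    std_x: bool = False,
    std_y: bool = False,
    store: ReplicateStore | None = None,
    level: float = 0.95,
) -> EffectTable:
    """Conditional (indirect) effects at every moderator-level combination.

    ``wlevels`` is a :class:`WLevels` table, a moderator name, or a list of
    names (default levels are then built from the estimates' moments).
    Moderators that moderate no edge on the path draw a warning: the effect
    is constant across them.
    """
    q = query if query is not None else PathQuery(x, tuple(m), y)
    edges = validate_path(est.model, q)
    wl = _resolve_wlevels(est, wlevels)
    path_mods = {
        mod for e in edges for mod, _ in est.model.moderators_of_edge(e)
    }
    supplied = set(wl.columns)
    for extra in sorted(supplied - path_mods):
        warnings.warn(
            f"{extra!r} moderates no component path of {q}; the effect is "
            "constant across its levels",
            stacklevel=2,
        )
    rows = []
    for r in wl.rows:
        e = indirect_effect(
            est,
            query=q,
            wvalues=r.values,
            std_x=std_x,
            std_y=std_y,
            store=store,
            level=level,
            warn=False,
        )
        rows.append((r, replace(e, wvalues=dict(r.values))))
    return EffectTable(
        query=q, wlevels=wl, rows=rows, std_x=std_x, std_y=std_y, level=level
    )


@dataclass
class IndexResult:
    """An index of (moderated) moderated mediation with its cells."""

    index: float
    ci: CIResult | None
    cells: tuple[EffectResult, ...]
    x: str
    y: str
    description: str = ""


def _path_moderators(est: ParamEstimates, q: PathQuery) -> set[str]:
    edges = validate_path(est.model, q)
    return {mod for e in edges for mod, _ in est.model.moderators_of_edge(e)}


def index_of_mome(
    est: ParamEstimates,
    x: str | None = None,
    m=(),
    y: str | None = None,
    w: str = "",
    *,
    query: PathQuery | None = None,
    store: ReplicateStore | None = None,
    level: float = 0.95,
) -> IndexResult:
    """Index of moderated mediation: unit-change difference in the effect.

    The conditional indirect effect at ``w = 1`` minus at ``w = 0`` (all
    other moderators held at 0).
    """
    q = query if query is not None else PathQuery(x, tuple(m), y)
    if w not in _path_moderators(est, q):
        raise EffectError(f"{w!r} moderates no component path of {q}")
    cells = tuple(
        indirect_effect(
            est, query=q, wvalues={w: v}, store=store, level=level, warn=False
        )
        for v in (1.0, 0.0)
    )
    index = cells[0].value - cells[1].value
    ci = None
    if store is not None:
        ci = percentile_ci(cells[0].replicates - cells[1].replicates, level)
    return IndexResult(
        index=index, ci=ci, cells=cells, x=q.x, y=q.y,
        description=f"index of moderated mediation of {w} for {q}",
    )


def index_of_momome(
    est: ParamEstimates,
    x: str | None = None,
    m=(),
    y: str | None = None,
    w: str = "",
    z: str = "",
    *,
    query: PathQuery | None = None,
    store: ReplicateStore | None = None,
    level: float = 0.95,
) -> IndexResult:
    """Index of moderated moderated mediation: the double difference
    (ind(w=1,z=1) - ind(w=1,z=0)) - (ind(w=0,z=1) - ind(w=0,z=0))."""
    q = query if query is not None else PathQuery(x, tuple(m), y)
    mods = _path_moderators(est, q)
    for name in (w, z):
        if name not in mods:
            raise EffectError(f"{name!r} moderates no component path of {q}")
    grid = [(1.0, 1.0), (1.0, 0.0), (0.0, 1.0), (0.0, 0.0)]
    cells = tuple(
        indirect_effect(
            est, query=q, wvalues={w: wv, z: zv}, store=store, level=level,
            warn=False,
        )
        for wv, zv in grid
    )
    index = (cells[0].value - cells[1].value) - (cells[2].value - cells[3].value)
    ci = None
    if store is not None:
        diff = (cells[0].replicates - cells[1].replicates) - (
            cells[2].replicates - cells[3].replicates
        )
        ci = percentile_ci(diff, level)
    return IndexResult(
        index=index, ci=ci, cells=cells, x=q.x, y=q.y,
        description=(
            f"index of moderated moderated mediation of {w} and {z} for {q}; "
            "levels compared: (Row 1 - Row 2) - (Row 3 - Row 4)"
        ),
    )


def cond_indirect_diff(
    table: EffectTable, from_row: int, to_row: int, level: float | None = None
) -> IndexResult:
    """Difference between two rows of a conditional-effects table.

    Rows are one-based, as printed.  With levels one SD apart this is the
    z-index of moderated mediation.
    """
    nrows = len(table)
    for r in (from_row, to_row):
        if not 1 <= r <= nrows:
            raise EffectError(f"row {r} out of range 1..{nrows}")
    e_from, e_to = table.effect(from_row), table.effect(to_row)
    index = e_to.value - e_from.value
    ci = None
    if e_to.replicates is not None and e_from.replicates is not None:
        ci = percentile_ci(
            e_to.replicates - e_from.replicates, level or table.level
        )
    return IndexResult(
        index=index, ci=ci, cells=(e_to, e_from),
        x=table.query.x, y=table.query.y,
        description=(
            f"change in conditional indirect effect of {table.query} from "
            f"{table.wrow(from_row).label!r} to {table.wrow(to_row).label!r}"
        ),
    )


def indirect_proportion(
    est: ParamEstimates, x: str | None = None, m=(), y: str | None = None,
    *, query: PathQuery | None = None,
) -> float:
    """Proportion of the total x -> y effect carried by one path.

    Defined only for unmoderated x -> y pathways whose effects all share
    one sign; refuses (raises :class:`EffectError`) otherwise.
    """
    q = query if query is not None else PathQuery(x, tuple(m), y)
    validate_path(est.model, q)
    paths = enumerate_paths(est.model, q.x, q.y)
    effects = []
    for p in paths:
        edges = validate_path(est.model, p)
        for e in edges:
            if est.model.moderators_of_edge(e):
                raise EffectError(
                    f"edge {e[0]} -> {e[1]} on path {p} is moderated; the "
                    "proportion of effect mediated is not defined for "
                    "moderated models"
                )
        effects.append(
            float(np.prod([conditional_coefficient(est, e) for e in edges]))
        )
    signs = {np.sign(v) for v in effects if v != 0}
    if len(signs) > 1:
        raise EffectError(
            "path effects have mixed signs; the proportion mediated is not "
            "interpretable"
        )
    total = sum(effects)
    if total == 0:
        raise EffectError("total effect is zero; proportion undefined")
    target = indirect_effect(est, query=q, warn=False).value
    return target / total
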