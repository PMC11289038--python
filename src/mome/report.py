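"""Plain-text reports for effects, tables, and indices.

Reports are a pure function of their inputs: identical effect objects give
byte-identical text.  Values print to 3 decimals, component coefficients in
the Computation line to 5 decimals, and a "Sig" flag marks effects whose CI
excludes zero (no p-values are fabricated).
"""

from __future__ import annotations

from .effects import EffectResult, EffectTable, IndexResult

__all__ = ["render_effect", "render_table", "render_index"]

_METHOD_NAMES = {"bootstrap": "Bootstrap", "montecarlo": "Monte Carlo"}


def _ci_line(e) -> str | None:
    if e.ci is None:
        return None
    method = _METHOD_NAMES.get((e.store_tag or ("",))[0], "Percentile")
    return (
        f"{e.ci.level * 100:.1f}% {method} CI: "
        f"[{e.ci.lo:.3f} to {e.ci.hi:.3f}]"
    )


def render_effect(e: EffectResult) -> str:
    """Text report for one (conditional / combined) effect."""
    conditional = bool(e.wvalues)
    if e.parts:
        title = "== Function of Effects =="
        value_name = "Function of Effects"
    elif conditional:
        title = "== Conditional Indirect Effect =="
        value_name = "Conditional Indirect Effect"
    else:
        title = "== Indirect Effect =="
        value_name = "Indirect Effect"
    lines = [title, ""]
    for p in e.paths:
        lines.append(f" Path: {p}")
    lines.append(f" {value_name}: {e.value:.3f}")
    ci = _ci_line(e)
    if ci:
        lines.append(f" {ci}")
    if conditional:
        when = ", ".join(f"{k} = {v:.3f}" for k, v in sorted(e.wvalues.items()))
        lines.append(f" When: {when}")
    lines.append("")
    lines.append(f"Computation Formula: {e.trace}")
    lines.append(f"Computation: {e.computation}")
    if e.components:
        lines.append("")
        lines.append("Coefficients of Component Paths:")
        lines.append("  Path  Conditional Effect  Original Coefficient")
        for c in e.components:
            lines.append(f"  {c.label}  {c.value:.3f}  {c.base:.3f}")
    return "\n".join(lines) + "\n"


def render_table(table: EffectTable) -> str:
    """Text report for a conditional-effects table."""
    wl = table.wlevels
    mod_names = [name for name, _ in wl.moderators]
    value_col = "std" if (table.std_x and table.std_y) else "ind"
    header = ["row"]
    header += [f"[{name}]" for name in mod_names]
    header += [f"({c})" for c in wl.columns]
    header += [value_col, "CI.lo", "CI.hi", "Sig"]
    comp_labels = [c.label for c in table.rows[0][1].components]
    header += comp_labels
    body = []
    for i, (wrow, e) in enumerate(table.rows, start=1):
        cells = [str(i)]
        cells += list(wrow.labels)
        cells += [f"{wrow.values[c]:.3f}" for c in wl.columns]
        cells.append(f"{e.value:.3f}")
        if e.ci is not None:
            cells += [f"{e.ci.lo:.3f}", f"{e.ci.hi:.3f}"]
            cells.append("Sig" if e.ci.excludes_zero() else "")
        else:
            cells += ["", "", ""]
        cells += [f"{c.value:.3f}" for c in e.components]
        body.append(cells)
    widths = [
        max(len(header[j]), *(len(row[j]) for row in body))
        for j in range(len(header))
    ]
    kind = (
        "Conditional effects" if not table.query.m else "Conditional indirect effects"
    )
    lines = [
        f"== {kind} ==",
        "",
        f" Path: {table.query}",
        f" Conditional on moderator(s): {', '.join(mod_names)}",
        f" Moderator(s) represented by: {', '.join(wl.columns)}",
        "",
        "  ".join(h.rjust(w) for h, w in zip(header, widths)),
    ]
    for row in body:
        lines.append("  ".join(c.rjust(w) for c, w in zip(row, widths)))
    if any(e.ci is not None for _, e in table.rows):
        method = _METHOD_NAMES.get(
            (table.rows[0][1].store_tag or ("",))[0], "percentile"
        )
        lines.append(
            f" - [CI.lo to CI.hi] are {table.level * 100:.1f}% percentile "
            f"confidence intervals ({method})."
        )
    return "\n".join(lines) + "\n"


def render_index(ir: IndexResult, title: str = "Index of Moderated Mediation") -> str:
    lines = [f"== {title} ==", ""]
    if ir.description:
        lines.append(f" {ir.description}")
    row = f" x: {ir.x}  y: {ir.y}  Index: {ir.index:.3f}"
    if ir.ci is not None:
        row += f"  CI: [{ir.ci.lo:.3f} to {ir.ci.hi:.3f}]"
        row += "  Sig" if ir.ci.excludes_zero() else ""
    lines.append(row)
    return "\n".join(lines) + "\n"
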