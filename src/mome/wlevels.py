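"""Moderator-level tables for continuous and dummy-coded moderators.

Conditional effects are evaluated at a grid of moderator values.  For a
continuous moderator the conventional grids are mean +/- 1 SD (labelled
"M+1.0SD" / "Mean" / "M-1.0SD") or the 16th/50th/84th percentiles; for a
categorical moderator each group is one row over its dummy columns.  With a
single moderator three levels are used by default; with two or more, two
levels each (+1 SD and -1 SD).

Moments for the sd/percentile methods come from the same complete-case set
used for fitting, so levels stay fixed at their point-estimate values
across bootstrap replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as iproduct

import numpy as np
import pandas as pd

from .estimation import ParamEstimates

__all__ = [
    "WLevels",
    "DummyCoding",
    "mod_levels",
    "merge_mod_levels",
    "default_levels",
    "factor2var",
    "categorical_wlevels",
]


@dataclass(frozen=True)
class WRow:
    """One moderator-level combination: per-moderator labels and values."""

    labels: tuple[str, ...]
    values: dict[str, float]

    @property
    def label(self) -> str:
        return "; ".join(self.labels)


@dataclass
class WLevels:
    """A table of moderator-level combinations."""

    moderators: list[tuple[str, tuple[str, ...]]]  # (display name, columns)
    rows: list[WRow]

    def __post_init__(self):
        columns = [c for _, cols in self.moderators for c in cols]
        if len(set(columns)) != len(columns):
            raise ValueError("moderators must use disjoint model columns")
        labels = [r.label for r in self.rows]
        if len(set(labels)) != len(labels):
            raise ValueError("row labels must be unique")
        for r in self.rows:
            missing = set(columns) - set(r.values)
            if missing:
                raise ValueError(f"row {r.label!r} does not set {sorted(missing)}")

    @property
    def columns(self) -> list[str]:
        return [c for _, cols in self.moderators for c in cols]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [{c: r.values[c] for c in self.columns} for r in self.rows],
            index=[r.label for r in self.rows],
        )
        df.index.name = "label"
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "WLevels":
        df = pd.read_csv(path, index_col=0)
        cols = tuple(df.columns)
        return cls(
            moderators=[(name or "+".join(cols), cols)],
            rows=[
                WRow((str(ix),), {c: float(row[c]) for c in cols})
                for ix, row in df.iterrows()
            ],
        )


def default_levels(n_moderators: int) -> int:
    """Levels per continuous moderator: 3 for one moderator, else 2."""
    if n_moderators < 1:
        raise ValueError("need at least one moderator")
    return 3 if n_moderators == 1 else 2


def _sd_label(k: float, sign: int) -> str:
    if sign == 0:
        return "Mean"
    return f"M{'+' if sign > 0 else '-'}{k:.1f}SD"


def mod_levels(
    source,
    w: str,
    method: str = "sd",
    *,
    k_sd: float = 1.0,
    n_levels: int = 3,
    values=None,
    labels=None,
) -> WLevels:
    """Levels of one continuous moderator.

    ``source`` is a :class:`ParamEstimates` (sd method) or a DataFrame
    (sd or percentile methods).  ``method`` is ``"sd"`` (mean +/- k SD),
    ``"percentile"`` (16th/50th/84th), or ``"values"`` (passthrough).
    ``n_levels`` 2 drops the middle row.  Rows are ordered high to low.
    """
    if method == "values":
        if values is None:
            raise ValueError("method='values' requires explicit values")
        vals = [float(v) for v in values]
        labs = [str(l) for l in labels] if labels else [f"{v:g}" for v in vals]
        if len(labs) != len(vals):
            raise ValueError("labels and values differ in length")
        return WLevels(
            moderators=[(w, (w,))],
            rows=[WRow((lab,), {w: v}) for lab, v in zip(labs, vals)],
        )
    if n_levels not in (2, 3):
        raise ValueError("n_levels must be 2 or 3 for sd/percentile methods")
    if method == "sd":
        if isinstance(source, ParamEstimates):
            mean, sd = float(source.means[w]), float(source.sds[w])
        else:
            col = source[w].dropna()
            mean, sd = float(col.mean()), float(col.std(ddof=1))
        if sd == 0:
            raise ValueError(f"moderator {w!r} has zero variance")
        triples = [
            (_sd_label(k_sd, +1), mean + k_sd * sd),
            (_sd_label(k_sd, 0), mean),
            (_sd_label(k_sd, -1), mean - k_sd * sd),
        ]
    elif method == "percentile":
        if isinstance(source, ParamEstimates):
            raise ValueError(
                "method='percentile' needs the raw data, not ParamEstimates"
            )
        col = np.asarray(source[w].dropna(), dtype=float)
        p84, p50, p16 = np.percentile(col, [84, 50, 16], method="linear")
        triples = [("84%", float(p84)), ("50%", float(p50)), ("16%", float(p16))]
    else:
        raise ValueError(f"unknown method {method!r}")
    if n_levels == 2:
        triples = [triples[0], triples[2]]
    return WLevels(
        moderators=[(w, (w,))],
        rows=[WRow((lab,), {w: v}) for lab, v in triples],
    )


def merge_mod_levels(levels: list[WLevels]) -> WLevels:
    """Cartesian product of level tables, first moderator varying slowest."""
    if not levels:
        raise ValueError("no level tables to merge")
    if len(levels) == 1:
        return levels[0]
    moderators = [m for lv in levels for m in lv.moderators]
    rows = []
    for combo in iproduct(*[lv.rows for lv in levels]):
        values: dict[str, float] = {}
        labels: tuple[str, ...] = ()
        for r in combo:
            values.update(r.values)
            labels += r.labels
        rows.append(WRow(labels, values))
    return WLevels(moderators=moderators, rows=rows)


@dataclass(frozen=True)
class DummyCoding:
    """k-1 dummy columns for a categorical variable, first level as reference."""

    source: str
    levels: tuple[str, ...]
    columns: tuple[str, ...]
    reference: str

    def __post_init__(self):
        if len(self.columns) != len(self.levels) - 1:
            raise ValueError("need one dummy column per non-reference level")

    def decode(self, dummies: pd.DataFrame) -> pd.Series:
        """Recover the label vector from dummy columns (round trip)."""
        labels = pd.Series(self.reference, index=dummies.index, dtype=object)
        for level, col in zip(self.levels[1:], self.columns):
            labels[dummies[col] == 1] = level
        return labels


def factor2var(
    column: pd.Series, prefix: str = "", levels=None
) -> tuple[pd.DataFrame, DummyCoding]:
    """Dummy-code a categorical column.

    Returns k-1 indicator columns named ``prefix + level`` (the first level
    in sorted-or-supplied order is the reference, coded all-zero) together
    with the :class:`DummyCoding` record.
    """
    column = pd.Series(column)
    if levels is None:
        if isinstance(column.dtype, pd.CategoricalDtype):
            levels = [str(l) for l in column.cat.categories]
        else:
            levels = sorted(str(l) for l in column.dropna().unique())
    else:
        levels = [str(l) for l in levels]
    if len(levels) < 2:
        raise ValueError("categorical moderator needs at least two levels")
    as_str = column.astype("object").astype(str)
    cols = tuple(prefix + l for l in levels[1:])
    dummies = pd.DataFrame(
        {c: (as_str == l).astype(float) for l, c in zip(levels[1:], cols)},
        index=column.index,
    )
    dummies[column.isna()] = np.nan
    coding = DummyCoding(
        source=str(column.name or "factor"),
        levels=tuple(levels),
        columns=cols,
        reference=levels[0],
    )
    return dummies, coding


def categorical_wlevels(coding: DummyCoding, name: str | None = None) -> WLevels:
    """One row per group of a dummy-coded moderator.

    The reference group sets all dummies to 0 and is labelled "Reference";
    each other group sets its own dummy to 1 (group name inferred from the
    dummy column names, stripping the shared prefix when one exists).
    """
    rows = [WRow(("Reference",), {c: 0.0 for c in coding.columns})]
    for level, col in zip(coding.levels[1:], coding.columns):
        values = {c: 1.0 if c == col else 0.0 for c in coding.columns}
        rows.append(WRow((level,), values))
    return WLevels(moderators=[(name or coding.source, coding.columns)], rows=rows)
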