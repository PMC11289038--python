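"""Synthetic datasets with the structure of the demonstration models.

The generator draws exogenous variables from a multivariate normal and
builds each endogenous variable from its linear equation (product terms
computed from the current columns) plus normal error, in causal order, so
the true coefficients are known exactly and parameter recovery, implied
covariances, and bootstrap coverage can all be checked against ground
truth.  Missing-completely-at-random injection emulates an incomplete
demonstration dataset (n = 200 with roughly 16% incomplete cases).

The default two-moderator demonstration model has two predictors (x1, x2),
three mediators (m1, m2, m3), two outcomes (y1, y2), two moderators (w1
moderating x1 -> m1; w2 moderating m2 -> y1) and two control variables
(c1, c2); default coefficients sit near typical reported estimates of such
a model so effects of realistic printed magnitude arise naturally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EquationDef",
    "SyntheticSpec",
    "generate",
    "inject_missing",
    "make_categorical",
    "model1_spec",
    "simple_mediation_spec",
    "MODEL1_SYNTAX",
    "MODEL1_PRODUCTS",
]

MODEL1_SYNTAX = """\
m1 ~ x1 + w1 + w1x1 + x2 + c1 + c2
m2 ~ m1 + c1 + c2
m3 ~ x2 + x1 + c1 + c2
y1 ~ m2 + w2 + w2m2 + x1 + x2 + m3 + c1 + c2
y2 ~ m3 + x2 + x1 + m2 + c1 + c2
"""

MODEL1_PRODUCTS = {"w1x1": ("w1", "x1"), "w2m2": ("w2", "m2")}


@dataclass(frozen=True)
class EquationDef:
    """One structural equation: outcome, coefficient map, and error SD."""

    outcome: str
    coef: dict[str, float]
    error_sd: float

    def __post_init__(self):
        if self.error_sd < 0:
            raise ValueError("error SD must be nonnegative")


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset."""

    n: int
    exo_names: tuple[str, ...]
    exo_cov: np.ndarray
    equations: list[EquationDef]
    products: dict[str, tuple[str, str]] = field(default_factory=dict)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.exo_cov = np.asarray(self.exo_cov, dtype=float)
        k = len(self.exo_names)
        if self.exo_cov.shape != (k, k):
            raise ValueError("exo_cov shape does not match exo_names")
        if np.linalg.eigvalsh(self.exo_cov)[0] <= 0:
            raise ValueError("exo_cov must be positive definite")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        known = set(self.exo_names)
        for eq in self.equations:
            for term in eq.coef:
                if term in known:
                    continue
                if term in self.products:
                    mod, focal = self.products[term]
                    if mod not in known or focal not in known:
                        raise ValueError(
                            f"equation for {eq.outcome!r} uses product "
                            f"{term!r} before its factors are generated"
                        )
                else:
                    raise ValueError(
                        f"equation for {eq.outcome!r} uses unknown term {term!r}"
                    )
            known.add(eq.outcome)

    @property
    def truth(self) -> dict:
        """Ground-truth record: coefficients and error SDs per outcome."""
        return {
            "coefficients": {eq.outcome: dict(eq.coef) for eq in self.equations},
            "error_sd": {eq.outcome: eq.error_sd for eq in self.equations},
        }


def _equicorr(k: int, rho: float) -> np.ndarray:
    return np.full((k, k), rho) + (1 - rho) * np.eye(k)


def model1_spec(
    n: int = 200, missing_rate: float = 0.155, seed: int = 0
) -> SyntheticSpec:
    """Default spec for the two-moderator demonstration model.

    Unit-variance exogenous variables with 0.2 equicorrelation; the default
    ``missing_rate`` of 0.155 at n = 200 yields about 31 incomplete cases.
    """
    exo = ("x1", "x2", "w1", "w2", "c1", "c2")
    equations = [
        EquationDef("m1", {"x1": 0.35, "w1": 0.02, "w1x1": 0.15, "x2": 0.16,
                           "c1": 0.10, "c2": 0.10}, 0.9),
        EquationDef("m2", {"m1": 0.55, "c1": 0.10, "c2": 0.10}, 0.9),
        EquationDef("m3", {"x2": 0.50, "x1": 0.32, "c1": 0.10, "c2": 0.10}, 0.9),
        EquationDef("y1", {"m2": 0.83, "w2": 0.43, "w2m2": 0.80, "x1": -0.03,
                           "x2": -0.11, "m3": 0.11, "c1": 0.10, "c2": 0.10}, 1.2),
        EquationDef("y2", {"m3": 0.55, "x2": -0.02, "x1": 0.03, "m2": -0.03,
                           "c1": 0.10, "c2": 0.10}, 0.9),
    ]
    return SyntheticSpec(
        n=n,
        exo_names=exo,
        exo_cov=_equicorr(len(exo), 0.2),
        equations=equations,
        products=dict(MODEL1_PRODUCTS),
        missing_rate=missing_rate,
        seed=seed,
    )


def simple_mediation_spec(
    n: int = 200, a: float = 0.3, b: float = 0.3, cp: float = 0.0, seed: int = 0
) -> SyntheticSpec:
    """x -> m -> y mediation with unit-variance normal x and unit errors."""
    return SyntheticSpec(
        n=n,
        exo_names=("x",),
        exo_cov=np.eye(1),
        equations=[
            EquationDef("m", {"x": a}, 1.0),
            EquationDef("y", {"m": b, "x": cp}, 1.0),
        ],
        seed=seed,
    )


def generate(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Draw one dataset from ``spec``; returns (data, truth record).

    Deterministic given the seed.  Product columns referenced by equations
    are materialized as data columns; MCAR injection is applied when
    ``spec.missing_rate`` is positive.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    k = len(spec.exo_names)
    L = np.linalg.cholesky(spec.exo_cov)
    exo = rng.standard_normal((spec.n, k)) @ L.T
    data = pd.DataFrame(exo, columns=list(spec.exo_names))

    def materialize(term: str) -> None:
        if term in data.columns:
            return
        mod, focal = spec.products[term]
        data[term] = data[mod] * data[focal]

    for eq in spec.equations:
        for term in eq.coef:
            materialize(term)
        lin = sum(c * data[t] for t, c in eq.coef.items())
        data[eq.outcome] = lin + rng.normal(0.0, eq.error_sd, spec.n)
    for term in spec.products:
        materialize(term)

    if spec.missing_rate > 0:
        observed = [c for c in data.columns if c not in spec.products]
        data[observed] = inject_missing(
            data[observed], spec.missing_rate, seed=int(rng.integers(2**31))
        )
        for term, (mod, focal) in spec.products.items():
            data[term] = data[mod] * data[focal]
    return data, spec.truth


def inject_missing(
    data: pd.DataFrame,
    rate: float,
    pattern: str = "case",
    seed: int = 0,
    col_rate: float = 0.3,
) -> pd.DataFrame:
    """Delete values completely at random.

    ``pattern="case"``: each case becomes incomplete with probability
    ``rate``; within an incomplete case each column is blanked with
    probability ``col_rate`` (at least one).  ``pattern="cell"``: each cell
    is blanked independently with probability ``rate``.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    data = data.copy()
    if rate == 0:
        return data
    rng = np.random.default_rng(seed)
    n, k = data.shape
    if pattern == "cell":
        mask = rng.random((n, k)) < rate
    elif pattern == "case":
        incomplete = rng.random(n) < rate
        mask = np.zeros((n, k), dtype=bool)
        cols = rng.random((n, k)) < col_rate
        forced = rng.integers(0, k, size=n)
        cols[np.arange(n), forced] = True
        mask[incomplete] = cols[incomplete]
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    values = data.to_numpy(dtype=float)
    values[mask] = np.nan
    return pd.DataFrame(values, index=data.index, columns=data.columns)


def make_categorical(
    data: pd.DataFrame, source: str, cuts, labels
) -> pd.Series:
    """Bin a continuous column into ordered groups with (lo, hi] intervals.

    A value exactly at a cut point falls in the lower bin.
    """
    cuts = list(cuts)
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("cut points must be strictly increasing")
    if len(labels) != len(cuts) + 1:
        raise ValueError("need one label per bin (len(cuts) + 1)")
    return pd.cut(
        data[source], bins=[-np.inf, *cuts, np.inf], labels=list(labels),
        right=True,
    )
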