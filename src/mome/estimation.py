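"""Per-equation ordinary least squares on one shared case set.

Every equation of the path model is fitted by OLS.  All equations must use
*exactly* the same cases (same case ids, not just the same count): effects
are products of coefficients from different equations, which is only
coherent when they describe one sample.  Missing data are handled by
explicit listwise deletion (:func:`complete_cases`) before fitting.

The estimates object also carries the sample means and SDs (n-1
denominator) of every model column on the shared case set -- these are the
SDs used for (partial) standardization -- and the sample covariance of the
exogenous columns (product columns included), which feeds the model-implied
covariance and the Monte Carlo replicate generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    EstimationError,
    ProductMismatchError,
    RankDeficiencyError,
    SameCasesError,
)
from .model_graph import PathModel, check_connected, parse_model

__all__ = [
    "ParamEstimates",
    "ImpliedCov",
    "fit_equations",
    "implied_covariance",
    "complete_cases",
    "ensure_product_columns",
    "load_data",
    "FIT_CALLS",
]

INTERCEPT = "(Intercept)"

#: Counter of equation-system fits, incremented by :func:`fit_equations`.
#: Lets callers assert that reusing a replicate store performs no refitting.
FIT_CALLS = 0

_PRODUCT_TOL = 1e-8


def load_data(path) -> pd.DataFrame:
    """Read a CSV data table; empty cells and "NA" are parsed as missing."""
    return pd.read_csv(path, na_values=["NA"])


def ensure_product_columns(
    model: PathModel, data: pd.DataFrame, verify: bool = True
) -> pd.DataFrame:
    """Compute missing product columns; verify the pre-computed ones.

    A registered product column already present in ``data`` must equal
    moderator x focal row-wise (within 1e-8) on rows where all three are
    observed; otherwise :class:`ProductMismatchError` is raised.
    """
    data = data.copy()
    for p in model.products:
        for v in (p.moderator, p.focal):
            if v not in data.columns:
                raise EstimationError(f"column {v!r} missing from the data")
        expected = data[p.moderator] * data[p.focal]
        if p.column not in data.columns:
            data[p.column] = expected
        elif verify:
            both = data[p.column].notna() & expected.notna()
            if not np.allclose(
                data.loc[both, p.column], expected[both], atol=_PRODUCT_TOL, rtol=0
            ):
                raise ProductMismatchError(
                    f"column {p.column!r} does not equal "
                    f"{p.moderator!r} * {p.focal!r} row-wise"
                )
    return data


def _model_columns(model: PathModel) -> list[str]:
    return sorted(model.variables) + [p.column for p in model.products]


def _equation_columns(model: PathModel, outcome: str) -> list[str]:
    return [outcome, *model.equation_for(outcome).terms]


def complete_cases(model: PathModel, data: pd.DataFrame) -> pd.DataFrame:
    """Listwise deletion: keep cases complete on every model column."""
    data = ensure_product_columns(model, data)
    return data.dropna(subset=_model_columns(model))


@dataclass
class ParamEstimates:
    """Coefficients, sampling covariances, and moments of a fitted model."""

    model: PathModel
    coefficients: dict[str, dict[str, float]]
    resid_var: dict[str, float]
    n: int
    means: pd.Series
    sds: pd.Series
    coef_cov: dict[str, pd.DataFrame] = field(default_factory=dict)
    exo_cov: pd.DataFrame | None = None
    case_ids: tuple = ()

    def __post_init__(self):
        for outcome, psi in self.resid_var.items():
            if psi < 0:
                raise EstimationError(f"negative residual variance for {outcome!r}")
        if (self.sds < 0).any():
            raise EstimationError("negative SD")

    @classmethod
    def from_coefficients(
        cls,
        model: PathModel | str,
        coefficients: dict[str, dict[str, float]],
        *,
        sds: dict[str, float] | None = None,
        means: dict[str, float] | None = None,
        n: int = 0,
        products: dict | None = None,
    ) -> "ParamEstimates":
        """Build estimates from known coefficients (e.g. a published table).

        ``model`` may be a :class:`PathModel` or model syntax.  Intercepts
        default to 0, residual variances to 0, means to 0 and SDs to 1
        unless supplied.  Useful for effect algebra on reported estimates,
        where raw data are unavailable.
        """
        if isinstance(model, str):
            model = parse_model(model, products=products)
        cols = _model_columns(model)
        coefs = {}
        for eq in model.equations:
            given = coefficients.get(eq.outcome, {})
            unknown = set(given) - set(eq.terms) - {INTERCEPT}
            if unknown:
                raise EstimationError(
                    f"coefficients for {eq.outcome!r} include terms not in its "
                    f"equation: {sorted(unknown)}"
                )
            row = {INTERCEPT: float(given.get(INTERCEPT, 0.0))}
            for t in eq.terms:
                row[t] = float(given.get(t, 0.0))
            coefs[eq.outcome] = row
        return cls(
            model=model,
            coefficients=coefs,
            resid_var={eq.outcome: 0.0 for eq in model.equations},
            n=n,
            means=pd.Series({c: float((means or {}).get(c, 0.0)) for c in cols}),
            sds=pd.Series({c: float((sds or {}).get(c, 1.0)) for c in cols}),
        )

    def coefficient(self, outcome: str, term: str) -> float:
        return self.coefficients[outcome][term]

    def to_json(self) -> str:
        payload = {
            "schema": "mome-estimates/1",
            "n": self.n,
            "coefficients": self.coefficients,
            "resid_var": self.resid_var,
            "means": self.means.to_dict(),
            "sds": self.sds.to_dict(),
            "coef_cov": {
                k: {"index": list(v.index), "values": v.to_numpy().tolist()}
                for k, v in self.coef_cov.items()
            },
            "exo_cov": None
            if self.exo_cov is None
            else {
                "index": list(self.exo_cov.index),
                "values": self.exo_cov.to_numpy().tolist(),
            },
            "model": self.model.to_syntax(),
            "products": {
                p.column: [p.moderator, p.focal] for p in self.model.products
            },
        }
        return json.dumps(payload, indent=1)


def fit_equations(model: PathModel, data: pd.DataFrame) -> ParamEstimates:
    """Fit every equation by OLS on the shared complete-case set.

    Raises :class:`SameCasesError` if the per-equation complete-case sets
    differ, and :class:`RankDeficiencyError` (naming the equation) on a
    rank-deficient design.
    """
    global FIT_CALLS
    check_connected(model)
    data = ensure_product_columns(model, data)
    missing = set(_model_columns(model)) - set(data.columns)
    if missing:
        raise EstimationError(f"columns missing from the data: {sorted(missing)}")

    case_sets = {}
    for eq in model.equations:
        cols = _equation_columns(model, eq.outcome)
        case_sets[eq.outcome] = frozenset(data.index[data[cols].notna().all(axis=1)])
    reference = next(iter(case_sets.values()))
    if any(s != reference for s in case_sets.values()):
        counts = {k: len(v) for k, v in case_sets.items()}
        raise SameCasesError(
            "equations must be fitted on exactly the same cases, not just the "
            f"same sample sizes; complete-case counts per outcome: {counts}. "
            "Apply listwise deletion (complete_cases) first."
        )
    shared = data.loc[sorted(reference), _model_columns(model)].astype(float)
    n = len(shared)

    coefficients, resid_var, coef_cov = {}, {}, {}
    for eq in model.equations:
        names = [INTERCEPT, *eq.terms]
        X = np.column_stack(
            [np.ones(n)] + [shared[t].to_numpy() for t in eq.terms]
        )
        y = shared[eq.outcome].to_numpy()
        p = X.shape[1]
        if n < p + 1:
            raise EstimationError(
                f"too few cases (n={n}) for equation {eq.outcome!r} with {p} terms"
            )
        if np.linalg.matrix_rank(X) < p:
            raise RankDeficiencyError(
                f"rank-deficient design for equation {eq.outcome!r}"
            )
        xtx = X.T @ X
        beta = np.linalg.solve(xtx, X.T @ y)
        resid = y - X @ beta
        psi = float(resid @ resid) / (n - p)
        coefficients[eq.outcome] = dict(zip(names, beta.tolist()))
        resid_var[eq.outcome] = psi
        coef_cov[eq.outcome] = pd.DataFrame(
            psi * np.linalg.inv(xtx), index=names, columns=names
        )

    FIT_CALLS += 1
    exo = model.exo_columns
    return ParamEstimates(
        model=model,
        coefficients=coefficients,
        resid_var=resid_var,
        n=n,
        means=shared.mean(),
        sds=shared.std(ddof=1),
        coef_cov=coef_cov,
        exo_cov=shared[exo].cov(),
        case_ids=tuple(shared.index),
    )


@dataclass
class ImpliedCov:
    """Model-implied covariance over all model variables (products included)."""

    cov: pd.DataFrame

    def sd(self, var: str) -> float:
        return float(np.sqrt(self.cov.loc[var, var]))

    @property
    def sds(self) -> pd.Series:
        return np.sqrt(pd.Series(np.diag(self.cov), index=self.cov.index))


def _structural_matrices(model: PathModel, coefficients: dict) -> tuple:
    """B (endo x endo), G (endo x exo-cols) from a coefficient mapping."""
    endo = model.endo_order
    exo = model.exo_columns
    endo_ix = {v: i for i, v in enumerate(endo)}
    exo_ix = {v: i for i, v in enumerate(exo)}
    B = np.zeros((len(endo), len(endo)))
    G = np.zeros((len(endo), len(exo)))
    for i, outcome in enumerate(endo):
        for term, value in coefficients[outcome].items():
            if term == INTERCEPT:
                continue
            if term in endo_ix:
                B[i, endo_ix[term]] = value
            else:
                G[i, exo_ix[term]] = value
    return B, G, endo, exo


def _implied_cov_arrays(B, G, S_exo, psi):
    """Recursive-system identity: full covariance from (B, G, S_exo, Psi).

    Endogenous block (I-B)^-1 (G S G' + Psi) (I-B)^-T; cross block
    (I-B)^-1 G S.  ``B`` strictly lower-triangularizable for a DAG, so
    (I-B) is always invertible.
    """
    ne = B.shape[0]
    A = np.linalg.solve(np.eye(ne) - B, np.eye(ne))
    GS = G @ S_exo
    endo_block = A @ (GS @ G.T + np.diag(psi)) @ A.T
    cross = A @ GS  # cov(endo, exo)
    top = np.concatenate([S_exo, cross.T], axis=1)
    bottom = np.concatenate([cross, endo_block], axis=1)
    return np.concatenate([top, bottom], axis=0)


def implied_covariance(model: PathModel, est: ParamEstimates) -> ImpliedCov:
    """Model-implied covariance of all variables from the fitted system.

    Product columns are treated as exogenous columns of ``exo_cov``.
    """
    if est.exo_cov is None:
        raise EstimationError("estimates carry no exogenous covariance")
    B, G, endo, exo = _structural_matrices(model, est.coefficients)
    S_exo = est.exo_cov.loc[exo, exo].to_numpy()
    psi = np.array([est.resid_var[v] for v in endo])
    full = _implied_cov_arrays(B, G, S_exo, psi)
    names = exo + endo
    return ImpliedCov(pd.DataFrame(full, index=names, columns=names))
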