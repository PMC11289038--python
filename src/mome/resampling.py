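"""Replicate parameter sets: nonparametric bootstrap and Monte Carlo draws.

A :class:`ReplicateStore` holds R replicate coefficient/SD/mean sets,
generated once and reused by every effect computation afterwards -- the
expensive resampling never has to be repeated when a new path or moderator
level is examined.

Replicates are generated in chunks with per-chunk seeds derived from the
top-level seed (`numpy.random.SeedSequence.spawn`), so the contents are
bit-identical for any worker count.

Bootstrap replicates refit every equation on a with-replacement resample of
the shared case set and record the resample's own means and SDs, so that
standardized effects are standardized with *per-replicate* SDs.  The fits
use batched normal equations (one solve per resample and equation), which
keeps R = 1000 bootstraps on a small model in the tens of milliseconds.

Monte Carlo replicates draw each equation's coefficient vector from a
multivariate normal centred at the estimates with that equation's sampling
covariance (independent across equations), residual variances as
psi_hat * chi2_df / df with df = n - p, and the exogenous covariance from a
Wishart with scale exo_cov/(n-1) and n-1 degrees of freedom; replicate SDs
come from each replicate's implied covariance.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from . import estimation
from .estimation import INTERCEPT, ParamEstimates, _implied_cov_arrays, _structural_matrices
from .exceptions import EstimationError, ReplicationError
from .model_graph import PathModel

__all__ = [
    "ReplicateStore",
    "CIResult",
    "bootstrap_estimates",
    "mc_estimates",
    "percentile_ci",
]

_EIG_TOL = 1e-10


@dataclass(frozen=True)
class CIResult:
    """A percentile confidence interval."""

    lo: float
    hi: float
    level: float

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError("lo > hi")

    def excludes_zero(self) -> bool:
        return self.lo > 0 or self.hi < 0


@dataclass
class ReplicateStore:
    """R replicate coefficient-and-SD sets from bootstrap or Monte Carlo."""

    method: str  # "bootstrap" | "montecarlo"
    R: int
    seed: int
    coef: dict[str, dict[str, np.ndarray]]  # outcome -> term -> (R,)
    sds: dict[str, np.ndarray]  # variable -> (R,)
    means: dict[str, np.ndarray]
    failures: int = 0

    def __post_init__(self):
        for outcome, terms in self.coef.items():
            for term, v in terms.items():
                if len(v) != self.R:
                    raise ValueError(
                        f"replicate vector for {outcome}~{term} has wrong length"
                    )

    @property
    def tag(self) -> tuple:
        """Provenance tag: replicate vectors combine only within one store."""
        return (self.method, self.R, self.seed)

    def coef_replicates(self, outcome: str, term: str) -> np.ndarray:
        return self.coef[outcome][term]

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "schema": "mome-replicates/1",
            "method": self.method,
            "R": self.R,
            "seed": self.seed,
            "failures": self.failures,
            "coef": {
                o: {t: v.tolist() for t, v in terms.items()}
                for o, terms in self.coef.items()
            },
            "sds": {k: v.tolist() for k, v in self.sds.items()},
            "means": {k: v.tolist() for k, v in self.means.items()},
        }
        text = json.dumps(payload)
        path = str(path)
        if path.endswith(".gz"):
            with gzip.open(path, "wt") as fh:
                fh.write(text)
        else:
            with open(path, "w") as fh:
                fh.write(text)

    @classmethod
    def load(cls, path) -> "ReplicateStore":
        path = str(path)
        opener = gzip.open if path.endswith(".gz") else open
        with opener(path, "rt") as fh:
            payload = json.load(fh)
        if payload.get("schema") != "mome-replicates/1":
            raise ValueError(f"unrecognized replicate-store schema in {path}")
        return cls(
            method=payload["method"],
            R=payload["R"],
            seed=payload["seed"],
            failures=payload["failures"],
            coef={
                o: {t: np.asarray(v) for t, v in terms.items()}
                for o, terms in payload["coef"].items()
            },
            sds={k: np.asarray(v) for k, v in payload["sds"].items()},
            means={k: np.asarray(v) for k, v in payload["means"].items()},
        )


def percentile_ci(values, level: float = 0.95) -> CIResult:
    """Percentile interval by linear-interpolation (type 7) quantiles."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty replicate vector")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2], method="linear")
    return CIResult(float(lo), float(hi), level)


def _chunk_sizes(R: int, chunk_size: int) -> list[int]:
    sizes = [chunk_size] * (R // chunk_size)
    if R % chunk_size:
        sizes.append(R % chunk_size)
    return sizes


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def _boot_chunk(values, eq_col_idx, r, seed_seq, max_attempts):
    """Fit all equations on ``r`` with-replacement resamples.

    ``values`` is the (n, V) complete-case matrix over all model columns;
    ``eq_col_idx`` maps each outcome to (y column, predictor columns).
    Resamples with rank-deficient designs are redrawn; the redraw count is
    returned as the chunk's failure count.
    """
    rng = np.random.default_rng(seed_seq)
    n, V = values.shape
    idx = rng.integers(0, n, size=(r, n))
    failures = 0
    attempts = 0
    betas = {}
    while True:
        rows = values[idx]  # (r, n, V)
        bad = np.zeros(r, dtype=bool)
        for outcome, (y_ix, x_ix) in eq_col_idx.items():
            p = len(x_ix) + 1
            X = np.concatenate(
                [np.ones((r, n, 1)), rows[:, :, x_ix]], axis=2
            )
            y = rows[:, :, y_ix]
            xtx = np.einsum("rni,rnj->rij", X, X)
            xty = np.einsum("rni,rn->ri", X, y)
            eig = np.linalg.eigvalsh(xtx)
            singular = eig[:, 0] <= _EIG_TOL * np.maximum(eig[:, -1], 1.0)
            bad |= singular
            solvable = ~singular
            beta = np.full((r, p), np.nan)
            if solvable.any():
                beta[solvable] = np.linalg.solve(
                    xtx[solvable], xty[solvable][..., None]
                )[..., 0]
            betas[outcome] = beta
        if not bad.any():
            break
        failures += int(bad.sum())
        attempts += int(bad.sum())
        if attempts > max_attempts:
            raise ReplicationError(
                f"more than {max_attempts} degenerate bootstrap resamples"
            )
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
    means = rows.mean(axis=1)  # (r, V)
    sds = rows.std(axis=1, ddof=1)
    return betas, means, sds, failures


def bootstrap_estimates(
    model: PathModel,
    data: pd.DataFrame,
    R: int,
    seed: int,
    *,
    chunk_size: int = 256,
    jobs: int = 1,
) -> ReplicateStore:
    """Nonparametric case-resampling bootstrap of the whole equation system.

    Deterministic given ``seed`` regardless of ``jobs``: replicates are
    partitioned into chunks with per-chunk derived seeds.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    est = estimation.fit_equations(model, data)  # validates; shared case set
    shared = estimation.ensure_product_columns(model, data).loc[
        list(est.case_ids), estimation._model_columns(model)
    ].astype(float)
    values = shared.to_numpy()
    columns = list(shared.columns)
    col_ix = {c: i for i, c in enumerate(columns)}
    eq_col_idx = {
        eq.outcome: (col_ix[eq.outcome], [col_ix[t] for t in eq.terms])
        for eq in model.equations
    }

    sizes = _chunk_sizes(R, chunk_size)
    seqs = np.random.SeedSequence(seed).spawn(len(sizes))
    max_attempts = 10 * R
    runner = Parallel(n_jobs=jobs) if jobs > 1 else None
    if runner is None:
        results = [
            _boot_chunk(values, eq_col_idx, r, sq, max_attempts)
            for r, sq in zip(sizes, seqs)
        ]
    else:
        results = runner(
            delayed(_boot_chunk)(values, eq_col_idx, r, sq, max_attempts)
            for r, sq in zip(sizes, seqs)
        )

    coef: dict[str, dict[str, np.ndarray]] = {}
    for eq in model.equations:
        names = [INTERCEPT, *eq.terms]
        stacked = np.concatenate([res[0][eq.outcome] for res in results], axis=0)
        coef[eq.outcome] = {t: stacked[:, j] for j, t in enumerate(names)}
    all_means = np.concatenate([res[1] for res in results], axis=0)
    all_sds = np.concatenate([res[2] for res in results], axis=0)
    failures = sum(res[3] for res in results)
    estimation.FIT_CALLS += R
    return ReplicateStore(
        method="bootstrap",
        R=R,
        seed=seed,
        coef=coef,
        sds={c: all_sds[:, j] for j, c in enumerate(columns)},
        means={c: all_means[:, j] for j, c in enumerate(columns)},
        failures=failures,
    )


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------


def _mc_chunk(est: ParamEstimates, r: int, seed_seq) -> tuple:
    rng = np.random.default_rng(seed_seq)
    model = est.model
    n = est.n
    exo = model.exo_columns
    endo = model.endo_order
    q = len(exo)

    # coefficient draws: block-diagonal MVN across equations
    draws: dict[str, dict[str, np.ndarray]] = {}
    psi_draws = np.empty((r, len(endo)))
    for k, outcome in enumerate(endo):
        eq = model.equation_for(outcome)
        names = [INTERCEPT, *eq.terms]
        cov = est.coef_cov[outcome].loc[names, names].to_numpy()
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as err:
            raise EstimationError(
                f"coefficient covariance for {outcome!r} is not positive definite"
            ) from err
        center = np.array([est.coefficients[outcome][t] for t in names])
        z = rng.standard_normal((r, len(names)))
        beta = center + z @ L.T
        draws[outcome] = {t: beta[:, j] for j, t in enumerate(names)}
        df = n - len(names)
        psi_draws[:, k] = est.resid_var[outcome] * rng.chisquare(df, size=r) / df

    # exogenous covariance draws: Wishart(n-1, exo_cov/(n-1))
    S = est.exo_cov.loc[exo, exo].to_numpy()
    W = stats.wishart.rvs(
        df=n - 1, scale=S / (n - 1), size=r, random_state=rng
    ).reshape(r, q, q)

    # replicate SDs from each replicate's implied covariance
    ne = len(endo)
    B3 = np.zeros((r, ne, ne))
    G3 = np.zeros((r, ne, q))
    endo_ix = {v: i for i, v in enumerate(endo)}
    exo_ix = {v: i for i, v in enumerate(exo)}
    for i, outcome in enumerate(endo):
        for term, vec in draws[outcome].items():
            if term == INTERCEPT:
                continue
            if term in endo_ix:
                B3[:, i, endo_ix[term]] = vec
            else:
                G3[:, i, exo_ix[term]] = vec
    A = np.linalg.solve(np.eye(ne) - B3, np.broadcast_to(np.eye(ne), (r, ne, ne)))
    GS = G3 @ W
    M = GS @ G3.transpose(0, 2, 1)
    M[:, np.arange(ne), np.arange(ne)] += psi_draws
    endo_cov = A @ M @ A.transpose(0, 2, 1)

    sds = {}
    for v, j in exo_ix.items():
        sds[v] = np.sqrt(W[:, j, j])
    for v, i in endo_ix.items():
        sds[v] = np.sqrt(endo_cov[:, i, i])
    return draws, sds


def mc_estimates(
    est: ParamEstimates,
    R: int,
    seed: int,
    *,
    chunk_size: int = 5000,
    jobs: int = 1,
) -> ReplicateStore:
    """Monte Carlo replicate parameter sets from the estimates' sampling law."""
    if R < 1:
        raise ValueError("R must be >= 1")
    if not est.coef_cov:
        raise EstimationError("estimates carry no coefficient covariances")
    if est.exo_cov is None:
        raise EstimationError("estimates carry no exogenous covariance")
    sizes = _chunk_sizes(R, chunk_size)
    seqs = np.random.SeedSequence(seed).spawn(len(sizes))
    if jobs > 1:
        results = Parallel(n_jobs=jobs)(
            delayed(_mc_chunk)(est, r, sq) for r, sq in zip(sizes, seqs)
        )
    else:
        results = [_mc_chunk(est, r, sq) for r, sq in zip(sizes, seqs)]

    model = est.model
    coef = {}
    for eq in model.equations:
        names = [INTERCEPT, *eq.terms]
        coef[eq.outcome] = {
            t: np.concatenate([res[0][eq.outcome][t] for res in results])
            for t in names
        }
    variables = list(results[0][1])
    sds = {v: np.concatenate([res[1][v] for res in results]) for v in variables}
    means = {v: np.full(R, est.means[v]) for v in variables}
    return ReplicateStore(
        method="montecarlo", R=R, seed=seed, coef=coef, sds=sds, means=means
    )
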