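"""Two-step proteomic association: LASSO screening, then moderated t-tests.

Given per-participant sleep phenotypes, covariates and an NPX matrix the
stage runs, per sleep outcome (secondary / daytime / afternoon TST):

1. **LASSO screening** — predict the standardized sleep outcome from all
   assay NPX columns plus the covariates; covariates are unpenalized
   (they are confounders to retain, the screen is over proteins). The
   penalty weight is chosen by seeded 10-fold cross-validation. Assays
   with non-zero coefficients form the shortlist.
2. **Per-assay linear models** — for each shortlisted assay, ordinary
   least squares of NPX (response) on the standardized sleep outcome and
   covariates, over the rows where the assay was measured (per-assay
   sample counts vary after QC exclusion).
3. **Empirical-Bayes variance moderation** — residual variances are
   shrunk toward a common prior fitted by moment-matching on the
   log-variances (the scaled-F hierarchical model), yielding moderated
   t-statistics with d0 extra degrees of freedom.
4. **Benjamini-Hochberg** step-up adjustment over the shortlist, with
   q < 0.05 declaring significance.

A quadratic variant adds the square of the standardized outcome
(centered) to the design and tests that coefficient instead, probing
for nonlinear dose-response.

The coordinate-descent LASSO solver lives here because the screen needs
per-coefficient penalty factors (zero for covariates), which generic
solvers do not expose. It minimizes

    (1/2n) * ||y - X b||^2 + lambda * sum_j w_j |b_j|

over a Gram-matrix representation with active-set sweeps and warm starts
along the lambda path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io import NPXMatrix

__all__ = [
    "AssayFit",
    "ModerationState",
    "AssociationResult",
    "prepare_design",
    "lasso_coordinate_descent",
    "lasso_path",
    "lasso_screen",
    "fit_assay",
    "estimate_prior",
    "squeeze_variance",
    "moderate",
    "bh_adjust",
    "run_association",
]

Outcome = Literal["secondary", "daytime", "afternoon"]

OUTCOME_FIELDS = {
    "secondary": "avg_secondary_tst",
    "daytime": "avg_daytime_tst",
    "afternoon": "avg_afternoon_tst",
}

COVARIATE_DESIGN_COLUMNS = (
    "age",
    "sex",
    "bmi",
    "steps_z",
    "metabolic_disease",
    "hypertension",
    "arrhythmia_hf",
    "cystatin_c",
)

SIGNIFICANCE_Q = 0.05


@dataclass
class AssayFit:
    """Per-assay OLS summary for the tested coefficient."""

    assay_id: str
    beta: float  # slope on the tested term, NPX log2 units per SD of outcome
    se_unscaled: float  # sqrt of the (X'X)^-1 diagonal for the tested term
    sigma2: float  # residual variance RSS / df_resid
    df_resid: int
    n_used: int

    @property
    def se_raw(self) -> float:
        return self.se_unscaled * np.sqrt(self.sigma2)


@dataclass
class ModerationState:
    """Empirical-Bayes shrinkage state and the resulting inference."""

    assay_ids: list[str]
    d0: float  # prior degrees of freedom, may be +inf
    s0_sq: float  # prior variance
    s_tilde_sq: np.ndarray  # posterior (moderated) variances
    t_mod: np.ndarray
    df_total: np.ndarray
    p: np.ndarray
    q: np.ndarray


@dataclass(frozen=True)
class AssociationResult:
    assay_id: str
    protein_id: str
    outcome: str
    beta_sleep: float
    se: float
    t_mod: float
    p: float
    q: float
    direction: str  # "up" iff beta_sleep > 0

    def __post_init__(self) -> None:
        expected = "up" if self.beta_sleep > 0 else "down"
        if self.direction != expected:
            raise ValueError("direction inconsistent with beta sign")


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def prepare_design(
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    outcome: Outcome,
    *,
    quadratic: bool = False,
) -> pd.DataFrame:
    """Assemble the per-participant design matrix for one sleep outcome.

    Columns: intercept, sleep_z (standardized outcome), optionally
    sleep_z_sq (its centered square), then the adjustment covariates with
    daily steps standardized and comorbidities as 0/1 indicators. The
    matrix must be full column rank on the included participants.
    """
    if outcome not in OUTCOME_FIELDS:
        raise ValueError(f"unknown outcome {outcome!r}")
    missing = [p for p in phenotypes.index if p not in covariates.index]
    if missing:
        raise ValueError(f"covariate table missing participants {missing[:5]}")
    cov = covariates.loc[phenotypes.index]
    sleep = phenotypes[OUTCOME_FIELDS[outcome]].to_numpy(dtype=float)
    design = pd.DataFrame(index=phenotypes.index.copy())
    design["intercept"] = 1.0
    design["sleep_z"] = _zscore(sleep)
    if quadratic:
        sq = design["sleep_z"].to_numpy() ** 2
        design["sleep_z_sq"] = sq - sq.mean()
    design["age"] = cov["age"].to_numpy(dtype=float)
    design["sex"] = cov["sex"].to_numpy(dtype=float)
    design["bmi"] = cov["bmi"].to_numpy(dtype=float)
    design["steps_z"] = _zscore(cov["avg_steps"].to_numpy(dtype=float))
    for c in ("metabolic_disease", "hypertension", "arrhythmia_hf"):
        vals = cov[c].to_numpy(dtype=float)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError(f"covariate {c} must be binary 0/1")
        if vals.min() == vals.max():
            # a comorbidity absent (or universal) in the cohort adjusts for
            # nothing and would make the design singular
            warnings.warn(f"covariate {c} is constant in this cohort; dropped")
            continue
        design[c] = vals
    design["cystatin_c"] = cov["cystatin_c"].to_numpy(dtype=float)

    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns past the numerical rank in a pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = [design.columns[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; collinear columns {bad}")
    return design


# ---------------------------------------------------------------------------
# LASSO coordinate descent
# ---------------------------------------------------------------------------


def _soft_threshold(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def lasso_objective(X, y, beta, lam, penalty) -> float:
    n = len(y)
    r = y - X @ beta
    return float(0.5 / n * r @ r + lam * np.abs(beta) @ penalty)


def _cd_sweep(G, c, lam, penalty, beta, g, idx) -> float:
    """One pass of coordinate updates over ``idx``; returns max scaled step.

    ``G`` = X'X/n, ``c`` = X'y/n, ``g`` = G @ beta maintained incrementally.
    """
    max_step = 0.0
    for j in idx:
        gjj = G[j, j]
        if gjj <= 0.0:
            continue
        rho = c[j] - g[j] + gjj * beta[j]
        if penalty[j] > 0.0:
            bj = _soft_threshold(rho, lam * penalty[j]) / gjj
        else:
            bj = rho / gjj
        delta = bj - beta[j]
        if delta != 0.0:
            beta[j] = bj
            g += G[:, j] * delta
            step = abs(delta) * np.sqrt(gjj)
            if step > max_step:
                max_step = step
    return max_step


def _cd_solve_py(G, c, lam, penalty, beta, tol, max_sweeps) -> int:
    """Reference active-set solve loop (pure NumPy); returns sweeps used."""
    g = G @ beta
    all_idx = np.arange(G.shape[0])
    sweeps = 0
    while sweeps < max_sweeps:
        step = _cd_sweep(G, c, lam, penalty, beta, g, all_idx)
        sweeps += 1
        if step < tol:
            return sweeps
        active = np.flatnonzero((beta != 0.0) | (penalty == 0.0))
        while sweeps < max_sweeps:
            step = _cd_sweep(G, c, lam, penalty, beta, g, active)
            sweeps += 1
            if step < tol:
                break
    return sweeps


try:  # compiled fast path; semantics identical to _cd_solve_py
    from numba import njit

    @njit(cache=True)
    def _cd_solve_jit(G, c, lam, penalty, beta, tol, max_sweeps):  # pragma: no cover
        p = G.shape[0]
        g = G @ beta
        active = np.empty(p, dtype=np.int64)
        sweeps = 0
        while sweeps < max_sweeps:
            max_step = 0.0
            for j in range(p):
                gjj = G[j, j]
                if gjj <= 0.0:
                    continue
                rho = c[j] - g[j] + gjj * beta[j]
                if penalty[j] > 0.0:
                    t = lam * penalty[j]
                    if rho > t:
                        bj = (rho - t) / gjj
                    elif rho < -t:
                        bj = (rho + t) / gjj
                    else:
                        bj = 0.0
                else:
                    bj = rho / gjj
                delta = bj - beta[j]
                if delta != 0.0:
                    beta[j] = bj
                    for i in range(p):
                        g[i] += G[i, j] * delta
                    step = abs(delta) * np.sqrt(gjj)
                    if step > max_step:
                        max_step = step
            sweeps += 1
            if max_step < tol:
                return sweeps
            n_act = 0
            for j in range(p):
                if beta[j] != 0.0 or penalty[j] == 0.0:
                    active[n_act] = j
                    n_act += 1
            while sweeps < max_sweeps:
                max_step = 0.0
                for a in range(n_act):
                    j = active[a]
                    gjj = G[j, j]
                    if gjj <= 0.0:
                        continue
                    rho = c[j] - g[j] + gjj * beta[j]
                    if penalty[j] > 0.0:
                        t = lam * penalty[j]
                        if rho > t:
                            bj = (rho - t) / gjj
                        elif rho < -t:
                            bj = (rho + t) / gjj
                        else:
                            bj = 0.0
                    else:
                        bj = rho / gjj
                    delta = bj - beta[j]
                    if delta != 0.0:
                        beta[j] = bj
                        for i in range(p):
                            g[i] += G[i, j] * delta
                        step = abs(delta) * np.sqrt(gjj)
                        if step > max_step:
                            max_step = step
                sweeps += 1
                if max_step < tol:
                    break
        return sweeps

    _cd_solve = _cd_solve_jit
except ImportError:  # pragma: no cover
    _cd_solve = _cd_solve_py


def lasso_coordinate_descent(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    penalty: np.ndarray | None = None,
    *,
    beta0: np.ndarray | None = None,
    gram: np.ndarray | None = None,
    xty: np.ndarray | None = None,
    tol: float = 1e-8,
    max_sweeps: int = 10_000,
) -> np.ndarray:
    """Solve (1/2n)||y - Xb||^2 + lam * sum_j penalty_j |b_j| by CD.

    ``penalty`` holds per-coefficient weights (0 leaves a column
    unpenalized, e.g. confounders); default is 1 for every column.
    Active-set strategy: full sweeps alternate with sweeps restricted to
    the currently non-zero set until a full sweep moves nothing.
    """
    n, p = X.shape
    if lam < 0:
        raise ValueError("lam must be non-negative")
    penalty = np.ones(p) if penalty is None else np.asarray(penalty, dtype=float)
    G = np.ascontiguousarray((X.T @ X) / n if gram is None else gram)
    c = np.ascontiguousarray((X.T @ y) / n if xty is None else xty, dtype=float)
    beta = np.zeros(p) if beta0 is None else beta0.astype(float).copy()
    sweeps = _cd_solve(G, c, float(lam), penalty, beta, float(tol), int(max_sweeps))
    if sweeps >= max_sweeps:
        warnings.warn("lasso coordinate descent hit max_sweeps without converging")
    return beta


def lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: Sequence[float],
    penalty: np.ndarray | None = None,
    *,
    tol: float = 1e-8,
    dfmax: int | None = None,
) -> np.ndarray:
    """Warm-started solutions along a decreasing lambda sequence.

    Returns an array of shape (len(lambdas), p). When ``dfmax`` is set,
    the path stops refining once a solution holds more than ``dfmax``
    non-zero penalized coefficients (the saturated, non-unique regime);
    later grid points reuse that solution.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0 or np.any(np.diff(lambdas) > 0):
        raise ValueError("lambda grid must be non-empty and non-increasing")
    n, p = X.shape
    G = (X.T @ X) / n
    c = (X.T @ y) / n
    betas = np.zeros((lambdas.size, p))
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        beta = lasso_coordinate_descent(
            X, y, lam, penalty, beta0=beta, gram=G, xty=c, tol=tol
        )
        betas[i] = beta
        if dfmax is not None and np.count_nonzero(beta) > dfmax:
            betas[i + 1 :] = beta
            break
    return betas


def _lambda_grid(X, y, penalty, n_lambda: int, eps: float) -> np.ndarray:
    """Grid from lambda_max (all penalized coefs zero) down to eps*lambda_max.

    With unpenalized columns present, lambda_max is computed on the
    residual after projecting y onto the unpenalized columns.
    """
    n = len(y)
    free = np.flatnonzero(penalty == 0.0)
    resid = y.astype(float)
    if free.size:
        Z = X[:, free]
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ coef
    pen = np.flatnonzero(penalty > 0.0)
    corr = np.abs(X[:, pen].T @ resid) / n / penalty[pen]
    lam_max = float(corr.max())
    if not np.isfinite(lam_max) or lam_max <= 0:
        raise ValueError(
            "degenerate lambda grid: no penalized predictor correlates with "
            "the outcome"
        )
    return np.geomspace(lam_max, lam_max * eps, n_lambda)


def lasso_screen(
    npx: NPXMatrix,
    design: pd.DataFrame,
    outcome_vector: np.ndarray | None = None,
    *,
    lambda_rule: Literal["cv-min", "cv-1se"] = "cv-min",
    seed: int = 0,
    n_folds: int = 10,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-2,
    penalize_covariates: bool = False,
) -> tuple[list[str], dict]:
    """Shortlist assays with non-zero LASSO coefficients for the outcome.

    The regression predicts the standardized sleep outcome (``sleep_z``
    from ``design`` unless ``outcome_vector`` is given) from all assay
    columns plus the design covariates. Assay columns are median-imputed
    (screening only; the per-assay fits later use untouched data) and
    standardized internally; covariates are unpenalized by default.
    lambda is chosen by seeded K-fold cross-validation: the CV-error
    minimizer (``cv-min``) or the largest lambda within one standard
    error of it (``cv-1se``).

    Unpenalized covariates are handled by projecting them out of the
    outcome and the assay columns before coordinate descent
    (Frisch-Waugh partialling): the penalized coefficients of the joint
    problem are exactly those of the LASSO on the partialled data, and
    the partialled problem is far better conditioned. During CV the
    projection is refit on each training fold and held-out folds are
    predicted with the joint model (covariate back-solve plus penalized
    part), so no information crosses fold boundaries through the
    projection.
    """
    participants = list(design.index)
    vals = npx.values.reindex(index=participants)
    y = (
        design["sleep_z"].to_numpy(dtype=float)
        if outcome_vector is None
        else np.asarray(outcome_vector, dtype=float)
    )
    n = len(y)
    if n != len(vals):
        raise ValueError("outcome vector and NPX participants disagree")

    # median imputation then standardization of assay columns
    assay_ids = [a for a in vals.columns if vals[a].notna().sum() >= 3 and vals[a].std() > 0]
    if not assay_ids:
        return [], {
            "lambda": None,
            "lambda_grid": np.array([]),
            "cv_mean_error": np.array([]),
            "cv_se_error": np.array([]),
            "n_selected": 0,
            "coefficients": {},
        }
    A = vals[assay_ids].to_numpy(dtype=float)
    med = np.nanmedian(A, axis=0)
    nan_mask = np.isnan(A)
    A[nan_mask] = np.take(med, np.nonzero(nan_mask)[1])
    A = (A - A.mean(axis=0)) / A.std(axis=0, ddof=1)

    cov_cols = [c for c in design.columns if c not in ("sleep_z", "sleep_z_sq")]
    Z = design[cov_cols].to_numpy(dtype=float)
    if penalize_covariates:
        # covariates join the penalized block (standardized; the intercept
        # is still projected out)
        keep = [c for c in cov_cols if c != "intercept"]
        Zk = design[keep].to_numpy(dtype=float)
        Zk = (Zk - Zk.mean(axis=0)) / Zk.std(axis=0, ddof=1)
        A = np.hstack([A, Zk])
        Z = design[["intercept"]].to_numpy(dtype=float)
    penalty = np.ones(A.shape[1])

    def _partial(Zm, Am, ym):
        # Frisch-Waugh: residualize the penalized block and outcome on Z
        Q, _ = np.linalg.qr(Zm)
        return Am - Q @ (Q.T @ Am), ym - Q @ (Q.T @ ym), Q

    X_full, y_full, _ = _partial(Z, A, y)
    lambdas = _lambda_grid(X_full, y_full, penalty, n_lambda, lambda_min_ratio)
    screen_tol = 1e-6  # selection is insensitive to tighter optimization
    dfmax = n  # saturated solutions cannot win CV and are not unique

    rng = np.random.default_rng(seed)
    fold_of = np.repeat(np.arange(n_folds), -(-n // n_folds))[:n]
    rng.shuffle(fold_of)
    cv_err = np.zeros((n_folds, len(lambdas)))
    for k in range(n_folds):
        tr = fold_of != k
        te = ~tr
        Xtr, ytr, Qtr = _partial(Z[tr], A[tr], y[tr])
        betas = lasso_path(Xtr, ytr, lambdas, penalty, tol=screen_tol, dfmax=dfmax)
        # covariate coefficients back-solved per lambda on the training fold
        fit_tr = A[tr] @ betas.T
        a_all, *_ = np.linalg.lstsq(Z[tr], y[tr, None] - fit_tr, rcond=None)
        pred = Z[te] @ a_all + A[te] @ betas.T
        cv_err[k] = ((pred - y[te, None]) ** 2).mean(axis=0)
    mean_err = cv_err.mean(axis=0)
    se_err = cv_err.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(mean_err.argmin())
    if lambda_rule == "cv-min":
        i_sel = i_min
    elif lambda_rule == "cv-1se":
        within = np.flatnonzero(mean_err <= mean_err[i_min] + se_err[i_min])
        i_sel = int(within.min())  # grid is decreasing: smallest index = largest lambda
    else:
        raise ValueError(f"unknown lambda rule {lambda_rule!r}")

    beta_full = lasso_path(X_full, y_full, lambdas[: i_sel + 1], penalty, tol=screen_tol)[-1]
    selected = [assay_ids[j] for j in np.flatnonzero(beta_full[: len(assay_ids)])]
    info = {
        "lambda": float(lambdas[i_sel]),
        "lambda_grid": lambdas,
        "cv_mean_error": mean_err,
        "cv_se_error": se_err,
        "n_selected": len(selected),
        "coefficients": dict(zip(assay_ids, beta_full[: len(assay_ids)])),
    }
    return selected, info


# ---------------------------------------------------------------------------
# per-assay OLS
# ---------------------------------------------------------------------------


def fit_assay(
    npx_column: pd.Series,
    design: pd.DataFrame,
    *,
    assay_id: str | None = None,
    term: str = "sleep_z",
) -> AssayFit | None:
    """OLS of one assay's NPX on the design over its non-missing rows.

    Returns ``None`` (unusable) when too few rows remain or the design
    loses full rank on them.
    """
    assay_id = assay_id if assay_id is not None else str(npx_column.name)
    ycol = npx_column.reindex(design.index)
    mask = ycol.notna().to_numpy()
    X = design.to_numpy(dtype=float)[mask]
    yv = ycol.to_numpy(dtype=float)[mask]
    n_used, k = X.shape
    if n_used < k + 3:
        return None
    j = design.columns.get_loc(term)
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return None
    if np.linalg.matrix_rank(X) < k:
        return None
    beta_all = XtX_inv @ (X.T @ yv)
    resid = yv - X @ beta_all
    df_resid = n_used - k
    sigma2 = float(resid @ resid) / df_resid
    return AssayFit(
        assay_id=assay_id,
        beta=float(beta_all[j]),
        se_unscaled=float(np.sqrt(XtX_inv[j, j])),
        sigma2=sigma2,
        df_resid=df_resid,
        n_used=n_used,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    f = lambda y: special.polygamma(1, y) - x
    lo, hi = 1e-12, 1e12
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12, maxiter=200))


def estimate_prior(sigma2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match the scaled-F prior (d0, s0^2) on observed log variances.

    Under the hierarchical model, log(s_g^2) has expectation
    log(s0^2) + digamma(df_g/2) - log(df_g/2) - digamma(d0/2) + log(d0/2)
    and excess variance trigamma(d0/2) beyond trigamma(df_g/2); the
    trigamma equation is inverted for d0, falling back to d0 = +inf when
    the observed spread does not exceed the sampling floor.
    """
    pos = sigma2 > 0
    if not np.any(pos):
        raise ValueError("all residual variances are zero; degenerate inputs")
    s2 = sigma2[pos]
    dfp = df[pos].astype(float)
    e = np.log(s2) - special.digamma(dfp / 2.0) + np.log(dfp / 2.0)
    emean = e.mean()
    if e.size < 2:
        return np.inf, float(np.exp(emean))
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, dfp / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    half_d0 = _trigamma_inverse(evar)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_sq


def squeeze_variance(sigma2, df, d0: float, s0_sq: float) -> np.ndarray:
    """Posterior variance s_tilde^2 = (d0 s0^2 + df s^2) / (d0 + df).

    The d0 = 0 limit returns the observed variances unchanged (no
    shrinkage); d0 = +inf collapses every variance to the prior s0^2.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.isinf(d0):
        return np.full_like(sigma2, s0_sq)
    return (d0 * s0_sq + df * sigma2) / (d0 + df)


def moderate(fits: Sequence[AssayFit]) -> ModerationState:
    """Shrink per-assay variances and compute moderated t, p and BH q.

    s_tilde^2 = (d0 s0^2 + df s^2) / (d0 + df); the moderated t uses the
    shrunken variance and gains d0 degrees of freedom.
    """
    if len(fits) < 2:
        raise ValueError("moderation needs at least two assay fits")
    sigma2 = np.array([f.sigma2 for f in fits])
    df = np.array([f.df_resid for f in fits])
    if np.all(sigma2 == 0):
        raise ValueError("all residual variances are zero; degenerate inputs")
    d0, s0_sq = estimate_prior(sigma2, df)
    s_tilde_sq = squeeze_variance(sigma2, df, d0, s0_sq)
    if np.isinf(d0):
        df_total = np.full_like(sigma2, np.inf)
    else:
        df_total = d0 + df.astype(float)
    beta = np.array([f.beta for f in fits])
    seu = np.array([f.se_unscaled for f in fits])
    with np.errstate(divide="ignore"):
        t_mod = beta / (seu * np.sqrt(s_tilde_sq))
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t_mod)),
        2.0 * stats.t.sf(np.abs(t_mod), np.where(np.isinf(df_total), 1.0, df_total)),
    )
    q = bh_adjust(p)
    return ModerationState(
        assay_ids=[f.assay_id for f in fits],
        d0=float(d0),
        s0_sq=float(s0_sq),
        s_tilde_sq=s_tilde_sq,
        t_mod=t_mod,
        df_total=df_total,
        p=p,
        q=q,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1; input order is
    preserved in the output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_association(
    npx: NPXMatrix,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    outcome: Outcome,
    *,
    quadratic: bool = False,
    lambda_rule: Literal["cv-min", "cv-1se"] = "cv-min",
    seed: int = 0,
    q_threshold: float = SIGNIFICANCE_Q,
) -> tuple[list[AssociationResult], dict]:
    """LASSO screen -> per-assay fits -> moderation -> BH over the shortlist.

    Returns every screened-and-fitted assay's result (sorted by p) and an
    info dict with the screening diagnostics and counts; callers declare
    significance at ``q < q_threshold``. For quadratic runs the reported
    test is on the quadratic coefficient.
    """
    design = prepare_design(phenotypes, covariates, outcome, quadratic=quadratic)
    selected, screen_info = lasso_screen(
        npx, design.drop(columns=["sleep_z_sq"], errors="ignore"),
        design["sleep_z"].to_numpy(),
        lambda_rule=lambda_rule,
        seed=seed,
    )
    term = "sleep_z_sq" if quadratic else "sleep_z"
    info = {
        "outcome": outcome,
        "n_screened": len(selected),
        "screen": screen_info,
        "skipped_assays": [],
        "term": term,
    }
    if not selected:
        warnings.warn(f"LASSO selected no assays for outcome {outcome!r}")
        return [], info

    fits: list[AssayFit] = []
    for a in selected:
        fit = fit_assay(npx.values[a], design, assay_id=a, term=term)
        if fit is None:
            info["skipped_assays"].append(a)
        else:
            fits.append(fit)
    if not fits:
        warnings.warn("no screened assay had enough non-missing samples to fit")
        return [], info

    if len(fits) == 1:
        warnings.warn(
            "single screened assay: no ensemble to borrow variance from; "
            "reporting the ordinary t-statistic"
        )
        f = fits[0]
        t = f.beta / f.se_raw if f.se_raw > 0 else np.inf
        p = 2.0 * stats.t.sf(abs(t), f.df_resid)
        state = ModerationState(
            assay_ids=[f.assay_id],
            d0=0.0,
            s0_sq=float(f.sigma2),
            s_tilde_sq=np.array([f.sigma2]),
            t_mod=np.array([t]),
            df_total=np.array([float(f.df_resid)]),
            p=np.array([p]),
            q=np.array([p]),
        )
    else:
        state = moderate(fits)
    info["moderation"] = {"d0": state.d0, "s0_sq": state.s0_sq}

    protein_of = npx.assays["protein_id"]
    results = [
        AssociationResult(
            assay_id=f.assay_id,
            protein_id=str(protein_of.get(f.assay_id, f.assay_id)),
            outcome=outcome,
            beta_sleep=f.beta,
            se=f.se_unscaled * float(np.sqrt(state.s_tilde_sq[i])),
            t_mod=float(state.t_mod[i]),
            p=float(state.p[i]),
            q=float(state.q[i]),
            direction="up" if f.beta > 0 else "down",
        )
        for i, f in enumerate(fits)
    ]
    results.sort(key=lambda r: (r.p, r.assay_id))
    info["n_significant"] = sum(r.q < q_threshold for r in results)
    return results, info
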